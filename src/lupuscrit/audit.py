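"""Internal-consistency audit of printed performance tables.

A printed row (sensitivity %, specificity %, accuracy %, group sizes)
over-determines itself: the one-decimal rates pin down unique integer
true-positive and true-negative counts, from which the accuracy can be
re-derived and compared with the printed value.
"""

from __future__ import annotations

from dataclasses import dataclass

from .evaluation import reconstruct_count, round_half_away
from .reference_tables import ReportedRow


@dataclass(frozen=True)
class AuditResult:
    row: ReportedRow
    tp: int
    tn: int
    accuracy_recomputed_pct: float
    accuracy_matches: bool


def audit_row(row: ReportedRow) -> AuditResult:
    """Reconstruct the TP/TN counts a printed row implies and re-derive
    its accuracy to one decimal."""
    tp = reconstruct_count(row.sensitivity_pct, row.n_cases)
    tn = reconstruct_count(row.specificity_pct, row.n_controls)
    acc = round_half_away(100.0 * (tp + tn) / (row.n_cases + row.n_controls), 1)
    return AuditResult(
        row=row,
        tp=tp,
        tn=tn,
        accuracy_recomputed_pct=acc,
        accuracy_matches=abs(acc - row.accuracy_pct) < 1e-9,
    )


def audit_rows(rows: tuple[ReportedRow, ...]) -> list[AuditResult]:
    return [audit_row(r) for r in rows]
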