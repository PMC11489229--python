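"""Reported diagnostic-performance figures for the four SLE criteria sets
in a 435-case / 430-control Colombian autoimmune cohort, as printed
(percentages rounded half away from zero to one decimal).

These are *inputs* to the internal-consistency audit: for each row the
integer true-positive / true-negative counts implied by the printed
sensitivity, specificity and group sizes are reconstructed with
:func:`lupuscrit.evaluation.reconstruct_count`, and the accuracy is
re-derived from those counts and compared with the printed value.

The without-polyautoimmunity SLERPI row is flagged ``consistent=False``:
the counts implied by 94.6% of 355 and 93.7% of 430 (336 and 403) give an
accuracy of 94.14% -> 94.1, while the printed accuracy is 94.2 — a
printed-rounding inconsistency that the audit is expected to surface, not
to silence.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ReportedRow:
    """One printed performance row: rates in percent, group sizes."""

    label: str
    criteria: str
    sensitivity_pct: float
    specificity_pct: float
    accuracy_pct: float
    n_cases: int
    n_controls: int
    consistent: bool = True  # False: printed accuracy known not to be integer-consistent


N_CASES = 435
N_CONTROLS = 430
N_CASES_WITHOUT_POLYA = 355

#: Overall performance by overt-polyautoimmunity stratum.
PERFORMANCE_BY_POLYA: tuple[ReportedRow, ...] = (
    ReportedRow("all SLE", "ACR-1997", 91.0, 98.8, 94.9, N_CASES, N_CONTROLS),
    ReportedRow("all SLE", "SLICC-2012", 94.5, 97.2, 95.8, N_CASES, N_CONTROLS),
    ReportedRow("all SLE", "EULAR/ACR-2019", 92.4, 93.3, 92.8, N_CASES, N_CONTROLS),
    ReportedRow("all SLE", "SLERPI", 95.4, 92.8, 94.1, N_CASES, N_CONTROLS),
    ReportedRow("SLE without PolyA", "ACR-1997", 90.4, 98.8, 95.0, N_CASES_WITHOUT_POLYA, N_CONTROLS),
    ReportedRow("SLE without PolyA", "SLICC-2012", 93.2, 97.2, 95.4, N_CASES_WITHOUT_POLYA, N_CONTROLS),
    ReportedRow("SLE without PolyA", "EULAR/ACR-2019", 91.5, 93.3, 92.5, N_CASES_WITHOUT_POLYA, N_CONTROLS),
    ReportedRow("SLE without PolyA", "SLERPI", 94.6, 93.7, 94.2, N_CASES_WITHOUT_POLYA, N_CONTROLS, consistent=False),
)

#: SLERPI performance by clinical subphenotype (specificity always over
#: the full control group, hence identical across rows).
PERFORMANCE_BY_SUBPHENOTYPE: tuple[ReportedRow, ...] = (
    ReportedRow("neuropsychiatric lupus", "SLERPI", 93.2, 92.8, 92.9, 88, N_CONTROLS),
    ReportedRow("lupus nephritis", "SLERPI", 96.0, 92.8, 93.5, 125, N_CONTROLS),
    ReportedRow("hematological lupus", "SLERPI", 98.8, 92.8, 94.5, 173, N_CONTROLS),
)

ALL_REPORTED_ROWS: tuple[ReportedRow, ...] = PERFORMANCE_BY_POLYA + PERFORMANCE_BY_SUBPHENOTYPE

#: Reported 95% CI for the overall SLERPI sensitivity (415/435).
SLERPI_SENSITIVITY_CI_PCT = (93.0, 97.2)
#: Reported AUC of the SLERPI score against the control group.
REPORTED_AUC = 0.987
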