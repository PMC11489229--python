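"""Synthetic case-control cohort generator.

Emulates the feature structure of a 435-case / 430-control autoimmune
case-control study: per-group Bernoulli prevalences for the 14-feature
SLERPI panel, an 18.4% overt-polyautoimmunity frequency in both groups, a
control group mixing six non-SLE index diseases, and SLE subphenotype
flags (neuropsychiatric, nephritis, hematological) coupled by default to
the features that define them clinically.

Features are drawn independently per subject by default; Table-style
summary statistics constrain only the marginals, so dependence between
features is opt-in through a Gaussian-copula latent-threshold scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy.stats import norm

from .records import (
    AUX_FEATURES,
    SLERPI_FEATURES,
    Group,
    IndexDisease,
    PatientRecord,
    Sex,
    Subphenotype,
)

#: Per-group feature prevalences of the emulated study population
#: (cases: SLE; controls: other autoimmune diseases).
CASE_PREVALENCE: dict[str, float] = {
    "malar_rash": 0.480,
    "scle_dle": 0.147,
    "alopecia": 0.526,
    "mucosal_ulcers": 0.391,
    "arthritis": 0.747,
    "serositis": 0.331,
    "neurological_disorder": 0.202,
    "leucopenia": 0.402,
    "thrombocytopenia_aiha": 0.103,
    "proteinuria": 0.285,
    "ana": 0.933,
    "low_c3_c4": 0.389,
    "immunological_disorder": 0.871,
    "ild": 0.0,
}

CONTROL_PREVALENCE: dict[str, float] = {
    "malar_rash": 0.002,
    "scle_dle": 0.0,
    "alopecia": 0.030,
    "mucosal_ulcers": 0.002,
    "arthritis": 0.674,
    "serositis": 0.0,
    "neurological_disorder": 0.033,
    "leucopenia": 0.074,
    "thrombocytopenia_aiha": 0.014,
    "proteinuria": 0.005,
    "ana": 0.588,
    "low_c3_c4": 0.016,
    "immunological_disorder": 0.123,
    "ild": 0.005,
}

#: Control-group index-disease composition (counts for n_control = 430).
CONTROL_DISEASE_MIX: dict[str, int] = {
    "RA": 253,
    "SS": 56,
    "AITD": 43,
    "MS": 47,
    "SSc": 30,
    "APS": 1,
}

#: (median, q1, q3) in years for the cosmetic age variables.
_AGE_QUARTILES = {
    "case": {"age": (48.0, 37.0, 59.0), "onset": (26.5, 19.0, 36.0), "dx": (28.5, 22.0, 40.0)},
    "control": {"age": (64.0, 54.0, 70.5), "onset": (40.0, 29.0, 50.0), "dx": (44.0, 33.5, 53.0)},
}

_FEMALE_FREQ = {"case": 0.913, "control": 0.851}


class CohortSpec(BaseModel):
    """Generator parameters; :func:`default_spec` fills in the emulated study."""

    n_case: int = Field(gt=0)
    n_control: int = Field(gt=0)
    prevalence: dict[str, dict[str, float]]
    polyA_freq: dict[str, float]
    control_disease_mix: dict[str, float]
    subphenotype_rule: str = "feature_coupled"
    correlation: Optional[list[list[float]]] = None
    seed: int = 0

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _validate(self) -> "CohortSpec":
        for grp in ("case", "control"):
            if grp not in self.prevalence:
                raise ValueError(f"prevalence must define group {grp!r}")
            for feat, p in self.prevalence[grp].items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"prevalence[{grp}][{feat}]={p} outside [0,1]")
            if not 0.0 <= self.polyA_freq.get(grp, 0.0) <= 1.0:
                raise ValueError("polyA_freq outside [0,1]")
        if set(self.prevalence["case"]) != set(self.prevalence["control"]):
            raise ValueError("case and control prevalence maps must share features")
        if self.subphenotype_rule not in ("feature_coupled", "independent"):
            raise ValueError("subphenotype_rule must be feature_coupled|independent")
        unknown = set(self.control_disease_mix) - {d.value for d in IndexDisease} | (
            set(self.control_disease_mix) & {"SLE"}
        )
        if unknown:
            raise ValueError(f"invalid control index diseases: {sorted(unknown)}")
        total = sum(self.control_disease_mix.values())
        if not (
            abs(total - self.n_control) < 1e-9 or abs(total - 1.0) < 1e-9
        ):
            raise ValueError(
                f"control_disease_mix must sum to n_control ({self.n_control}) "
                f"or to 1.0 as proportions; got {total}"
            )
        if self.correlation is not None:
            R = np.asarray(self.correlation, dtype=float)
            k = len(self.feature_order)
            if R.shape != (k, k):
                raise ValueError(f"correlation must be {k}x{k} over the feature order")
            if not np.allclose(R, R.T, atol=1e-10):
                raise ValueError("correlation matrix must be symmetric")
            if not np.allclose(np.diag(R), 1.0, atol=1e-10):
                raise ValueError("correlation matrix must have unit diagonal")
            if np.linalg.eigvalsh(R).min() < -1e-8:
                raise ValueError("correlation matrix must be positive semidefinite")
        return self

    @property
    def feature_order(self) -> tuple[str, ...]:
        """Feature order used for drawing and for the correlation matrix."""
        return tuple(self.prevalence["case"].keys())


@dataclass
class CohortTable:
    records: list[PatientRecord]
    spec_used: CohortSpec
    seed_used: int

    def __len__(self) -> int:
        return len(self.records)

    def cases(self) -> list[PatientRecord]:
        return [r for r in self.records if r.group is Group.case]

    def controls(self) -> list[PatientRecord]:
        return [r for r in self.records if r.group is Group.control]

    def to_dataframe(self) -> pd.DataFrame:
        from .io import cohort_to_dataframe

        return cohort_to_dataframe(self)


def default_spec(seed: int = 0) -> CohortSpec:
    """The emulated study population: 435 SLE cases vs 430 autoimmune
    controls, 14-feature marginal prevalences, overt polyautoimmunity at
    18.4% in both groups, and the six-disease control mix.

    Auxiliary vocabulary features not summarized in the source population
    (anemia, biopsy findings, individual autoantibodies, fever,
    photosensitivity) default to prevalence 0 in both groups and can be
    overridden through the ``prevalence`` maps.
    """
    case = dict(CASE_PREVALENCE)
    control = dict(CONTROL_PREVALENCE)
    for aux in AUX_FEATURES:
        case[aux] = 0.0
        control[aux] = 0.0
    return CohortSpec(
        n_case=435,
        n_control=430,
        prevalence={"case": case, "control": control},
        polyA_freq={"case": 0.184, "control": 0.184},
        control_disease_mix={k: float(v) for k, v in CONTROL_DISEASE_MIX.items()},
        seed=seed,
    )


def _draw_features(
    rng: np.random.Generator,
    n: int,
    probs: np.ndarray,
    correlation: Optional[np.ndarray],
) -> np.ndarray:
    """n x k binary matrix with marginals ``probs``; Gaussian copula when
    a correlation matrix is given, independent Bernoulli otherwise."""
    if correlation is None:
        return (rng.random((n, len(probs))) < probs).astype(np.int8)
    # latent thresholding: X_j = 1  iff  Z_j <= Phi^{-1}(p_j)
    k = len(probs)
    w, V = np.linalg.eigh(correlation)
    L = V * np.sqrt(np.clip(w, 0.0, None))  # PSD-safe factor
    z = rng.standard_normal((n, k)) @ L.T
    with np.errstate(divide="ignore"):
        thresh = norm.ppf(probs)  # -inf at p=0, +inf at p=1
    return (z <= thresh).astype(np.int8)


def _sample_ages(rng: np.random.Generator, n: int, quartiles: tuple[float, float, float]) -> np.ndarray:
    # log-normal matched to the printed median and IQR
    med, q1, q3 = quartiles
    mu = np.log(med)
    sigma = np.log(q3 / q1) / (2 * norm.ppf(0.75))
    return np.round(np.exp(rng.normal(mu, sigma, size=n)), 1)


def _mix_counts(mix: dict[str, float], n_control: int) -> dict[str, int]:
    total = sum(mix.values())
    if abs(total - 1.0) < 1e-9 and n_control != 1:
        # proportions -> integer counts by largest remainder
        raw = {d: p * n_control for d, p in mix.items()}
        counts = {d: int(np.floor(v)) for d, v in raw.items()}
        short = n_control - sum(counts.values())
        for d in sorted(raw, key=lambda d: raw[d] - counts[d], reverse=True)[:short]:
            counts[d] += 1
        return counts
    return {d: int(round(v)) for d, v in mix.items()}


def generate_cohort(spec: CohortSpec, seed: Optional[int] = None) -> CohortTable:
    """Draw a cohort; fully reproducible from ``spec`` and the seed
    (argument overrides ``spec.seed``)."""
    seed_used = spec.seed if seed is None else seed
    streams = np.random.SeedSequence(seed_used).spawn(6)
    rng_feat, rng_polya, rng_mix, rng_sub, rng_age, rng_sex = (
        np.random.default_rng(s) for s in streams
    )

    order = spec.feature_order
    R = np.asarray(spec.correlation, dtype=float) if spec.correlation is not None else None
    groups = {
        "case": spec.n_case,
        "control": spec.n_control,
    }
    feats = {
        grp: _draw_features(
            rng_feat, n, np.array([spec.prevalence[grp][f] for f in order]), R
        )
        for grp, n in groups.items()
    }
    polya = {
        grp: (rng_polya.random(n) < spec.polyA_freq.get(grp, 0.0)).astype(int)
        for grp, n in groups.items()
    }

    diseases = []
    for d, c in _mix_counts(spec.control_disease_mix, spec.n_control).items():
        diseases += [IndexDisease(d)] * c
    if len(diseases) != spec.n_control:
        raise ValueError(
            f"control_disease_mix resolves to {len(diseases)} controls, "
            f"expected {spec.n_control}"
        )
    rng_mix.shuffle(diseases)

    sub_rates = {"neuropsychiatric": 88 / 435, "nephritis": 125 / 435, "hematological": 173 / 435}
    records: list[PatientRecord] = []
    for grp, n in groups.items():
        ages = _sample_ages(rng_age, n, _AGE_QUARTILES[grp]["age"])
        onset = _sample_ages(rng_age, n, _AGE_QUARTILES[grp]["onset"])
        dx = _sample_ages(rng_age, n, _AGE_QUARTILES[grp]["dx"])
        female = rng_sex.random(n) < _FEMALE_FREQ[grp]
        indep_sub = {
            s: (rng_sub.random(n) < r).astype(int) for s, r in sub_rates.items()
        } if spec.subphenotype_rule == "independent" else None
        for i in range(n):
            fmap = {f: int(feats[grp][i, j]) for j, f in enumerate(order)}
            subs: set[Subphenotype] = set()
            if grp == "case":
                if spec.subphenotype_rule == "feature_coupled":
                    if fmap.get("neurological_disorder", 0):
                        subs.add(Subphenotype.neuropsychiatric)
                    if fmap.get("proteinuria", 0):
                        subs.add(Subphenotype.nephritis)
                    if fmap.get("leucopenia", 0) or fmap.get("thrombocytopenia_aiha", 0) or fmap.get("anemia", 0):
                        subs.add(Subphenotype.hematological)
                else:
                    subs = {Subphenotype(s) for s, flags in indep_sub.items() if flags[i]}
            records.append(
                PatientRecord(
                    id=f"{'SLE' if grp == 'case' else 'CTL'}-{i + 1:04d}",
                    group=Group(grp),
                    features=fmap,
                    polyA=int(polya[grp][i]),
                    index_disease=IndexDisease.SLE if grp == "case" else diseases[i],
                    subphenotypes=frozenset(subs),
                    age_years=float(ages[i]),
                    age_onset_years=float(min(onset[i], ages[i])),
                    age_dx_years=float(min(dx[i], ages[i])),
                    sex=Sex.F if female[i] else Sex.M,
                )
            )
    return CohortTable(records=records, spec_used=spec, seed_used=seed_used)


def empirical_prevalence(cohort: CohortTable, feature: str, group: Group | str) -> tuple[float, int]:
    """(proportion, count) of ``feature`` = 1 within a group."""
    group = Group(group)
    members = [r for r in cohort.records if r.group is group]
    if not members:
        raise ValueError(f"no records in group {group.value!r}")
    count = sum(r.feature(feature) for r in members)
    return count / len(members), count
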