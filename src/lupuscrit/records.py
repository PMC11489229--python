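"""Patient records and the binary feature vocabulary.

The core vocabulary is the 14-feature panel of the SLE Risk Probability
Index (SLERPI): twelve clinical/serological lupus manifestations, the
merged thrombocytopenia/autoimmune-hemolytic-anemia item, and interstitial
lung disease (the single feature that counts *against* lupus).  Auxiliary
features extend the vocabulary with items the comparator criteria sets
(ACR-1997, SLICC-2012, EULAR/ACR-2019) need but that a SLERPI-oriented
registry records separately or not at all.
"""

from __future__ import annotations

import enum
from typing import Optional

from pydantic import BaseModel, Field, field_validator, model_validator

#: The 14 SLERPI features, in conventional reporting order.
SLERPI_FEATURES: tuple[str, ...] = (
    "malar_rash",
    "scle_dle",
    "alopecia",
    "mucosal_ulcers",
    "arthritis",
    "serositis",
    "neurological_disorder",
    "leucopenia",
    "thrombocytopenia_aiha",
    "proteinuria",
    "ana",
    "low_c3_c4",
    "immunological_disorder",
    "ild",
)

#: Items required by the comparator criteria sets but outside the SLERPI panel.
AUX_FEATURES: tuple[str, ...] = (
    "anemia",
    "biopsy_proven_nephritis",
    "anti_dsdna",
    "anti_sm",
    "antiphospholipid",
    "direct_coombs",
    "photosensitivity",
    "fever",
)

VOCABULARY: tuple[str, ...] = SLERPI_FEATURES + AUX_FEATURES


class Group(str, enum.Enum):
    case = "case"
    control = "control"


class IndexDisease(str, enum.Enum):
    SLE = "SLE"
    RA = "RA"
    SS = "SS"
    AITD = "AITD"
    MS = "MS"
    SSc = "SSc"
    APS = "APS"


class Subphenotype(str, enum.Enum):
    neuropsychiatric = "neuropsychiatric"
    nephritis = "nephritis"
    hematological = "hematological"


class Sex(str, enum.Enum):
    F = "F"
    M = "M"


class PatientRecord(BaseModel):
    """One subject: binary feature map, group label, strata flags, demographics.

    Features absent from ``features`` are treated as 0 by every scoring
    engine (unobserved-is-absent, the usual retrospective-registry coding).
    """

    id: str
    group: Group
    features: dict[str, int] = Field(default_factory=dict)
    polyA: int = 0
    index_disease: Optional[IndexDisease] = None
    subphenotypes: frozenset[Subphenotype] = Field(default_factory=frozenset)
    age_years: Optional[float] = None
    age_onset_years: Optional[float] = None
    age_dx_years: Optional[float] = None
    sex: Optional[Sex] = None

    model_config = {"frozen": True}

    @field_validator("features")
    @classmethod
    def _check_features(cls, v: dict[str, int]) -> dict[str, int]:
        for name, val in v.items():
            if name not in VOCABULARY:
                raise ValueError(f"unknown feature {name!r} (not in vocabulary)")
            if val not in (0, 1):
                raise ValueError(f"feature {name!r} must be 0/1, got {val!r}")
        return v

    @field_validator("polyA")
    @classmethod
    def _check_polya(cls, v: int) -> int:
        if v not in (0, 1):
            raise ValueError("polyA must be 0 or 1")
        return v

    @field_validator("age_years", "age_onset_years", "age_dx_years")
    @classmethod
    def _check_ages(cls, v: Optional[float]) -> Optional[float]:
        if v is not None and v < 0:
            raise ValueError("ages must be nonnegative")
        return v

    @model_validator(mode="after")
    def _check_group_consistency(self) -> "PatientRecord":
        if self.group is Group.control and self.index_disease is IndexDisease.SLE:
            raise ValueError("control subjects cannot have SLE as index disease")
        if self.group is Group.control and self.subphenotypes:
            raise ValueError("subphenotype flags are only permitted for cases")
        return self

    def feature(self, name: str) -> int:
        """Value of a vocabulary feature; absent features read as 0."""
        if name not in VOCABULARY:
            raise KeyError(f"unknown feature {name!r} (not in vocabulary)")
        return self.features.get(name, 0)
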