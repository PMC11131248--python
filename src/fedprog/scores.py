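"""Clinical comparator rules: PESI, sPESI, and the PUMCH score.

Three additive point scores used at the bedside to stratify 30-day
mortality risk in acute pulmonary thromboembolism.  PESI sums the patient's
age in years with weighted comorbidity/vital-sign points; sPESI is its
simplified six-item one-point-each version; the PUMCH rule is a ten-item
score that additionally uses serum calcium <= 2.13 mmol/L.  Each scorer
returns a per-component breakdown so totals are auditable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort

__all__ = [
    "ClinicalRecord",
    "ScoreBreakdown",
    "pesi_score",
    "spesi_score",
    "pumch_score",
    "records_from_cohort",
    "score_cohort",
]


@dataclass(frozen=True)
class ClinicalRecord:
    """The raw-unit inputs the three rules need for one patient."""

    age: float
    male: bool = False
    cancer: bool = False
    chronic_heart_failure: bool = False
    chronic_pulmonary_disease: bool = False
    pulse_ge_110: bool = False
    sbp_lt_100: bool = False
    resp_gt_30: bool = False
    temp_lt_36: bool = False
    altered_mental_status: bool = False
    sao2_lt_90: bool = False
    calcium_le_2_13: bool = False

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError("age must be nonnegative")


@dataclass(frozen=True)
class ScoreBreakdown:
    """One rule's components (variable, points) and their total."""

    rule: str
    components: tuple[tuple[str, float], ...]
    total: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "components", tuple(self.components))
        if abs(self.total - sum(p for _, p in self.components)) > 1e-9:
            raise ValueError("total does not equal the component sum")


def _breakdown(rule: str, parts: list[tuple[str, float]]) -> ScoreBreakdown:
    present = [(name, pts) for name, pts in parts if pts != 0]
    return ScoreBreakdown(rule, tuple(present), float(sum(p for _, p in present)))


def pesi_score(record: ClinicalRecord) -> ScoreBreakdown:
    """Pulmonary Embolism Severity Index: age in years plus weighted items."""
    r = record
    parts = [
        ("age_years", float(r.age)),
        ("male_sex", 10.0 * r.male),
        ("cancer", 30.0 * r.cancer),
        ("chronic_heart_failure", 10.0 * r.chronic_heart_failure),
        ("chronic_pulmonary_disease", 10.0 * r.chronic_pulmonary_disease),
        ("pulse_ge_110", 20.0 * r.pulse_ge_110),
        ("sbp_lt_100", 30.0 * r.sbp_lt_100),
        ("resp_gt_30", 20.0 * r.resp_gt_30),
        ("temp_lt_36", 20.0 * r.temp_lt_36),
        ("altered_mental_status", 60.0 * r.altered_mental_status),
        ("sao2_lt_90", 20.0 * r.sao2_lt_90),
    ]
    return _breakdown("PESI", parts)


def spesi_score(record: ClinicalRecord) -> ScoreBreakdown:
    """Simplified PESI: one point per present factor, six factors."""
    r = record
    parts = [
        ("age_gt_80", 1.0 * (r.age > 80)),
        ("cancer", 1.0 * r.cancer),
        ("chronic_heart_failure", 1.0 * r.chronic_heart_failure),
        ("pulse_ge_110", 1.0 * r.pulse_ge_110),
        ("sbp_lt_100", 1.0 * r.sbp_lt_100),
        ("sao2_lt_90", 1.0 * r.sao2_lt_90),
    ]
    return _breakdown("sPESI", parts)


def pumch_score(record: ClinicalRecord) -> ScoreBreakdown:
    """The PUMCH rule: ten weighted items including low serum calcium."""
    r = record
    parts = [
        ("age_gt_80", 2.0 * (r.age > 80)),
        ("male_sex", 1.0 * r.male),
        ("cancer", 5.0 * r.cancer),
        ("chronic_heart_failure", 2.0 * r.chronic_heart_failure),
        ("chronic_pulmonary_disease", 3.0 * r.chronic_pulmonary_disease),
        ("pulse_ge_110", 3.0 * r.pulse_ge_110),
        ("sbp_lt_100", 3.0 * r.sbp_lt_100),
        ("altered_mental_status", 2.0 * r.altered_mental_status),
        ("sao2_lt_90", 1.0 * r.sao2_lt_90),
        ("calcium_le_2_13", 1.0 * r.calcium_le_2_13),
    ]
    return _breakdown("PUMCH", parts)


# Cohort column -> ClinicalRecord flag; flags are read from the discrete
# columns (mean-imputed binary cells round at 0.5, i.e. to the majority
# class), age from the continuous column.
_FLAG_COLUMNS = (
    "male_sex",
    "cancer",
    "chronic_heart_failure",
    "chronic_pulmonary_disease",
    "pulse_ge_110",
    "sbp_lt_100",
    "resp_gt_30",
    "temp_lt_36",
    "altered_mental_status",
    "sao2_lt_90",
    "calcium_le_2_13",
)


def records_from_cohort(cohort: Cohort) -> list[ClinicalRecord]:
    """Map a cohort's RAW (imputed, unstandardized) rows to clinical records.

    Point scores need raw units, so a cohort whose age column looks
    standardized (mean far below adult ages) is rejected rather than scored.
    """
    if cohort.has_missing:
        raise ValueError("impute the cohort before scoring")
    age = cohort.column("age")
    if abs(float(age.mean())) < 18.0:
        raise ValueError(
            "age column mean is near 0 - cohort appears standardized; "
            "clinical scores need raw units"
        )
    flags = {name: cohort.column(name) >= 0.5 for name in _FLAG_COLUMNS}
    return [
        ClinicalRecord(
            age=float(age[i]),
            male=bool(flags["male_sex"][i]),
            cancer=bool(flags["cancer"][i]),
            chronic_heart_failure=bool(flags["chronic_heart_failure"][i]),
            chronic_pulmonary_disease=bool(flags["chronic_pulmonary_disease"][i]),
            pulse_ge_110=bool(flags["pulse_ge_110"][i]),
            sbp_lt_100=bool(flags["sbp_lt_100"][i]),
            resp_gt_30=bool(flags["resp_gt_30"][i]),
            temp_lt_36=bool(flags["temp_lt_36"][i]),
            altered_mental_status=bool(flags["altered_mental_status"][i]),
            sao2_lt_90=bool(flags["sao2_lt_90"][i]),
            calcium_le_2_13=bool(flags["calcium_le_2_13"][i]),
        )
        for i in range(cohort.n)
    ]


def score_cohort(cohort: Cohort) -> pd.DataFrame:
    """Batch scoring: one row per patient with pesi/spesi/pumch totals."""
    records = records_from_cohort(cohort)
    return pd.DataFrame(
        {
            "row_index": np.arange(cohort.n),
            "pesi": [pesi_score(r).total for r in records],
            "spesi": [spesi_score(r).total for r in records],
            "pumch": [pumch_score(r).total for r in records],
        }
    )
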