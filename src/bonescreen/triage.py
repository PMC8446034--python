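"""T-scores, osteoporosis and fracture-risk classification, device
cross-calibration, and dual-threshold triage.

The T-score is the standard standardisation ``(BMD - young-adult mean) /
young-adult SD``; osteoporosis is T <= -2.5.  Ten-year fracture-risk
percentages from a pluggable risk model are flagged high-risk at >= 20%
(major osteoporotic) and >= 3% (hip), both inclusive.

Triage routes a predicted BMD or T-score against two operating points
T1 < T2: values below T1 are classified osteoporotic, values in
[T1, T2) are referred for confirmatory DXA, and values at or above T2
are classified non-osteoporotic.  With T1 at a >= 95% PPV operating
point and T2 at a >= 95% NPV operating point, only the middle band
needs a DXA scan.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from enum import Enum
from typing import Iterable, Mapping, Sequence

import math

__all__ = [
    "ReferenceTable",
    "default_reference_table",
    "RiskAssessment",
    "TriageCategory",
    "TriageDecision",
    "DeviceCalibration",
    "ToyLogisticRiskModel",
    "t_score",
    "bmd_from_t_score",
    "lowest_t",
    "classify_risk",
    "convert_device",
    "triage",
    "triage_summary",
    "summarize_counts",
    "round_half_up",
    "OSTEOPOROSIS_T_THRESHOLD",
    "HIGH_MAJOR_RISK_PCT",
    "HIGH_HIP_RISK_PCT",
]

OSTEOPOROSIS_T_THRESHOLD = -2.5
HIGH_MAJOR_RISK_PCT = 20.0
HIGH_HIP_RISK_PCT = 3.0


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal half-up rounding, as used in table-style percentage reports."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ReferenceTable:
    """Young-adult reference mean and SD (g/cm^2) per site and, optionally,
    per vertebra level (key ``"spine_L1"`` overrides ``"spine"``)."""

    entries: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for key, (mean, sd) in self.entries.items():
            if not sd > 0:
                raise ValueError(f"reference SD for {key!r} must be > 0")

    def get(self, site: str, vertebra_level: str | None = None) -> tuple[float, float]:
        if vertebra_level is not None:
            key = f"{site}_{vertebra_level}"
            if key in self.entries:
                return self.entries[key]
        if site not in self.entries:
            raise KeyError(f"no reference entry for site {site!r}")
        return self.entries[site]


def default_reference_table() -> ReferenceTable:
    """Representative young-adult references (NHANES-III-style hip, Hologic
    manufacturer-style lumbar values); real deployments supply their own."""
    return ReferenceTable({"hip": (0.942, 0.122), "spine": (1.047, 0.110)})


def t_score(bmd: float, ref_mean: float, ref_sd: float) -> float:
    """``(bmd - ref_mean) / ref_sd``; exact affine transform, invertible."""
    if not ref_sd > 0:
        raise ValueError("reference SD must be > 0")
    return (bmd - ref_mean) / ref_sd


def bmd_from_t_score(t: float, ref_mean: float, ref_sd: float) -> float:
    """Inverse of :func:`t_score`."""
    if not ref_sd > 0:
        raise ValueError("reference SD must be > 0")
    return ref_mean + t * ref_sd


def lowest_t(
    t_scores: Mapping[str, float], assessable: Iterable[str] | None = None
) -> float:
    """Minimum T-score over the assessable ROIs only."""
    keys = set(t_scores) if assessable is None else set(assessable)
    vals = [t for k, t in t_scores.items() if k in keys]
    if not vals:
        raise ValueError("no assessable ROI with a T-score")
    return min(vals)


@dataclass(frozen=True)
class RiskAssessment:
    """Osteoporosis and 10-year fracture-risk flags for one patient."""

    patient_id: str
    lowest_t: float
    osteoporotic: bool
    major_risk_pct: float | None = None
    hip_risk_pct: float | None = None
    high_major: bool | None = None
    high_hip: bool | None = None

    def __post_init__(self) -> None:
        if self.osteoporotic != (self.lowest_t <= OSTEOPOROSIS_T_THRESHOLD):
            raise ValueError("osteoporotic flag inconsistent with lowest_t")
        for pct, flag, cut in (
            (self.major_risk_pct, self.high_major, HIGH_MAJOR_RISK_PCT),
            (self.hip_risk_pct, self.high_hip, HIGH_HIP_RISK_PCT),
        ):
            if (pct is None) != (flag is None):
                raise ValueError("risk percentage and flag must be set together")
            if pct is not None:
                if not 0.0 <= pct <= 100.0:
                    raise ValueError("risk percentages must lie in [0, 100]")
                if flag != (pct >= cut):
                    raise ValueError("high-risk flag inconsistent with cut-off")


def classify_risk(
    patient_id: str,
    lowest_t_score: float,
    major_risk_pct: float | None = None,
    hip_risk_pct: float | None = None,
) -> RiskAssessment:
    """Apply the inclusive cut-offs: osteoporosis at T <= -2.5, high risk at
    major >= 20% and hip >= 3%."""
    return RiskAssessment(
        patient_id=patient_id,
        lowest_t=lowest_t_score,
        osteoporotic=lowest_t_score <= OSTEOPOROSIS_T_THRESHOLD,
        major_risk_pct=major_risk_pct,
        hip_risk_pct=hip_risk_pct,
        high_major=None if major_risk_pct is None else major_risk_pct >= HIGH_MAJOR_RISK_PCT,
        high_hip=None if hip_risk_pct is None else hip_risk_pct >= HIGH_HIP_RISK_PCT,
    )


@dataclass(frozen=True)
class DeviceCalibration:
    """Linear cross-calibration between densitometer makes, per site."""

    slope: float
    intercept: float

    def inverse(self) -> "DeviceCalibration":
        return DeviceCalibration(1.0 / self.slope, -self.intercept / self.slope)


def convert_device(bmd: float, calibration: DeviceCalibration) -> float:
    """Affine device conversion ``slope * bmd + intercept``; identity at
    slope 1, intercept 0."""
    return calibration.slope * bmd + calibration.intercept


class TriageCategory(str, Enum):
    OSTEOPOROTIC = "classified_osteoporotic"
    REFER_DXA = "refer_dxa"
    NON_OSTEOPOROTIC = "classified_non_osteoporotic"


@dataclass(frozen=True)
class TriageDecision:
    patient_id: str
    category: TriageCategory
    value: float
    t1: float
    t2: float


def triage(value: float, t1: float, t2: float, patient_id: str = "") -> TriageDecision:
    """Three-way routing: value < T1 -> classified osteoporotic;
    T1 <= value < T2 -> refer for DXA; value >= T2 -> classified
    non-osteoporotic.  ``value``, T1, T2 share one scale (BMD g/cm^2 or
    T-score)."""
    if not t1 < t2:
        raise ValueError("t1 must be < t2")
    if not math.isfinite(value):
        raise ValueError("triage value must be finite")
    if value < t1:
        cat = TriageCategory.OSTEOPOROTIC
    elif value < t2:
        cat = TriageCategory.REFER_DXA
    else:
        cat = TriageCategory.NON_OSTEOPOROTIC
    return TriageDecision(patient_id=patient_id, category=cat, value=value, t1=t1, t2=t2)


def summarize_counts(counts: Mapping[str, int], cohort_n: int) -> dict:
    """Counts and one-decimal half-up percentages per triage category."""
    if cohort_n <= 0:
        raise ValueError("cohort_n must be positive")
    out = {"cohort_n": cohort_n, "categories": {}}
    for cat in TriageCategory:
        c = int(counts.get(cat.value, 0))
        out["categories"][cat.value] = {
            "count": c,
            "percent": round_half_up(100.0 * c / cohort_n),
        }
    return out


def triage_summary(decisions: Sequence[TriageDecision], cohort_n: int | None = None) -> dict:
    """Tabulate triage decisions into counts and percentages."""
    if not decisions:
        raise ValueError("no triage decisions to summarize")
    if cohort_n is None:
        cohort_n = len(decisions)
    counts: dict[str, int] = {}
    for d in decisions:
        counts[d.category.value] = counts.get(d.category.value, 0) + 1
    return summarize_counts(counts, cohort_n)


class ToyLogisticRiskModel:
    """Documented toy logistic risk score for pipeline testing.

    THIS IS NOT FRAX.  It maps (age, sex, height, weight, BMD) through a
    fixed logistic form so that risk rises with age and falls with BMD,
    producing percentages on the same [0, 100] scale a real 10-year
    fracture-risk calculator would return.  Any object with the same
    ``predict`` signature can replace it (e.g. a wrapper around an
    external calculator).
    """

    def predict(
        self, age: float, sex: str, height_cm: float, weight_kg: float, bmd: float
    ) -> tuple[float, float]:
        """Return (major_osteoporotic_pct, hip_pct)."""
        bmi = weight_kg / (height_cm / 100.0) ** 2
        sex_term = 0.4 if sex == "F" else 0.0
        z_major = -2.2 + 0.05 * (age - 65.0) - 5.0 * (bmd - 0.8) - 0.03 * (bmi - 24.0) + sex_term
        z_hip = -3.6 + 0.07 * (age - 65.0) - 7.0 * (bmd - 0.8) - 0.03 * (bmi - 24.0) + sex_term
        major = 100.0 / (1.0 + math.exp(-z_major))
        hip = 100.0 / (1.0 + math.exp(-z_hip))
        return major, hip
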