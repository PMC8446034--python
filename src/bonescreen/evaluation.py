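"""Agreement, calibration, discrimination statistics and the 95% PPV/NPV
threshold search.

Conventions
-----------
* Calibration is the ordinary least-squares regression of *measured on
  predicted*, so a perfectly calibrated model has slope 1;
  calibration-in-the-large is ``mean(measured) - mean(predicted)`` and is
  algebraically identical to the Bland-Altman bias.
* For osteoporosis discrimination, a *lower* predicted BMD means a more
  positive (diseased) case; :func:`osteoporosis_scores` provides the
  orientation.
* AUROC is the trapezoidal area (rank statistic with tie correction);
  AUPRC is step-wise average precision, not trapezoidal PR interpolation.
* Reported percentages round half-up to one decimal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score

from .triage import round_half_up

__all__ = [
    "PairedSample",
    "ConfusionCounts",
    "AgreementStats",
    "CalibrationStats",
    "BlandAltmanStats",
    "ConfusionMetrics",
    "ThresholdResult",
    "agreement_stats",
    "calibration",
    "bland_altman",
    "confusion_metrics",
    "roc_pr_curves",
    "osteoporosis_scores",
    "find_threshold",
    "wilson_interval",
]


@dataclass(frozen=True)
class PairedSample:
    """Paired predicted/measured values for one unit each."""

    predicted: np.ndarray
    measured: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.predicted, dtype=float)
        m = np.asarray(self.measured, dtype=float)
        if p.shape != m.shape or p.ndim != 1:
            raise ValueError("predicted and measured must be equal-length 1-D arrays")
        if not (np.isfinite(p).all() and np.isfinite(m).all()):
            raise ValueError("paired sample contains non-finite values")
        object.__setattr__(self, "predicted", p)
        object.__setattr__(self, "measured", m)

    def __len__(self) -> int:
        return len(self.predicted)


@dataclass(frozen=True)
class AgreementStats:
    pearson_r: float
    r2: float
    rmse: float


def agreement_stats(s: PairedSample) -> AgreementStats:
    """Pearson r plus R^2 and RMSE of the OLS fit of measured on predicted.

    RMSE is the root mean squared OLS residual (denominator n).
    Requires n >= 3 and nonzero variance on both sides.
    """
    if len(s) < 3:
        raise ValueError("agreement statistics need n >= 3")
    if np.std(s.predicted) == 0 or np.std(s.measured) == 0:
        raise ValueError("agreement statistics need nonzero variance")
    r = float(stats.pearsonr(s.predicted, s.measured).statistic)
    fit = stats.linregress(s.predicted, s.measured)
    resid = s.measured - (fit.intercept + fit.slope * s.predicted)
    return AgreementStats(
        pearson_r=r,
        r2=float(fit.rvalue**2),
        rmse=float(np.sqrt(np.mean(resid**2))),
    )


@dataclass(frozen=True)
class CalibrationStats:
    slope: float
    calibration_in_the_large: float


def calibration(s: PairedSample) -> CalibrationStats:
    """OLS slope of measured on predicted and mean(measured) - mean(predicted)."""
    if len(s) < 3:
        raise ValueError("calibration needs n >= 3")
    if np.std(s.predicted) == 0:
        raise ValueError("calibration needs nonzero predicted variance")
    fit = stats.linregress(s.predicted, s.measured)
    return CalibrationStats(
        slope=float(fit.slope),
        calibration_in_the_large=float(np.mean(s.measured) - np.mean(s.predicted)),
    )


@dataclass(frozen=True)
class BlandAltmanStats:
    bias: float
    sd: float


def bland_altman(s: PairedSample) -> BlandAltmanStats:
    """Mean and sample SD (n-1) of the differences measured - predicted."""
    if len(s) < 2:
        raise ValueError("Bland-Altman needs n >= 2")
    diffs = s.measured - s.predicted
    return BlandAltmanStats(bias=float(np.mean(diffs)), sd=float(np.std(diffs, ddof=1)))


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")
        if self.total == 0:
            raise ValueError("confusion table is empty")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class ConfusionMetrics:
    """Rates as fractions in [0, 1]; odds ratio with Woolf log CI."""

    accuracy: float
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    odds_ratio: float
    or_ci: tuple[float, float]


def wilson_interval(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if n == 0:
        raise ValueError("empty denominator")
    z = stats.norm.ppf(0.5 + level / 2.0)
    p = k / n
    denom = 1.0 + z**2 / n
    centre = (p + z**2 / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return centre - half, centre + half


def _rate(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def confusion_metrics(c: ConfusionCounts) -> ConfusionMetrics:
    """Standard confusion-table rates plus the odds ratio.

    The odds ratio uses the Woolf log method for its 95% CI; when any cell
    is zero, 0.5 is added to every cell (Haldane-Anscombe continuity
    correction) for both the estimate and the interval.
    """
    cells = (c.tp, c.fp, c.tn, c.fn)
    if 0 in cells:
        a, b, d, e = (x + 0.5 for x in cells)
    else:
        a, b, d, e = map(float, cells)
    or_est = (a * d) / (b * e)
    se = math.sqrt(1 / a + 1 / b + 1 / d + 1 / e)
    z = stats.norm.ppf(0.975)
    ci = (or_est * math.exp(-z * se), or_est * math.exp(z * se))
    return ConfusionMetrics(
        accuracy=(c.tp + c.tn) / c.total,
        sensitivity=_rate(c.tp, c.tp + c.fn),
        specificity=_rate(c.tn, c.tn + c.fp),
        ppv=_rate(c.tp, c.tp + c.fp),
        npv=_rate(c.tn, c.tn + c.fn),
        odds_ratio=or_est,
        or_ci=ci,
    )


def osteoporosis_scores(predicted_bmd: np.ndarray) -> np.ndarray:
    """Orient predicted BMD for discrimination: lower BMD = higher score."""
    return -np.asarray(predicted_bmd, dtype=float)


def roc_pr_curves(scores, labels) -> tuple[float, float]:
    """(AUROC, AUPRC) for binary ``labels`` against ``scores`` where a
    higher score indicates the positive class.

    AUROC is the trapezoidal/rank-statistic area; AUPRC is step-wise
    average precision.
    """
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("labels must contain both classes")
    return (
        float(roc_auc_score(labels, scores)),
        float(average_precision_score(labels, scores)),
    )


@dataclass(frozen=True)
class ThresholdResult:
    """Outcome of the PPV/NPV threshold search.

    ``found`` is False when no threshold attains the target on the sample;
    the remaining fields are then None.
    """

    found: bool
    threshold: float | None = None
    attained: float | None = None
    n_captured: int | None = None
    n_total: int | None = None


def find_threshold(values, labels, target: float = 0.95, kind: str = "ppv") -> ThresholdResult:
    """Operating point with PPV or NPV at least ``target``.

    Values are on the predicted BMD/T-score scale (low = diseased).  For
    ``kind="ppv"`` a unit is called positive when ``value < t``; the
    search returns the *largest* t satisfying PPV >= target, which
    captures the most positives subject to the constraint.  For
    ``kind="npv"`` a unit is called negative when ``value >= t``; the
    search returns the *smallest* such t.  Unattainable targets yield
    ``ThresholdResult(found=False)``.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if values.shape != labels.shape or values.ndim != 1:
        raise ValueError("values and labels must be equal-length 1-D arrays")
    if labels.all() or (~labels).all():
        raise ValueError("both classes must be present")
    if kind not in ("ppv", "npv"):
        raise ValueError("kind must be 'ppv' or 'npv'")

    order = np.argsort(values, kind="stable")
    v = values[order]
    y = labels[order]
    n = len(v)
    pos_prefix = np.concatenate([[0], np.cumsum(y)])  # positives among v[:i]
    uniq_idx = np.flatnonzero(np.r_[np.diff(v) != 0, True])  # last index of each run

    best: ThresholdResult = ThresholdResult(found=False)
    if kind == "ppv":
        # candidate thresholds: each unique value (predict positive strictly
        # below it) and +inf (everything positive)
        candidates = [(int(i), v[i]) for i in np.flatnonzero(np.r_[True, np.diff(v) != 0])]
        cand = [(i, t) for i, t in candidates] + [(n, np.inf)]
        for i, t in cand:  # i = number of units with value < t
            tp = int(pos_prefix[i])
            called = i
            if called == 0:
                continue
            ppv = tp / called
            if ppv >= target:
                best = ThresholdResult(True, float(t), ppv, tp, called)
        return best
    # NPV: predict negative when value >= t; smallest t wins
    total_pos = int(pos_prefix[-1])
    cand_idx = list(np.flatnonzero(np.r_[True, np.diff(v) != 0]))
    for i in cand_idx:  # units v[i:] are called negative; threshold t = v[i]
        called = n - i
        fn = total_pos - int(pos_prefix[i])
        tn = called - fn
        npv = tn / called
        if npv >= target:
            return ThresholdResult(True, float(v[i]), npv, tn, called)
    return ThresholdResult(found=False)


def as_percent(x: float) -> float:
    """Fraction -> one-decimal half-up percentage."""
    return round_half_up(100.0 * x)
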