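"""Automated radiograph quality assessment.

Hip: fracture and implant detection scores are the maximum detector
response inside the hip ROI polygon; an ROI at or above either threshold
is excluded.

Spine: a three-step procedure per scan.  (1) vertebrae with a positive
implant or VCF detection are excluded; (2) survivors failing any of the
three morphometric deformity criteria are excluded; (3) survivors whose
predicted T-score deviates from the mean of their assessable neighbours
by more than a configurable delta (default 1.0 T-score units, following
the ISCD vertebra-exclusion convention) are excluded.  A scan with fewer
than two assessable vertebrae is inadmissible as a whole.

Detectors are pluggable: anything with ``detect(image, channel) ->
DetectionMap``.  A synthetic detector that reads phantom ground truth is
bundled for testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Protocol, Sequence

import numpy as np
import shapely
from shapely.geometry import Polygon, box

from .morphometry import VertebraLandmarks, compute_morphometry, VERTEBRA_LEVELS

__all__ = [
    "DetectionMap",
    "QAResult",
    "QAThresholds",
    "Detector",
    "SyntheticDetector",
    "ConfigurationError",
    "aggregate_roi_score",
    "hip_qa",
    "spine_qa",
    "neighbor_exclusion",
    "qa_report",
]

CHANNELS = ("fracture", "implant", "vcf")

REASON_FRACTURE = "fracture"
REASON_IMPLANT = "implant"
REASON_VCF = "vcf_detected"
REASON_DEFORMITY = "morphometric_deformity"
REASON_NEIGHBOR = "neighbor_deviation"
REASON_TOO_FEW = "too_few_vertebrae"


class ConfigurationError(RuntimeError):
    """A detector channel or configuration entry required by QA is missing."""


@dataclass(frozen=True)
class DetectionMap:
    """Probability grid aligned to the source image (values in [0, 1])."""

    values: np.ndarray
    channel: str

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}")
        v = np.asarray(self.values)
        if v.ndim != 2 or v.size == 0:
            raise ValueError("values must be a nonempty 2-D grid")
        if v.min() < 0.0 or v.max() > 1.0:
            raise ValueError("detection map values must lie in [0, 1]")


@dataclass(frozen=True)
class QAResult:
    """Admissibility decision for one ROI, with reason codes and scores."""

    roi_id: str
    reasons: frozenset[str] = frozenset()
    scores: Mapping[str, float] = field(default_factory=dict)

    @property
    def admissible(self) -> bool:
        return not self.reasons


@dataclass(frozen=True)
class QAThresholds:
    """Detector operating points (scores at or above are positive) and the
    neighbour-deviation delta in T-score units."""

    fracture: float = 0.5
    implant: float = 0.5
    vcf: float = 0.5
    neighbor_delta: float = 1.0


class Detector(Protocol):
    """Plug-in contract: one probability grid per requested channel."""

    def detect(self, image: np.ndarray, channel: str) -> DetectionMap: ...


class SyntheticDetector:
    """Testing detector driven by ground-truth phantom labels.

    ``positives`` maps a channel name to truth: a positive channel yields a
    uniform map at ``hot`` (default 0.9), a negative one at ``cold``
    (default 0.05).  For spine scans, per-vertebra truth is supplied as
    ``{level: {channel, ...}}`` via :meth:`for_level`.
    """

    def __init__(self, positives: Iterable[str] = (), hot: float = 0.9, cold: float = 0.05):
        self.positives = frozenset(positives)
        unknown = self.positives - set(CHANNELS)
        if unknown:
            raise ValueError(f"unknown channels: {sorted(unknown)}")
        self.hot = hot
        self.cold = cold

    def detect(self, image: np.ndarray, channel: str) -> DetectionMap:
        if channel not in CHANNELS:
            raise ConfigurationError(f"detector has no channel {channel!r}")
        level = self.hot if channel in self.positives else self.cold
        return DetectionMap(
            values=np.full(np.asarray(image).shape, level), channel=channel
        )


def aggregate_roi_score(
    dmap: DetectionMap, roi_polygon: Sequence[tuple[float, float]]
) -> float:
    """Maximum map response over grid cells whose centres fall inside the
    polygon (boundary inclusive).

    Cell (row i, col j) has its centre at (x=j, y=i), 0-based.  Raises if
    the polygon has fewer than 3 vertices, zero area, lies fully outside
    the map, or covers no cell centre.
    """
    if len(roi_polygon) < 3:
        raise ValueError("ROI polygon needs at least 3 vertices")
    poly = Polygon(roi_polygon)
    if poly.area == 0.0:
        raise ValueError("ROI polygon has zero area")
    values = np.asarray(dmap.values)
    h, w = values.shape
    extent = box(-0.5, -0.5, w - 0.5, h - 0.5)
    if not poly.intersects(extent):
        raise ValueError("ROI polygon lies fully outside the detection map")
    minx, miny, maxx, maxy = poly.bounds
    j0, j1 = max(int(np.floor(minx)), 0), min(int(np.ceil(maxx)), w - 1)
    i0, i1 = max(int(np.floor(miny)), 0), min(int(np.ceil(maxy)), h - 1)
    if j1 < j0 or i1 < i0:
        raise ValueError("ROI polygon covers no grid cell centre")
    jj, ii = np.meshgrid(np.arange(j0, j1 + 1), np.arange(i0, i1 + 1))
    pts = shapely.points(jj.ravel().astype(float), ii.ravel().astype(float))
    inside = shapely.covers(poly, pts)
    if not inside.any():
        raise ValueError("ROI polygon covers no grid cell centre")
    sub = values[i0 : i1 + 1, j0 : j1 + 1].ravel()
    return float(sub[inside].max())


def hip_qa(
    image: np.ndarray,
    hip_roi_polygon: Sequence[tuple[float, float]],
    detector: Detector,
    thresholds: QAThresholds = QAThresholds(),
    roi_id: str = "hip",
) -> QAResult:
    """Hip ROI admissibility from fracture and implant detector scores.

    A score at or above its threshold (inclusive) marks the ROI
    inadmissible with the corresponding reason.
    """
    reasons = set()
    scores = {}
    for channel, thr, reason in (
        ("fracture", thresholds.fracture, REASON_FRACTURE),
        ("implant", thresholds.implant, REASON_IMPLANT),
    ):
        try:
            dmap = detector.detect(image, channel)
        except ConfigurationError:
            raise
        except Exception as exc:  # missing channel surfaces as configuration
            raise ConfigurationError(f"detector failed on channel {channel!r}") from exc
        score = aggregate_roi_score(dmap, hip_roi_polygon)
        scores[channel] = score
        if score >= thr:
            reasons.add(reason)
    return QAResult(roi_id=roi_id, reasons=frozenset(reasons), scores=scores)


def neighbor_exclusion(
    values: Mapping[str, float], delta: float = 1.0
) -> set[str]:
    """Exclude vertebrae deviating from their assessable neighbours.

    ``values`` maps vertebra levels (subset of L1..L4) to T-scores.  Each
    vertebra is compared against the mean of its up-to-two nearest
    assessable vertebrae in the L1-L4 chain: an interior vertebra uses its
    adjacent neighbour on each side, a chain endpoint uses the two nearest
    inward vertebrae (or the single other vertebra when only two are
    assessable).  A vertebra deviating from that mean by more than
    ``delta`` strictly is excluded.  All decisions are one simultaneous
    pass on the pre-exclusion values (no cascade).
    """
    if len(values) < 2:
        raise ValueError("neighbor exclusion needs at least 2 vertebrae")
    chain = [lv for lv in VERTEBRA_LEVELS if lv in values]
    last = len(chain) - 1
    excluded: set[str] = set()
    for idx, lv in enumerate(chain):
        if 0 < idx < last:
            ref = (values[chain[idx - 1]] + values[chain[idx + 1]]) / 2.0
        elif idx == 0:
            inward = chain[1:3]
            ref = float(np.mean([values[x] for x in inward]))
        else:
            inward = chain[max(last - 2, 0) : last]
            ref = float(np.mean([values[x] for x in inward]))
        if abs(values[lv] - ref) > delta:
            excluded.add(lv)
    return excluded


def spine_qa(
    vertebra_set: Sequence[tuple[VertebraLandmarks, Mapping[str, DetectionMap]]],
    predicted_values: Mapping[str, float] | None = None,
    thresholds: QAThresholds = QAThresholds(),
) -> list[QAResult]:
    """Three-step spine QA; returns one QAResult per input vertebra.

    Steps: implant/VCF detection (scores aggregated over the vertebra
    hexagon in pixel coordinates), morphometric deformity criteria, and
    neighbour deviation on ``predicted_values`` (per-level T-scores by
    default) for the remaining vertebrae.  If fewer than two vertebrae
    survive, the survivors are additionally marked ``too_few_vertebrae`` so
    the whole scan is inadmissible.  Results are order-independent and are
    returned in the input order.
    """
    if not vertebra_set:
        raise ValueError("empty vertebra set")
    levels = [lm.vertebra_level for lm, _ in vertebra_set]
    if len(set(levels)) != len(levels):
        raise ValueError("duplicate vertebra levels in scan")

    reasons: dict[str, set[str]] = {lv: set() for lv in levels}
    scores: dict[str, dict[str, float]] = {lv: {} for lv in levels}

    # step 1: implant / VCF detection
    for lm, maps in vertebra_set:
        lv = lm.vertebra_level
        for channel, thr, reason in (
            ("implant", thresholds.implant, REASON_IMPLANT),
            ("vcf", thresholds.vcf, REASON_VCF),
        ):
            if channel not in maps:
                raise ConfigurationError(f"missing detection map {channel!r} for {lv}")
            score = aggregate_roi_score(maps[channel], lm.outline_pixels())
            scores[lv][channel] = score
            if score >= thr:
                reasons[lv].add(reason)

    # step 2: six-point morphometry on step-1 survivors
    for lm, _ in vertebra_set:
        lv = lm.vertebra_level
        if reasons[lv]:
            continue
        morpho = compute_morphometry(lm)
        scores[lv].update(r1=morpho.r1, r2=morpho.r2, r3=morpho.r3)
        if morpho.abnormal:
            reasons[lv].add(REASON_DEFORMITY)

    # step 3: neighbour deviation among survivors with predicted values
    survivors = [lv for lv in levels if not reasons[lv]]
    if predicted_values is not None and len(survivors) >= 2:
        vals = {lv: predicted_values[lv] for lv in survivors if lv in predicted_values}
        if len(vals) >= 2:
            for lv in neighbor_exclusion(vals, thresholds.neighbor_delta):
                reasons[lv].add(REASON_NEIGHBOR)

    # minimum-count rule on the survivor set
    survivors = [lv for lv in levels if not reasons[lv]]
    if len(survivors) < 2:
        for lv in survivors:
            reasons[lv].add(REASON_TOO_FEW)

    return [
        QAResult(roi_id=lv, reasons=frozenset(reasons[lv]), scores=scores[lv])
        for lv in levels
    ]


def qa_report(results: Sequence[QAResult]):
    """QA results as a table: one row per ROI (scores, reasons, admissibility)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "roi_id": r.roi_id,
                "admissible": r.admissible,
                "reasons": ";".join(sorted(r.reasons)),
                **{f"score_{k}": v for k, v in r.scores.items()},
            }
            for r in results
        ]
    )
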