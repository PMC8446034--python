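"""Synthetic phantom data: landmark sets, ROI images, and paired cohorts.

This module emulates the paired radiograph-ROI / DXA-BMD data the screening
pipeline consumes, with known ground truth, so every downstream stage is
testable without clinical data.

Phantom ROI images
------------------
A phantom ROI is a 16-bit single-channel image: a uniform soft-tissue
background of 10 000 grey levels containing a centred "bone" disc of
30 000 grey levels whose *area fraction* is an affine function of the true
areal BMD.  The noise-free mean intensity is therefore (up to pixel
discretisation of the disc) affine and strictly monotone in BMD, and —
because the density is carried by the disc's area rather than its absolute
brightness — the signal survives the per-image min–max normalisation used
by the regressor.  Additive Gaussian noise (``noise_sd`` grey levels,
truncated to the 16-bit range) models radiographic noise.

The generators are pure functions of their arguments: all randomness flows
from the explicit ``rng_seed`` and identical inputs give bit-identical
outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .morphometry import VertebraLandmarks, VERTEBRA_LEVELS
from .regression import ROIImage

__all__ = [
    "Deformity",
    "PhantomSpec",
    "CohortRecord",
    "generate_vertebra_landmarks",
    "generate_phantom_roi",
    "expected_mean_intensity",
    "generate_cohort",
    "cohort_to_frame",
    "write_cohort_csv",
    "read_cohort_csv",
    "write_roi_image",
    "read_roi_image",
]

BACKGROUND_LEVEL = 10_000.0
BONE_LEVEL = 30_000.0
#: supported areal-density range, g/cm^2
BMD_RANGE = (0.2, 1.6)
#: disc area fraction is affine in BMD over BMD_RANGE
_AREA_FRAC_RANGE = (0.05, 0.30)

OSTEOPOROSIS_T = -2.5


class Deformity(str, Enum):
    NONE = "none"
    WEDGE = "wedge"
    BICONCAVE = "biconcave"
    CRUSH = "crush"
    SEVERE_FLAT = "severe_flat"


@dataclass(frozen=True)
class PhantomSpec:
    """Ground-truth description of one phantom vertebra/hip ROI."""

    true_bmd: float
    deformity: Deformity = Deformity.NONE
    severity: float = 0.0
    noise_sd: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.true_bmd > 0:
            raise ValueError("true_bmd must be strictly positive")
        if not 0.0 <= self.severity <= 1.0:
            raise ValueError("severity must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _deformity_heights(
    deformity: Deformity, severity: float, base_height: float
) -> tuple[float, float, float]:
    """(h_a, h_p, h_m) for one deformity family.

    wedge:       anterior height scaled by 1-severity, posterior kept,
                 middle interpolated halfway;
    biconcave:   middle height scaled by 1-severity;
    crush / severe_flat: all three heights scaled by 1-severity.
    At severity 0 every family reduces to the identity geometry.
    """
    h = base_height
    s = severity
    if deformity is Deformity.NONE:
        return h, h, h
    if deformity is Deformity.WEDGE:
        return (1 - s) * h, h, (1 - 0.5 * s) * h
    if deformity is Deformity.BICONCAVE:
        return h, h, (1 - s) * h
    # crush and severe_flat: uniform collapse of the whole body
    return (1 - s) * h, (1 - s) * h, (1 - s) * h


def generate_vertebra_landmarks(
    spec: PhantomSpec,
    base_height: float = 25.0,
    base_width: float = 35.0,
    vertebra_level: str = "L1",
    origin: tuple[float, float] = (0.0, 0.0),
    pixel_spacing: float = 0.15,
) -> VertebraLandmarks:
    """Synthesize six landmarks (mm) realising the requested deformity.

    The vertebra is an axis-aligned hexagon: anterior points at ``x =
    origin_x``, posterior points at ``x = origin_x + base_width``, middle
    points at mid-width; each point pair is centred vertically on
    ``origin_y`` and separated by the family's height.  Morphometry of the
    result reproduces the requested heights exactly.
    """
    if not (base_height > 0 and base_width > 0):
        raise ValueError("base_height and base_width must be > 0")
    h_a, h_p, h_m = _deformity_heights(spec.deformity, spec.severity, base_height)
    if min(h_a, h_p, h_m) <= 0:
        raise ValueError("severity 1.0 collapses the vertebra to zero height")
    x0, y0 = origin
    xm = x0 + base_width / 2.0
    xp = x0 + base_width
    return VertebraLandmarks(
        anterior_superior=(x0, y0 - h_a / 2.0),
        anterior_inferior=(x0, y0 + h_a / 2.0),
        posterior_superior=(xp, y0 - h_p / 2.0),
        posterior_inferior=(xp, y0 + h_p / 2.0),
        middle_superior=(xm, y0 - h_m / 2.0),
        middle_inferior=(xm, y0 + h_m / 2.0),
        vertebra_level=vertebra_level,
        pixel_spacing=pixel_spacing,
    )


def _disc_mask(true_bmd: float, size_px: int) -> np.ndarray:
    lo, hi = BMD_RANGE
    f_lo, f_hi = _AREA_FRAC_RANGE
    # clamp outside the supported range rather than extrapolating
    t = min(max((true_bmd - lo) / (hi - lo), 0.0), 1.0)
    area_frac = f_lo + (f_hi - f_lo) * t
    radius = size_px * math.sqrt(area_frac / math.pi)
    c = (size_px - 1) / 2.0
    yy, xx = np.mgrid[0:size_px, 0:size_px]
    return (xx - c) ** 2 + (yy - c) ** 2 <= radius**2


def expected_mean_intensity(true_bmd: float, size_px: int) -> float:
    """Noise-free mean intensity m(true_bmd) of a phantom ROI.

    ``m = background + (bone - background) * disc_area_fraction`` with the
    discrete pixel-count area fraction; affine and strictly increasing in
    BMD up to pixel discretisation of the disc radius.
    """
    frac = _disc_mask(true_bmd, size_px).mean()
    return BACKGROUND_LEVEL + (BONE_LEVEL - BACKGROUND_LEVEL) * frac


def generate_phantom_roi(
    spec: PhantomSpec,
    size_px: int = 64,
    site: str = "vertebra",
    vertebra_level: str | None = "L1",
    roi_id: str | None = None,
    pixel_spacing: float = 1.2,
) -> ROIImage:
    """Render a deterministic 16-bit phantom ROI for ``spec``.

    The default 64 px at 1.2 mm spacing spans 76.8 mm, which resamples to
    exactly 512 px at the model's 0.15 mm working resolution.
    """
    if size_px < 32:
        raise ValueError("size_px must be >= 32")
    mask = _disc_mask(spec.true_bmd, size_px)
    img = np.full((size_px, size_px), BACKGROUND_LEVEL, dtype=np.float64)
    img[mask] = BONE_LEVEL
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.rng_seed)
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    grid = np.clip(np.rint(img), 0, 65535).astype(np.uint16)
    return ROIImage(
        grid=grid,
        pixel_spacing=pixel_spacing,
        site=site,
        vertebra_level=vertebra_level if site == "vertebra" else None,
        roi_id=roi_id,
    )


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

#: default osteoporosis prevalences of the emulated screening populations
DEFAULT_PREVALENCE = {"hip": 0.215, "spine": 0.433}

# representative young-adult reference values (g/cm^2) used to convert the
# sampled T-scores into areal densities; configurable downstream
_REF = {"hip": (0.942, 0.122), "spine": (1.047, 0.110)}


@dataclass(frozen=True)
class CohortRecord:
    """One synthetic patient with per-ROI true and DXA-measured BMD."""

    patient_id: str
    age: float
    sex: str  # F | M
    site: str  # hip | spine
    true_bmd: Mapping[str, float]  # roi_id -> g/cm^2
    measured_bmd: Mapping[str, float]
    days_between: int
    height_cm: float = 160.0
    weight_kg: float = 60.0

    def __post_init__(self) -> None:
        if not 40.0 <= self.age <= 90.0:
            raise ValueError("age must lie in [40, 90] years")
        if self.sex not in ("F", "M"):
            raise ValueError("sex must be 'F' or 'M'")
        if self.site not in ("hip", "spine"):
            raise ValueError("site must be 'hip' or 'spine'")
        if any(v <= 0 for v in self.measured_bmd.values()):
            raise ValueError("measured_bmd must be strictly positive")

    def lowest_true_t(self) -> float:
        mean, sd = _REF[self.site]
        return min((v - mean) / sd for v in self.true_bmd.values())


def _roi_ids(site: str) -> tuple[str, ...]:
    return ("hip_left", "hip_right") if site == "hip" else VERTEBRA_LEVELS


def generate_cohort(
    n: int,
    prevalence: float | None = None,
    site: str = "hip",
    dxa_noise_sd: float = 0.01,
    rng_seed: int = 0,
) -> list[CohortRecord]:
    """Sample ``n`` patients with per-ROI true/measured BMD.

    Osteoporosis status is Bernoulli(``prevalence``) per patient (defaults
    to 21.5% for hip and 43.3% for spine screening populations).  The
    patient's lowest T-score is drawn uniformly from (-4.2, -2.5] when
    osteoporotic and (-2.5, 1.5) otherwise; per-ROI T-scores sit at or
    above that minimum, and BMD follows from the young-adult reference.
    DXA measurement noise is Gaussian with SD ``dxa_noise_sd`` g/cm^2
    (precision-level, an assumption rather than a reported figure).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if prevalence is None:
        prevalence = DEFAULT_PREVALENCE[site]
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError("prevalence must lie in [0, 1]")
    if site not in ("hip", "spine"):
        raise ValueError("site must be 'hip' or 'spine'")
    rng = np.random.default_rng(rng_seed)
    mean, sd = _REF[site]
    rois = _roi_ids(site)
    age_mu = 72.0 if site == "hip" else 67.0
    frac_female = 0.774 if site == "hip" else 0.796
    days_scale = 29 / math.log(2) if site == "hip" else 16 / math.log(2)

    records: list[CohortRecord] = []
    for i in range(n):
        osteo = rng.random() < prevalence
        if osteo:
            t_low = rng.uniform(-4.2, -2.5)
        else:
            t_low = rng.uniform(np.nextafter(-2.5, 0.0), 1.5)
        offsets = np.abs(rng.normal(0.0, 0.25, size=len(rois)))
        offsets[rng.integers(len(rois))] = 0.0  # one ROI attains the minimum
        t_per_roi = t_low + offsets
        true = {r: mean + t * sd for r, t in zip(rois, t_per_roi)}
        measured = {
            r: max(v + rng.normal(0.0, dxa_noise_sd), 0.01) for r, v in true.items()
        }
        age = float(np.clip(rng.normal(age_mu, 11.0), 40.0, 90.0))
        sex = "F" if rng.random() < frac_female else "M"
        height = float(np.clip(rng.normal(157.0 if sex == "F" else 168.0, 6.0), 130, 200))
        weight = float(np.clip(rng.normal(58.0 if sex == "F" else 68.0, 10.0), 35, 130))
        days = int(min(round(rng.exponential(days_scale)), 180))
        records.append(
            CohortRecord(
                patient_id=f"P{i:05d}",
                age=age,
                sex=sex,
                site=site,
                true_bmd=true,
                measured_bmd=measured,
                days_between=days,
                height_cm=height,
                weight_kg=weight,
            )
        )
    return records


COHORT_COLUMNS = [
    "patient_id",
    "age",
    "sex",
    "site",
    "roi_id",
    "true_bmd",
    "measured_bmd",
    "days_between",
    "height_cm",
    "weight_kg",
]


def cohort_to_frame(records: Sequence[CohortRecord]) -> pd.DataFrame:
    """Long-format cohort table: one row per (patient, ROI)."""
    rows = []
    for r in records:
        for roi in r.true_bmd:
            rows.append(
                {
                    "patient_id": r.patient_id,
                    "age": r.age,
                    "sex": r.sex,
                    "site": r.site,
                    "roi_id": roi,
                    "true_bmd": r.true_bmd[roi],
                    "measured_bmd": r.measured_bmd[roi],
                    "days_between": r.days_between,
                    "height_cm": r.height_cm,
                    "weight_kg": r.weight_kg,
                }
            )
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def write_cohort_csv(records: Sequence[CohortRecord], path) -> None:
    cohort_to_frame(records).to_csv(path, index=False)


def read_cohort_csv(path) -> list[CohortRecord]:
    df = pd.read_csv(path)
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV missing columns: {sorted(missing)}")
    records = []
    for pid, g in df.groupby("patient_id", sort=False):
        first = g.iloc[0]
        records.append(
            CohortRecord(
                patient_id=str(pid),
                age=float(first.age),
                sex=str(first.sex),
                site=str(first.site),
                true_bmd={str(r.roi_id): float(r.true_bmd) for r in g.itertuples()},
                measured_bmd={
                    str(r.roi_id): float(r.measured_bmd) for r in g.itertuples()
                },
                days_between=int(first.days_between),
                height_cm=float(first.height_cm),
                weight_kg=float(first.weight_kg),
            )
        )
    return records


def write_roi_image(roi: ROIImage, path) -> None:
    """Store an ROI as a 16-bit single-channel PNG or TIFF."""
    iio.imwrite(path, roi.grid.astype(np.uint16))


def read_roi_image(
    path,
    pixel_spacing: float,
    site: str,
    vertebra_level: str | None = None,
    roi_id: str | None = None,
) -> ROIImage:
    grid = np.asarray(iio.imread(path))
    return ROIImage(
        grid=grid,
        pixel_spacing=pixel_spacing,
        site=site,
        vertebra_level=vertebra_level,
        roi_id=roi_id,
    )
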