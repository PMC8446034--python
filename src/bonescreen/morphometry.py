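"""Six-point vertebral morphometry and automated deformity criteria.

A vertebral body on a lateral radiograph is summarised by six landmarks:
two anterior, two posterior, and two middle (mid-plate) points on the
superior and inferior end plates.  From them four distances are derived —
anterior height ``h_a``, posterior height ``h_p``, middle height ``h_m``
and width ``w`` — and three ratio criteria in the spirit of the Genant
semiquantitative method flag moderate-to-severe compression deformity:

* wedge/crush:  min(h_a, h_p) / max(h_a, h_p) < 0.8
* biconcave:    h_m / max(h_a, h_p)           < 0.6
* severe:       max(h_a, h_p) / w             < 0.55

All comparisons are strict; a ratio exactly at its threshold is normal.
Coordinates are in millimetres, x rightward and y downward.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence, TextIO

import pandas as pd
from shapely.geometry import Polygon

__all__ = [
    "DegenerateGeometryError",
    "VertebraLandmarks",
    "VertebralMorphometry",
    "DeformityClass",
    "compute_morphometry",
    "classify_deformity",
    "read_landmark_file",
    "write_landmark_file",
    "morphometry_table",
    "WEDGE_CRUSH_THRESHOLD",
    "BICONCAVE_THRESHOLD",
    "SEVERE_THRESHOLD",
    "VERTEBRA_LEVELS",
]

VERTEBRA_LEVELS = ("L1", "L2", "L3", "L4")

#: strict-inequality thresholds of the three deformity criteria
WEDGE_CRUSH_THRESHOLD = 0.8
BICONCAVE_THRESHOLD = 0.6
SEVERE_THRESHOLD = 0.55

LANDMARK_NAMES = (
    "anterior_superior",
    "anterior_inferior",
    "posterior_superior",
    "posterior_inferior",
    "middle_superior",
    "middle_inferior",
)


class DegenerateGeometryError(ValueError):
    """Landmark configuration that cannot be measured (coincident points,
    self-intersecting outline)."""


Point = tuple[float, float]


def _dist(p: Point, q: Point) -> float:
    return math.hypot(p[0] - q[0], p[1] - q[1])


@dataclass(frozen=True)
class VertebraLandmarks:
    """Six named landmarks (mm) for one vertebra.

    Points follow the canonical ordering ``anterior_superior,
    anterior_inferior, posterior_superior, posterior_inferior,
    middle_superior, middle_inferior``.  ``pixel_spacing`` (mm/pixel) is
    kept so detection maps in pixel coordinates can be aligned with the
    millimetre geometry.
    """

    anterior_superior: Point
    anterior_inferior: Point
    posterior_superior: Point
    posterior_inferior: Point
    middle_superior: Point
    middle_inferior: Point
    vertebra_level: str
    pixel_spacing: float = 1.0

    def __post_init__(self) -> None:
        if self.vertebra_level not in VERTEBRA_LEVELS:
            raise ValueError(f"vertebra_level must be one of {VERTEBRA_LEVELS}")
        if not self.pixel_spacing > 0:
            raise ValueError("pixel_spacing must be > 0")
        for name in LANDMARK_NAMES:
            p = getattr(self, name)
            if not (math.isfinite(p[0]) and math.isfinite(p[1])):
                raise ValueError(f"landmark {name} is not finite")
        for sup, inf in (
            ("anterior_superior", "anterior_inferior"),
            ("posterior_superior", "posterior_inferior"),
            ("middle_superior", "middle_inferior"),
        ):
            if getattr(self, sup) == getattr(self, inf):
                raise DegenerateGeometryError(
                    f"{sup} and {inf} coincide; height undefined"
                )

    def points(self) -> dict[str, Point]:
        return {name: getattr(self, name) for name in LANDMARK_NAMES}

    def outline(self) -> list[Point]:
        """Hexagonal outline in anatomical order (superior edge anterior to
        posterior, then inferior edge posterior to anterior)."""
        return [
            self.anterior_superior,
            self.middle_superior,
            self.posterior_superior,
            self.posterior_inferior,
            self.middle_inferior,
            self.anterior_inferior,
        ]

    def outline_pixels(self) -> list[Point]:
        """Outline converted from mm to pixel coordinates."""
        s = self.pixel_spacing
        return [(x / s, y / s) for x, y in self.outline()]


class DeformityClass(str, Enum):
    NORMAL = "normal"
    WEDGE_OR_CRUSH = "wedge_or_crush"
    BICONCAVE = "biconcave"
    SEVERE = "severe"


@dataclass(frozen=True)
class VertebralMorphometry:
    """Heights, width, criterion ratios and deformity flags for one vertebra."""

    vertebra_level: str
    h_a: float
    h_p: float
    h_m: float
    w: float
    r1: float  # min(h_a, h_p) / max(h_a, h_p)
    r2: float  # h_m / max(h_a, h_p)
    r3: float  # max(h_a, h_p) / w
    c1: bool
    c2: bool
    c3: bool

    @property
    def abnormal(self) -> bool:
        return self.c1 or self.c2 or self.c3


def compute_morphometry(landmarks: VertebraLandmarks) -> VertebralMorphometry:
    """Measure one vertebra from its six landmarks.

    Heights are the Euclidean distances within the anterior, posterior and
    middle point pairs.  Width is the mean of the superior-edge and
    inferior-edge anterior-to-posterior distances (the symmetric reading of
    "mean distance between the anterior and posterior points").

    Raises
    ------
    DegenerateGeometryError
        If any height pair coincides or the hexagonal outline
        self-intersects.
    """
    outline = Polygon(landmarks.outline())
    if not outline.is_valid or outline.area <= 0.0:
        raise DegenerateGeometryError("vertebra outline is self-intersecting or flat")

    h_a = _dist(landmarks.anterior_superior, landmarks.anterior_inferior)
    h_p = _dist(landmarks.posterior_superior, landmarks.posterior_inferior)
    h_m = _dist(landmarks.middle_superior, landmarks.middle_inferior)
    w_sup = _dist(landmarks.anterior_superior, landmarks.posterior_superior)
    w_inf = _dist(landmarks.anterior_inferior, landmarks.posterior_inferior)
    if w_sup == 0.0 or w_inf == 0.0:
        raise DegenerateGeometryError("anterior and posterior points coincide")
    w = 0.5 * (w_sup + w_inf)

    hi = max(h_a, h_p)
    r1 = min(h_a, h_p) / hi
    r2 = h_m / hi
    r3 = hi / w
    return VertebralMorphometry(
        vertebra_level=landmarks.vertebra_level,
        h_a=h_a,
        h_p=h_p,
        h_m=h_m,
        w=w,
        r1=r1,
        r2=r2,
        r3=r3,
        c1=r1 < WEDGE_CRUSH_THRESHOLD,
        c2=r2 < BICONCAVE_THRESHOLD,
        c3=r3 < SEVERE_THRESHOLD,
    )


def classify_deformity(m: VertebralMorphometry) -> DeformityClass:
    """Map the criterion flags to a deformity label.

    When several criteria fire the precedence is severe (c3) over
    wedge/crush (c1) over biconcave (c2): a vertebra collapsed enough to
    trip the severe criterion is reported as severe regardless of its
    shape, and an asymmetric height loss dominates a mid-plate depression.
    """
    if m.c3:
        return DeformityClass.SEVERE
    if m.c1:
        return DeformityClass.WEDGE_OR_CRUSH
    if m.c2:
        return DeformityClass.BICONCAVE
    return DeformityClass.NORMAL


# ---------------------------------------------------------------------------
# landmark file format (one vertebra per record; coordinates in mm)
# ---------------------------------------------------------------------------

_HEADER = "# bonescreen landmarks v1"


def write_landmark_file(landmark_sets: Iterable[VertebraLandmarks], fh: TextIO) -> None:
    """Write landmark records as structured text.

    Format::

        # bonescreen landmarks v1
        vertebra L1 pixel_spacing 0.15
        anterior_superior 10.000000 5.000000
        ... (six labelled x,y pairs, mm)
    """
    fh.write(_HEADER + "\n")
    for lm in landmark_sets:
        fh.write(f"vertebra {lm.vertebra_level} pixel_spacing {lm.pixel_spacing!r}\n")
        for name in LANDMARK_NAMES:
            x, y = getattr(lm, name)
            fh.write(f"{name} {x!r} {y!r}\n")


def read_landmark_file(fh: TextIO) -> list[VertebraLandmarks]:
    """Parse the structured-text landmark format written by
    :func:`write_landmark_file`."""
    lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    records: list[VertebraLandmarks] = []
    i = 0
    while i < len(lines):
        head = lines[i].split()
        if head[0] != "vertebra" or len(head) != 4 or head[2] != "pixel_spacing":
            raise ValueError(f"malformed landmark record header: {lines[i]!r}")
        level, spacing = head[1], float(head[3])
        fields: dict[str, Point] = {}
        for j in range(1, 7):
            name, xs, ys = lines[i + j].split()
            if name not in LANDMARK_NAMES:
                raise ValueError(f"unknown landmark name {name!r}")
            fields[name] = (float(xs), float(ys))
        records.append(
            VertebraLandmarks(vertebra_level=level, pixel_spacing=spacing, **fields)
        )
        i += 7
    return records


def morphometry_table(measures: Sequence[VertebralMorphometry]) -> pd.DataFrame:
    """Per-vertebra morphometry rows: four measures, three ratios, flags."""
    return pd.DataFrame(
        [
            {
                "vertebra_level": m.vertebra_level,
                "h_a_mm": m.h_a,
                "h_p_mm": m.h_p,
                "h_m_mm": m.h_m,
                "w_mm": m.w,
                "r1": m.r1,
                "r2": m.r2,
                "r3": m.r3,
                "c1": m.c1,
                "c2": m.c2,
                "c3": m.c3,
                "abnormal": m.abnormal,
                "deformity": classify_deformity(m).value,
            }
            for m in measures
        ]
    )
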