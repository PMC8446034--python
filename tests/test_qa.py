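"""Quality assessment: score aggregation, hip exclusion, spine three-step QA."""

import numpy as np
import pytest
from matplotlib.path import Path as MplPath

from bonescreen.morphometry import VERTEBRA_LEVELS
from bonescreen.phantom import Deformity, PhantomSpec, generate_vertebra_landmarks
from bonescreen.qa import (
    ConfigurationError,
    DetectionMap,
    QAThresholds,
    SyntheticDetector,
    aggregate_roi_score,
    hip_qa,
    neighbor_exclusion,
    spine_qa,
)

SQUARE = [(0.0, 0.0), (10.0, 0.0), (10.0, 10.0), (0.0, 10.0)]


def brute_force_max(values, polygon):
    """Independent oracle: exhaustive scan of every cell centre."""
    h, w = values.shape
    path = MplPath(polygon)
    best = None
    for i in range(h):
        for j in range(w):
            # small positive radius makes the boundary inclusive
            if path.contains_point((j, i), radius=1e-9) or path.contains_point(
                (j, i), radius=-1e-9
            ):
                best = values[i, j] if best is None else max(best, values[i, j])
    return best


class TestAggregateROIScore:
    def test_uniform_zero_map(self):
        dmap = DetectionMap(np.zeros((16, 16)), "fracture")
        assert aggregate_roi_score(dmap, SQUARE) == 0.0

    def test_single_hot_cell_inside(self):
        values = np.full((16, 16), 0.1)
        values[5, 5] = 0.9
        assert aggregate_roi_score(DetectionMap(values, "implant"), SQUARE) == 0.9

    def test_hot_cell_outside_polygon_ignored(self):
        values = np.full((16, 16), 0.1)
        values[15, 15] = 0.9
        assert aggregate_roi_score(DetectionMap(values, "implant"), SQUARE) == 0.1

    def test_matches_brute_force_on_random_polygons(self):
        rng = np.random.default_rng(21)
        for _ in range(100):
            values = rng.random((24, 24))
            centre = rng.uniform(4, 20, 2)
            radii = rng.uniform(2.5, 8.0)
            angles = np.sort(rng.uniform(0, 2 * np.pi, rng.integers(3, 8)))
            poly = [
                (centre[0] + radii * np.cos(a), centre[1] + radii * np.sin(a))
                for a in angles
            ]
            try:
                score = aggregate_roi_score(DetectionMap(values, "vcf"), poly)
            except ValueError:
                continue  # degenerate random polygon
            assert score == brute_force_max(values, poly)

    def test_degenerate_polygons_rejected(self):
        dmap = DetectionMap(np.zeros((8, 8)), "fracture")
        with pytest.raises(ValueError):
            aggregate_roi_score(dmap, [(0, 0), (1, 1)])
        with pytest.raises(ValueError):
            aggregate_roi_score(dmap, [(0, 0), (5, 5), (10, 10)])  # zero area
        with pytest.raises(ValueError):
            aggregate_roi_score(dmap, [(50, 50), (60, 50), (55, 60)])  # outside


class TestHipQA:
    def test_clean_hip_is_admissible(self):
        res = hip_qa(np.zeros((16, 16)), SQUARE, SyntheticDetector())
        assert res.admissible and not res.reasons

    def test_saturated_implant_detector_excludes(self):
        res = hip_qa(np.zeros((16, 16)), SQUARE, SyntheticDetector({"implant"}, hot=1.0))
        assert not res.admissible
        assert res.reasons == {"implant"}

    def test_score_exactly_at_threshold_excludes(self):
        det = SyntheticDetector({"fracture"}, hot=0.5)
        res = hip_qa(np.zeros((16, 16)), SQUARE, det, QAThresholds(fracture=0.5))
        assert not res.admissible and "fracture" in res.reasons


class TestNeighborExclusion:
    def test_homogeneous_values_keep_all(self):
        values = dict(zip(VERTEBRA_LEVELS, (-1.0, -1.1, -0.9, -1.0)))
        assert neighbor_exclusion(values) == set()

    def test_single_interior_outlier_excluded_alone(self):
        values = dict(zip(VERTEBRA_LEVELS, (-1.0, -2.6, -1.0, -1.1)))
        assert neighbor_exclusion(values) == {"L2"}

    def test_deviation_exactly_at_delta_retained(self):
        values = dict(zip(VERTEBRA_LEVELS, (-1.0, -2.0, -1.0, -1.0)))
        # L2 deviates from mean(L1, L3) = -1.0 by exactly 1.0 -> retained
        assert neighbor_exclusion(values) == set()

    def test_endpoint_outlier_excluded(self):
        values = dict(zip(VERTEBRA_LEVELS, (-3.0, -1.2, -1.0, -1.1)))
        assert neighbor_exclusion(values) == {"L1"}

    def test_needs_two_values(self):
        with pytest.raises(ValueError):
            neighbor_exclusion({"L1": -1.0})


def clean_maps(shape=(16, 16)):
    det = SyntheticDetector()
    return {ch: det.detect(np.zeros(shape), ch) for ch in ("implant", "vcf")}


def hot_maps(channels, shape=(16, 16)):
    det = SyntheticDetector(channels)
    return {ch: det.detect(np.zeros(shape), ch) for ch in ("implant", "vcf")}


def vertebra(level, deformity=Deformity.NONE, severity=0.0, y=0.0):
    lm = generate_vertebra_landmarks(
        PhantomSpec(true_bmd=0.8, deformity=deformity, severity=severity),
        vertebra_level=level,
        origin=(1.0, y),
        pixel_spacing=5.0,  # keeps the pixel-space hexagon inside a 16x16 map
    )
    return lm


class TestSpineQA:
    def test_four_clean_vertebrae_all_admissible(self):
        vset = [(vertebra(lv, y=30.0 + 2 * i), clean_maps())
                for i, lv in enumerate(VERTEBRA_LEVELS)]
        values = dict(zip(VERTEBRA_LEVELS, (-1.0, -1.1, -1.0, -0.9)))
        results = spine_qa(vset, values)
        assert all(r.admissible for r in results)

    def test_three_step_trace_leaves_l1_l4(self):
        """L2 VCF-flagged, L3 morphometrically abnormal, L1+L4 clean: the
        scan stays admissible with exactly L1 and L4 assessable."""
        vset = [
            (vertebra("L1", y=30.0), clean_maps()),
            (vertebra("L2", y=32.0), hot_maps({"vcf"})),
            (vertebra("L3", deformity=Deformity.BICONCAVE, severity=0.5, y=34.0),
             clean_maps()),
            (vertebra("L4", y=36.0), clean_maps()),
        ]
        values = dict(zip(VERTEBRA_LEVELS, (-1.0, -1.0, -1.0, -1.1)))
        results = {r.roi_id: r for r in spine_qa(vset, values)}
        assert results["L1"].admissible and results["L4"].admissible
        assert results["L2"].reasons == {"vcf_detected"}
        assert results["L3"].reasons == {"morphometric_deformity"}

    def test_too_few_vertebrae_marks_survivor(self):
        vset = [
            (vertebra("L1", y=30.0), hot_maps({"implant"})),
            (vertebra("L2", y=32.0), hot_maps({"implant"})),
            (vertebra("L3", y=34.0), hot_maps({"implant"})),
            (vertebra("L4", y=36.0), clean_maps()),
        ]
        results = {r.roi_id: r for r in spine_qa(vset, None)}
        assert results["L4"].reasons == {"too_few_vertebrae"}
        assert all(not r.admissible for r in results.values())

    def test_neighbor_step_uses_predicted_values(self):
        vset = [(vertebra(lv, y=30.0 + 2 * i), clean_maps())
                for i, lv in enumerate(VERTEBRA_LEVELS)]
        values = dict(zip(VERTEBRA_LEVELS, (-1.0, -2.6, -1.0, -1.1)))
        results = {r.roi_id: r for r in spine_qa(vset, values)}
        assert results["L2"].reasons == {"neighbor_deviation"}
        assert sum(r.admissible for r in results.values()) == 3

    def test_order_independence(self):
        vset = [(vertebra(lv, y=30.0 + 2 * i), clean_maps())
                for i, lv in enumerate(VERTEBRA_LEVELS)]
        values = dict(zip(VERTEBRA_LEVELS, (-1.0, -2.6, -1.0, -1.1)))
        forward = {r.roi_id: (r.admissible, r.reasons) for r in spine_qa(vset, values)}
        backward = {
            r.roi_id: (r.admissible, r.reasons) for r in spine_qa(vset[::-1], values)
        }
        assert forward == backward

    def test_empty_scan_rejected(self):
        with pytest.raises(ValueError):
            spine_qa([], None)

    def test_missing_detection_map_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            spine_qa([(vertebra("L1", y=30.0), {})], None)
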