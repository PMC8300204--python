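"""Cluster and unrest index formulas against hand and brute-force oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import directed_hausdorff as scipy_dh

from hensight.flock import FlockSimConfig
from hensight.indexes import (
    CameraGeometry,
    UndefinedTermError,
    cluster_index,
    directed_hausdorff,
    index_series,
    mean_pairwise_distance,
    pixel_to_cm_factor,
    unrest_index,
)
from hensight.pipeline import simulate_recording_indexes
from hensight.segmentation import Shape


def brute_mean_pairwise(pts):
    tot, n = 0.0, 0
    for i in range(len(pts)):
        for j in range(i + 1, len(pts)):
            tot += math.dist(pts[i], pts[j])
            n += 1
    return tot / n


def brute_directed_hausdorff(A, B):
    return max(min(math.dist(a, b) for b in B) for a in A)


class TestCameraScale:
    def test_reference_rig_value(self):
        # hand oracle: 2 * 150 * tan(30 deg) / 352
        k = pixel_to_cm_factor(CameraGeometry(150, 60, 352))
        assert k == pytest.approx(300 * math.tan(math.radians(30)) / 352)
        assert k == pytest.approx(0.4921, abs=1e-4)

    def test_degenerate_height(self):
        assert pixel_to_cm_factor(CameraGeometry(0, 60, 352)) == 0.0

    def test_linear_in_height(self):
        k1 = pixel_to_cm_factor(CameraGeometry(150, 60, 352))
        k2 = pixel_to_cm_factor(CameraGeometry(300, 60, 352))
        assert k2 == pytest.approx(2 * k1)

    def test_flat_lens_rejected(self):
        with pytest.raises(ValueError):
            CameraGeometry(150, 180, 352)


class TestMeanPairwiseDistance:
    def test_single_pair(self):
        assert mean_pairwise_distance([(0, 0), (3, 4)]) == 5.0

    def test_collinear_triple(self):
        assert mean_pairwise_distance([(0, 0), (0, 3), (0, 6)]) == 4.0

    def test_matches_double_loop_oracle(self, rng):
        pts = rng.uniform(0, 300, (10, 2))
        assert mean_pairwise_distance(pts) == pytest.approx(
            brute_mean_pairwise(pts.tolist()), abs=1e-9
        )

    def test_fewer_than_two_points_undefined(self):
        with pytest.raises(UndefinedTermError):
            mean_pairwise_distance([(1, 1)])


TOY_SHAPES = [Shape(100, 40, (0.0, 0.0)), Shape(100, 40, (30.0, 40.0))]


class TestClusterIndex:
    def test_two_blob_toy_n_minus_1(self):
        # hand oracle: 2*100*sqrt(240^2+352^2) / (40*50*1) = 42.60
        val = cluster_index(TOY_SHAPES, h=240, w=352)
        assert val == pytest.approx(2 * 100 * math.hypot(240, 352) / (40 * 50 * 1))
        assert val == pytest.approx(42.60, abs=0.01)

    def test_two_blob_toy_n_inverse_is_half(self):
        v1 = cluster_index(TOY_SHAPES, h=240, w=352, variant="n_minus_1")
        v2 = cluster_index(TOY_SHAPES, h=240, w=352, variant="n_inverse")
        assert v2 == pytest.approx(v1 / 2)
        assert v2 == pytest.approx(21.30, abs=0.01)

    def test_strictly_increasing_as_flock_tightens(self):
        # shrinking the mean pair distance with all else fixed raises the index
        vals = []
        for scale in (1.0, 0.5, 0.25):
            shapes = [
                Shape(100, 40, (0.0, 0.0)),
                Shape(100, 40, (30.0 * scale, 40.0 * scale)),
            ]
            vals.append(cluster_index(shapes, h=240, w=352))
        assert vals[0] < vals[1] < vals[2]

    @pytest.mark.parametrize("variant", ["n_minus_1", "n_inverse"])
    def test_translation_invariance(self, variant, rng):
        shapes = [
            Shape(80, 36, tuple(c)) for c in rng.uniform(50, 150, (6, 2))
        ]
        moved = [
            Shape(s.area, s.perimeter, (s.centroid[0] + 17.5, s.centroid[1] - 9.25))
            for s in shapes
        ]
        assert cluster_index(shapes, 240, 352, variant) == pytest.approx(
            cluster_index(moved, 240, 352, variant)
        )

    @pytest.mark.parametrize("variant", ["n_minus_1", "n_inverse"])
    def test_decreasing_in_cluster_count(self, variant, rng):
        # more blobs at the same area/perimeter/spacing -> smaller index
        def ring(n):
            ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
            return [
                Shape(100, 40, (100 + 50 * np.cos(a), 100 + 50 * np.sin(a)))
                for a in ang
            ]

        # D-bar of a regular ring varies with n; divide it out to isolate nA
        vals = []
        for n in (3, 5, 9):
            shapes = ring(n)
            d = mean_pairwise_distance([s.centroid for s in shapes])
            vals.append(cluster_index(shapes, 240, 352, variant) * d)
        assert vals[0] > vals[1] > vals[2]

    def test_single_blob_undefined(self):
        with pytest.raises(UndefinedTermError):
            cluster_index([Shape(100, 40, (0, 0))], 240, 352)


class TestHausdorff:
    def test_identical_sets_zero(self, rng):
        pts = rng.uniform(0, 100, (8, 2))
        assert directed_hausdorff(pts, pts) == 0.0

    def test_asymmetry(self):
        A, B = [(0, 0), (1, 0)], [(0, 0)]
        assert directed_hausdorff(A, B) == 1.0
        assert directed_hausdorff(B, A) == 0.0

    def test_matches_double_loop_oracle(self, rng):
        A = rng.uniform(0, 200, (15, 2))
        B = rng.uniform(0, 200, (15, 2))
        assert directed_hausdorff(A, B) == pytest.approx(
            brute_directed_hausdorff(A.tolist(), B.tolist()), abs=1e-9
        )

    def test_cross_check_against_scipy(self, rng):
        for _ in range(20):
            A = rng.uniform(0, 200, (rng.integers(1, 40), 2))
            B = rng.uniform(0, 200, (rng.integers(1, 40), 2))
            assert directed_hausdorff(A, B) == pytest.approx(
                scipy_dh(A, B)[0], abs=1e-9
            )

    def test_empty_set_undefined(self):
        with pytest.raises(UndefinedTermError):
            directed_hausdorff([], [(0, 0)])


class TestUnrestIndex:
    def test_no_movement_is_zero(self, rng):
        pts = rng.uniform(0, 100, (12, 2))
        assert unrest_index(pts, pts, k=0.7) == 0.0

    def test_rigid_translation_equals_scaled_norm(self, rng):
        # the Hausdorff distance of a rigid translation is the translation norm
        pts = rng.uniform(20, 200, (10, 2))
        moved = pts + np.array([3.0, 4.0])
        assert unrest_index(pts, moved, k=0.5) == pytest.approx(2.5)

    def test_symmetric_in_frame_order(self, rng):
        a = rng.uniform(0, 100, (7, 2))
        b = rng.uniform(0, 100, (9, 2))
        assert unrest_index(a, b, 0.49) == pytest.approx(unrest_index(b, a, 0.49))

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(scale=st.floats(0.1, 10.0))
    def test_linear_in_k(self, scale):
        a = [(0.0, 0.0), (10.0, 5.0)]
        b = [(2.0, 1.0), (12.0, 9.0)]
        assert unrest_index(a, b, scale) == pytest.approx(scale * unrest_index(a, b, 1.0))

    def test_nonnegative_and_zero_iff_equal_sets(self, rng):
        a = rng.uniform(0, 50, (6, 2))
        b = a + 0.5
        assert unrest_index(a, b, 1.0) > 0
        # duplicated points still form the same set
        assert unrest_index(a, np.vstack([a, a[:2]]), 1.0) == 0.0


class TestIndexSeries:
    def _static_table(self, n_frames):
        rows = []
        for f in range(n_frames):
            for b, (x, y) in enumerate([(50.0, 60.0), (150.0, 90.0), (250.0, 200.0)]):
                rows.append((f, float(f), b, 90, 40, x, y))
        return pd.DataFrame(
            rows,
            columns=["frame", "ts_s", "blob_id", "area_px2", "perimeter_px", "cx_px", "cy_px"],
        )

    def test_counts_for_15_min_recording(self):
        # a 900-frame recording at 1 fps yields 900 cluster values and
        # 899 unrest pairs
        series = index_series(
            self._static_table(900), CameraGeometry(), frame_hw=(240, 352)
        )
        assert len(series) == 900
        assert series["cluster_valid"].sum() == 900
        assert series["unrest_valid"].sum() == 899

    def test_static_flock_has_zero_unrest(self):
        series = index_series(
            self._static_table(10), CameraGeometry(), frame_hw=(240, 352)
        )
        assert np.allclose(series["unrest_index_cm"].dropna(), 0.0)

    def test_empty_frames_flagged_not_dropped(self):
        tab = self._static_table(5)
        tab = tab[tab["frame"] != 2]  # frame 2 lost all blobs
        series = index_series(tab, CameraGeometry(), frame_hw=(240, 352))
        assert len(series) == 5
        row = series[series["frame"] == 2].iloc[0]
        assert not row["cluster_valid"] and np.isnan(row["cluster_index"])
        # the pair spanning the gap is broken on both sides
        assert not series[series["frame"] == 3].iloc[0]["unrest_valid"]

    def test_unsorted_frames_rejected(self):
        tab = self._static_table(4).iloc[::-1].reset_index(drop=True)
        with pytest.raises(ValueError):
            index_series(tab, CameraGeometry(), frame_hw=(240, 352))

    def test_unrest_increases_with_motility(self):
        # simulation ground truth: doubling step_sigma raises mean unrest
        means = []
        for sigma in (5.0, 10.0):
            vals = []
            for seed in range(20):
                idx = simulate_recording_indexes(
                    FlockSimConfig(step_sigma=sigma, duration_s=20, seed=1000 + seed)
                )
                vals.append(np.nanmean(idx["unrest_index_cm"]))
            means.append(np.mean(vals))
        assert means[1] > means[0]
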