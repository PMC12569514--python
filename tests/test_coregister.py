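"""Homography estimation/application and pixel -> spot aggregation."""

import numpy as np
import pandas as pd
import pytest

from metalspot import (
    ElementalMap,
    Homography,
    LandmarkSet,
    SpotLayout,
    aggregate_to_spots,
    estimate_homography,
    transform_points,
)
from metalspot.preprocess import TissueMask

UNIT_SQUARE = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])


class TestEstimateHomography:
    def test_identity_correspondences(self):
        h = estimate_homography(LandmarkSet(UNIT_SQUARE, UNIT_SQUARE))
        np.testing.assert_allclose(h.H, np.eye(3), atol=1e-10)
        assert h.rmse == pytest.approx(0.0, abs=1e-10)

    def test_exact_affine_recovery(self):
        A = np.array([[2.0, 0.0, 10.0], [0.0, 2.0, -5.0], [0.0, 0.0, 1.0]])
        rng = np.random.default_rng(0)
        src = rng.uniform(0, 100, (12, 2))
        dst = transform_points(Homography(A), src)
        h = estimate_homography(LandmarkSet(src, dst))
        np.testing.assert_allclose(h.H, A, atol=1e-8)

    def test_exact_projective_recovery(self):
        P = np.array([[1.2, 0.1, 5.0], [-0.05, 0.9, 3.0], [1e-4, -2e-4, 1.0]])
        rng = np.random.default_rng(1)
        src = rng.uniform(0, 200, (20, 2))
        dst = transform_points(Homography(P), src)
        h = estimate_homography(LandmarkSet(src, dst))
        np.testing.assert_allclose(h.H, P, atol=1e-8)

    def test_noisy_landmarks_rmse_bound(self):
        # 30 fiducials, sigma = 1 target noise: empirical bound from a
        # Monte-Carlo oracle run (max observed rmse 1.61 over 100 seeds)
        H_true = Homography(
            np.array([[5.0, 0.2, 30.0], [-0.1, 5.0, 20.0], [0.0, 0.0, 1.0]])
        )
        worst = 0.0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            src = rng.uniform(0, 400, (30, 2))
            dst = transform_points(H_true, src) + rng.normal(0, 1.0, (30, 2))
            h = estimate_homography(LandmarkSet(src, dst))
            worst = max(worst, h.rmse)
        assert worst <= 2.0

    def test_collinear_sources_rejected(self):
        src = np.column_stack([np.arange(5.0), np.arange(5.0) * 2])
        with pytest.raises(ValueError, match="collinear"):
            estimate_homography(LandmarkSet(src, src))

    def test_too_few_or_duplicate_pairs_rejected(self):
        with pytest.raises(ValueError):
            LandmarkSet(UNIT_SQUARE[:3], UNIT_SQUARE[:3])
        dup = np.vstack([UNIT_SQUARE, UNIT_SQUARE[0]])
        with pytest.raises(ValueError, match="duplicate"):
            LandmarkSet(dup, dup)


class TestTransformPoints:
    def test_identity_fixes_points(self):
        pts = np.random.default_rng(0).uniform(-5, 5, (10, 2))
        np.testing.assert_array_equal(transform_points(Homography(np.eye(3)), pts), pts)

    def test_translation_exact(self):
        T = np.array([[1.0, 0.0, 10.0], [0.0, 1.0, -5.0], [0.0, 0.0, 1.0]])
        pts = np.array([[0.0, 0.0], [3.0, 4.0]])
        out = transform_points(Homography(T), pts)
        np.testing.assert_array_equal(out, pts + [10.0, -5.0])

    def test_roundtrip_through_inverse(self):
        P = Homography(np.array([[1.1, 0.2, 3.0], [0.1, 0.9, -2.0], [1e-4, 0.0, 1.0]]))
        pts = np.random.default_rng(1).uniform(0, 100, (50, 2))
        back = transform_points(P.inverse(), transform_points(P, pts))
        np.testing.assert_allclose(back, pts, atol=1e-9)

    def test_point_at_infinity_errors(self):
        P = Homography(np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [1.0, 0.0, 1.0]]))
        with pytest.raises(ValueError, match="infinity"):
            transform_points(P, np.array([[-1.0, 0.0]]))


def one_spot_layout(x=0.0, y=0.0, diameter=55.0):
    return SpotLayout(
        pd.DataFrame({"spot_id": ["s0"], "x_um": [x], "y_um": [y]}),
        diameter_um=diameter,
    )


class TestAggregateToSpots:
    def test_hand_computed_mean_of_pseudologs(self):
        # 4 in-radius pixels {1,1,3,3}: mean(log1p) = (2*0.6931 + 2*1.3863)/4
        data = np.zeros((1, 10, 10), dtype=np.float32)
        data[0, 0, 0] = 1.0
        data[0, 0, 1] = 1.0
        data[0, 1, 0] = 3.0
        data[0, 1, 1] = 3.0
        mask = np.zeros((10, 10), bool)
        mask[:2, :2] = True
        emap = ElementalMap(["Cu"], data, 5.0)
        spots = one_spot_layout(x=0.5, y=0.5)
        sem = aggregate_to_spots(
            emap, TissueMask(mask), spots, Homography(np.eye(3)), min_pixels=1
        )
        assert sem.values.loc["s0", "Cu"] == pytest.approx(
            (2 * np.log1p(1.0) + 2 * np.log1p(3.0)) / 4, abs=1e-6
        )
        assert sem.pixel_count.loc["s0"] == 4

    def test_pixel_just_outside_radius_unassigned(self):
        data = np.ones((1, 1, 2), dtype=np.float32)
        mask = np.ones((1, 2), bool)
        emap = ElementalMap(["Cu"], data, 5.0)
        # pixel 0 at x=0 is the spot centre; pixel 1 at x=radius+eps
        spots = one_spot_layout(x=0.0, y=0.0, diameter=55.0)
        h = Homography(np.array([[27.5 + 1e-6, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]))
        sem = aggregate_to_spots(emap, TissueMask(mask), spots, h, min_pixels=1)
        assert sem.pixel_count.loc["s0"] == 1

    def test_equidistant_pixel_beyond_both_radii(self):
        # two spots 100 um apart; a pixel at 50 um from each is outside the
        # 27.5 um capture radius of both -> zero retained spots
        data = np.ones((1, 1, 1), dtype=np.float32)
        spots = SpotLayout(
            pd.DataFrame(
                {"spot_id": ["a", "b"], "x_um": [0.0, 100.0], "y_um": [0.0, 0.0]}
            ),
            diameter_um=55.0,
        )
        h = Homography(np.array([[1.0, 0.0, 50.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]))
        with pytest.raises(ValueError):
            aggregate_to_spots(
                ElementalMap(["Cu"], data, 5.0),
                TissueMask(np.ones((1, 1), bool)),
                spots,
                h,
                min_pixels=1,
            )

    def test_constant_blocks_give_exact_log1p(self):
        # identity H, spots centred on pixel blocks of constant value v
        v = 4.0
        data = np.full((1, 40, 40), v, dtype=np.float32)
        emap = ElementalMap(["Cu"], data, 5.0)
        spots = SpotLayout(
            pd.DataFrame(
                {"spot_id": ["a", "b"], "x_um": [10.0, 30.0], "y_um": [20.0, 20.0]}
            ),
            diameter_um=16.0,
        )
        sem = aggregate_to_spots(
            emap, TissueMask(np.ones((40, 40), bool)), spots, Homography(np.eye(3)),
            min_pixels=1,
        )
        np.testing.assert_allclose(sem.values.to_numpy(), np.log1p(v), rtol=1e-6)

    def test_partition_each_pixel_counts_once(self):
        rng = np.random.default_rng(0)
        data = rng.gamma(2, 1, (1, 60, 60)).astype(np.float32)
        emap = ElementalMap(["Cu"], data, 5.0)
        xs, ys = np.meshgrid(np.arange(3) * 20.0 + 10, np.arange(3) * 20.0 + 10)
        spots = SpotLayout(
            pd.DataFrame(
                {
                    "spot_id": [f"s{i}" for i in range(9)],
                    "x_um": xs.ravel(),
                    "y_um": ys.ravel(),
                }
            ),
            diameter_um=19.0,
        )
        sem = aggregate_to_spots(
            emap, TissueMask(np.ones((60, 60), bool)), spots, Homography(np.eye(3)),
            min_pixels=1, radius_um=10.0,
        )
        # radius = half pitch: assigned pixel sets tile without overlap
        assert sem.pixel_count.sum() <= 60 * 60

    def test_permutation_invariance_in_spot_order(self):
        rng = np.random.default_rng(1)
        data = rng.gamma(2, 1, (2, 50, 50)).astype(np.float32)
        emap = ElementalMap(["Cu", "Fe"], data, 5.0)
        xs, ys = np.meshgrid(np.arange(2) * 25.0 + 12, np.arange(2) * 25.0 + 12)
        table = pd.DataFrame(
            {
                "spot_id": [f"s{i}" for i in range(4)],
                "x_um": xs.ravel(),
                "y_um": ys.ravel(),
            }
        )
        mask = TissueMask(np.ones((50, 50), bool))
        a = aggregate_to_spots(emap, mask, SpotLayout(table), Homography(np.eye(3)), min_pixels=1)
        b = aggregate_to_spots(
            emap, mask, SpotLayout(table.iloc[::-1]), Homography(np.eye(3)), min_pixels=1
        )
        pd.testing.assert_frame_equal(
            a.values.sort_index(), b.values.sort_index()
        )

    def test_min_pixels_drops_sparse_spots(self):
        data = np.ones((1, 10, 10), dtype=np.float32)
        mask = np.zeros((10, 10), bool)
        mask[0, 0] = True                       # one usable pixel near spot a
        mask[5:9, 5:9] = True                   # 16 pixels near spot b
        spots = SpotLayout(
            pd.DataFrame(
                {"spot_id": ["a", "b"], "x_um": [0.0, 6.5], "y_um": [0.0, 6.5]}
            ),
            diameter_um=7.0,
        )
        sem = aggregate_to_spots(
            ElementalMap(["Cu"], data, 5.0), TissueMask(mask), spots,
            Homography(np.eye(3)), min_pixels=3, radius_um=3.0,
        )
        assert list(sem.values.index) == ["b"]
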