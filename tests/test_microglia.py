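"""Binarization, skeleton properties and the 2D Sholl crossing machinery."""

import numpy as np
import pytest
from scipy import ndimage

from oracles import sholl_2d_crossings
from gliaquant.imgsim import SimParams, generate_cortex_stack
from gliaquant.microglia import (
    Skeleton,
    binarize,
    identity_baseline,
    ramification_metrics,
    skeletonize,
    sholl_2d,
    zone_statistics,
)


def _line_skeleton(size=201, half_len_px=100):
    px = np.zeros((size, size), bool)
    c = size // 2
    px[c, c - half_len_px : c + half_len_px + 1] = True
    return Skeleton(px, 1.0), (c + 0.5, c + 0.5)


def _cross_skeleton(size=201, half_len_px=100):
    skel, center = _line_skeleton(size, half_len_px)
    c = size // 2
    skel.pixels[c - half_len_px : c + half_len_px + 1, c] = True
    return skel, center


class TestBinarize:
    def test_manual_level_on_zeros(self):
        mask, level = binarize(np.zeros((8, 8)), manual_level=1.0)
        assert not mask.any() and level == 1.0

    def test_otsu_separates_bimodal_halves(self):
        img = np.zeros((20, 20))
        img[:, 10:] = 100.0
        mask, _ = binarize(img)
        assert np.array_equal(mask, img == 100.0)

    def test_flat_image_with_otsu_fails_with_advice(self):
        with pytest.raises(ValueError, match="manual_level"):
            binarize(np.full((8, 8), 3.0))


class TestSkeletonize:
    def test_wide_bar_thins_to_line(self):
        mask = np.zeros((20, 60), bool)
        mask[8:13, 5:55] = True
        skel = skeletonize(mask, 1.0)
        # away from the bar ends the skeleton is a one-pixel horizontal line
        core = skel.pixels[:, 15:45]
        assert np.all(core.sum(axis=0) == 1)

    def test_idempotent_on_arbor_masks(self, small_layout):
        params = SimParams(nucleus_count={"negative": 0, "cfos_plus": 0,
                                          "cfos_plusplus": 0}, noise_sd=0.0, seed=2)
        stack, _ = generate_cortex_stack(params, small_layout, nz=1)
        mask, _ = binarize(stack.channel("microglia"))
        once = skeletonize(mask, 0.5).pixels
        twice = skeletonize(once, 0.5).pixels
        assert np.array_equal(once, twice)

    def test_component_count_preserved(self, rng):
        struct = np.ones((3, 3), int)
        for seed in range(20):
            r = np.random.default_rng(seed)
            mask = ndimage.binary_dilation(r.random((80, 80)) > 0.965, iterations=2)
            before = ndimage.label(mask, structure=struct)[1]
            after = ndimage.label(skeletonize(mask, 1.0).pixels, structure=struct)[1]
            assert after == before

    def test_empty_in_empty_out(self):
        assert not skeletonize(np.zeros((5, 5), bool), 1.0).pixels.any()


class TestRamificationMetrics:
    def test_trivial_fields(self):
        img = np.full((10, 10), 4.0)
        empty = np.zeros((10, 10), bool)
        m = ramification_metrics(img, empty, Skeleton(empty, 1.0))
        assert m["skeleton_area_pct"] == 0 and m["threshold_area_pct"] == 0
        assert m["mean_gray"] == pytest.approx(4.0)
        full = np.ones((10, 10), bool)
        assert ramification_metrics(img, full, Skeleton(empty, 1.0))[
            "threshold_area_pct"
        ] == 100.0

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            ramification_metrics(
                np.zeros((5, 5)), np.zeros((6, 6), bool),
                Skeleton(np.zeros((5, 5), bool), 1.0),
            )


class TestSholl2D:
    def test_line_cuts_every_circle_twice(self):
        skel, center = _line_skeleton()
        prof = sholl_2d(skel, center, r_max_um=49, dr_um=1)
        assert np.all(prof.crossings == 2)

    def test_cross_cuts_four_times(self):
        skel, center = _cross_skeleton()
        prof = sholl_2d(skel, center, r_max_um=49, dr_um=1)
        # the 4-pixel ring at r=1 cannot separate the four arms
        assert np.all(prof.crossings[1:] == 4)

    def test_empty_skeleton_all_zero(self):
        skel = Skeleton(np.zeros((64, 64), bool), 1.0)
        prof = sholl_2d(skel, (32.0, 32.0), r_max_um=20, dr_um=1)
        assert np.all(prof.crossings == 0)

    def test_center_outside_rejected(self):
        skel = Skeleton(np.zeros((32, 32), bool), 1.0)
        with pytest.raises(ValueError, match="outside"):
            sholl_2d(skel, (100.0, 5.0))

    def test_out_of_bounds_circle_flagged_partial(self):
        skel, _ = _line_skeleton(size=61, half_len_px=30)
        prof = sholl_2d(skel, (5.5, 30.5), r_max_um=20, dr_um=1)
        assert prof.partial[-1]

    def test_matches_walk_oracle_on_random_skeletons(self):
        for seed in range(15):
            r = np.random.default_rng(seed)
            mask = r.random((96, 96)) > 0.92
            skel = skeletonize(mask, 1.0)
            cx, cy = r.integers(10, 86, 2)
            prof = sholl_2d(skel, (cx + 0.5, cy + 0.5), r_max_um=25, dr_um=1)
            for radius, got in zip(prof.radii_um, prof.crossings):
                assert got == sholl_2d_crossings(
                    skel.pixels, (int(cx), int(cy)), int(round(radius))
                )

    def test_rotating_the_grid_preserves_counts(self):
        r = np.random.default_rng(8)
        mask = skeletonize(r.random((81, 81)) > 0.9, 1.0).pixels
        center = (40.5, 40.5)
        p0 = sholl_2d(Skeleton(mask, 1.0), center, 30, 1).crossings
        p90 = sholl_2d(Skeleton(np.rot90(mask).copy(), 1.0), center, 30, 1).crossings
        assert np.array_equal(p0, p90)

    def test_adding_pixels_never_reduces_crossings(self):
        r = np.random.default_rng(3)
        base = r.random((64, 64)) > 0.95
        extra = base | (r.random((64, 64)) > 0.97)
        c = (32.5, 32.5)
        p_base = sholl_2d(Skeleton(base, 1.0), c, 20, 1).crossings
        p_more = sholl_2d(Skeleton(extra, 1.0), c, 20, 1).crossings
        assert np.all(p_more >= p_base)


class TestIdentityBaseline:
    def test_identity_curve_flattens_to_zero(self):
        radii = np.arange(1.0, 21.0)
        prof = sholl_2d(Skeleton(np.zeros((64, 64), bool), 1.0), (32.0, 32.0), 20, 1)
        prof.crossings = radii.astype(int)
        adj = identity_baseline(prof)
        assert np.allclose(adj.baseline_adjusted, 0.0)

    def test_empty_profile_maps_to_minus_radius_and_inverts(self):
        prof = sholl_2d(Skeleton(np.zeros((64, 64), bool), 1.0), (32.0, 32.0), 20, 1)
        adj = identity_baseline(prof)
        assert np.allclose(adj.baseline_adjusted, -adj.radii_um)
        assert np.array_equal(adj.baseline_adjusted + adj.radii_um, adj.crossings)


class TestZoneStatistics:
    def _profiles(self, values, n=10):
        skel = Skeleton(np.zeros((128, 128), bool), 1.0)
        profs = []
        for v in range(n):
            p = sholl_2d(skel, (64.0, 64.0), 40, 1)
            p.crossings = np.full(len(p.radii_um), values(v), dtype=int)
            profs.append(p)
        return profs

    def test_identical_groups_not_significant(self):
        groups = {"a": self._profiles(lambda v: 3), "b": self._profiles(lambda v: 3)}
        _, tests = zone_statistics(groups)
        assert (tests["p"] > 0.9).all()

    def test_fully_separated_groups_give_zero_u(self):
        groups = {
            "lo": self._profiles(lambda v: v),
            "hi": self._profiles(lambda v: 100 + v),
        }
        _, tests = zone_statistics(groups)
        n1n2 = 100
        for _, row in tests.iterrows():
            assert min(row["U"], n1n2 - row["U"]) == 0
            assert row["p"] < 1e-3

    def test_single_center_group_rejected(self):
        groups = {"a": self._profiles(lambda v: 1, n=1), "b": self._profiles(lambda v: 1)}
        with pytest.raises(ValueError, match="2 centers"):
            zone_statistics(groups)
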