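import math

import numpy as np
import pytest

from cephalo.core import ContractError, CropTransform, ImageSpace, LandmarkSet, N_LANDMARKS
from cephalo.heatmaps import (
    DecodeError,
    HeatmapStack,
    ParameterError,
    decode,
    encode,
    heatmap_l2_loss,
)


def make_set(scheme, coords_px, side=256):
    space = ImageSpace(side, side, mm_per_px=None)
    return LandmarkSet(scheme, space, coords_px, role="ground_truth")


def grid_coords(scheme, seed=0, lo=40.0, hi=200.0):
    rng = np.random.default_rng(seed)
    return rng.uniform(lo, hi, size=(N_LANDMARKS, 2))


class TestEncode:
    def test_normalized_peak_value_sigma1(self, scheme):
        coords = np.full((N_LANDMARKS, 2), 80.0)  # heatmap node (20, 20) at r=4
        ls = make_set(scheme, coords)
        hs = encode(ls, sigma=1.0, grid_shape=(64, 64), normalized=True)
        assert hs.maps[0, 20, 20] == pytest.approx(1.0 / (2.0 * math.pi))

    def test_peak1_variant_is_one_at_center(self, scheme):
        coords = np.full((N_LANDMARKS, 2), 80.0)
        ls = make_set(scheme, coords)
        hs = encode(ls, sigma=2.7, grid_shape=(64, 64), normalized=False)
        assert hs.maps[5, 20, 20] == pytest.approx(1.0)

    def test_hand_evaluated_off_center_value(self, scheme):
        # landmark at heatmap (10, 20); value at (13, 20) derived by hand from
        # the Gaussian formula: exp(-9 / (2 * 1.5^2)) / (2 pi 1.5^2)
        coords = np.zeros((N_LANDMARKS, 2))
        coords[:, 0] = 40.0  # x -> 10
        coords[:, 1] = 80.0  # y -> 20
        ls = make_set(scheme, coords)
        hs = encode(ls, sigma=1.5, grid_shape=(64, 64), normalized=True)
        expected = math.exp(-9.0 / 4.5) / (2.0 * math.pi * 2.25)
        assert hs.maps[0, 20, 13] == pytest.approx(expected, rel=1e-12)

    def test_sigma_must_be_positive(self, scheme):
        ls = make_set(scheme, grid_coords(scheme))
        with pytest.raises(ParameterError):
            encode(ls, sigma=0.0)

    def test_off_grid_landmark_truncated_not_error(self, scheme):
        coords = grid_coords(scheme)
        coords[0] = (-400.0, -400.0)
        ls = make_set(scheme, coords)
        hs = encode(ls, sigma=1.5, grid_shape=(64, 64))
        assert np.all(np.isfinite(hs.maps))
        assert hs.maps[0].max() < hs.maps[1].max()

    def test_normalized_mass_is_one_interior(self, scheme):
        coords = np.full((N_LANDMARKS, 2), 128.0)  # center, far from borders
        ls = make_set(scheme, coords)
        hs = encode(ls, sigma=1.5, grid_shape=(64, 64), normalized=True)
        assert hs.maps[0].sum() == pytest.approx(1.0, abs=1e-3)

    def test_integer_translation_equivariance(self, scheme):
        coords = grid_coords(scheme, seed=3, lo=60.0, hi=120.0)
        ls1 = make_set(scheme, coords)
        ls2 = make_set(scheme, coords + 4.0 * 3)  # 3 heatmap px at r=4
        h1 = encode(ls1, sigma=1.5, grid_shape=(64, 64)).maps
        h2 = encode(ls2, sigma=1.5, grid_shape=(64, 64)).maps
        np.testing.assert_allclose(h2[:, 3:, 3:], h1[:, :-3, :-3], atol=1e-12)


class TestDecode:
    def test_single_pixel_maps_to_input_space(self, scheme):
        maps = np.zeros((N_LANDMARKS, 64, 64))
        maps[:, 20, 10] = 1.0  # (x=10, y=20)
        hs = HeatmapStack(maps=maps, sigma=1.5, reduction=4)
        space = ImageSpace(256, 256, mm_per_px=None)
        ls = decode(hs, scheme, space, offset=False)
        assert ls.role == "stage1"
        np.testing.assert_allclose(ls.coords, np.tile([40.0, 80.0], (N_LANDMARKS, 1)))

    def test_symmetric_gaussian_no_offset_applied(self, scheme):
        coords = np.full((N_LANDMARKS, 2), 80.0)  # exactly on node (20, 20)
        ls = make_set(scheme, coords)
        hs = encode(ls, sigma=1.5, grid_shape=(64, 64))
        dec = decode(hs, scheme, ls.space, offset=True)
        np.testing.assert_allclose(dec.coords, coords, atol=1e-12)

    def test_subpixel_shift_goes_quarter_pixel_toward_larger_neighbor(self, scheme):
        coords = np.full((N_LANDMARKS, 2), 80.0)
        coords[:, 0] += 0.3 * 4  # +0.3 heatmap px in x
        ls = make_set(scheme, coords)
        hs = encode(ls, sigma=1.5, grid_shape=(64, 64))
        dec = decode(hs, scheme, ls.space, offset=True)
        # argmax stays at node 20; right neighbor is larger -> +0.25 hm px = +1 input px
        np.testing.assert_allclose(dec.coords[:, 0], 81.0, atol=1e-12)
        np.testing.assert_allclose(dec.coords[:, 1], 80.0, atol=1e-12)

    def test_all_equal_channel_raises_naming_channel(self, scheme):
        maps = np.zeros((N_LANDMARKS, 8, 8))
        maps[1:, 3, 3] = 1.0  # channel 1 (index 0) stays flat
        hs = HeatmapStack(maps=maps, sigma=1.5, reduction=4)
        with pytest.raises(DecodeError, match="channel 1"):
            decode(hs, scheme, ImageSpace(32, 32, mm_per_px=None))

    def test_crop_inversion(self, scheme, space1200):
        crop = CropTransform.full_frame(space1200, target_side=256)
        rng = np.random.default_rng(5)
        coords = rng.uniform(150.0, 1050.0, size=(N_LANDMARKS, 2))
        ls = LandmarkSet(scheme, space1200, coords)
        hs = encode(ls, sigma=1.5, grid_shape=(64, 64), crop=crop)
        dec = decode(hs, scheme, space1200, offset=True)
        # 0.25 hm px residual * 4 (reduction) / (256/1200) scale ~= 4.7 source px
        assert np.max(np.abs(dec.coords - coords)) <= 0.5 * 4 / crop.scale


class TestRoundTripProperties:
    def test_round_trip_within_half_heatmap_px(self, scheme):
        worst = 0.0
        for seed in range(100):
            coords = grid_coords(scheme, seed=seed, lo=16.0, hi=240.0)
            ls = make_set(scheme, coords)
            hs = encode(ls, sigma=1.5, grid_shape=(64, 64))
            dec = decode(hs, scheme, ls.space, offset=True)
            err_hm = np.hypot(*((dec.coords - coords) / 4.0).T)
            worst = max(worst, err_hm.max())
        assert worst <= 0.5

    def test_offset_reduces_mean_error(self, scheme):
        errs_on, errs_off = [], []
        for seed in range(100):
            coords = grid_coords(scheme, seed=1000 + seed, lo=16.0, hi=240.0)
            ls = make_set(scheme, coords)
            hs = encode(ls, sigma=1.5, grid_shape=(64, 64))
            for flag, acc in ((True, errs_on), (False, errs_off)):
                dec = decode(hs, scheme, ls.space, offset=flag)
                acc.append(np.hypot(*(dec.coords - coords).T).mean())
        assert np.mean(errs_on) <= np.mean(errs_off)


class TestLoss:
    def test_identical_is_zero(self, scheme):
        ls = make_set(scheme, grid_coords(scheme))
        hs = encode(ls, sigma=1.5)
        assert heatmap_l2_loss(hs, hs) == 0.0

    def test_single_pixel_difference(self, scheme):
        maps = np.zeros((N_LANDMARKS, 8, 8))
        gt = HeatmapStack(maps=maps.copy(), sigma=1.5)
        pred_maps = maps.copy()
        pred_maps[4, 2, 2] = 2.0
        pred = HeatmapStack(maps=pred_maps, sigma=1.5)
        assert heatmap_l2_loss(gt, pred) == pytest.approx(4.0)

    def test_matches_brute_force_loop(self, scheme):
        rng = np.random.default_rng(8)
        a = HeatmapStack(maps=rng.random((N_LANDMARKS, 6, 5)), sigma=1.0)
        b = HeatmapStack(maps=rng.random((N_LANDMARKS, 6, 5)), sigma=1.0)
        total = 0.0
        for c in range(N_LANDMARKS):
            for i in range(6):
                for j in range(5):
                    total += (a.maps[c, i, j] - b.maps[c, i, j]) ** 2
        assert heatmap_l2_loss(a, b) == pytest.approx(total, rel=1e-12)

    def test_shape_mismatch(self, scheme):
        a = HeatmapStack(maps=np.zeros((N_LANDMARKS, 8, 8)), sigma=1.0)
        b = HeatmapStack(maps=np.zeros((N_LANDMARKS, 4, 4)), sigma=1.0)
        with pytest.raises(ContractError):
            heatmap_l2_loss(a, b)
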