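"""Segmentation chains against analytic phantoms and exhaustive oracles."""

import numpy as np
import pytest

from coilwatch import (
    LevelSetParams,
    SeedError,
    fill_internal_holes,
    grayscale_open,
    levelset_refine,
    otsu_threshold,
    segment_coil,
    segment_vascular,
)
from coilwatch.segmentation import DegenerateImageError
from coilwatch.volumes import BinaryMask, ImageVolume


def otsu_oracle(values):
    """Independent exhaustive search over all candidate cuts."""
    values = np.asarray(values, float)
    uniq = np.unique(values)
    best_t, best_v = None, -1.0
    for i in range(len(uniq) - 1):
        t = 0.5 * (uniq[i] + uniq[i + 1])
        lo, hi = values[values <= t], values[values > t]
        w0, w1 = len(lo) / len(values), len(hi) / len(values)
        v = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if v > best_v + 1e-12:
            best_v, best_t = v, t
    return best_t


def dice(a, b):
    return 2 * np.logical_and(a, b).sum() / (a.sum() + b.sum())


def ball_image(radius_mm=3.0, n=48, spacing=0.25, fg=100.0, bg=10.0, noise=0.0, seed=0):
    x = (np.arange(n) * spacing)[:, None, None]
    y = (np.arange(n) * spacing)[None, :, None]
    z = (np.arange(n) * spacing)[None, None, :]
    c = n * spacing / 2
    mask = (x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2 <= radius_mm**2
    vals = np.where(mask, fg, bg)
    if noise:
        vals = vals + np.random.default_rng(seed).normal(0, noise, vals.shape)
    return ImageVolume(vals, spacing=(spacing,) * 3), mask


# ---------------------------------------------------------------------------
# grayscale opening
# ---------------------------------------------------------------------------

class TestGrayscaleOpen:
    def test_radius_zero_identity(self):
        vol, _ = ball_image(noise=3, seed=1)
        assert np.array_equal(grayscale_open(vol, 0).values, vol.values)

    def test_removes_single_bright_voxel(self):
        vals = np.zeros((9, 9, 9))
        vals[4, 4, 4] = 50.0
        out = grayscale_open(ImageVolume(vals, spacing=(1, 1, 1)), 1)
        assert out.values[4, 4, 4] == 0.0

    def test_constant_unchanged_and_antiextensive(self):
        vol = ImageVolume(np.full((8, 8, 8), 7.0), spacing=(1, 1, 1))
        assert np.array_equal(grayscale_open(vol, 1).values, vol.values)
        noisy, _ = ball_image(noise=5, seed=2)
        assert np.all(grayscale_open(noisy, 1).values <= noisy.values + 1e-12)

    def test_idempotent(self):
        vol, _ = ball_image(noise=5, seed=3)
        once = grayscale_open(vol, 1)
        twice = grayscale_open(once, 1)
        assert np.allclose(once.values, twice.values)

    def test_oversized_radius_rejected(self):
        vol, _ = ball_image(n=16)
        with pytest.raises(ValueError):
            grayscale_open(vol, 10)


# ---------------------------------------------------------------------------
# Otsu
# ---------------------------------------------------------------------------

class TestOtsu:
    def test_splits_two_point_masses(self):
        values = np.array([0.0] * 50 + [100.0] * 50)
        t = otsu_threshold(values)
        assert 0 < t < 100

    def test_two_gaussian_modes(self, rng):
        values = np.concatenate(
            [rng.normal(10, 5, 400), rng.normal(200, 5, 400)]
        )
        t = otsu_threshold(values)
        assert 25 < t < 185

    def test_binary_values_stable_convention(self):
        assert otsu_threshold(np.array([0.0, 1.0, 0.0, 1.0])) == pytest.approx(0.5)

    def test_degenerate_histogram_rejected(self):
        with pytest.raises(DegenerateImageError):
            otsu_threshold(np.full(10, 3.0))
        with pytest.raises(DegenerateImageError):
            otsu_threshold(np.array([1.0]))

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(30):
            values = rng.integers(0, 12, size=rng.integers(5, 40)).astype(float)
            if len(np.unique(values)) < 2:
                continue
            ours = otsu_threshold(values)
            oracle = otsu_oracle(values)
            # identical class split, allowing different within-gap placement
            assert np.array_equal(values > ours, values > oracle)


# ---------------------------------------------------------------------------
# hole filling
# ---------------------------------------------------------------------------

class TestFillInternalHoles:
    def _mask(self, arr):
        return BinaryMask(arr, spacing=(1, 1, 1))

    def test_hollow_sphere_becomes_solid(self):
        _, ball = ball_image(radius_mm=5, n=24, spacing=1.0)
        _, inner = ball_image(radius_mm=3, n=24, spacing=1.0)
        shell = ball & ~inner
        filled = fill_internal_holes(self._mask(shell))
        assert np.array_equal(filled.values, ball)

    def test_torus_through_hole_retained(self):
        n = 32
        x, y, z = np.mgrid[0:n, 0:n, 0:n]
        c = n / 2
        r_major, r_minor = 9.0, 3.5
        d = (np.sqrt((x - c) ** 2 + (y - c) ** 2) - r_major) ** 2 + (z - c) ** 2
        torus = d <= r_minor**2
        out = fill_internal_holes(self._mask(torus))
        assert np.array_equal(out.values, torus)

    def test_solid_cube_idempotent(self):
        cube = np.zeros((10, 10, 10), bool)
        cube[2:8, 2:8, 2:8] = True
        out = fill_internal_holes(self._mask(cube))
        assert np.array_equal(out.values, cube)

    def test_output_superset_and_errors(self):
        cube = np.zeros((8, 8, 8), bool)
        cube[2:6, 2:6, 2:6] = True
        cube[3, 3, 3] = False
        out = fill_internal_holes(self._mask(cube), connectivity=6)
        assert out.values[3, 3, 3]
        assert np.all(out.values >= cube)
        with pytest.raises(ValueError):
            fill_internal_holes(self._mask(np.zeros((4, 4, 4), bool)))
        with pytest.raises(ValueError):
            fill_internal_holes(self._mask(cube), connectivity=18)


# ---------------------------------------------------------------------------
# level set
# ---------------------------------------------------------------------------

class TestLevelSet:
    def test_zero_iterations_identity(self):
        vol, mask = ball_image()
        init = BinaryMask(mask, spacing=vol.spacing)
        out = levelset_refine(vol, init, LevelSetParams(iterations=0))
        assert np.array_equal(out.values, init.values)

    def test_empty_init_rejected(self):
        vol, _ = ball_image()
        with pytest.raises(ValueError):
            levelset_refine(vol, BinaryMask(np.zeros(vol.shape, bool), spacing=vol.spacing))

    def test_recovers_eroded_sphere(self):
        from scipy import ndimage

        vol, mask = ball_image(noise=0.0)
        eroded = ndimage.binary_erosion(mask)
        out = levelset_refine(
            vol, BinaryMask(eroded, spacing=vol.spacing), LevelSetParams(iterations=10)
        )
        assert dice(out.values, mask) >= 0.95

    def test_front_locality_bound(self, rng):
        # balloon, attachment and smoothing each move the front at most one
        # voxel per iteration: even on pure noise the result stays within a
        # 3-voxel/iteration neighborhood of the init
        from scipy import ndimage

        vals = rng.normal(0, 1, (32, 32, 32))
        init = np.zeros((32, 32, 32), bool)
        init[14:18, 14:18, 14:18] = True
        params = LevelSetParams(iterations=4)
        out = levelset_refine(
            ImageVolume(vals, spacing=(1, 1, 1)),
            BinaryMask(init, spacing=(1, 1, 1)),
            params,
        )
        allowed = ndimage.binary_dilation(init, iterations=3 * params.iterations)
        assert not np.any(out.values & ~allowed)


# ---------------------------------------------------------------------------
# full chains on phantoms
# ---------------------------------------------------------------------------

class TestVascularChain:
    def test_volume_within_5pct_of_truth(self, tiny_scenario, tiny_subject):
        images, truth = tiny_subject
        mask = segment_vascular(images["1-"]["subtracted"], truth.seed_point_mm)
        # truth: sac ellipsoid + vessel capsule, minus their lens overlap;
        # bound with the voxelized union of the generating solids
        sc = tiny_scenario
        from coilwatch.phantoms import _ellipsoid_mask, _polyline_mask

        solids = _ellipsoid_mask(sc, sc.sac_center_mm["1-"], sc.sac_axes_mm["1-"])
        solids |= _polyline_mask(sc, sc.vessel_path_mm, sc.vessel_radius_mm)
        true_cc = solids.sum() * mask.voxel_volume_mm3 / 1000.0
        assert mask.volume_cc() == pytest.approx(true_cc, rel=0.05)

    def test_seed_insensitive(self, tiny_subject):
        images, truth = tiny_subject
        seed = np.asarray(truth.seed_point_mm)
        m1 = segment_vascular(images["1-"]["subtracted"], seed)
        m2 = segment_vascular(images["1-"]["subtracted"], seed + [0.8, -0.6, 0.5])
        assert np.array_equal(m1.values, m2.values)

    def test_background_seed_rejected(self, tiny_subject):
        images, _ = tiny_subject
        with pytest.raises(SeedError):
            segment_vascular(images["1-"]["subtracted"], (0.9, 0.9, 0.9))
        with pytest.raises(SeedError):
            segment_vascular(images["1-"]["subtracted"], (-5.0, 2.0, 2.0))


class TestCoilChain:
    def test_volume_within_10pct_of_truth(self, tiny_subject):
        images, truth = tiny_subject
        seed = np.asarray(truth.seed_point_mm)
        mask = segment_coil(images["1+"]["baseline"], voi_mm=(seed - 6.0, seed + 6.0))
        assert mask.volume_cc() == pytest.approx(
            truth.true_coil_volume_cc["1+"], rel=0.10
        )

    def test_sealed_cavity_filled_tunnel_retained(self):
        # hollow ball -> cavity filled; torus-like through hole -> retained
        n, sp = 40, 0.5
        x = (np.arange(n) * sp)[:, None, None]
        y = (np.arange(n) * sp)[None, :, None]
        z = (np.arange(n) * sp)[None, None, :]
        c = n * sp / 2
        r = np.sqrt((x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2)
        shell = (r <= 6.0) & (r >= 3.0)
        tunnel = (x - c) ** 2 + (y - c) ** 2 <= 1.44  # bore along z
        solid_with_cavity = shell & ~tunnel * 0  # sealed shell
        vals = np.where(shell, 180.0, 10.0)
        vol = ImageVolume(vals, spacing=(sp,) * 3, modality="baseline")
        mask = segment_coil(vol)
        center = (n // 2,) * 3
        assert mask.values[center]  # cavity included in the coil mass

        bored = shell & ~tunnel
        vol2 = ImageVolume(np.where(bored, 180.0, 10.0), spacing=(sp,) * 3, modality="baseline")
        mask2 = segment_coil(vol2)
        assert not mask2.values[center]  # through-tunnel stays open

    def test_no_coil_rejected(self):
        vol = ImageVolume(np.full((16, 16, 16), 10.0), spacing=(1, 1, 1), modality="baseline")
        with pytest.raises(ValueError):
            segment_coil(vol)


def test_noise_robustness_monotone(tiny_scenario):
    """Dice against truth does not improve as intensity noise rises."""
    from coilwatch import make_subject
    from coilwatch.phantoms import _ellipsoid_mask, _polyline_mask
    from dataclasses import replace

    scores = []
    for noise in (2.0, 8.0, 20.0):
        sc = replace(tiny_scenario, noise_sd=noise)
        images, truth = make_subject(sc)
        mask = segment_vascular(images["1-"]["subtracted"], truth.seed_point_mm)
        solids = _ellipsoid_mask(sc, sc.sac_center_mm["1-"], sc.sac_axes_mm["1-"])
        solids |= _polyline_mask(sc, sc.vessel_path_mm, sc.vessel_radius_mm)
        scores.append(dice(mask.values, solids))
    assert scores[0] >= 0.9
    for lo, hi in zip(scores[1:], scores[:-1]):
        assert lo <= hi + 0.01
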