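"""Structure-tensor orientations, k-means segmentation and patch metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cordisp.grids import RegularGrid
from cordisp.histology import (
    HistologyImage,
    OrientationField,
    make_patch_grid,
    patch_circular_variance,
    patch_staining_fraction,
    segment_neurites,
    segment_stain,
    structure_tensor_orientations,
)


def _stripe_image(angle_deg, n=300, period=12.0, pixel_um=1.008):
    i, j = np.mgrid[0:n, 0:n].astype(float)
    t = np.deg2rad(angle_deg)
    phase = -np.sin(t) * i + np.cos(t) * j  # varies across the stripes
    return HistologyImage(0.5 + 0.4 * np.sin(2 * np.pi * phase / period), pixel_um)


class TestStructureTensor:
    @pytest.mark.parametrize("angle", [0.0, 30.0, 75.0, 120.0])
    def test_recovers_stripe_orientation(self, angle):
        img = _stripe_image(angle)
        fld = structure_tensor_orientations(img, 1.0, 4.0)
        core = fld.weight[40:-40, 40:-40] > 0.5
        th = np.degrees(fld.theta[40:-40, 40:-40][core])
        dev = np.abs((th - angle + 90) % 180 - 90)
        assert np.median(dev) < 1.0

    def test_constant_image_zero_weights(self):
        fld = structure_tensor_orientations(HistologyImage(np.full((64, 64), 0.3)),
                                            1.0, 4.0)
        assert np.all(fld.weight == 0)

    def test_rotation_equivariance(self):
        img = _stripe_image(30.0)
        fld = structure_tensor_orientations(img, 1.0, 4.0)
        rot = HistologyImage(np.rot90(img.data).copy(), img.pixel_size_um)
        fld90 = structure_tensor_orientations(rot, 1.0, 4.0)
        med = np.median(fld.theta[40:-40, 40:-40][fld.weight[40:-40, 40:-40] > 0.5])
        med90 = np.median(fld90.theta[40:-40, 40:-40][fld90.weight[40:-40, 40:-40] > 0.5])
        dev = np.abs((np.degrees(med90 - med) - 90 + 90) % 180 - 90)
        assert dev < 1.0

    def test_unresolvable_kernel_rejected(self):
        img = HistologyImage(np.zeros((16, 16)), pixel_size_um=4.0)
        with pytest.raises(ValueError, match="half a pixel"):
            structure_tensor_orientations(img, sigma_d_um=1.0)

    def test_tiny_image_rejected(self):
        with pytest.raises(ValueError, match="3 x 3"):
            structure_tensor_orientations(HistologyImage(np.zeros((2, 5))), 1.0, 4.0)


class TestSegmentation:
    def test_two_tone_exact(self):
        rng = np.random.default_rng(0)
        img = np.full((100, 100), 0.9)
        dark = rng.random((100, 100)) < 0.2
        img[dark] = 0.1
        mask = segment_neurites(HistologyImage(img), k=4)
        assert np.array_equal(mask, dark)

    def test_constant_image_empty_mask(self):
        with pytest.warns(UserWarning, match="degenerate"):
            mask = segment_neurites(HistologyImage(np.full((50, 50), 0.8)))
        assert not mask.any()

    def test_stain_fully_covers_region(self):
        img = np.full((100, 100), 0.9)
        img[20:80, 20:80] = 0.05
        mask = segment_stain(HistologyImage(img), k=3)
        assert mask[20:80, 20:80].all()
        assert not mask[:10].any()

    def test_k_validation(self):
        with pytest.raises(ValueError):
            segment_neurites(HistologyImage(np.zeros((10, 10))), k=1)

    def test_deterministic(self):
        rng = np.random.default_rng(1)
        img = HistologyImage(rng.random((200, 200)))
        a = segment_neurites(img, seed=3)
        b = segment_neurites(img, seed=3)
        assert np.array_equal(a, b)

    def test_neurite_mask_tracks_generator_coverage(self):
        from cordisp.phantom import make_phantom, simulate_fiber_image
        from test_phantom import _one_region_spec, _uniform_region

        gt = make_phantom(_one_region_spec(_uniform_region(odi=0.3, ndi=0.6)))
        img = simulate_fiber_image(gt, seed=5)
        drawn = img.data < 0.82  # pixels actually darkened by the generator
        mask = segment_neurites(img, k=4)
        ratio = mask.sum() / drawn.sum()
        assert 0.8 < ratio < 1.2


class TestPatchCircularVariance:
    def _field(self, theta, weight=None, px_um=10.0):
        theta = np.asarray(theta, dtype=np.float32)
        w = np.ones_like(theta) if weight is None else np.asarray(weight, np.float32)
        return OrientationField(theta, w, np.ones(theta.shape, bool), px_um)

    def test_identical_angles_zero(self):
        f = self._field(np.full((60, 60), 0.7), np.random.default_rng(0).random((60, 60)))
        grid = RegularGrid((1, 1), (0.6, 0.6))
        pm = patch_circular_variance(f, grid, min_pixels=10)
        assert pm.values[0, 0] == pytest.approx(0.0, abs=1e-7)

    def test_orthogonal_pair_is_one(self):
        theta = np.zeros((60, 60), np.float32)
        theta[::2] = np.pi / 2
        f = self._field(theta)
        pm = patch_circular_variance(f, RegularGrid((1, 1), (0.6, 0.6)), min_pixels=10)
        assert pm.values[0, 0] == pytest.approx(1.0, abs=1e-7)

    def test_uniform_angles_near_one(self, rng):
        theta = rng.uniform(0, np.pi, (100, 100)).astype(np.float32)
        f = self._field(theta)
        pm = patch_circular_variance(f, RegularGrid((1, 1), (1.0, 1.0)), min_pixels=10)
        assert pm.values[0, 0] == pytest.approx(1.0, abs=0.02)

    @given(st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=25, deadline=None)
    def test_invariant_to_weight_rescaling(self, scale):
        rng = np.random.default_rng(7)
        theta = rng.uniform(0, np.pi, (40, 40)).astype(np.float32)
        w = rng.random((40, 40)).astype(np.float32)
        grid = RegularGrid((2, 2), (0.2, 0.2))
        a = patch_circular_variance(self._field(theta, w), grid, min_pixels=5)
        b = patch_circular_variance(self._field(theta, w * scale), grid, min_pixels=5)
        assert np.allclose(a.values, b.values, atol=1e-6, equal_nan=True)

    def test_sparse_patches_masked_invalid(self):
        theta = np.zeros((40, 40), np.float32)
        w = np.zeros((40, 40), np.float32)
        w[:10, :10] = 1.0
        f = self._field(theta, w)
        grid = RegularGrid((2, 2), (0.2, 0.2))
        pm = patch_circular_variance(f, grid, min_pixels=50)
        assert pm.valid[0, 0]
        assert not pm.valid[1, 1]
        assert np.isnan(pm.values[1, 1])

    def test_empty_grid_rejected(self):
        f = self._field(np.zeros((10, 10), np.float32))
        with pytest.raises(ValueError):
            patch_circular_variance(f, RegularGrid((0, 1), (0.1, 0.1)))

    def test_dispersion_ladder_rank_correlation(self):
        """End-to-end: patch-median CV strictly follows generating ODI."""
        from scipy.stats import spearmanr

        from cordisp.phantom import make_phantom, simulate_fiber_image
        from test_phantom import _one_region_spec, _uniform_region

        odis = (0.05, 0.1, 0.2, 0.35, 0.55, 0.8)
        medians = []
        for odi in odis:
            gt = make_phantom(_one_region_spec(_uniform_region(odi=odi, ndi=0.7)))
            img = simulate_fiber_image(gt, seed=11)
            neur = segment_neurites(img, k=4)
            fld = structure_tensor_orientations(img, sigma_d_um=8.0, sigma_s_um=24.0,
                                                neurite_mask=neur)
            grid = make_patch_grid(img)
            pm = patch_circular_variance(fld, grid, min_pixels=50)
            medians.append(np.nanmedian(pm.values))
        rho = spearmanr(odis, medians).statistic
        assert rho == 1.0
        assert np.all(np.diff(medians) > 0)


class TestPatchStainingFraction:
    def test_full_and_empty_masks(self):
        grid = RegularGrid((2, 2), (0.2, 0.2))
        full = patch_staining_fraction(np.ones((40, 40), bool), grid, 10.0)
        empty = patch_staining_fraction(np.zeros((40, 40), bool), grid, 10.0)
        assert np.all(full.values == 1.0)
        assert np.all(empty.values == 0.0)

    def test_checkerboard_half(self):
        mask = np.indices((40, 40)).sum(axis=0) % 2 == 0
        grid = RegularGrid((2, 2), (0.2, 0.2))
        pm = patch_staining_fraction(mask, grid, 10.0)
        assert np.allclose(pm.values, 0.5)

    def test_zero_tissue_patch_invalid(self):
        tissue = np.zeros((40, 40), bool)
        tissue[:20, :20] = True
        grid = RegularGrid((2, 2), (0.2, 0.2))
        pm = patch_staining_fraction(np.ones((40, 40), bool), grid, 10.0,
                                     tissue_mask=tissue)
        assert pm.valid[0, 0] and not pm.valid[1, 1]
        assert np.isnan(pm.values[1, 1])

    def test_phantom_stain_fraction_recovered(self):
        from cordisp.phantom import make_phantom, simulate_stain_image
        from test_phantom import _one_region_spec, _uniform_region

        region = _uniform_region(stain_fraction_true=dict(MSF=0.30, NSF=0.3,
                                                          ASF=0.2, uGSF=0.1))
        gt = make_phantom(_one_region_spec(region))
        img = simulate_stain_image(gt, "MSF", seed=2)
        mask = segment_stain(img, k=3)
        grid = make_patch_grid(img)
        pm = patch_staining_fraction(mask, grid, img.pixel_size_um,
                                     tissue_mask=gt.tissue_mask_histo)
        assert np.nanmedian(pm.values) == pytest.approx(0.30, abs=0.02)
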