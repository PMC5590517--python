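"""Phantom generator: rasterization, ground-truth contrasts, noise model,
and the statistical properties of the synthetic histology images."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from cordisp.phantom import (
    STAINS,
    PhantomSpec,
    TissueRegion,
    default_phantom_spec,
    make_phantom,
    simulate_dwi,
    simulate_fiber_image,
    simulate_stain_image,
)
from cordisp.protocol import AcquisitionProtocol
from cordisp.reference import circular_variance_of_angles


def _uniform_region(label="WM", odi=0.1, ndi=0.65, extent=(5.12, 6.4), **kw):
    geom = box(0.0, 0.0, extent[0], extent[1])
    defaults = dict(
        odi_true=odi, ndi_true=ndi, ivf_true=0.05, dot_true=0.1,
        mu_angle_deg=90.0,
        stain_fraction_true=dict(MSF=0.5, NSF=0.3, ASF=0.2, uGSF=0.15),
        n_rois=1, jitter_rel=0.0, jitter_mu_deg=0.0,
    )
    defaults.update(kw)
    return TissueRegion(label, geom, **defaults)


def _one_region_spec(region=None, grid=(32, 32), histo_um=8.0, seed=0):
    region = region or _uniform_region()
    return PhantomSpec([region], grid_shape=grid, histo_pixel_um=histo_um, seed=seed)


@pytest.fixture(scope="module")
def small_protocol():
    # compact multi-shell scheme to keep simulation cheap
    rng = np.random.default_rng(0)
    bvals = [0.0] * 4
    bvecs = [[0.0, 0.0, 0.0]] * 4
    for b in (520.0, 2080.0, 4680.0, 13000.0):
        for _ in range(8):
            v = rng.standard_normal(3)
            v /= np.linalg.norm(v)
            bvals.append(b)
            bvecs.append(v.tolist())
    return AcquisitionProtocol(bvals, bvecs)


class TestMakePhantom:
    def test_uniform_region_constant_truth(self):
        gt = make_phantom(_one_region_spec())
        odi_map = gt.truth_map("odi")
        inside = gt.tissue_mask_mri
        assert inside.all()
        assert np.all(odi_map[inside] == 0.1)

    def test_default_spec_lesion_ordering(self):
        gt = make_phantom(default_phantom_spec("ms", seed=3, grid_shape=(32, 32),
                                               histo_pixel_um=8.0))
        t = gt.roi_table
        wm = t[t.region_label == "WM"]["odi"].mean()
        wml = t[t.region_label == "WM_lesion"]["odi"].mean()
        gm = t[t.region_label == "GM"]["odi"].mean()
        assert wml < wm < gm
        assert (t[t.region_label == "WM_lesion"]["MSF"].mean()
                < t[t.region_label == "WM"]["MSF"].mean())

    def test_conflicting_overlap_rejected(self):
        a = _uniform_region("WM", extent=(5.12, 6.4))
        b = _uniform_region("GM", extent=(5.12, 6.4))
        with pytest.raises(ValueError, match="WM.*GM|GM.*WM"):
            make_phantom(PhantomSpec([a, b], grid_shape=(32, 32),
                                     histo_pixel_um=8.0))

    def test_geometry_outside_grid_rejected(self):
        big = _uniform_region(extent=(50.0, 50.0))
        with pytest.raises(ValueError, match="outside"):
            PhantomSpec([big], grid_shape=(32, 32), histo_pixel_um=8.0)

    def test_roi_count_matches_study_design(self):
        ms = make_phantom(default_phantom_spec("ms", seed=0, grid_shape=(48, 48),
                                               histo_pixel_um=8.0))
        ctrl = make_phantom(default_phantom_spec("control", seed=0, grid_shape=(48, 48),
                                                 histo_pixel_um=8.0))
        assert len(ms.roi_table) == 28
        assert len(ctrl.roi_table) == 20

    def test_deterministic(self):
        a = make_phantom(default_phantom_spec("ms", seed=9, grid_shape=(32, 32),
                                              histo_pixel_um=8.0))
        b = make_phantom(default_phantom_spec("ms", seed=9, grid_shape=(32, 32),
                                              histo_pixel_um=8.0))
        assert np.array_equal(a.roi_mri, b.roi_mri)
        pd.testing.assert_frame_equal(a.roi_table, b.roi_table)


class TestSimulateDwi:
    def test_infinite_snr_is_noise_free_forward_model(self, small_protocol):
        from cordisp.noddi import NoddiParams, noddi_signal
        from cordisp.watson import kappa_from_odi

        gt = make_phantom(_one_region_spec())
        dwi = simulate_dwi(gt, small_protocol, snr_b0=np.inf)
        row = gt.roi_table.iloc[0]
        ang = np.deg2rad(row["mu_angle_deg"])
        expected = noddi_signal(
            NoddiParams(v_iso=row["ivf"], v_ir=row["dot"], v_in=row["ndi"],
                        kappa=kappa_from_odi(row["odi"]),
                        mu=(np.cos(ang), np.sin(ang), 0.0)),
            small_protocol,
        )
        assert np.array_equal(dwi.signal[3, 3, 0], expected)

    def test_same_seed_identical(self, small_protocol):
        gt = make_phantom(_one_region_spec())
        a = simulate_dwi(gt, small_protocol, snr_b0=20.0, seed=5)
        b = simulate_dwi(gt, small_protocol, snr_b0=20.0, seed=5)
        assert np.array_equal(a.signal, b.signal)

    def test_rayleigh_mean_when_signal_vanishes(self, small_protocol):
        # free-water region: at b=13000 the true signal is ~exp(-26) ~ 0,
        # so the magnitude is Rayleigh with mean sigma*sqrt(pi/2)
        region = _uniform_region(ivf_true=1.0, dot_true=0.0)
        gt = make_phantom(_one_region_spec(region))
        snr = 1.0  # sigma = 1
        draws = []
        for seed in range(100):
            dwi = simulate_dwi(gt, small_protocol, snr_b0=snr, seed=seed)
            draws.append(dwi.signal[:, :, 0, small_protocol.bvals == 13000.0])
        m = np.mean(draws)
        assert m == pytest.approx(np.sqrt(np.pi / 2), abs=0.01)

    def test_rician_second_moment_identity(self, small_protocol):
        gt = make_phantom(_one_region_spec())
        snr = 10.0
        sigma = 1.0 / snr
        noise_free = simulate_dwi(gt, small_protocol, snr_b0=np.inf)
        draws = []
        for seed in range(60):
            dwi = simulate_dwi(gt, small_protocol, snr_b0=snr, seed=seed)
            draws.append(dwi.signal[:, :, 0, :] ** 2)
        second = np.mean(draws, axis=0)
        expected = noise_free.signal[:, :, 0, :] ** 2 + 2 * sigma**2
        assert np.allclose(second.mean(axis=(0, 1)), expected.mean(axis=(0, 1)),
                           atol=3e-3)

    def test_missing_ground_truth_rejected(self, small_protocol):
        gt = make_phantom(_one_region_spec())
        gt.roi_table = gt.roi_table.drop(columns=["odi"])
        with pytest.raises(ValueError, match="odi"):
            simulate_dwi(gt, small_protocol)


class TestFiberImage:
    def test_near_parallel_limit(self):
        region = _uniform_region(odi=1e-6, mu_angle_deg=30.0)
        gt = make_phantom(_one_region_spec(region))
        _, strokes = simulate_fiber_image(gt, seed=1, return_strokes=True)
        dev = np.degrees(np.abs(np.angle(np.exp(2j * (strokes.angle_rad - np.deg2rad(30)))) / 2))
        assert np.all(dev < 1.0)

    def test_isotropic_limit_uniform_histogram(self):
        from scipy import stats

        region = _uniform_region(odi=0.999, ndi=0.9)
        gt = make_phantom(PhantomSpec([region], grid_shape=(32, 32),
                                      histo_pixel_um=4.0, seed=0))
        _, strokes = simulate_fiber_image(gt, seed=2, return_strokes=True)
        assert len(strokes) >= 10_000
        counts, _ = np.histogram(strokes.angle_rad, bins=18, range=(0, np.pi))
        assert stats.chisquare(counts).pvalue > 0.01

    def test_blank_region_background_only(self):
        region = _uniform_region(ndi=0.0)
        gt = make_phantom(_one_region_spec(region))
        img, strokes = simulate_fiber_image(gt, seed=3, return_strokes=True)
        assert len(strokes) == 0
        assert np.all(img.data >= 0.85)

    def test_same_seed_identical(self):
        gt = make_phantom(_one_region_spec())
        a = simulate_fiber_image(gt, seed=4)
        b = simulate_fiber_image(gt, seed=4)
        assert np.array_equal(a.data, b.data)

    def test_stroke_dispersion_monotone_in_odi(self):
        """Generator self-consistency: the brute-force circular variance of
        sampled stroke angles increases across the default dispersion ladder."""
        cvs = []
        for odi in (0.05, 0.1, 0.2, 0.35, 0.55, 0.8):
            region = _uniform_region(odi=odi, ndi=0.8)
            gt = make_phantom(_one_region_spec(region))
            _, strokes = simulate_fiber_image(gt, seed=7, return_strokes=True)
            cvs.append(circular_variance_of_angles(strokes.angle_rad.to_numpy()))
        assert np.all(np.diff(cvs) > 0)


class TestStainImage:
    def test_zero_fraction_no_dark_pixels(self):
        region = _uniform_region(stain_fraction_true=dict(MSF=0.0, NSF=0.3,
                                                          ASF=0.2, uGSF=0.1))
        gt = make_phantom(_one_region_spec(region))
        img = simulate_stain_image(gt, "MSF", seed=1)
        assert np.all(img.data[gt.tissue_mask_histo] > 0.5)

    def test_full_fraction_fills_region(self):
        region = _uniform_region(stain_fraction_true=dict(MSF=1.0, NSF=0.3,
                                                          ASF=0.2, uGSF=0.1))
        gt = make_phantom(_one_region_spec(region))
        img = simulate_stain_image(gt, "MSF", seed=1)
        assert np.all(img.data[gt.tissue_mask_histo] < 0.2)

    def test_intermediate_fraction_realized(self):
        # >= 1000 x 1000 px region at the target fraction
        region = _uniform_region(stain_fraction_true=dict(MSF=0.30, NSF=0.3,
                                                          ASF=0.2, uGSF=0.1))
        spec = PhantomSpec([region], grid_shape=(32, 32), histo_pixel_um=5.0, seed=0)
        gt = make_phantom(spec)
        img = simulate_stain_image(gt, "MSF", seed=2)
        assert min(img.data.shape) >= 1000
        dark = img.data < 0.45
        realized = dark[gt.tissue_mask_histo].mean()
        assert realized == pytest.approx(0.30, abs=0.01)

    def test_unknown_stain_rejected(self):
        gt = make_phantom(_one_region_spec())
        with pytest.raises(ValueError, match="unknown stain"):
            simulate_stain_image(gt, "PLP")

    def test_same_seed_identical(self):
        gt = make_phantom(_one_region_spec())
        a = simulate_stain_image(gt, "NSF", seed=6)
        b = simulate_stain_image(gt, "NSF", seed=6)
        assert np.array_equal(a.data, b.data)
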