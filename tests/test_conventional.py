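"""Conventional OCTL: correction, fitting, compensation, thresholding."""

import numpy as np
import pytest

from octl import metrics as met
from octl.conventional import (
    CalibrationProfile,
    ConventionalConfig,
    FitPolicy,
    SurfaceMap,
    compensate,
    correct_system,
    detect_surface,
    estimate_system_response,
    fit_attenuation,
    flatten_and_crop,
    run_conventional,
    threshold_vessels,
)
from octl.phantom import (
    PhantomSpec,
    make_calibration_volume,
    make_eye_phantom,
)
from octl.preprocess import DB_PER_NEPER, normalize_noise
from octl.volume import VesselMask

from conftest import ideal_spec, realistic_spec, straight_tube


def _flat_surface(shape, z):
    return SurfaceMap(np.full(shape[:2], z, dtype=int))


class TestSystemResponse:
    def test_recovers_injected_response(self):
        # construction oracle: render with a known H, estimate, compare
        spec = ideal_spec(
            mu_t=0.0,
            shape=(8, 8, 200),
            confocal_focus_um=300.0,
            confocal_rayleigh_um=400.0,
            rolloff_db_per_mm=6.0,
        )
        from octl.phantom import system_response_db

        cal = make_calibration_volume(spec)
        cal.noise_normalized = True
        prof = estimate_system_response(cal, mu_cal=0.0)
        injected = system_response_db(spec, np.arange(200))
        injected = injected - injected.max()
        np.testing.assert_allclose(prof.h_db, injected, atol=0.1)

    def test_flat_response_matched_mu_is_zero(self):
        spec = ideal_spec(mu_t=0.3, shape=(4, 4, 150))
        cal = make_calibration_volume(spec)
        cal.noise_normalized = True
        prof = estimate_system_response(cal, mu_cal=0.3)
        assert np.allclose(prof.h_db[: prof.valid_depth_px], 0.0, atol=0.01)

    def test_source_intensity_invariance(self):
        a = make_calibration_volume(ideal_spec(mu_t=0.1, source_level_db=40.0))
        b = make_calibration_volume(ideal_spec(mu_t=0.1, source_level_db=46.0))
        a.noise_normalized = b.noise_normalized = True
        pa = estimate_system_response(a, 0.1)
        pb = estimate_system_response(b, 0.1)
        np.testing.assert_allclose(pa.h_db, pb.h_db, atol=1e-3)

    def test_rejects_inhomogeneous_calibration(self):
        spec = ideal_spec(mu_t=0.0, shape=(16, 16, 100))
        cal = make_calibration_volume(spec)
        data = cal.data.copy()
        data[:8] += 40.0          # half the field much brighter
        cal = cal.with_data(data, noise_normalized=True)
        with pytest.raises(ValueError, match="homogeneous"):
            estimate_system_response(cal, 0.0, homogeneity_bound_db=5.0)


class TestCorrectSystem:
    def test_zero_profile_is_identity(self):
        vol = make_calibration_volume(ideal_spec(mu_t=0.2))
        prof = CalibrationProfile(np.zeros(vol.nz), 0.0, vol.axial_pitch_um, vol.nz)
        np.testing.assert_array_equal(correct_system(vol, prof).data, vol.data)

    def test_corrected_slope_is_pure_attenuation(self):
        spec = ideal_spec(
            mu_t=1.0,
            shape=(4, 4, 200),
            confocal_rayleigh_um=600.0,
            rolloff_db_per_mm=4.0,
        )
        vol = make_calibration_volume(spec)
        cal = make_calibration_volume(
            ideal_spec(mu_t=0.0, shape=(4, 4, 200),
                       confocal_rayleigh_um=600.0, rolloff_db_per_mm=4.0)
        )
        cal.noise_normalized = True
        prof = estimate_system_response(cal, 0.0)
        out = correct_system(vol, prof)
        z = vol.depth_axis_mm()
        slope = np.polyfit(z, out.data.mean(axis=(0, 1)), 1)[0]
        assert slope == pytest.approx(-2.0 * 1.0 * DB_PER_NEPER, rel=1e-4)

    def test_double_correction_differs_by_profile(self):
        vol = make_calibration_volume(ideal_spec(mu_t=0.2))
        h = np.linspace(0, -5, vol.nz)
        prof = CalibrationProfile(h, 0.0, vol.axial_pitch_um, vol.nz)
        once = correct_system(vol, prof)
        twice = correct_system(once, prof)
        np.testing.assert_allclose(
            (once.data - twice.data)[0, 0], h.astype(np.float32), atol=1e-5
        )

    def test_depth_mismatch_rejected(self):
        vol = make_calibration_volume(ideal_spec())
        prof = CalibrationProfile(np.zeros(7), 0.0, 5.0, 7)
        with pytest.raises(ValueError, match="mismatch"):
            correct_system(vol, prof)


class TestFitAttenuation:
    @pytest.mark.parametrize("mu", [0.5, 1.0, 2.0, 4.0])
    def test_exact_recovery_noiseless(self, mu):
        spec = ideal_spec(mu_t=mu, shape=(4, 4, 384), surface_offset_px=10)
        vol, _ = make_eye_phantom(spec)
        vol.noise_normalized = True
        att = fit_attenuation(vol, _flat_surface(spec.shape, 10))
        assert np.nanmedian(att.mu) == pytest.approx(mu, rel=1e-6)

    def test_constant_ascan_gives_zero(self):
        from octl.volume import OCTVolume

        vol = OCTVolume(np.full((4, 4, 100), 20.0, np.float32), 5.0,
                        noise_normalized=True)
        att = fit_attenuation(vol, _flat_surface((4, 4, 100), 0))
        assert np.allclose(att.mu[att.valid], 0.0, atol=1e-9)

    def test_speckled_median_within_10pct(self):
        # 4096 A-scans of fully developed speckle
        spec = realistic_spec(shape=(64, 64, 768), mu_t=2.0,
                              surface_offset_px=0, seed=11,
                              confocal_rayleigh_um=1e12, rolloff_db_per_mm=0.0)
        vol = make_calibration_volume(spec)
        vol = normalize_noise(vol)
        att = fit_attenuation(vol, _flat_surface(spec.shape, 0))
        assert np.nanmedian(att.mu) == pytest.approx(2.0, rel=0.10)

    def test_short_window_flagged_invalid(self):
        spec = ideal_spec(mu_t=2.0, shape=(4, 4, 64), surface_offset_px=50)
        vol, _ = make_eye_phantom(spec)
        vol.noise_normalized = True
        att = fit_attenuation(vol, _flat_surface(spec.shape, 50))
        assert not att.valid.any()
        assert np.isnan(att.mu).all()


class TestCompensate:
    def test_flattens_homogeneous_tissue(self):
        spec = ideal_spec(mu_t=2.0, shape=(4, 4, 384), surface_offset_px=10)
        vol, _ = make_eye_phantom(spec)
        vol.noise_normalized = True
        surf = _flat_surface(spec.shape, 10)
        att = fit_attenuation(vol, surf)
        comp = compensate(vol, att, surf)
        z = vol.depth_axis_mm()
        w = slice(15, 300)
        for x in range(4):
            slope = np.polyfit(z[w], comp.data[x, 0, w], 1)[0]
            assert abs(slope) < 0.01          # dB per mm

    def test_zero_mu_is_identity(self):
        from octl.conventional import AttenuationMap
        from octl.volume import OCTVolume

        vol = OCTVolume(np.random.default_rng(0).normal(20, 3, (4, 4, 64))
                        .astype(np.float32), 5.0)
        att = AttenuationMap(
            mu=np.zeros((4, 4)),
            window_start=np.zeros((4, 4), int),
            window_end=np.full((4, 4), 63),
            r_squared=np.ones((4, 4)),
            valid=np.ones((4, 4), bool),
        )
        out = compensate(vol, att, _flat_surface((4, 4, 64), 0))
        np.testing.assert_allclose(out.data, vol.data, atol=1e-6)

    def test_vessel_deficit_survives_compensation(self):
        spec = ideal_spec(
            mu_t=2.0, shape=(48, 16, 384), surface_offset_px=10,
            vessels=[straight_tube(24, 80, 16, radius_um=60.0, deficit_db=15.0)],
        )
        vol, truth = make_eye_phantom(spec)
        vol.noise_normalized = True
        surf = _flat_surface(spec.shape, 10)
        att = fit_attenuation(vol, surf)
        comp = compensate(vol, att, surf)
        z = 80
        inside = truth.mask[:, :, z]
        tissue = ~truth.mask[:, :, z]
        gap = comp.data[:, :, z][tissue].mean() - comp.data[:, :, z][inside].mean()
        assert gap >= 7.5


class TestThreshold:
    def _comp(self):
        spec = ideal_spec(
            mu_t=1.0, shape=(32, 16, 256), surface_offset_px=8,
            vessels=[straight_tube(16, 60, 16, radius_um=50.0, deficit_db=15.0)],
        )
        vol, truth = make_eye_phantom(spec)
        vol.noise_normalized = True
        surf = _flat_surface(spec.shape, 8)
        att = fit_attenuation(vol, surf)
        return compensate(vol, att, surf), truth, surf

    def test_extreme_thresholds(self):
        comp, truth, surf = self._comp()
        assert not threshold_vessels(comp, comp.data.min() - 1, surf).data.any()
        below = np.arange(comp.nz)[None, None, :] > surf.data[:, :, None]
        full = threshold_vessels(comp, comp.data.max() + 1, surf)
        np.testing.assert_array_equal(full.data, below)

    def test_midway_threshold_recovers_vessel(self):
        comp, truth, surf = self._comp()
        tissue_mean = comp.data[:, :, 30:200][~truth.mask[:, :, 30:200]].mean()
        mask = threshold_vessels(comp, tissue_mean - 7.5, surf)
        assert met.iou(mask.data, truth.mask) >= 0.8

    def test_threshold_monotonicity(self):
        comp, _, surf = self._comp()
        m1 = threshold_vessels(comp, 20.0, surf).data
        m2 = threshold_vessels(comp, 25.0, surf).data
        assert not (m1 & ~m2).any()


class TestDetectSurface:
    def test_flat_surface(self):
        spec = realistic_spec(surface_offset_px=40, shape=(64, 16, 384))
        vol, _ = make_eye_phantom(spec)
        vol = normalize_noise(vol)
        surf = detect_surface(vol)
        assert np.abs(surf.data - 40).max() <= 1

    def test_tilted_plane(self):
        spec = realistic_spec(
            surface_offset_px=10, surface_tilt_um=(1.2, 0.0), shape=(96, 16, 384)
        )
        vol, truth = make_eye_phantom(spec)
        vol = normalize_noise(vol)
        surf = detect_surface(vol)
        rms = np.sqrt(np.mean((surf.data - truth.surface) ** 2))
        assert rms <= 2.0

    def test_pure_noise_flagged_unreliable(self):
        # a volume of nothing but fully developed speckle noise at the floor
        rng = np.random.default_rng(0)
        data = 10.0 * np.log10(rng.exponential(1.0, (32, 8, 384))).astype(np.float32)
        from octl.volume import OCTVolume

        vol = OCTVolume(data, axial_pitch_um=5.47, noise_normalized=True)
        with pytest.warns(UserWarning):
            surf = detect_surface(vol)
        assert not surf.reliable


class TestFlattenAndCrop:
    def test_flat_surface_at_zero_is_crop_only(self):
        spec = ideal_spec(mu_t=1.0, shape=(8, 8, 256))
        vol = make_calibration_volume(spec)
        out = flatten_and_crop(vol, _flat_surface(spec.shape, 0), 200.0)
        crop_px = round(200.0 / vol.physical_pitch_um)
        np.testing.assert_array_equal(out.data, vol.data[:, :, :crop_px])

    def test_tilted_phantom_flattens_to_zero(self):
        spec = realistic_spec(
            surface_offset_px=12, surface_tilt_um=(1.0, 0.5), shape=(64, 32, 384)
        )
        vol, truth = make_eye_phantom(spec)
        vol = normalize_noise(vol)
        surf = detect_surface(vol)
        flat = flatten_and_crop(vol, surf, 400.0)
        resurf = detect_surface(flat)
        # the step now sits at the image border; Gaussian smoothing puts the
        # first edge pixel a row or two below it
        assert np.abs(resurf.data).max() <= 3
        assert np.median(resurf.data) <= 1

    def test_mask_volume_correspondence(self):
        spec = realistic_spec(
            surface_offset_px=20,
            shape=(64, 16, 384),
            vessels=[straight_tube(32, 80, 16, radius_um=50.0, deficit_db=20.0)],
        )
        vol, truth = make_eye_phantom(spec)
        vol = normalize_noise(vol)
        surf = detect_surface(vol)
        mask = VesselMask(truth.mask, provenance="ground_truth",
                          physical_pitch_um=vol.physical_pitch_um)
        fm = flatten_and_crop(mask, surf, 500.0)
        fv = flatten_and_crop(vol, surf, 500.0)
        # vessel voxels in the flattened volume stay the dark ones
        inside = fv.data[fm.data].mean()
        outside = fv.data[(~fm.data) & (fv.data != 0)].mean()
        assert outside - inside > 5.0

    def test_crop_beyond_depth_rejected(self):
        spec = ideal_spec(shape=(4, 4, 64))
        vol = make_calibration_volume(spec)
        with pytest.raises(ValueError, match="exceeds"):
            flatten_and_crop(vol, _flat_surface(spec.shape, 0), 5000.0)


class TestRunConventional:
    def test_clean_vessel_phantom_iou(self, flat_calibration):
        spec = ideal_spec(
            mu_t=2.0, shape=(48, 24, 256), surface_offset_px=12,
            vessels=[straight_tube(24, 80, 24, radius_um=50.0, deficit_db=15.0)],
        )
        vol, truth = make_eye_phantom(spec)
        vol.noise_normalized = True
        res = run_conventional(vol, flat_calibration,
                               ConventionalConfig(theta_rel_db=7.5))
        tm = VesselMask(truth.mask, provenance="ground_truth",
                        physical_pitch_um=vol.physical_pitch_um)
        tflat = flatten_and_crop(tm, res.surface, 500.0)
        assert met.iou(res.mask.data, tflat.data) >= 0.8

    def test_vessel_free_phantom_low_density(self, flat_calibration):
        spec = ideal_spec(mu_t=2.0, shape=(48, 24, 256), surface_offset_px=12)
        vol, _ = make_eye_phantom(spec)
        vol.noise_normalized = True
        res = run_conventional(vol, flat_calibration, ConventionalConfig())
        assert met.volume_density(res.mask) < 1.0

    def test_orientation_robustness(self):
        # x <-> y transpose of the phantom yields the transposed mask
        spec = realistic_spec(
            shape=(64, 64, 384), surface_offset_px=20, seed=5,
            vessels=[straight_tube(32, 90, 64, radius_um=50.0, deficit_db=20.0)],
        )
        vol, _ = make_eye_phantom(spec)
        cal = make_calibration_volume(
            realistic_spec(shape=(64, 64, 384), mu_t=0.0, surface_offset_px=0, seed=6)
        )
        cfg = ConventionalConfig()
        res = run_conventional(vol, cal, cfg)
        vol_t = vol.with_data(np.transpose(vol.data, (1, 0, 2)))
        res_t = run_conventional(vol_t, cal, cfg)
        assert met.iou(res.mask.data,
                       np.transpose(res_t.mask.data, (1, 0, 2))) >= 0.95
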