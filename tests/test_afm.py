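"""AFM pipeline: calibration, baseline correction, contact detection,
indentation, Hertz fitting, map processing, transects, gradient statistic
and the rank-sum test."""

import numpy as np
import pytest

from stomamech.afm import (AfmConfig, ForceCurve, TransectProfile,
                           calibrate_curve, compute_indentation,
                           correct_baseline_tilt, detect_contact_point,
                           fit_hertz_pyramid, gradient_statistic, hertz_force,
                           mann_whitney_u, process_force_map)
from stomamech.synthetic import NoiseModel, make_ground_truth, \
    simulate_force_map

CFG = AfmConfig()


def make_curve(E_MPa=5.0, z0=500.0, n=300, z_max=2000.0, cfg=CFG,
               noise_sd=0.0, tilt=0.0, offset=0.0, rng=None, volts=False):
    """Noise-free (or noisy) synthetic approach curve with known contact
    point and modulus; the forward model inverts the cantilever-bending
    relation exactly."""
    z = np.linspace(0.0, z_max, n)
    zp = np.maximum(z - z0, 0.0)
    q = cfg.hertz_prefactor * E_MPa / cfg.spring_constant
    delta = (np.sqrt(1.0 + 4.0 * q * zp) - 1.0) / (2.0 * q)
    F = hertz_force(delta, E_MPa, cfg)
    F = F + tilt * z + offset
    if noise_sd > 0:
        F = F + noise_sd * (rng or np.random.default_rng(0)).standard_normal(n)
    if volts:
        return ForceCurve(z, F / (cfg.sensitivity * cfg.spring_constant),
                          calibrated=False)
    out = ForceCurve(z, F, calibrated=True)
    return out


class TestCalibration:
    def test_dimensional_arithmetic(self):
        # 1 V * 20 nm/V * 45 N/m = 900 nN
        raw = ForceCurve(np.arange(5.0), np.ones(5), calibrated=False)
        cal = calibrate_curve(raw, AfmConfig(sensitivity=20.0,
                                             spring_constant=45.0))
        assert np.allclose(cal.deflection, 900.0)

    def test_zero_deflection_zero_force(self):
        raw = ForceCurve(np.arange(5.0), np.zeros(5))
        assert np.allclose(calibrate_curve(raw, CFG).deflection, 0.0)

    def test_linearity_in_sensitivity(self):
        raw = ForceCurve(np.arange(5.0), np.ones(5))
        f1 = calibrate_curve(raw, AfmConfig(sensitivity=10.0)).deflection
        f2 = calibrate_curve(raw, AfmConfig(sensitivity=20.0)).deflection
        assert np.allclose(f2, 2.0 * f1)


class TestBaselineCorrection:
    def test_recovers_known_tilt_and_offset(self):
        c = make_curve(tilt=0.05, offset=30.0)
        out = correct_baseline_tilt(c)
        pre = out.deflection[out.z < 400]
        assert np.abs(pre.mean()) < 0.01 * np.ptp(out.deflection)
        m = np.polyfit(out.z[out.z < 400], pre, 1)[0]
        assert abs(m) < 1e-3

    def test_idempotent_on_flat_curve(self):
        c = make_curve()
        once = correct_baseline_tilt(c)
        twice = correct_baseline_tilt(once)
        assert np.allclose(once.deflection, twice.deflection, atol=1e-9)

    def test_contact_from_first_sample_rejected(self):
        c = make_curve(z0=-500.0)   # contact before the ramp starts
        with pytest.raises(ValueError):
            correct_baseline_tilt(c)


class TestContactDetection:
    def test_noiseless_recovery_within_1nm(self):
        for z0 in (300.0, 500.0, 900.0):
            c = correct_baseline_tilt(make_curve(z0=z0))
            est = detect_contact_point(c, CFG)
            assert est is not None and abs(est - z0) < 1.0

    def test_all_zero_force_flags_no_contact(self):
        c = ForceCurve(np.linspace(0, 1000, 200), np.zeros(200),
                       calibrated=True)
        c.corrected = True
        assert detect_contact_point(c, CFG) is None

    def test_noisy_recovery_within_10nm(self):
        errs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            c = make_curve(z0=500.0, noise_sd=0.02 * CFG.setpoint_nN, rng=rng)
            est = detect_contact_point(correct_baseline_tilt(c), CFG)
            assert est is not None
            errs.append(abs(est - 500.0))
        assert np.mean(errs) < 10.0


class TestIndentation:
    def test_rigid_surface_zero_indentation(self):
        z = np.linspace(0, 1000, 200)
        z0 = 400.0
        F = np.maximum(z - z0, 0.0) * CFG.spring_constant  # pure bending
        c = ForceCurve(z, F, calibrated=True)
        delta, _ = compute_indentation(c, CFG, z0)
        assert np.abs(delta).max() < 1e-9

    def test_forward_model_roundtrip(self):
        E = 8.0
        c = make_curve(E_MPa=E, z0=500.0)
        delta, F = compute_indentation(c, CFG, 500.0)
        ref = hertz_force(delta, E, CFG)
        good = F > 1.0
        assert np.allclose(F[good], ref[good], rtol=1e-6)

    def test_midrange_modulus_depth_in_reported_range(self):
        # at the 1000 nN setpoint a mid-range wall modulus indents 100-1000 nm
        for E in (4.0, 8.0, 12.0):
            delta_set = np.sqrt(CFG.setpoint_nN / (CFG.hertz_prefactor * E))
            assert 100.0 <= delta_set <= 1000.0


class TestHertzFit:
    def test_noiseless_roundtrip_within_0p1pct(self):
        c = make_curve(E_MPa=5.0, z0=500.0)
        delta, F = compute_indentation(c, CFG, 500.0)
        Ea, diag = fit_hertz_pyramid(delta, F, CFG)
        assert diag["flag"] == 0
        assert Ea == pytest.approx(5.0, rel=1e-3)

    def test_matches_brute_force_grid_search(self, rng):
        for _ in range(20):
            E = float(rng.uniform(1.0, 30.0))
            c = make_curve(E_MPa=E, z0=400.0,
                           noise_sd=5.0, rng=rng)
            delta, F = compute_indentation(correct_baseline_tilt(c), CFG, 400.0)
            Ea, _ = fit_hertz_pyramid(delta, F, CFG)
            # brute force over the quadratic coefficient
            dmax = delta.max()
            win = (delta >= 0.1 * dmax)
            cs = np.linspace(0.2, 5.0, 20001) * CFG.hertz_prefactor * E
            sse = [np.sum((F[win] - ci * delta[win] ** 2) ** 2) for ci in cs]
            c_best = cs[int(np.argmin(sse))]
            assert Ea * CFG.hertz_prefactor == pytest.approx(c_best, rel=1e-3)

    def test_all_zero_force_flagged(self):
        Ea, diag = fit_hertz_pyramid(np.linspace(0, 500, 50), np.zeros(50), CFG)
        assert np.isnan(Ea) and diag["flag"] != 0

    def test_too_few_points_flagged(self):
        Ea, diag = fit_hertz_pyramid(np.array([1.0, 2.0]),
                                     np.array([0.1, 0.4]), CFG)
        assert np.isnan(Ea) and diag["flag"] != 0


class TestMapPipeline:
    def test_uniform_field_roundtrip_within_1pct(self):
        cfg = AfmConfig(map_size_um=10.0, grid=8)
        pat = make_ground_truth("young", field_size_um=10.0,
                                pose={"center": (5.0, 5.0),
                                      "semi_axes": (2.0, 1.5), "angle": 0.0},
                                E_inner=5.0, E_outer=5.0, E_pole=5.0,
                                E_bg=5.0)
        fm = simulate_force_map(pat, cfg, NoiseModel(
            seed=3, deflection_noise_nN=0.0, contact_jitter_nm=0.0,
            tilt_slope_nN_per_nm=0.0, offset_nN=0.0, modulus_jitter_rel=0.0))
        ea = process_force_map(fm, cfg)
        good = ea.flag == 0
        assert good.mean() > 0.99
        assert np.allclose(ea.Ea[good], 5.0, rtol=0.01)

    def test_grid_preserved(self):
        cfg = AfmConfig(map_size_um=30.0, grid=16)
        pat = make_ground_truth("young")
        fm = simulate_force_map(pat, cfg, NoiseModel(seed=1))
        ea = process_force_map(fm, cfg)
        assert ea.Ea.shape == (16, 16)

    def test_constant_force_offset_invariance(self):
        c0 = make_curve(E_MPa=6.0, z0=500.0)
        c1 = ForceCurve(c0.z, c0.deflection + 55.0, calibrated=True)

        def ea_of(c):
            cc = correct_baseline_tilt(c)
            z0 = detect_contact_point(cc, CFG)
            return fit_hertz_pyramid(*compute_indentation(cc, CFG, z0), CFG)[0]

        assert ea_of(c1) == pytest.approx(ea_of(c0), rel=1e-3)


class TestTransectAndGradient:
    def test_flat_profile_from_uniform_map(self):
        from stomamech.afm import EaMap, extract_transect
        img = np.full((64, 64), 7.0)
        blank = np.zeros_like(img)
        ea = EaMap(img, blank, blank, blank, np.zeros_like(img, int), 30.0)
        prof = extract_transect(ea, {"center": (15.0, 15.0),
                                     "semi_axes": (8.0, 5.0), "angle": 0.0})
        assert np.allclose(prof.Ea, 7.0)

    def test_constructed_four_gaussian_profile(self):
        # inner peak 10 MPa, outer 6 MPa, 1 um apart per cell -> 4.0 MPa/um
        s = np.linspace(0, 16, 801)

        def g(c, h, w=0.25):
            return h * np.exp(-0.5 * ((s - c) / w) ** 2)

        Ea = 2.0 + g(3.0, 4.0) + g(4.0, 8.0) + g(12.0, 8.0) + g(13.0, 4.0)
        prof = TransectProfile(s, Ea, "diameter")
        assert gradient_statistic(prof) == pytest.approx(4.0, abs=0.05)

    def test_equal_peaks_give_zero(self):
        s = np.linspace(0, 16, 801)

        def g(c, h, w=0.25):
            return h * np.exp(-0.5 * ((s - c) / w) ** 2)

        Ea = 2.0 + g(3.0, 6.0) + g(4.0, 6.0) + g(12.0, 6.0) + g(13.0, 6.0)
        prof = TransectProfile(s, Ea, "diameter")
        assert gradient_statistic(prof) == pytest.approx(0.0, abs=1e-9)

    def test_offset_invariance_and_linear_scaling(self):
        s = np.linspace(0, 16, 801)

        def g(c, h, w=0.25):
            return h * np.exp(-0.5 * ((s - c) / w) ** 2)

        base = g(3.0, 4.0) + g(4.0, 8.0) + g(12.0, 8.0) + g(13.0, 4.0)
        g0 = gradient_statistic(TransectProfile(s, 2.0 + base, "diameter"))
        g_off = gradient_statistic(TransectProfile(s, 7.0 + base, "diameter"))
        g_scaled = gradient_statistic(TransectProfile(s, 2.0 + 3.0 * base,
                                                      "diameter"))
        assert g_off == pytest.approx(g0, rel=1e-9)
        assert g_scaled == pytest.approx(3.0 * g0, rel=1e-9)

    def test_three_peak_gmc_not_computable(self):
        s = np.linspace(0, 16, 801)

        def g(c, h, w=0.25):
            return h * np.exp(-0.5 * ((s - c) / w) ** 2)

        Ea = 2.0 + g(3.0, 6.0) + g(8.0, 6.0) + g(13.0, 6.0)
        assert gradient_statistic(TransectProfile(s, Ea, "diameter")) is None


class TestMannWhitney:
    def test_identical_samples_give_half_product(self):
        a = [1.0, 2.0, 3.0, 4.0]
        U, _ = mann_whitney_u(a, list(a))
        assert U == len(a) * len(a) / 2

    def test_exact_small_sample_p(self):
        # {1,2} vs {3,4}: most extreme of C(4,2)=6 arrangements -> p = 1/3
        _, p = mann_whitney_u([1.0, 2.0], [3.0, 4.0])
        assert p == pytest.approx(1.0 / 3.0, rel=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])
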