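import numpy as np
import pytest

from cardiact import (
    Curve,
    FdgKinetics,
    GdKinetics,
    InfusionProtocol,
    concentration_to_t1,
    frame_curve,
    generate_puncta_slide,
    generate_trichrome_slide,
    sample_molli,
    simulate_iot_grid,
    simulate_plasma_curve,
    simulate_tissue_fdg,
    simulate_tissue_gd,
)
from cardiact.errors import InvalidParameterError, RangeError

from oracles import fdg_tissue_oracle, gd_tissue_oracle, plasma_ode_oracle


class TestInfusionProtocol:
    def test_defaults_match_protocol_design(self, protocol):
        assert protocol.t_end == 150.0
        assert protocol.windows == ((10.0, 40.0), (60.0, 90.0), (120.0, 150.0))
        assert protocol.suppression_onset == 40.0

    def test_total_gd_dose(self, protocol):
        assert protocol.total_gd_dose_mmol_per_kg == pytest.approx(0.6, rel=1e-12)

    @pytest.mark.parametrize(
        "windows",
        [
            ((40.0, 10.0),),  # reversed
            ((10.0, 40.0), (30.0, 90.0)),  # overlapping
            ((10.0, 40.0), (60.0, 200.0)),  # outside protocol
        ],
    )
    def test_invalid_windows_rejected(self, windows):
        with pytest.raises(InvalidParameterError):
            InfusionProtocol(windows=windows)

    def test_suppression_must_precede_second_window(self):
        with pytest.raises(InvalidParameterError):
            InfusionProtocol(suppression_onset=65.0)


class TestCurve:
    def test_rejects_unsorted_times(self):
        with pytest.raises(InvalidParameterError):
            Curve(np.array([0.0, 2.0, 1.0]), np.array([1.0, 2.0, 3.0]))

    def test_rejects_nonfinite(self):
        with pytest.raises(InvalidParameterError):
            Curve(np.array([0.0, 1.0]), np.array([1.0, np.nan]))

    def test_rejects_empty(self):
        with pytest.raises(InvalidParameterError):
            Curve(np.array([]), np.array([]))


class TestPlasmaCurve:
    def test_zero_elimination_is_linear_ramp(self, protocol):
        c = simulate_plasma_curve(protocol, vd=200.0, kel=0.0, grid=0.5, rate=4.0)
        i = np.searchsorted(c.times, 10.0)
        assert c.times[i] == 10.0
        assert c.values[i] == pytest.approx(0.2, rel=1e-12)

    def test_plateau_limit(self):
        proto = InfusionProtocol(t_end=150.0)
        c = simulate_plasma_curve(proto, vd=200.0, kel=0.2, grid=0.5, rate=4.0)
        assert c.values[-1] == pytest.approx(4.0 / (200.0 * 0.2), rel=1e-6)

    def test_matches_ode_oracle(self, protocol):
        c = simulate_plasma_curve(protocol, vd=200.0, kel=0.02, grid=0.1, rate=4.0)
        oracle = plasma_ode_oracle(4.0, 200.0, 0.02, c.times, dt=0.01)
        np.testing.assert_allclose(c.values, oracle, rtol=1e-6, atol=1e-12)
        i50 = np.searchsorted(c.times, 50.0)
        assert abs(c.values[i50] - oracle[i50]) <= 1e-6 * oracle[i50]

    def test_invalid_parameters(self, protocol):
        with pytest.raises(InvalidParameterError):
            simulate_plasma_curve(protocol, vd=0.0, kel=0.02)
        with pytest.raises(InvalidParameterError):
            simulate_plasma_curve(protocol, vd=200.0, kel=0.02, grid=0.0)

    def test_noise_reproducible_under_seed(self, protocol):
        a = simulate_plasma_curve(protocol, vd=200.0, kel=0.02, seed=7, noise_cv=0.05)
        b = simulate_plasma_curve(protocol, vd=200.0, kel=0.02, seed=7, noise_cv=0.05)
        np.testing.assert_array_equal(a.values, b.values)

    def test_nonnegative_and_finite(self, protocol):
        c = simulate_plasma_curve(protocol, vd=200.0, kel=0.02, seed=3, noise_cv=0.2)
        assert np.all(c.values >= 0) and np.all(np.isfinite(c.values))


class TestTissueFdg:
    def test_no_uptake_is_pure_blood_signal(self, fdg_plasma):
        kin = FdgKinetics(k1=0.0, k2=0.15, k3=0.05, vb=0.07)
        ct = simulate_tissue_fdg(fdg_plasma, kin)
        np.testing.assert_allclose(ct.values, 0.07 * fdg_plasma.values, atol=1e-12)

    def test_unit_suppression_matches_constant_k3_oracle(self, fdg_plasma):
        kin = FdgKinetics(k1=0.1, k2=0.15, k3=0.05, vb=0.05, suppression_factor=1.0)
        ct = simulate_tissue_fdg(fdg_plasma, kin)
        oracle = fdg_tissue_oracle(fdg_plasma.times, fdg_plasma.values, kin, onset=40.0)
        np.testing.assert_allclose(ct.values, oracle, rtol=1e-5, atol=1e-9)

    def test_suppressed_run_matches_oracle(self, fdg_plasma):
        kin = FdgKinetics(
            k1=0.1, k2=0.15, k3=0.05, vb=0.05, suppression_factor=0.1, transition_tau=5.0
        )
        ct = simulate_tissue_fdg(fdg_plasma, kin, onset=40.0)
        oracle = fdg_tissue_oracle(fdg_plasma.times, fdg_plasma.values, kin, onset=40.0)
        np.testing.assert_allclose(ct.values, oracle, rtol=1e-5, atol=1e-9)

    def test_negative_rates_rejected(self):
        with pytest.raises(InvalidParameterError):
            FdgKinetics(k1=-0.1)

    def test_onset_must_be_in_range(self, fdg_plasma):
        with pytest.raises(InvalidParameterError):
            simulate_tissue_fdg(fdg_plasma, FdgKinetics(), onset=1000.0)

    def test_suppression_lowers_late_patlak_slope(self, fdg_plasma, protocol):
        from cardiact import fit_patlak, patlak_points

        base = FdgKinetics(k1=0.1, k2=0.15, k3=0.05, vb=0.05, suppression_factor=1.0)
        supp = FdgKinetics(k1=0.1, k2=0.15, k3=0.05, vb=0.05, suppression_factor=0.3)
        late = protocol.windows[2]
        ki = {}
        for name, kin in (("base", base), ("supp", supp)):
            ct = simulate_tissue_fdg(fdg_plasma, kin, onset=40.0)
            ki[name] = fit_patlak(patlak_points(ct, fdg_plasma), late).ki
        assert ki["supp"] < ki["base"]


class TestTissueGd:
    def test_no_exchange_is_plasma_volume_only(self, gd_plasma):
        kin = GdKinetics(ktrans=0.0, ve=0.3, vp=0.05, hct=0.45)
        ct = simulate_tissue_gd(gd_plasma, kin)
        np.testing.assert_allclose(ct.values, 0.05 * 0.55 * gd_plasma.values, atol=1e-14)

    def test_equilibrium_limit(self):
        # long plateau: interstitium equilibrates with plasma
        proto = InfusionProtocol(t_end=600.0, windows=())
        plasma = simulate_plasma_curve(proto, vd=250.0, kel=0.2, grid=0.5)
        kin = GdKinetics(ktrans=0.3, ve=0.4, vp=0.03, hct=0.45)
        ct = simulate_tissue_gd(plasma, kin)
        blood = (1 - kin.hct) * plasma.values[-1]
        expected_ratio = kin.ve / (1 - kin.hct) + kin.vp
        assert ct.values[-1] / blood == pytest.approx(expected_ratio, rel=1e-3)

    def test_matches_ode_oracle(self, gd_plasma):
        kin = GdKinetics(ktrans=0.1, ve=0.48, vp=0.02)
        ct = simulate_tissue_gd(gd_plasma, kin)
        oracle = gd_tissue_oracle(gd_plasma.times, gd_plasma.values, kin)
        np.testing.assert_allclose(ct.values, oracle, rtol=1e-5, atol=1e-10)

    def test_zero_ve_with_exchange_rejected(self, gd_plasma):
        with pytest.raises(InvalidParameterError):
            simulate_tissue_gd(gd_plasma, GdKinetics(ktrans=0.1, ve=0.0))


class TestConcentrationToT1:
    def test_zero_concentration_returns_native(self):
        assert concentration_to_t1(0.0, 1234.5, 4.5) == pytest.approx(1234.5, rel=1e-14)

    def test_closed_form_value(self):
        # 1/(1/1000 + 4.5e-3 * 0.5) ms
        expected = 1.0 / (0.001 + 0.00225)
        assert concentration_to_t1(0.5, 1000.0, 4.5) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(307.692, abs=5e-4)

    def test_strictly_decreasing_in_concentration(self):
        concs = np.linspace(0.0, 3.0, 50)
        t1 = concentration_to_t1(concs, 1100.0, 4.5)
        assert np.all(np.diff(t1) < 0)

    def test_invalid_inputs(self):
        with pytest.raises(InvalidParameterError):
            concentration_to_t1(0.5, -1.0, 4.5)
        with pytest.raises(InvalidParameterError):
            concentration_to_t1(-0.5, 1000.0, 4.5)


@pytest.fixture(scope="module")
def t1_curves(gd_plasma, reference_gd_kinetics):
    kin = reference_gd_kinetics
    tissue = simulate_tissue_gd(gd_plasma, kin)
    myo = Curve(tissue.times, concentration_to_t1(tissue.values, kin.t10_tissue, kin.r1))
    blood_conc = (1 - kin.hct) * gd_plasma.values
    blood = Curve(
        gd_plasma.times, concentration_to_t1(blood_conc, kin.t10_blood, kin.r1)
    )
    return myo, blood


class TestSampleMolli:
    def test_zero_noise_is_exact_interpolation(self, t1_curves):
        myo, blood = t1_curves
        times = np.arange(0.0, 151.0, 10.0)
        table = sample_molli(myo, blood, times, noise_sd=0.0)
        np.testing.assert_array_equal(table.t1_myo_ms, myo.interp(times))
        np.testing.assert_array_equal(table.t1_blood_ms, blood.interp(times))

    def test_deterministic_under_seed(self, t1_curves):
        myo, blood = t1_curves
        times = np.arange(0.0, 151.0, 10.0)
        a = sample_molli(myo, blood, times, noise_sd=15.0, seed=11)
        b = sample_molli(myo, blood, times, noise_sd=15.0, seed=11)
        np.testing.assert_array_equal(a.t1_myo_ms, b.t1_myo_ms)
        np.testing.assert_array_equal(a.t1_blood_ms, b.t1_blood_ms)

    def test_noise_sd_calibration(self, t1_curves):
        # 1000 noisy draws: empirical SD of the added noise within 10% of 20 ms
        myo, blood = t1_curves
        times = np.linspace(0.0, 150.0, 200)
        clean = np.asarray(myo.interp(times))
        residuals = []
        for seed in range(5):
            table = sample_molli(myo, blood, times, noise_sd=20.0, seed=seed)
            residuals.append(table.t1_myo_ms - clean)
        sd = np.std(np.concatenate(residuals))
        assert abs(sd - 20.0) < 2.0

    def test_out_of_range_sample_time(self, t1_curves):
        myo, blood = t1_curves
        with pytest.raises(RangeError):
            sample_molli(myo, blood, [0.0, 160.0])


class TestTrichromeSlides:
    def test_zero_fraction_empty_mask(self):
        slide = generate_trichrome_slide((64, 64), 0.0, seed=0)
        assert not slide.truth_mask.any()
        assert slide.truth_fraction == 0.0

    def test_full_fraction_full_mask(self):
        slide = generate_trichrome_slide((64, 64), 1.0, seed=0)
        assert slide.truth_mask.all()
        assert slide.truth_fraction == 1.0

    def test_requested_fraction_honoured(self):
        slide = generate_trichrome_slide((256, 256), 0.2, seed=42)
        assert 0.195 <= slide.truth_fraction <= 0.205

    def test_bit_reproducible(self):
        a = generate_trichrome_slide((64, 64), 0.3, seed=5)
        b = generate_trichrome_slide((64, 64), 0.3, seed=5)
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_invalid_fraction(self):
        with pytest.raises(InvalidParameterError):
            generate_trichrome_slide((64, 64), 1.5)


class TestPunctaSlides:
    def test_no_puncta_stays_at_background(self):
        slide = generate_puncta_slide((128, 128), 0, background_sd=5.0, seed=1)
        # 128*128 draws: maximum should stay within a generous gaussian tail
        assert slide.pixels.max() <= 10.0 + 6 * 5.0

    def test_spot_centers_dominate_background(self):
        slide = generate_puncta_slide(
            (128, 128), 10, amplitude=500.0, background_sd=5.0, seed=2
        )
        background_cap = 10.0 + 6 * 5.0
        for r, c, _amp in slide.truth_spots:
            assert slide.pixels[int(round(r)), int(round(c))] > background_cap

    def test_bit_reproducible(self):
        a = generate_puncta_slide((64, 64), 5, seed=9)
        b = generate_puncta_slide((64, 64), 5, seed=9)
        np.testing.assert_array_equal(a.pixels, b.pixels)


@pytest.fixture(scope="module")
def coarse_plasma(protocol):
    return simulate_plasma_curve(protocol, vd=250.0, kel=0.05, grid=0.5)


class TestIotGrid:
    def test_no_penetration_constant_apparent_volume(self, coarse_plasma):
        vols = simulate_iot_grid(
            50, (0.0, 0.0), 0.5, (30.0, 150.0), coarse_plasma, seed=0
        )
        assert vols[30.0] == vols[150.0] == 50

    def test_fast_exchange_vanishes(self, coarse_plasma):
        vols = simulate_iot_grid(
            50, (5.0, 5.0), 0.5, (30.0, 150.0), coarse_plasma, seed=0
        )
        assert vols[30.0] == 0 and vols[150.0] == 0

    def test_monotone_filling_over_seeds(self, coarse_plasma):
        for seed in range(100):
            vols = simulate_iot_grid(
                40, (0.0, 0.02), 0.5, (30.0, 150.0), coarse_plasma, seed=seed
            )
            assert vols[150.0] <= vols[30.0]

    def test_reduction_percent_plumbs_into_kinetics(self, coarse_plasma):
        from cardiact import volume_reduction

        vols = simulate_iot_grid(
            200, (0.0, 0.03), 0.5, (30.0, 150.0), coarse_plasma, seed=3
        )
        if vols[30.0] > 0:
            pct = volume_reduction(float(vols[30.0]), float(vols[150.0]))
            assert 0.0 <= pct <= 100.0

    def test_empty_grid_rejected(self, coarse_plasma):
        with pytest.raises(InvalidParameterError):
            simulate_iot_grid(0, (0.0, 0.01), 0.5, (30.0, 150.0), coarse_plasma)


class TestFrameCurve:
    def test_constant_curve_frames_to_constant(self):
        c = Curve(np.arange(0.0, 30.0, 0.1), np.full(300, 2.5))
        framed = frame_curve(c, 3.0)
        assert len(framed) == 9  # last partial frame dropped
        np.testing.assert_allclose(framed.values, 2.5)
        assert framed.times[0] == pytest.approx(1.5)

    def test_invalid_frame_length(self):
        c = Curve(np.arange(0.0, 30.0, 0.1), np.zeros(300))
        with pytest.raises(InvalidParameterError):
            frame_curve(c, 0.0)
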