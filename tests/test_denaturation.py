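"""Two-state model evaluation, observable extraction, and fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stabscan.constants import R_GAS
from stabscan.denaturation import (EmissionSpectrum, SignalCurve,
                                   build_signal_curve, eval_chemical_model,
                                   eval_thermal_model, extract_lambda_max,
                                   fit_chemical, fit_thermal,
                                   stability_deltas)
from stabscan.errors import DegenerateTransitionError, ValidationError
from stabscan.synthetic import SpectraSimConfig, simulate_spectra_series


class TestModelEvaluation:
    def test_thermal_midpoint_is_half_amplitude(self):
        assert eval_thermal_model(50, 333, 100, -60, 333.0) == pytest.approx(
            100 - 30, abs=1e-12)

    def test_thermal_worked_value(self):
        # independent recomputation: u = (dH/R)(1/Tm - 1/x)
        u = (50.0 / R_GAS) * (1 / 333.0 - 1 / 343.0)
        expected = 100 - 60 * np.exp(u) / (1 + np.exp(u))
        assert eval_thermal_model(50, 333, 100, -60, 343.0) == pytest.approx(
            expected, rel=1e-12)
        assert expected == pytest.approx(45.9696, abs=5e-4)

    def test_thermal_step_limit(self):
        y = eval_thermal_model(5e4, 333, 100, -60, 332.0)
        assert abs(y - 100) < 1e-6 * 60

    def test_chemical_midpoint_is_half_amplitude(self):
        assert eval_chemical_model(4, 2, 330, 20, 298, 2.0) == pytest.approx(
            340.0, abs=1e-12)

    def test_chemical_worked_value(self):
        v = -(4 - 2 * 1.0) / (R_GAS * 298)
        expected = 330 + 20 * np.exp(v) / (1 + np.exp(v))
        got = eval_chemical_model(4, 2, 330, 20, 298, 1.0)
        assert got == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(330.66, abs=5e-3)

    def test_chemical_folded_limit(self):
        y = eval_chemical_model(10.0, 2.0, 330, 20, 298, 0.0)
        assert abs(y - 330) < 1e-6 * 20

    @given(st.floats(5, 200), st.floats(280, 380),
           st.floats(-100, 100), st.floats(0.5, 80))
    @settings(max_examples=40, deadline=None)
    def test_thermal_monotone_in_x(self, dh, tm, yn, yd):
        x = np.linspace(280.0, 380.0, 60)
        y = eval_thermal_model(dh, tm, yn, yd, x)
        assert np.all(np.diff(y) >= -1e-12)  # increasing for yd > 0


class TestLambdaMax:
    def test_on_grid_peak(self):
        lam = np.arange(300.0, 361.0)
        spec = EmissionSpectrum(lam, np.exp(-0.5 * ((lam - 330) / 10) ** 2), 300)
        res = extract_lambda_max(spec)
        assert res.wavelength_nm == pytest.approx(330.0, abs=1e-9)
        assert not res.at_boundary

    def test_subgrid_peak_matches_dense_argmax(self):
        lam = np.arange(300.0, 361.0)
        centre = 331.3
        f = lambda w: np.exp(-0.5 * ((w - centre) / 9.0) ** 2)
        spec = EmissionSpectrum(lam, f(lam), 300)
        dense = np.arange(300.0, 361.0, 0.001)
        oracle = dense[np.argmax(f(dense))]
        got = extract_lambda_max(spec).wavelength_nm
        assert got == pytest.approx(oracle, abs=0.05)

    def test_boundary_flagged(self):
        lam = np.arange(300.0, 361.0)
        res = extract_lambda_max(EmissionSpectrum(lam, lam * 1.0, 300))
        assert res.wavelength_nm == 360.0 and res.at_boundary

    def test_flat_spectrum_rejected(self):
        lam = np.arange(300.0, 310.0)
        with pytest.raises(ValidationError):
            extract_lambda_max(EmissionSpectrum(lam, np.ones_like(lam), 300))


class TestSignalCurve:
    def test_lambda_max_sigmoid_shape(self, noise_free_thermal_series):
        cfg, series = noise_free_thermal_series
        curve = build_signal_curve(series, "lambda_max")
        assert curve.y[0] == pytest.approx(cfg.lambda_n, abs=1.0)
        assert curve.y[-1] == pytest.approx(cfg.lambda_u, abs=1.5)
        assert np.all(np.diff(curve.y) >= -1e-9)

    def test_peak_intensity_decays_through_transition(self, noise_free_thermal_series):
        """Peak intensity falls monotonically while the native band dominates.

        Once the native band has fully decayed the spectrum maximum sits on
        the unfolded band and creeps back up toward its height, so strict
        monotonicity is only expected up to ~90% unfolded.
        """
        from stabscan.synthetic import unfolded_fraction
        cfg, series = noise_free_thermal_series
        curve = build_signal_curve(series, "peak_intensity")
        fu = unfolded_fraction(cfg, curve.x)
        core = fu <= 0.9
        assert np.all(np.diff(curve.y[core]) < 0)
        # the net decay dwarfs the post-transition recovery
        drop = curve.y[0] - curve.y.min()
        recovery = curve.y[-1] - curve.y.min()
        assert drop > 5 * recovery

    def test_too_few_conditions_rejected(self):
        cfg = SpectraSimConfig(noise_sigma=0.0,
                               conditions=np.array([300.0, 320, 340.0]))
        with pytest.raises(ValidationError):
            build_signal_curve(simulate_spectra_series(cfg), "lambda_max")


def _recovery_case(mode, rng):
    if mode == "thermal":
        truth = dict(tm=rng.uniform(315, 345), dh_app=rng.uniform(30, 90))
        cfg = SpectraSimConfig(mode=mode, noise_sigma=0.0,
                               seed=int(rng.integers(2**31)), **truth)
    else:
        dg = rng.uniform(2.5, 6.0)
        m = rng.uniform(1.5, 3.0)
        truth = dict(dg_app=dg, m_value=m)
        cfg = SpectraSimConfig(mode=mode, noise_sigma=0.0,
                               conditions=np.arange(0.0, 4.01, 0.2),
                               seed=int(rng.integers(2**31)), **truth)
    return cfg, truth


class TestFits:
    def test_noise_free_thermal_recovery(self):
        """Noise-free curves on the affine channel recover truth to 1e-4."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            cfg, truth = _recovery_case("thermal", rng)
            curve = build_signal_curve(simulate_spectra_series(cfg),
                                       "integrated_intensity")
            fit = fit_thermal(curve)
            assert fit.converged
            assert fit.tm == pytest.approx(truth["tm"], rel=1e-4)
            assert fit.dh_app == pytest.approx(truth["dh_app"], rel=1e-4)

    def test_noise_free_chemical_recovery(self):
        rng = np.random.default_rng(43)
        for _ in range(20):
            cfg, truth = _recovery_case("chemical", rng)
            curve = build_signal_curve(simulate_spectra_series(cfg),
                                       "integrated_intensity")
            fit = fit_chemical(curve)
            assert fit.dg_app == pytest.approx(truth["dg_app"], rel=1e-4)
            assert fit.m_value == pytest.approx(truth["m_value"], rel=1e-4)
            assert fit.d_half == pytest.approx(truth["dg_app"] / truth["m_value"],
                                               rel=1e-4)

    def test_chemical_midpoint_crosses_at_d_half(self):
        """fu = 0.5 exactly at x = dG/m = 2 M for the 4/2 ground truth."""
        cfg = SpectraSimConfig(mode="chemical", dg_app=4.0, m_value=2.0,
                               noise_sigma=0.0,
                               conditions=np.arange(0.0, 4.01, 0.25))
        from stabscan.synthetic import unfolded_fraction
        assert unfolded_fraction(cfg, 2.0) == pytest.approx(0.5, abs=1e-12)

    def test_flat_curve_rejected(self):
        x = np.linspace(290, 360, 15)
        y = 100 + 0.01 * np.where(np.arange(15) % 2 == 0, 1.0, -1.0)
        curve = SignalCurve(x, y, "peak_intensity")
        with pytest.raises(DegenerateTransitionError):
            fit_thermal(curve)

    @given(st.floats(0.2, 5.0), st.floats(-50.0, 50.0))
    @settings(max_examples=15, deadline=None)
    def test_affine_signal_invariance(self, a, b):
        """y -> a*y + b moves only (Yn, Yd), never (Tm, dH_app)."""
        x = np.linspace(293.0, 363.0, 15)
        y = eval_thermal_model(50.0, 333.0, 100.0, -60.0, x)
        f1 = fit_thermal(SignalCurve(x, y, "peak_intensity"))
        f2 = fit_thermal(SignalCurve(x, a * y + b, "peak_intensity"))
        assert f2.tm == pytest.approx(f1.tm, rel=1e-6)
        assert f2.dh_app == pytest.approx(f1.dh_app, rel=1e-6)
        assert f2.yn == pytest.approx(a * f1.yn + b, rel=1e-5, abs=1e-6)
        assert f2.yd == pytest.approx(a * f1.yd, rel=1e-5)

    def test_fitted_midpoint_signal_identity(self):
        x = np.linspace(293.0, 363.0, 15)
        y = eval_thermal_model(50.0, 333.0, 100.0, -60.0, x)
        fit = fit_thermal(SignalCurve(x, y, "peak_intensity"))
        model_at_tm = eval_thermal_model(fit.dh_app, fit.tm, fit.yn, fit.yd,
                                         fit.tm)
        assert model_at_tm == pytest.approx((2 * fit.yn + fit.yd) / 2, abs=1e-9)


class TestStabilityDeltas:
    def _thermal(self, tm):
        return type("F", (), {"tm": tm})()

    def _chem(self, d):
        return type("F", (), {"d_half": d})()

    def test_wild_type_self_deltas_zero(self):
        out = stability_deltas({"WT": self._thermal(333.0)},
                               {"WT": self._chem(2.0)},
                               {"WT": self._chem(1.635)})
        assert out["WT"].delta_tm == 0.0
        assert out["WT"].delta_delta_d_half == 0.0
        assert out["WT"].delta_d_half == pytest.approx(0.365)

    def test_destabilising_sign(self):
        out = stability_deltas({"WT": self._thermal(333.0),
                                "MUT": self._thermal(323.0)})
        assert out["MUT"].delta_tm == pytest.approx(10.0)

    def test_missing_wild_type_rejected(self):
        with pytest.raises(ValidationError):
            stability_deltas({"MUT": self._thermal(323.0)})
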