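"""Tests for exponential-phase analysis, rate-dependence fits, global
regression, confidence contours and decay fitting."""

import lmfit
import numpy as np
import pytest

import lumidyn as ld
from lumidyn.fitting import (
    RateDependenceFit,
    estimate_sigma,
    fit_decay,
    fit_exponentials,
    fit_rate_dependence,
    minimize_residual,
)
from lumidyn.synth import KineticDesign, NoiseSpec, gen_decay_trace, gen_kinetic_dataset


class TestFitExponentials:
    def test_noiseless_double_exponential_round_trip(self):
        t = np.linspace(0, 1, 40)
        y = 1.0 - 0.3 * np.exp(-150 * t) - 0.1 * np.exp(-11 * t)
        ph = fit_exponentials(t, y, n_phases=2)
        assert ph.k_fast == pytest.approx(150.0, rel=1e-3)
        assert ph.k_slow == pytest.approx(11.0, rel=1e-3)
        assert ph.F_SS == pytest.approx(1.0, rel=1e-3)
        assert ph.amplitudes[0] == pytest.approx(-0.3, rel=1e-3)
        assert ph.amplitudes[1] == pytest.approx(-0.1, rel=1e-3)

    def test_value_at_zero_equals_offset_plus_amplitudes(self):
        t = np.linspace(0, 2, 30)
        y = 0.5 + 0.2 * np.exp(-3.0 * t)
        ph = fit_exponentials(t, y, n_phases=1)
        assert ph.evaluate(np.array([0.0]))[0] == pytest.approx(
            ph.F_SS + sum(ph.amplitudes)
        )

    def test_constant_signal_rejected(self):
        t = np.linspace(0, 1, 30)
        with pytest.raises(ValueError, match="constant"):
            fit_exponentials(t, np.ones_like(t), n_phases=1)

    def test_single_phase_data_flagged_for_double_fit(self):
        t = np.linspace(0, 2, 60)
        y = 1.0 + 0.4 * np.exp(-5.0 * t)
        with pytest.raises(ValueError, match="degenerate|single"):
            fit_exponentials(t, y, n_phases=2)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            fit_exponentials(np.linspace(0, 1, 8), np.linspace(1, 0, 8), n_phases=2)


class TestFitRateDependence:
    def test_one_step_linear_recovery_exact(self):
        S = np.array([1.0, 2.0, 5.0, 10.0, 20.0])
        k_obs = 1.0 * S + 2.0
        fit = fit_rate_dependence(S, "ONE_STEP", k_obs=k_obs)
        assert fit.rates.k_plus1 == pytest.approx(1.0, abs=1e-8)
        assert fit.rates.k_minus1 == pytest.approx(2.0, abs=1e-8)

    def test_one_step_amplitude_recovery(self):
        S = np.array([0.5, 1.0, 2.0, 4.0, 8.0, 16.0])
        A = 10.0 * S / (2.0 + S)
        fit = fit_rate_dependence(S, "ONE_STEP", k_obs=S + 1.0, amplitude=A)
        assert fit.A_lim == pytest.approx(10.0, abs=1e-6)
        assert fit.K_d == pytest.approx(2.0, abs=1e-6)

    def test_induced_fit_recovery_from_exact_laws(self):
        S = np.array([2.0, 5.0, 10.0, 20.0, 50.0])
        rates = ld.RateConstantSet(k_plus1=3.0, k_minus1=60.0, k_plus2=25.0, k_minus2=4.0)
        pairs = [ld.observed_rates_analytic(rates, "INDUCED_FIT", s) for s in S]
        fit = fit_rate_dependence(
            S, "INDUCED_FIT",
            k_fast=np.array([p.k_fast for p in pairs]),
            k_slow=np.array([p.k_slow for p in pairs]),
        )
        assert fit.rates.k_plus1 == pytest.approx(3.0, rel=1e-6)
        assert fit.rates.k_minus1 == pytest.approx(60.0, rel=1e-6)
        assert fit.rates.k_plus2 == pytest.approx(25.0, rel=1e-4)
        assert fit.rates.k_minus2 == pytest.approx(4.0, rel=1e-4)

    def test_underdetermined_rejected(self):
        with pytest.raises(ValueError, match="3 distinct"):
            fit_rate_dependence(np.array([5.0, 5.0]), "ONE_STEP", k_obs=np.array([1.0, 1.0]))
        with pytest.raises(ValueError, match="identical"):
            fit_rate_dependence(
                np.array([1.0, 2.0, 3.0]), "ONE_STEP", k_obs=np.array([4.0, 4.0, 4.0])
            )


def _steady_state_setup():
    rates = ld.RateConstantSet(k_minus1=250.0, k_plus2=4.2, k_plus3=30.0)
    spec = ld.make_mechanism("CYCLE_RAPID_EQ", rates)
    obs = ld.ObservationModel("LUMINESCENCE_CUMULATIVE", f=50.0)
    return spec, obs


class TestFitGlobal:
    def test_noiseless_round_trip_small_design(self):
        """Noiseless simulate->fit recovers the generating constants; kept on
        a reduced 3-concentration design (the full study design is exercised
        by the acceptance suite)."""
        spec, obs = _steady_state_setup()
        design = KineticDesign(
            S_concentrations=(1.0, 2.2, 10.0), E0=0.05, n_replicates=1,
            t_max=600.0, n_points=50,
        )
        ds = gen_kinetic_dataset(spec, obs, design, NoiseSpec(level=0.0, seed=3))
        fr = ld.fit_global(
            ds, spec, obs, free_params=["k_minus1", "k_plus2", "k_plus3", "f"],
            starts={"k_minus1": 100.0, "k_plus2": 1.0, "k_plus3": 10.0, "f": 30.0},
        )
        assert fr.estimates["k_plus2"] == pytest.approx(4.2, rel=1e-3)
        assert fr.estimates["k_minus1"] == pytest.approx(250.0, rel=1e-3)
        assert fr.estimates["k_plus3"] == pytest.approx(30.0, rel=1e-3)
        assert fr.estimates["f"] == pytest.approx(50.0, rel=5e-3)

    def test_optimum_beats_random_perturbations(self):
        spec, obs = _steady_state_setup()
        design = KineticDesign(
            S_concentrations=(1.0, 5.0, 10.0), E0=0.05, n_replicates=1,
            t_max=400.0, n_points=30,
        )
        ds = gen_kinetic_dataset(spec, obs, design, NoiseSpec(level=0.01, seed=8))
        fr = ld.fit_global(
            ds, spec, obs, free_params=["k_minus1", "k_plus2", "k_plus3"],
            starts={"k_minus1": 250.0, "k_plus2": 4.2, "k_plus3": 30.0},
        )
        rng = np.random.default_rng(99)
        p0 = fr._params
        for _ in range(100):
            p = p0.copy()
            for name in ("k_minus1", "k_plus2", "k_plus3"):
                p[name].value *= 1.0 + rng.uniform(-0.2, 0.2)
            chi2 = float(np.sum(fr._residual(p) ** 2))
            assert chi2 >= fr.chi2 * (1 - 1e-9)

    def test_conc_adjust_factors_stay_in_box(self):
        spec, obs = _steady_state_setup()
        design = KineticDesign(
            S_concentrations=(1.0, 5.0, 10.0), E0=0.05, n_replicates=1,
            t_max=400.0, n_points=25,
        )
        ds = gen_kinetic_dataset(spec, obs, design, NoiseSpec(level=0.02, seed=4))
        fr = ld.fit_global(
            ds, spec, obs, free_params=["k_plus2"], adjust_conc=True,
            starts={"k_plus2": 4.0},
        )
        assert fr.conc_factors is not None
        for v in fr.conc_factors.values():
            assert 0.95 - 1e-9 <= v <= 1.05 + 1e-9


class TestConfidenceContour:
    @staticmethod
    def _linear_fit(seed=42, sigma=0.5, n=30):
        rng = np.random.default_rng(seed)
        x = np.linspace(0, 10, n)
        y = 2.0 + 0.7 * x + rng.normal(0, sigma, n)
        params = lmfit.Parameters()
        params.add("a", value=0.0)
        params.add("b", value=0.0)
        resid = lambda p: (y - (p["a"].value + p["b"].value * x)) / sigma
        fr = minimize_residual(resid, params)
        X = np.column_stack([np.ones_like(x), x])
        var_b = sigma**2 * np.linalg.inv(X.T @ X)[1, 1]
        return fr, var_b

    def test_bounds_match_analytic_profile(self):
        """Ratio-convention bounds agree with the closed-form profile-chi2
        interval of the straight-line Gaussian model within 2%."""
        fr, var_b = self._linear_fit()
        for thr in (0.9, 0.95):
            cc = ld.confidence_contour(fr, "b", thr)
            half = np.sqrt(fr.chi2 * (1 / thr - 1) * var_b)
            assert cc.lower == pytest.approx(fr.estimates["b"] - half, rel=0.02)
            assert cc.upper == pytest.approx(fr.estimates["b"] + half, rel=0.02)

    def test_interval_nesting_and_collapse(self):
        fr, _ = self._linear_fit()
        c90 = ld.confidence_contour(fr, "b", 0.9)
        c95 = ld.confidence_contour(fr, "b", 0.95)
        assert c90.lower <= c95.lower <= c95.upper <= c90.upper
        c100 = ld.confidence_contour(fr, "b", 1.0)
        assert c100.lower == c100.upper == fr.estimates["b"]
        for cc in (c90, c95):
            assert cc.lower <= fr.estimates["b"] <= cc.upper

    def test_bad_threshold_rejected(self):
        fr, _ = self._linear_fit()
        with pytest.raises(ValueError, match="threshold"):
            ld.confidence_contour(fr, "b", 1.5)

    def test_delta_convention_available(self):
        fr, var_b = self._linear_fit()
        cc = ld.confidence_contour(fr, "b", 1.0, convention="delta")
        # delta-chi2 = 1 is the 1-sigma profile interval
        assert cc.upper - cc.lower == pytest.approx(2 * np.sqrt(var_b), rel=0.05)


class TestCompareMechanisms:
    def test_identical_candidates_tie(self):
        spec = ld.make_mechanism("ONE_STEP", ld.RateConstantSet(k_plus1=2.0, k_minus1=40.0))
        obs = ld.ObservationModel("FLUORESCENCE", f=5.0, a=0.4,
                                  mechanism_kind=ld.MechanismKind.ONE_STEP)
        design = KineticDesign(
            S_concentrations=(5.0, 30.0, 100.0), E0=1.0, n_replicates=1,
            t_max=0.3, n_points=40,
        )
        ds = gen_kinetic_dataset(spec, obs, design, NoiseSpec(level=0.02, seed=2))
        cand = dict(
            name="x", spec=spec, obs=obs, free=["k_plus1", "k_minus1"],
            starts={"k_plus1": 1.0, "k_minus1": 10.0},
        )
        rows = ld.compare_mechanisms(ds, [dict(cand), dict(cand, name="y")])
        assert rows[0]["tie"] is True

    def test_failing_candidate_ranked_last_with_reason(self):
        spec = ld.make_mechanism("ONE_STEP", ld.RateConstantSet(k_plus1=2.0, k_minus1=40.0))
        obs = ld.ObservationModel("FLUORESCENCE", f=5.0, a=0.4,
                                  mechanism_kind=ld.MechanismKind.ONE_STEP)
        design = KineticDesign(
            S_concentrations=(5.0, 30.0, 100.0), E0=1.0, n_replicates=1,
            t_max=0.3, n_points=30,
        )
        ds = gen_kinetic_dataset(spec, obs, design, NoiseSpec(level=0.02, seed=2))
        bad_obs = ld.ObservationModel("LUMINESCENCE_CUMULATIVE", f=1.0)  # no P species
        rows = ld.compare_mechanisms(ds, [
            dict(name="good", spec=spec, obs=obs, free=["k_plus1", "k_minus1"],
                 starts={"k_plus1": 1.0, "k_minus1": 10.0}),
            dict(name="bad", spec=spec, obs=bad_obs, free=["k_plus1"]),
        ])
        assert rows[-1]["name"] == "bad" and rows[-1]["failed"]
        assert rows[-1]["failure"]


class TestFitDecay:
    def test_exponential_half_life_identity(self):
        t, y, _ = gen_decay_trace("exponential", t_half=100.0, noise=NoiseSpec(level=0.0))
        fit = fit_decay(t, y, "exponential")
        assert fit.t_half == pytest.approx(100.0, rel=1e-9)
        assert fit.t_half == pytest.approx(np.log(2) / fit.params["k"])

    def test_noisy_exponential_within_two_percent(self):
        t, y, _ = gen_decay_trace(
            "exponential", t_half=100.0, noise=NoiseSpec(level=0.01, seed=5)
        )
        fit = fit_decay(t, y, "exponential")
        assert fit.t_half == pytest.approx(100.0, rel=0.02)

    def test_logistic_round_trip(self):
        t, y, _ = gen_decay_trace(
            "logistic", t_half=50.0, hill=2.5, noise=NoiseSpec(level=0.01, seed=6)
        )
        fit = fit_decay(t, y, "logistic")
        assert fit.t_half == pytest.approx(50.0, rel=0.02)

    def test_rising_signal_rejected(self):
        t = np.linspace(0, 10, 50)
        with pytest.raises(ValueError, match="no overall decay"):
            fit_decay(t, 1.0 + t, "exponential")


def test_sigma_estimator_tracks_noise_level():
    rng = np.random.default_rng(11)
    t = np.linspace(0, 10, 200)
    y = np.exp(-t / 5) + rng.normal(0, 0.02, len(t))
    est = estimate_sigma(y)
    assert est == pytest.approx(0.02, rel=0.4)
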