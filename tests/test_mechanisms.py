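"""Unit and property tests for the kinetic mechanism presets and simulator."""

import numpy as np
import pytest

import lumidyn as ld
from lumidyn.mechanisms import (
    DIFFUSION_LIMIT,
    MechanismKind,
    initial_velocity,
    instantaneous_luminescence,
)

ALL_KINDS = list(MechanismKind)


def full_rates():
    return ld.RateConstantSet(
        k_plus1=5.0, k_minus1=50.0, k_plus2=10.0, k_minus2=2.0,
        k_plus3=30.0, k_minus3=100.0,
    )


class TestMakeMechanism:
    def test_rapid_eq_cycle_fixes_diffusion_limited_constants(self):
        spec = ld.make_mechanism(
            "CYCLE_RAPID_EQ",
            ld.RateConstantSet(k_minus1=250.0, k_plus2=4.2, k_plus3=30.0),
        )
        assert spec.rates.k_plus1 == DIFFUSION_LIMIT
        assert spec.rates.k_minus3 == DIFFUSION_LIMIT

    def test_irreversible_cycle_fixes_k_minus1_zero(self):
        spec = ld.make_mechanism(
            "CYCLE_IRREV",
            ld.RateConstantSet(k_plus1=5.0, k_plus2=4.2, k_plus3=30.0),
        )
        assert spec.rates.k_minus1 == 0.0
        assert spec.rates.k_minus3 == DIFFUSION_LIMIT

    def test_missing_constants_named_in_error(self):
        with pytest.raises(ValueError, match="k-1.*k\\+2.*k-2"):
            ld.make_mechanism("INDUCED_FIT", ld.RateConstantSet(k_plus1=10.0))

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            ld.RateConstantSet(k_plus1=-1.0)

    @pytest.mark.parametrize("kind", ALL_KINDS)
    def test_stoichiometry_conserves_enzyme_and_substrate(self, kind):
        spec = ld.make_mechanism(kind, full_rates())
        enzyme = {"E": 1, "E*": 1, "E.S": 1, "E*.S": 1, "E.P": 1}
        moiety = {"S": 1, "E.S": 1, "E*.S": 1, "E.P": 1, "P": 1}
        for rxn in spec.reactions:
            for weights in (enzyme, moiety):
                before = sum(weights.get(s, 0) for s in rxn.reactants)
                after = sum(weights.get(s, 0) for s in rxn.products)
                assert before == after

    def test_json_round_trip(self):
        spec = ld.make_mechanism(
            "CYCLE_RAPID_EQ",
            ld.RateConstantSet(k_minus1=250.0, k_plus2=4.2, k_plus3=30.0),
        )
        back = ld.MechanismSpec.from_json(spec.to_json())
        assert back.kind == spec.kind
        assert back.rates == spec.rates


class TestSimulate:
    def test_no_enzyme_no_turnover(self):
        spec = ld.make_mechanism(
            "CYCLE_IRREV", ld.RateConstantSet(k_plus1=5.0, k_plus2=4.2, k_plus3=30.0)
        )
        traj = ld.simulate_mechanism(spec, {"E": 0.0, "S": 10.0}, np.linspace(0, 100, 50))
        assert np.all(traj["P"] == 0.0)

    def test_irreversible_cycle_runs_to_completion(self):
        spec = ld.make_mechanism(
            "CYCLE_IRREV", ld.RateConstantSet(k_plus1=5.0, k_plus2=4.2, k_plus3=30.0)
        )
        traj = ld.simulate_mechanism(spec, {"E": 1.0, "S": 10.0}, np.linspace(0, 5000, 60))
        total_product = traj["P"][-1] + traj["E.P"][-1]
        assert total_product == pytest.approx(10.0, rel=1e-5)

    def test_bad_grids_rejected(self):
        spec = ld.make_mechanism("ONE_STEP", ld.RateConstantSet(k_plus1=1.0, k_minus1=2.0))
        with pytest.raises(ValueError, match="strictly increasing"):
            ld.simulate_mechanism(spec, {"E": 1.0}, np.array([0.0, 1.0, 1.0]))
        with pytest.raises(ValueError, match=">= 0"):
            ld.simulate_mechanism(spec, {"E": -1.0}, np.linspace(0, 1, 10))

    @pytest.mark.parametrize("kind", ALL_KINDS)
    def test_conservation_along_trajectories(self, kind):
        """Total enzyme and total substrate moiety constant to 1e-6 relative,
        over seeded random rate/initial draws."""
        rng = np.random.default_rng(1234)
        enzyme_sp = ("E", "E*", "E.S", "E*.S", "E.P")
        moiety_sp = ("S", "E.S", "E*.S", "E.P", "P")
        for _ in range(20):
            vals = {n: float(rng.uniform(0.1, 50.0)) for n in (
                "k_plus1", "k_minus1", "k_plus2", "k_minus2", "k_plus3", "k_minus3")}
            spec = ld.make_mechanism(kind, ld.RateConstantSet(**vals))
            E0, S0 = rng.uniform(0.1, 5.0), rng.uniform(0.5, 50.0)
            traj = ld.simulate_mechanism(
                spec, {"E": E0, "S": S0}, np.linspace(0, 10.0, 25)
            )
            etot = sum(traj[s] for s in enzyme_sp if s in spec.species)
            stot = sum(traj[s] for s in moiety_sp if s in spec.species)
            assert np.max(np.abs(etot / E0 - 1)) < 1e-6
            assert np.max(np.abs(stot / S0 - 1)) < 1e-6

    def test_michaelis_menten_limit(self):
        """Initial velocity matches kcat*E0*S0/(Km+S0) within 2% for E0<<S0 in
        the rapid-equilibrium regime (k+2 << k-1, k+3)."""
        rates = ld.RateConstantSet(k_minus1=250.0, k_plus2=0.2, k_plus3=30.0)
        spec = ld.make_mechanism("CYCLE_RAPID_EQ", rates)
        ss = ld.steady_state_from_rates(rates, "CYCLE_RAPID_EQ")
        E0 = ss.Km / 1000
        for ratio in (0.2, 1.0, 5.0, 25.0):
            S0 = ratio * ss.Km
            v = initial_velocity(spec, E0, S0)
            v_mm = ss.kcat * E0 * S0 / (ss.Km + S0)
            assert v == pytest.approx(v_mm, rel=0.02)


class TestSteadyStateParams:
    def test_rapid_eq_identities(self):
        ss = ld.steady_state_from_rates(
            ld.RateConstantSet(k_minus1=250.0, k_plus2=4.2, k_plus3=30.0),
            "CYCLE_RAPID_EQ",
        )
        assert (ss.kcat, ss.Km, ss.Kp) == (4.2, 2.5, 0.3)

    def test_irreversible_specificity_constant(self):
        ss = ld.steady_state_from_rates(
            ld.RateConstantSet(k_plus1=7.0, k_plus2=4.2, k_plus3=30.0),
            "CYCLE_IRREV",
        )
        assert ss.kcat_over_Km == 7.0

    def test_zero_k_minus1_flagged_degenerate(self):
        ss = ld.steady_state_from_rates(
            ld.RateConstantSet(k_minus1=0.0, k_plus2=4.2, k_plus3=30.0),
            "CYCLE_RAPID_EQ",
        )
        assert ss.Km == 0.0 and ss.degenerate

    def test_binding_mechanisms_rejected(self):
        with pytest.raises(ValueError, match="catalytic cycle"):
            ld.steady_state_from_rates(full_rates(), "INDUCED_FIT")


class TestObservedRates:
    def test_induced_fit_values(self):
        r = ld.observed_rates_analytic(
            ld.RateConstantSet(k_plus1=10.0, k_minus1=100.0, k_plus2=20.0, k_minus2=1.0),
            "INDUCED_FIT", S=5.0,
        )
        assert r.k_fast == pytest.approx(150.0)
        r10 = ld.observed_rates_analytic(
            ld.RateConstantSet(k_plus1=10.0, k_minus1=100.0, k_plus2=20.0, k_minus2=1.0),
            "INDUCED_FIT", S=10.0,
        )
        # hand evaluation: 20*(0.1*10)/(0.1*10+1) + 1
        assert r10.k_slow == pytest.approx(11.0)

    def test_conformational_selection_as_printed(self):
        r = ld.observed_rates_analytic(
            ld.RateConstantSet(k_plus1=5.0, k_minus1=50.0, k_plus2=10.0, k_minus2=2.0),
            "CONF_SELECTION", S=1.0,
        )
        assert r.k_fast == pytest.approx(60.0)
        assert r.k_slow == pytest.approx(15.0 / 7.0)

    def test_one_step_rate_and_amplitude(self):
        r = ld.observed_rates_analytic(
            ld.RateConstantSet(k_plus1=1.0, k_minus1=2.0), "ONE_STEP",
            S=3.0, A_lim=10.0, K_d=2.0,
        )
        assert r.k_obs == pytest.approx(5.0)
        r2 = ld.observed_rates_analytic(
            ld.RateConstantSet(k_plus1=1.0, k_minus1=2.0), "ONE_STEP",
            S=2.0, A_lim=10.0, K_d=2.0,
        )
        assert r2.amplitude == pytest.approx(5.0)

    def test_zero_k_minus1_rejected_for_induced_fit(self):
        with pytest.raises(ValueError, match="k-1"):
            ld.observed_rates_analytic(
                ld.RateConstantSet(k_plus1=1.0, k_minus1=0.0, k_plus2=1.0, k_minus2=1.0),
                "INDUCED_FIT", S=1.0,
            )

    def test_rates_strictly_increasing_in_S(self):
        """Monotonicity of the fast-phase and one-step laws in substrate."""
        S = np.linspace(0, 100, 40)
        kf = [
            ld.observed_rates_analytic(
                ld.RateConstantSet(k_plus1=3.0, k_minus1=40.0, k_plus2=5.0, k_minus2=1.0),
                "INDUCED_FIT", s).k_fast
            for s in S
        ]
        ko = [
            ld.observed_rates_analytic(
                ld.RateConstantSet(k_plus1=3.0, k_minus1=40.0), "ONE_STEP", s).k_obs
            for s in S
        ]
        assert np.all(np.diff(kf) > 0)
        assert np.all(np.diff(ko) > 0)

    def test_eigenvalue_oracle_matches_if_law_under_separation(self):
        """Eq-style IF fast/slow laws agree with the exact relaxation
        eigenvalues within 5% when k-1 >> k+2 + k-2 (timescale separation)."""
        rng = np.random.default_rng(77)
        for _ in range(100):
            k2 = rng.uniform(0.1, 5.0)
            km2 = rng.uniform(0.1, 5.0)
            km1 = 100.0 * (k2 + km2) * rng.uniform(1.0, 10.0)
            k1 = rng.uniform(0.5, 20.0)
            S = rng.uniform(0.0, 100.0)
            rates = ld.RateConstantSet(k_plus1=k1, k_minus1=km1, k_plus2=k2, k_minus2=km2)
            law = ld.observed_rates_analytic(rates, "INDUCED_FIT", S)
            eig = ld.relaxation_rates_numeric(rates, "INDUCED_FIT", S)
            assert law.k_fast == pytest.approx(eig.k_fast, rel=0.05)
            assert law.k_slow == pytest.approx(eig.k_slow, rel=0.05)


class TestObserveTrace:
    def _if_traj(self):
        spec = ld.make_mechanism(
            "INDUCED_FIT",
            ld.RateConstantSet(k_plus1=2.0, k_minus1=20.0, k_plus2=5.0, k_minus2=1.0),
        )
        return ld.simulate_mechanism(spec, {"E": 1.0, "S": 10.0}, np.linspace(0, 2, 30))

    def test_fluorescence_weighted_sum(self):
        traj = self._if_traj()
        obs = ld.ObservationModel("FLUORESCENCE", f=1.0, a=0.5, b=0.2)
        _, sig = ld.observe_trace(traj, obs)
        expect = traj["E"] + 0.5 * traj["E.S"] + 0.2 * traj["E*.S"]
        np.testing.assert_allclose(sig, expect, rtol=1e-12)

    def test_cumulative_luminescence_scales_product(self):
        spec = ld.make_mechanism(
            "CYCLE_IRREV", ld.RateConstantSet(k_plus1=5.0, k_plus2=4.2, k_plus3=30.0)
        )
        traj = ld.simulate_mechanism(spec, {"E": 1.0, "S": 10.0}, np.linspace(0, 10, 20))
        _, sig = ld.observe_trace(traj, ld.ObservationModel("LUMINESCENCE_CUMULATIVE", f=50.0))
        np.testing.assert_allclose(sig, 50.0 * traj["P"], rtol=1e-12)

    def test_instantaneous_rate_consistent_with_cumulative(self):
        spec = ld.make_mechanism(
            "CYCLE_IRREV", ld.RateConstantSet(k_plus1=5.0, k_plus2=4.2, k_plus3=30.0)
        )
        t = np.linspace(0, 50, 400)
        traj = ld.simulate_mechanism(spec, {"E": 0.5, "S": 5.0}, t)
        _, rate = instantaneous_luminescence(traj)
        # trapezoid integral of the instantaneous rate recovers the cumulative
        # curve (tolerance dominated by the sharp t=0 binding transient)
        cum = np.concatenate([[0.0], np.cumsum((rate[1:] + rate[:-1]) / 2 * np.diff(t))])
        np.testing.assert_allclose(cum, traj["P"], atol=2e-2)

    def test_missing_species_rejected(self):
        traj = self._if_traj()
        with pytest.raises(KeyError, match="'P'"):
            ld.observe_trace(traj, ld.ObservationModel("LUMINESCENCE_CUMULATIVE", f=1.0))
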