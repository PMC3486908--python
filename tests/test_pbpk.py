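"""Unit and property tests for the whole-body PBPK engine."""

import math

import numpy as np
import pytest

from hepaflux.pbpk import (
    Compartment,
    ConfigurationError,
    DoseEvent,
    Flow,
    KineticProcess,
    PBPKModel,
    Species,
    State,
    calibrate,
    linear_steady_state,
    link_metabolite,
    local_sensitivity,
    simulate,
    steady_state,
)


def _init_state(model, amount, compartment="box", species=0):
    st = model.zero_state()
    ci = model.compartment_names.index(compartment)
    st.amounts[species, ci] = amount
    return st


class TestSimulate:
    def test_first_order_decay_matches_closed_form(self, one_compartment):
        """100 µmol decaying at k=0.01/min reaches 100·e^{-1} after 100 min."""
        model = one_compartment(k=0.01)
        traj = simulate(model, 100.0, dt=1.0, init=_init_state(model, 100.0))
        assert traj.amount("x", "box")[-1] == pytest.approx(100.0 * math.exp(-1.0), rel=1e-6)
        assert len(traj) == 101

    def test_empty_system_stays_zero(self, one_compartment):
        model = one_compartment(k=0.05)
        traj = simulate(model, 60.0, dt=1.0)
        assert np.all(traj.amounts == 0.0)

    def test_mass_conservation_without_elimination(self, closed_two_compartment):
        """With eliminations disabled total amount is constant to 1e-6/day."""
        model = closed_two_compartment()
        traj = simulate(model, 1440.0, dt=1.0, init=_init_state(model, 70.0, "a"))
        total = traj.amount("x")
        assert np.max(np.abs(total - total[0])) / total[0] < 1e-6

    def test_flow_equilibration_equal_partition(self, closed_two_compartment):
        model = closed_two_compartment(k_a=1.0, k_b=1.0)
        traj = simulate(model, 2000.0, dt=1.0, init=_init_state(model, 70.0, "a"))
        assert traj.conc("x", "a")[-1] == pytest.approx(traj.conc("x", "b")[-1], rel=1e-6)

    def test_partition_ratio_at_equilibrium(self, closed_two_compartment):
        """Tissue/blood concentration ratio equals the partition coefficient."""
        model = closed_two_compartment(k_a=1.0, k_b=3.0)
        traj = simulate(model, 4000.0, dt=1.0, init=_init_state(model, 70.0, "a"))
        assert traj.conc("x", "b")[-1] / traj.conc("x", "a")[-1] == pytest.approx(3.0, rel=1e-5)

    def test_step_halving_changes_little(self, calibrated_ammonia_model):
        t1 = simulate(calibrated_ammonia_model, 720.0, dt=1.0)
        t2 = simulate(calibrated_ammonia_model, 720.0, dt=0.5)
        c1 = t1.conc("ammonia", "venous")[-1]
        c2 = t2.conc("ammonia", "venous")[-1]
        assert abs(c1 - c2) / c2 < 0.005

    def test_dose_injection_oral_and_iv(self):
        model = PBPKModel(
            compartments=[Compartment("venous", 3.0), Compartment("gut_lumen", 1.0, "lumen")],
            flows=[],
            species=[Species("d")],
            processes=[KineticProcess("abs", "oral_absorption", "gut_lumen", "d",
                                      {"ka": 0.1, "to": "venous"})],
            doses=[DoseEvent("d", 50.0, "oral", (0.0, 60.0))],
            oral_dose_compartment="gut_lumen",
        )
        traj = simulate(model, 120.0, dt=1.0)
        assert traj.amount("d")[-1] == pytest.approx(100.0, rel=1e-9)  # mass conserved
        assert traj.amount("d", "venous")[-1] > 90.0  # mostly absorbed

    def test_unknown_reference_raises(self):
        with pytest.raises(ConfigurationError):
            PBPKModel(
                compartments=[Compartment("a", 1.0)],
                flows=[],
                species=[Species("x")],
                processes=[KineticProcess("p", "first_order", "nowhere", "x", {"k": 0.1})],
            )

    def test_disconnected_flow_graph_raises(self):
        with pytest.raises(ConfigurationError, match="not connected"):
            PBPKModel(
                compartments=[Compartment("a", 1.0), Compartment("b", 1.0), Compartment("c", 1.0)],
                flows=[Flow("a", "b", 1.0)],
                species=[Species("x")],
                processes=[],
            )

    @pytest.mark.parametrize("bad", [
        dict(amount=-1.0), dict(times=(10.0, 5.0)), dict(route="nasal"),
    ])
    def test_invalid_dose_raises(self, bad):
        kwargs = dict(species="x", amount=1.0, route="oral", times=(0.0,))
        kwargs.update(bad)
        with pytest.raises(ConfigurationError):
            DoseEvent(**kwargs)


class TestSteadyState:
    def test_zero_production_gives_zero(self, one_compartment):
        res = steady_state(one_compartment(k=0.05), max_time=2880.0)
        assert res.converged
        assert np.all(res.state.amounts == 0.0)

    def test_production_over_k_closed_form(self, one_compartment):
        """C_ss = p/k for zero-order production p against first-order loss k."""
        model = one_compartment(k=0.02, production=0.5)
        res = steady_state(model, tol=1e-6, max_time=40000.0)
        assert res.converged
        c = res.state.amounts[0, 0] / 10.0
        assert c == pytest.approx(0.5 / 0.02, rel=1e-4)

    def test_non_convergence_is_flagged_not_raised(self, one_compartment):
        model = one_compartment(k=1e-6, production=1.0)
        res = steady_state(model, tol=1e-9, max_time=120.0)
        assert not res.converged

    def test_linear_steady_state_matches_integration(self, calibrated_ammonia_model):
        exact = linear_steady_state(calibrated_ammonia_model)
        num = steady_state(calibrated_ammonia_model, tol=1e-7, max_time=40000.0)
        assert num.converged
        np.testing.assert_allclose(num.state.amounts, exact.amounts, rtol=1e-3)

    def test_production_equals_elimination_at_steady_state(self, calibrated_ammonia_model):
        st = linear_steady_state(calibrated_ammonia_model)
        comp = calibrated_ammonia_model.compile()
        prod = comp.process_rate("production", st.amounts)
        elim = comp.process_rate("liver_clearance", st.amounts) + comp.process_rate(
            "kidney_clearance", st.amounts)
        assert prod == pytest.approx(elim, rel=1e-9)


class TestLinkMetabolite:
    def _parent(self, k=0.05):
        return PBPKModel(
            compartments=[Compartment("box", 10.0)],
            flows=[],
            species=[Species("parent")],
            processes=[KineticProcess("clear", "first_order", "box", "parent", {"k": k})],
            iv_compartment="box",
        )

    def _metabolite(self):
        return PBPKModel(
            compartments=[Compartment("box", 10.0)],
            flows=[],
            species=[Species("met")],
            processes=[],
            iv_compartment="box",
        )

    def test_mass_conservation_yield_one(self):
        merged = link_metabolite(self._parent(), self._metabolite(), "clear", 1.0)
        traj = simulate(merged, 500.0, dt=1.0, init=_init_state(merged, 100.0))
        cleared = 100.0 - traj.amount("parent", "box")[-1]
        formed = traj.amount("met", "box")[-1]
        assert formed == pytest.approx(cleared, rel=1e-9)

    def test_yield_zero_gives_no_metabolite(self):
        merged = link_metabolite(self._parent(), self._metabolite(), "clear", 0.0)
        traj = simulate(merged, 200.0, dt=1.0, init=_init_state(merged, 100.0))
        assert np.all(traj.amount("met", "box") == 0.0)

    def test_compartment_mismatch_raises(self):
        other = PBPKModel(
            compartments=[Compartment("box", 99.0)],
            flows=[], species=[Species("met")], processes=[], iv_compartment="box",
        )
        with pytest.raises(ConfigurationError):
            link_metabolite(self._parent(), other, "clear")

    def test_non_clearance_process_rejected(self):
        parent = PBPKModel(
            compartments=[Compartment("box", 10.0)],
            flows=[], species=[Species("parent")],
            processes=[KineticProcess("prod", "zero_order_production", "box", "parent",
                                      {"rate": 1.0})],
            iv_compartment="box",
        )
        with pytest.raises(ConfigurationError):
            link_metabolite(parent, self._metabolite(), "prod")


class TestCalibrate:
    def test_single_parameter_self_consistency(self, one_compartment):
        """A target generated by the model itself is recovered exactly."""
        model = one_compartment(k=0.02, production=0.5)
        truth = 0.02

        def obs(m):
            return m.get_param("process:elim:k") * 25.0  # trivially computable observable

        model.set_param("process:elim:k", 0.05)  # start away from the truth
        fit = calibrate(model, ["process:elim:k"], [(obs, truth * 25.0)])
        assert fit.parameters["process:elim:k"] == pytest.approx(truth, rel=1e-6)
        assert fit.identifiable

    def test_two_parameter_recovery_from_noisy_decay(self, one_compartment):
        """Refitting (k, production) to 1 %-noisy steady-state observables
        recovers both within 5 %."""
        rng = np.random.default_rng(7)
        true_k, true_p = 0.015, 0.4
        model = one_compartment(k=true_k, production=true_p)

        def c_ss(m):
            return linear_steady_state(m).amounts[0, 0] / 10.0

        def decay_60(m):
            traj = simulate(m, 60.0, dt=1.0, init=_init_state(m, 2000.0))
            return traj.amount("x", "box")[-1]

        targets = [
            (c_ss, c_ss(model) * (1 + 0.01 * rng.standard_normal())),
            (decay_60, decay_60(model) * (1 + 0.01 * rng.standard_normal())),
        ]
        model.set_param("process:elim:k", 0.03)
        model.set_param("process:prod:rate", 0.2)
        fit = calibrate(model, ["process:elim:k", "process:prod:rate"], targets)
        assert fit.parameters["process:elim:k"] == pytest.approx(true_k, rel=0.05)
        assert fit.parameters["process:prod:rate"] == pytest.approx(true_p, rel=0.05)

    def test_flat_objective_warns(self, one_compartment):
        model = one_compartment(k=0.02, production=0.5)
        with pytest.warns(UserWarning, match="flat"):
            calibrate(model, ["process:prod:rate"], [(lambda m: 1.0, 1.0)])


class TestLocalSensitivity:
    def test_independent_observable_is_zero(self, one_compartment):
        model = one_compartment(k=0.02, production=0.5)
        assert local_sensitivity(model, "process:elim:k", lambda m: 42.0) == 0.0

    def test_production_sensitivity_is_one(self, one_compartment):
        """C_ss = p/k is linear in p, so the normalized sensitivity is 1."""
        model = one_compartment(k=0.02, production=0.5)
        obs = lambda m: linear_steady_state(m).amounts[0, 0]
        assert local_sensitivity(model, "process:prod:rate", obs) == pytest.approx(1.0, abs=1e-6)

    def test_elimination_sensitivity_is_minus_one(self, one_compartment):
        model = one_compartment(k=0.02, production=0.5)
        obs = lambda m: linear_steady_state(m).amounts[0, 0]
        s = local_sensitivity(model, "process:elim:k", obs, delta=0.01)
        assert s == pytest.approx(-1.0, abs=1e-3)

    def test_zero_observable_flagged(self, one_compartment):
        model = one_compartment(k=0.02)
        with pytest.raises(ZeroDivisionError):
            local_sensitivity(model, "process:elim:k", lambda m: 0.0)


class TestAmmoniaFixture:
    """The calibrated whole-body ammonia model against its printed targets."""

    def test_calibrated_rates(self, calibrated_ammonia_model):
        from hepaflux.toyliver import ammonia_rates

        rates = ammonia_rates(calibrated_ammonia_model)
        assert rates["venous_uM"] == pytest.approx(29.0, abs=1e-6)
        assert rates["production"] == pytest.approx(0.694, abs=1e-9)
        assert rates["liver"] == pytest.approx(0.163, abs=0.001)
        assert rates["kidney"] == pytest.approx(0.530, abs=0.001)

    def test_long_simulation_approaches_venous_target(self, calibrated_ammonia_model):
        traj = simulate(calibrated_ammonia_model, 2880.0, dt=1.0)
        assert traj.conc("ammonia", "venous")[-1] == pytest.approx(29.0, rel=0.01)

    def test_trajectory_frame_schema(self, calibrated_ammonia_model):
        traj = simulate(calibrated_ammonia_model, 10.0, dt=1.0)
        df = traj.to_frame()
        assert list(df.columns) == ["time_min", "compartment", "species", "concentration_uM"]
        assert len(df) == 11 * 5  # steps+1 times x compartments
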