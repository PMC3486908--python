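"""Tests for inhibition kinetics and the dFBA coupling loop."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hepaflux.coupling import (
    DirectLink,
    Event,
    InhibitionParams,
    MultiscaleModel,
    calibrate_ki_to_max_inhibition,
    combined_relative_activity,
    constrain_flux,
    dfba_step,
    ki_from_ic50,
    relative_activity,
    simulate_coupled,
)
from hepaflux.network import MetabolicNetwork, Objective, Reaction, fba
from hepaflux.pbpk import (
    Compartment,
    KineticProcess,
    PBPKModel,
    Species,
    State,
    linear_steady_state,
    simulate,
)
from hepaflux.toyliver import AMMONIA_OBJECTIVE, V_REF, make_ammonia_network


class TestRelativeActivity:
    def test_uninhibited_is_one(self):
        assert relative_activity(0.0, InhibitionParams(ic50=15.6)) == 1.0

    def test_at_ic50_is_half(self):
        assert relative_activity(15.6, InhibitionParams(ic50=15.6)) == pytest.approx(0.5)

    def test_oxypurinol_working_point(self):
        """45 µM against IC50 15.6 µM leaves 1/(1+45/15.6) = 25.7 % activity."""
        assert relative_activity(45.0, InhibitionParams(ic50=15.6)) == pytest.approx(
            0.2574, abs=5e-5)

    def test_ki_only_uses_cheng_prusoff_equivalence(self):
        # Ki = IC50/2 under the substrate-at-Km convention
        assert relative_activity(10.0, InhibitionParams(ki=5.0)) == pytest.approx(0.5)

    def test_negative_concentration_raises(self):
        with pytest.raises(ValueError):
            relative_activity(-1.0, InhibitionParams(ic50=10.0))

    @given(i1=st.floats(0, 1e4), i2=st.floats(0, 1e4))
    def test_monotone_nonincreasing_and_bounded(self, i1, i2):
        p = InhibitionParams(ic50=13.4)
        lo, hi = sorted([i1, i2])
        assert 0.0 <= relative_activity(hi, p) <= relative_activity(lo, p) <= 1.0

    def test_combined_same_site_competitive(self):
        p1, p2 = InhibitionParams(ic50=13.4), InhibitionParams(ic50=15.6)
        relE = combined_relative_activity([(5.0, p1), (45.0, p2)])
        assert relE == pytest.approx(1.0 / (1.0 + 5.0 / 13.4 + 45.0 / 15.6))

    def test_combined_empty_is_one(self):
        assert combined_relative_activity([]) == 1.0

    def test_noncompetitive_variant_is_stronger(self):
        p = InhibitionParams(ic50=10.0)
        assert relative_activity(10.0, p, "noncompetitive") < relative_activity(10.0, p)


class TestChengPrusoff:
    @pytest.mark.parametrize("ic50,expected", [(13.4, 6.7), (15.6, 7.8)])
    def test_substrate_at_km_halves_ic50(self, ic50, expected):
        assert ki_from_ic50(ic50, S=1.0, Km=1.0) == pytest.approx(expected)

    def test_no_substrate_limit(self):
        assert ki_from_ic50(13.4, S=0.0, Km=5.0) == 13.4

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            ki_from_ic50(-1.0, 1.0, 1.0)


class TestKiCalibration:
    def test_half_inhibition_gives_ic50_equal_cmax(self):
        ki = calibrate_ki_to_max_inhibition(100.0, 0.5)
        assert 2 * ki == pytest.approx(100.0)
        assert relative_activity(100.0, InhibitionParams(ki=ki)) == pytest.approx(0.5)

    def test_gsh_depletion_level(self):
        """80 % maximal depletion leaves relE(c_max) = 0.2."""
        ki = calibrate_ki_to_max_inhibition(250.0, 0.8)
        assert relative_activity(250.0, InhibitionParams(ki=ki)) == pytest.approx(0.2)

    def test_low_dose_limit_near_unity(self):
        ki = calibrate_ki_to_max_inhibition(100.0, 0.5)
        assert relative_activity(0.1, InhibitionParams(ki=ki)) >= 0.99

    @pytest.mark.parametrize("mi", [0.0, 1.0, -0.2, 1.5])
    def test_degenerate_inhibition_raises(self, mi):
        with pytest.raises(ValueError):
            calibrate_ki_to_max_inhibition(100.0, mi)


class TestConstrainFlux:
    def test_full_activity_keeps_reference_optimum(self):
        net = make_ammonia_network()
        rid, bounds = constrain_flux(net, "UC", 1.0, 0.0725)
        sol = fba(net, AMMONIA_OBJECTIVE, {rid: bounds})
        assert sol.objective_value == pytest.approx(0.163, abs=1e-9)

    def test_blocked_enzyme_drops_dependent_objective(self):
        net = make_ammonia_network()
        rid, bounds = constrain_flux(net, "UC", 0.0, 0.0725)
        sol = fba(net, AMMONIA_OBJECTIVE, {rid: bounds})
        # only the obligatory gln/ala demands remain: 2·0.008 + 0.002
        assert sol.objective_value == pytest.approx(0.018, abs=1e-9)

    def test_half_activity_halves_urea_export(self):
        """Hand LP: capping the urea cycle at 0.5·0.0725 gives urea 0.03625."""
        net = make_ammonia_network()
        rid, bounds = constrain_flux(net, "UC", 0.5, 0.0725)
        sol = fba(net, AMMONIA_OBJECTIVE, {rid: bounds})
        assert sol["EX_urea"] == pytest.approx(0.03625, abs=1e-9)

    def test_unknown_reaction_raises(self):
        from hepaflux.network import NetworkLoadError

        with pytest.raises(NetworkLoadError):
            constrain_flux(make_ammonia_network(), "nope", 1.0, 1.0)

    @given(r1=st.floats(0, 1), r2=st.floats(0, 1))
    def test_tightening_monotonicity(self, r1, r2):
        """A smaller relE never increases the maximized objective."""
        lo, hi = sorted([r1, r2])
        net = make_ammonia_network()
        get = lambda relE: fba(net, AMMONIA_OBJECTIVE,
                               {"UC": constrain_flux(net, "UC", relE, 0.0725)[1]}).objective_value
        assert get(lo) <= get(hi) + 1e-12


def _ammonia_ms(uptake_ub=None, schedules=None) -> MultiscaleModel:
    from hepaflux.scenarios import _build_ammonia_multiscale

    return _build_ammonia_multiscale(uptake_ub=uptake_ub, otc_schedule=None) if schedules is None \
        else _build_ammonia_multiscale(uptake_ub=uptake_ub, otc_schedule=schedules)


class TestDfbaStep:
    def test_unperturbed_step_equals_pure_pbpk_step(self):
        """With non-binding network caps a coupled step equals a PBPK step."""
        ms = _ammonia_ms(uptake_ub=10.0)  # far above any offered rate
        init = linear_steady_state(ms.pbpk)
        coupled_state, sol = dfba_step(ms, init)
        pure = simulate(ms.pbpk, ms.dt, ms.dt, init=init)
        np.testing.assert_allclose(coupled_state.amounts, pure.amounts[-1], rtol=2e-5)
        # the exchange flux sits exactly on the PBPK-offered bound
        offered = ms.pbpk.compile().process_rate("liver_clearance", init.amounts) / V_REF
        assert sol["EX_nh3"] == pytest.approx(offered, abs=1e-9)

    def test_blocked_urea_cycle_caps_uptake_at_0072(self):
        ms = _ammonia_ms(schedules=lambda t: 0.0)
        for rid in ("EX_gln", "EX_ala"):
            r = ms.network.reaction(rid)
            ms.network.set_bounds(rid, 4 * r.lower_bound, 4 * r.upper_bound)
        init = linear_steady_state(ms.pbpk)
        _, sol = dfba_step(ms, init)
        assert sol["EX_nh3"] == pytest.approx(0.072, abs=1e-9)
        # even though the PBPK model offers ~0.163
        offered = ms.pbpk.compile().process_rate("liver_clearance", init.amounts) / V_REF
        assert offered > 0.15

    def test_zero_state_changes_only_by_production(self):
        ms = _ammonia_ms()
        state = State(0.0, ms.pbpk.zero_state().amounts)
        new, sol = dfba_step(ms, state)
        assert sol.status == "infeasible" or sol.objective_value <= 1e-12
        # linked hepatic removal fell back to zero, so the only change is
        # production (minus a sliver of first-pass renal elimination)
        prod = ms.pbpk.compile().process_rate("production", state.amounts) * ms.dt
        total = new.amounts.sum()
        assert 0.9 * prod <= total <= prod + 1e-9


class TestSimulateCoupled:
    def test_unperturbed_equivalence_within_0p1_percent(self):
        """Coupled and uncoupled trajectories agree to 0.1 % when nothing
        is impaired and the exchange caps never bind."""
        ms = _ammonia_ms(uptake_ub=10.0)  # far above any offered rate
        init = linear_steady_state(ms.pbpk)
        res = simulate_coupled(ms, 1440.0, init=init)
        pure = simulate(ms.pbpk, 1440.0, ms.dt, init=init)
        c_coupled = res.trajectory.conc("ammonia", "venous")
        c_pure = pure.conc("ammonia", "venous")
        assert np.max(np.abs(c_coupled - c_pure) / c_pure) < 1e-3

    def test_mass_handoff_is_exact_per_step(self):
        """Amount removed by the linked process equals flux·volume·dt."""
        net = MetabolicNetwork([
            Reaction("EX_x", {"x[c]": 1.0}, 0.0, 0.05, is_exchange=True),
            Reaction("SINK", {"x[c]": -1.0}, 0.0, np.inf),
        ])
        model = PBPKModel(
            compartments=[Compartment("liver", 2.0)],
            flows=[],
            species=[Species("x")],
            processes=[KineticProcess("clear", "first_order", "liver", "x", {"k": 0.01})],
            iv_compartment="liver",
        )
        ms = MultiscaleModel(model, net, Objective({"EX_x": 1.0}),
                             direct_links=[DirectLink("clear", "EX_x", "uptake", volume_basis=10.0)])
        state = State(0.0, np.array([[100.0]]))
        for _ in range(20):
            new, sol = dfba_step(ms, state)
            removed = state.amounts[0, 0] - new.amounts[0, 0]
            assert removed == pytest.approx(sol["EX_x"] * 10.0 * ms.dt, abs=1e-9)
            state = new

    def test_halved_dt_changes_endpoint_little(self):
        def run(dt):
            ms = _ammonia_ms(schedules=lambda t: max(0.0, 1.0 - t / 720.0))
            ms.dt = dt
            init = linear_steady_state(ms.pbpk)
            res = simulate_coupled(ms, 1440.0, init=init)
            return res.trajectory.conc("ammonia", "venous")[-1]

        assert abs(run(1.0) - run(0.5)) / run(0.5) < 0.005

    def test_events_modify_network_at_their_time(self):
        ms = _ammonia_ms(schedules=lambda t: 0.0)
        init = linear_steady_state(ms.pbpk)

        def raise_caps(network):
            for rid in ("EX_gln", "EX_ala"):
                r = network.reaction(rid)
                network.set_bounds(rid, 4 * r.lower_bound, 4 * r.upper_bound)

        res = simulate_coupled(ms, 120.0, events=[Event(60.0, raise_caps, "caps")], init=init)
        uptake = res.flux_series("EX_nh3")
        assert uptake[30] == pytest.approx(0.018, abs=1e-9)   # demands only, OTC blocked
        assert uptake[90] == pytest.approx(0.072, abs=1e-9)   # after fourfold upregulation
        assert res.events_applied == ["caps"]

    def test_infeasible_fba_falls_back_to_zero_rates(self):
        # demands exceed what the offered uptake can supply at low ammonia
        ms = _ammonia_ms()
        state = State(0.0, ms.pbpk.zero_state().amounts)
        res = simulate_coupled(ms, 30.0, init=state)
        assert res.fallback_steps > 0

    def test_slack_reuse_matches_exact_mode(self):
        """The memoized solver path returns the same fluxes as re-solving."""
        def run(reuse):
            ms = _ammonia_ms(schedules=lambda t: max(0.0, 1.0 - t / 360.0))
            ms.reuse_slack_solutions = reuse
            init = linear_steady_state(ms.pbpk)
            return simulate_coupled(ms, 480.0, init=init)

        a, b = run(True), run(False)
        np.testing.assert_allclose(a.fluxes, b.fluxes, atol=1e-9)
        np.testing.assert_allclose(a.trajectory.amounts, b.trajectory.amounts, rtol=1e-9)

    def test_relE_series_recorded(self):
        ms = _ammonia_ms(schedules=lambda t: max(0.0, 1.0 - t / 100.0))
        init = linear_steady_state(ms.pbpk)
        res = simulate_coupled(ms, 120.0, init=init)
        relE = res.relE_series["UC"]  # the OTC-tagged urea-cycle reaction
        assert relE[0] == pytest.approx(1.0)
        assert relE[-1] == 0.0
        assert np.all(np.diff(relE) <= 1e-12)


class TestMultiscaleValidation:
    def test_direct_link_must_target_exchange(self):
        from hepaflux.network import NetworkLoadError

        ms_kwargs = dict(
            pbpk=_ammonia_ms().pbpk,
            network=make_ammonia_network(),
            objective=AMMONIA_OBJECTIVE,
        )
        with pytest.raises(NetworkLoadError):
            MultiscaleModel(direct_links=[DirectLink("liver_clearance", "UC")], **ms_kwargs)

    def test_unknown_link_ids_raise(self):
        from hepaflux.pbpk import ConfigurationError

        with pytest.raises(ConfigurationError):
            MultiscaleModel(
                pbpk=_ammonia_ms().pbpk,
                network=make_ammonia_network(),
                objective=AMMONIA_OBJECTIVE,
                direct_links=[DirectLink("nope", "EX_nh3")],
            )
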