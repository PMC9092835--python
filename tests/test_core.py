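"""Core engine: RHS assembly, integration, events, steady state, mass audit."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from s100b_pbpk.core import (Compartment, ConfigurationError, FluxTerm,
                             NoSteadyStateError, ScenarioEvent, assemble_rhs,
                             find_steady_state, integrate,
                             integrate_fixed_step, mass_audit)

from conftest import make_spec, random_closed_spec


class TestAssembleRhs:
    def test_zero_state_is_fixed_point(self, two_compartment_loop):
        spec, V, Q = two_compartment_loop
        rhs = assemble_rhs(spec)
        assert np.allclose(rhs(0.0, np.zeros(2)), 0.0)

    def test_two_compartment_loop_mass_transfer(self, two_compartment_loop):
        spec, V, Q = two_compartment_loop
        rhs = assemble_rhs(spec)
        dc = rhs(0.0, np.array([1.0, 0.0]))
        assert dc[0] == pytest.approx(-Q * 1.0 / V)
        assert dc[1] == pytest.approx(+Q * 1.0 / V)

    def test_clamped_compartment_has_zero_derivative(self):
        comps = [Compartment("src", 1.0, 5.0, "cellular", clamped=True),
                 Compartment("dst", 2.0, 0.0, "vascular")]
        spec = make_spec(comps, [FluxTerm("src", "dst", 3.0, "blood", "in")])
        rhs = assemble_rhs(spec)
        dc = rhs(0.0, np.array([5.0, 0.0]))
        assert dc[0] == 0.0
        assert dc[1] == pytest.approx(3.0 * 5.0 / 2.0)

    def test_unknown_edge_compartment_is_configuration_error(self):
        comps = [Compartment("A", 1.0, 0.0, "vascular")]
        spec = make_spec(comps, [FluxTerm("A", "nowhere", 1.0, "blood", "x")])
        with pytest.raises(ConfigurationError, match="nowhere"):
            assemble_rhs(spec)

    def test_model1_venous_derivative_matches_hand_summed_fluxes(self, model1):
        """Independent flux summation over the printed flow table."""
        rhs = assemble_rhs(model1)
        state = model1.initial_state()
        dc = rhs(0.0, state)
        idx = model1.index()
        c = dict(zip(model1.names, state))
        venous_flows = {  # organ vascular fraction -> venous, ml/h
            "Heart tissue vascular fraction": 9000.0,
            "Bone tissue vascular fraction": 15000.0,
            "Kidney tissue vascular fraction": 66000.0,
            "Adipose tissue vascular fraction": 15600.0,
            "Skin tissue vascular fraction": 18000.0,
            "Muscle tissue vascular fraction": 45000.0,
            "Gut tissue vascular fraction": 66000.0,
            "Brain tissue vascular fraction": 42000.0,
        }
        hand = sum(q * c[n] for n, q in venous_flows.items())
        hand += 3100.0 * c["Lymph"] + 3139.0 * c["Arterial blood"]
        hand -= 313980.0 * c["Venous blood"]
        assert dc[idx["Venous blood"]] == pytest.approx(hand / 2500.0,
                                                        rel=1e-12)


class TestIntegrate:
    def test_no_transport_means_no_change(self):
        comps = [Compartment("A", 1.0, 2.0, "vascular"),
                 Compartment("B", 3.0, 0.5, "vascular")]
        spec = make_spec(comps, [FluxTerm("A", "B", 0.0, "blood", "off")])
        res = integrate(spec, 10.0, dt_out=1.0)
        assert np.allclose(res.concentrations, [[2.0, 0.5]] * len(res.times))

    def test_single_decay_matches_closed_form(self, decay_compartment):
        spec, V, Q, c0 = decay_compartment
        res = integrate(spec, 8.0, dt_out=0.25)
        expected = c0 * np.exp(-Q * res.times / V)
        assert np.allclose(res.conc("A"), expected, atol=1e-8)

    def test_output_grid_includes_event_times(self, model2):
        ev = [ScenarioEvent(3.33, "controls.bbb_index", 1.0)]
        res = integrate(model2, 10.0, events=ev, dt_out=1.0)
        assert 3.33 in res.times
        assert np.all(np.diff(res.times) > 0)

    def test_event_splitting_consistency(self, model2):
        """[0,T] with an event equals [0,t*], apply change, then [t*,T]."""
        from s100b_pbpk import build_model2
        t_star, t_end = 5.0, 12.0
        full = integrate(model2, t_end, dt_out=0.25, events=[
            ScenarioEvent(t_star, "controls.bbb_index", 1.0)])
        part1 = integrate(model2, t_star, dt_out=0.25)
        spec2 = build_model2()
        spec2.params.controls.bbb_index = 1.0
        part2 = integrate(spec2, t_end - t_star, dt_out=0.25,
                          state0=part1.final_state)
        k = np.nonzero(full.times == t_star)[0][0]
        assert np.allclose(full.concentrations[k:], part2.concentrations,
                           atol=1e-7)

    def test_events_do_not_mutate_caller_spec(self, model2):
        before = model2.params.controls.bbb_index
        integrate(model2, 2.0, events=[
            ScenarioEvent(1.0, "controls.bbb_index", 1.0)], dt_out=0.5)
        assert model2.params.controls.bbb_index == before

    def test_adaptive_agrees_with_fixed_step_reference(self, model1, model2):
        """Both full models over 25 h, within 0.1 % relative."""
        for spec, dt in ((model1, 2e-4), (model2, 1e-3)):
            adap = integrate(spec, 25.0, dt_out=5.0)
            ref = integrate_fixed_step(spec, 25.0, dt=dt, dt_out=5.0)
            a, f = adap.concentrations[-1], ref.concentrations[-1]
            denom = np.maximum(np.abs(f), 1e-6 * np.abs(f).max())
            assert np.max(np.abs(a - f) / denom) < 1e-3

    def test_nonnegative_concentrations(self, model1, model2):
        for spec in (model1, model2):
            res = integrate(spec, 50.0, dt_out=0.5)
            assert res.concentrations.min() >= -1e-9


class TestSteadyState:
    def test_all_zero_spec_is_steady_at_t0(self):
        comps = [Compartment("A", 1.0, 0.0, "vascular"),
                 Compartment("B", 1.0, 0.0, "vascular")]
        spec = make_spec(comps, [FluxTerm("A", "B", 5.0, "blood", "x")])
        state, t = find_steady_state(spec)
        assert t == 0.0
        assert np.allclose(state, 0.0)

    def test_single_decay_reaches_steady_zero(self, decay_compartment):
        spec, V, Q, c0 = decay_compartment
        state, t = find_steady_state(spec, t_max=200.0)
        assert abs(state[0]) < 1e-12
        assert t > 0

    def test_constant_source_never_steady(self):
        comps = [Compartment("res", 1.0, 10.0, "cellular", clamped=True),
                 Compartment("pool", 1.0, 0.0, "vascular")]
        spec = make_spec(comps, [FluxTerm("res", "pool", 1.0, "trauma", "in")])
        with pytest.raises(NoSteadyStateError):
            find_steady_state(spec, t_max=50.0)

    def test_tolerance_must_be_positive(self, decay_compartment):
        with pytest.raises(ValueError):
            find_steady_state(decay_compartment[0], tol=0.0)


class TestMassAudit:
    def test_closed_system_conserves_mass(self, two_compartment_loop):
        spec, _, _ = two_compartment_loop
        res = integrate(spec, 100.0, dt_out=1.0)
        audit = mass_audit(res, tol=1e-6)
        assert audit.ok
        assert audit.max_residual < 1e-6

    def test_model2_source_sink_balance(self, model2):
        """Clamped glia in, renal/salivary out: residual at solver tolerance."""
        from s100b_pbpk import build_model2
        spec = build_model2()
        spec.params.controls.trauma_index = 1.0
        res = integrate(spec, 50.0, dt_out=0.5)
        audit = mass_audit(res, tol=1e-9)
        assert audit.ok
        assert res.cum_in[-1] > 0          # glial release occurred
        assert res.cumulative_excreted()[-1] > 0

    def test_totally_empty_model2_stays_empty(self):
        """No organ/blood S100B, no BBB leak, no glymphatics: mass stays 0."""
        from s100b_pbpk import build_model2
        spec = build_model2()
        spec.params.controls.glymphatics = 0.0
        for comp in spec.compartments.values():
            if not comp.clamped:
                comp.concentration = 0.0
        res = integrate(spec, 50.0, dt_out=1.0)
        assert np.all(res.total_mass() == 0.0)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(2, 6))
    def test_conservation_property_random_closed_specs(self, seed, n):
        rng = np.random.default_rng(seed)
        spec = random_closed_spec(rng, n)
        res = integrate(spec, 20.0, dt_out=1.0)
        total = res.total_mass()
        assert np.max(np.abs(total - total[0])) <= 1e-6 * max(total[0], 1.0)
        assert res.concentrations.min() >= -1e-9


class TestLinearity:
    def test_scaling_initial_concentrations_scales_trajectories(self, model1):
        lam = 2.5
        base = integrate(model1, 10.0, dt_out=1.0)
        scaled = integrate(model1, 10.0, dt_out=1.0,
                           state0=lam * model1.initial_state())
        assert np.allclose(scaled.concentrations, lam * base.concentrations,
                           rtol=1e-5, atol=1e-9)


class TestValidation:
    def test_negative_rate_rejected(self):
        with pytest.raises(ConfigurationError):
            FluxTerm("A", "B", -1.0, "blood", "bad")

    def test_self_edge_rejected(self):
        with pytest.raises(ConfigurationError):
            FluxTerm("A", "A", 1.0, "blood", "loop")

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(ConfigurationError):
            Compartment("A", 0.0, 0.0, "vascular")

    def test_model1_flow_imbalance_report_matches_table_sums(self, model1):
        """The printed table leaves ~34,241 ml/h of cardiac output unrouted;
        the report must state the imbalance rather than hide it."""
        qin, qout = model1.flow_imbalance()["Arterial blood"]
        assert qin == pytest.approx(313_980.0)
        organ_outflows = (66000 + 45000 + 9000 + 15000 + 15600 + 18000
                          + 66000 + 42000)
        assert qout == pytest.approx(organ_outflows + 3139.0)
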