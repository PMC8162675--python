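"""Gating evaluation, membrane dynamics, and the kinetic transformations."""

import copy
import warnings

import numpy as np
import pytest
from scipy import optimize

import thalaswitch as ts
from thalaswitch._formulas import Formula
from thalaswitch.channel_models import (
    GatingSpec,
    IonCurrentSpec,
    NeuronModel,
    evaluate_gate,
    ionic_currents,
    membrane_rhs,
    model_from_dict,
    model_to_dict,
)

V_GRID = np.linspace(-120.0, 60.0, 181)


def leak_only_model(g_leak=0.1, e_leak=-70.0, c_m=1.0):
    """All voltage-gated conductances zeroed: a passive RC membrane."""
    m = ts.load_builtin("5")
    m = copy.deepcopy(m)
    for cur in m.currents:
        cur.g_max = 0.0
    m.current("leak").g_max = g_leak
    m.current("leak").reversal = e_leak
    m.c_m = c_m
    return m


class TestEvaluateGate:
    def test_sigmoid_midpoint_is_half(self):
        g = GatingSpec("m_x", "activation", 2,
                       Formula("boltzmann", (-55.0, -7.0)),
                       Formula("constant", (3.0,)))
        ss, tau = evaluate_gate(g, -55.0)
        assert ss == pytest.approx(0.5)
        assert tau == pytest.approx(3.0)

    @pytest.mark.parametrize("model_id", ["1", "5", "6", "5p", "6p"])
    def test_steady_states_bounded_and_taus_positive(self, model_id, all_models):
        m = all_models[model_id]
        for cur in m.currents:
            for g in cur.gates:
                if g.ca_dependent:
                    continue
                ss, tau = evaluate_gate(g, V_GRID)
                assert np.all((ss >= 0) & (ss <= 1))
                if not g.is_instantaneous:
                    assert np.all(tau > 0)

    def test_tau_scale_is_linear(self, model1):
        cat = model1.current("CaT")
        g = copy.deepcopy([x for x in cat.gates if x.kind == "activation"][0])
        _, tau1 = evaluate_gate(g, V_GRID)
        g.tau_scale = 10.0
        _, tau10 = evaluate_gate(g, V_GRID)
        np.testing.assert_allclose(tau10, 10.0 * tau1, rtol=1e-14)

    def test_rejects_nonfinite_voltage(self, model1):
        g = model1.current("CaT").gates[0]
        with pytest.raises(ValueError):
            evaluate_gate(g, np.nan)


class TestMembraneRhs:
    def test_passive_limit_gives_current_over_capacitance(self):
        m = leak_only_model(g_leak=0.0, c_m=2.0)
        y = m.initial_state(-65.0)
        dy = membrane_rhs(m, y, i_app=3.0)
        assert dy[0] == pytest.approx(3.0 / 2.0)
        # gate derivatives still evaluated from V
        assert np.all(np.isfinite(dy))

    def test_vanishes_at_root_found_independently(self, model1):
        y0 = model1.initial_state(-65.0)
        sol = optimize.root(lambda y: membrane_rhs(model1, y, 0.0), y0,
                            method="hybr", tol=1e-13)
        assert sol.success
        res = membrane_rhs(model1, sol.x, 0.0)
        assert np.max(np.abs(res)) < 1e-9

    def test_leak_only_relaxation_matches_rc_closed_form(self):
        g, e, cm, i_app = 0.1, -70.0, 1.0, 2.0
        m = leak_only_model(g_leak=g, e_leak=e, c_m=cm)
        v_inf = e + i_app / g
        tau = cm / g
        dt, n = 0.01, 5000
        y = m.initial_state(-80.0)
        for _ in range(n):
            y = y + dt * membrane_rhs(m, y, i_app)
        exact = v_inf + (-80.0 - v_inf) * np.exp(-n * dt / tau)
        assert y[0] == pytest.approx(exact, abs=5e-3)

    def test_dimension_mismatch_rejected(self, model1):
        with pytest.raises(ValueError):
            membrane_rhs(model1, np.zeros(model1.n_state + 1))


class TestRestoredVariant:
    def test_steady_state_activation_unchanged(self, model5, model5p):
        act5 = [g for g in model5.current("CaT").gates if g.kind == "activation"][0]
        act5p = [g for g in model5p.current("CaT").gates if g.kind == "activation"][0]
        np.testing.assert_array_equal(
            act5.steady_state(V_GRID), act5p.steady_state(V_GRID)
        )
        assert act5.is_instantaneous and not act5p.is_instantaneous

    def test_fast_tau_limit_recovers_instantaneous_model(self, model5, model5p):
        """Singular limit: with the restored gate at its steady state, the
        voltage derivative equals the instantaneous model's, and a short
        trajectory with tau scaled toward zero tracks the parent's."""
        from thalaswitch.sim_engine import StepProtocol, integrate, single_cell_system

        # exact rhs identity on the slow manifold m = m_inf(V)
        act_idx = [g.name for _, g in model5p.dynamic_gates()].index("m_CaT") + 1
        act = [g for g in model5p.current("CaT").gates if g.kind == "activation"][0]
        for v0 in (-90.0, -70.0, -50.0, -20.0):
            y5 = model5.initial_state(v0)
            y5p = model5p.initial_state(v0)
            y5p[act_idx] = float(act.steady_state(v0))
            dv5 = membrane_rhs(model5, y5, 1.0)[0]
            dv5p = membrane_rhs(model5p, y5p, 1.0)[0]
            assert dv5p == pytest.approx(dv5, rel=1e-12)

        # trajectory consistency under a hyperpolarizing excursion
        fastp = ts.scale_cat_tau(copy.deepcopy(model5p), 1e-3)
        fastp.recommended_dt = 1e-4
        proto = StepProtocol(-0.5, -1.5, 30.0, 30.0)
        r_inst = integrate(single_cell_system(copy.deepcopy(model5)), proto, 1e-4,
                           v0=-70.0, record_cells=[0], trace_dt=1.0)
        r_fast = integrate(single_cell_system(fastp), proto, 1e-4,
                           v0=-70.0, record_cells=[0], trace_dt=1.0)
        np.testing.assert_allclose(
            r_fast.voltage_trace(0), r_inst.voltage_trace(0), atol=2.0
        )

    def test_restored_tau_sits_in_slow_band(self, model5, model5p):
        a = ts.timescale_anchors(model5p)
        assert a.fast < a.tau_m_cat < a.tau_h_cat

    def test_already_dynamic_model_warns_and_copies(self, model1):
        with warnings.catch_warnings(record=True) as w:
            warnings.simplefilter("always")
            out = ts.make_restored_variant(model1)
        assert len(w) == 1
        assert out is not model1
        assert model_to_dict(out)["currents"] == model_to_dict(model1)["currents"]


class TestScaleCatTau:
    def test_identity_at_eta_one(self, model1):
        out = ts.scale_cat_tau(model1, 1.0)
        assert model_to_dict(out) == model_to_dict(model1)

    def test_inverse_scaling_roundtrip(self, model1):
        out = ts.scale_cat_tau(ts.scale_cat_tau(model1, 100.0), 1 / 100.0)
        act = [g for g in out.current("CaT").gates if g.kind == "activation"][0]
        assert act.tau_scale == pytest.approx(1.0)

    def test_only_cat_activation_scaled(self, model1):
        out = ts.scale_cat_tau(model1, 7.0)
        for cur, m_cur in zip(out.currents, model1.currents):
            for g, m_g in zip(cur.gates, m_cur.gates):
                expected = m_g.tau_scale * (7.0 if g.name == "m_CaT" else 1.0)
                assert g.tau_scale == pytest.approx(expected)

    def test_rejects_nonpositive_eta_and_instantaneous_gate(self, model1, model5):
        with pytest.raises(ValueError):
            ts.scale_cat_tau(model1, 0.0)
        with pytest.raises(ValueError):
            ts.scale_cat_tau(model5, 2.0)


class TestTimescaleAnchors:
    def test_slow_models_have_ordered_anchors(self, slow_cat_models):
        for m in slow_cat_models.values():
            a = ts.timescale_anchors(m)
            assert a.fast < a.tau_m_cat < a.ultraslow

    def test_anchor_scales_with_eta(self, model1):
        a0 = ts.timescale_anchors(model1)
        a5 = ts.timescale_anchors(ts.scale_cat_tau(model1, 5.0))
        assert a5.tau_m_cat == pytest.approx(5.0 * a0.tau_m_cat)
        assert a5.tau_h_cat == pytest.approx(a0.tau_h_cat)
        assert a5.fast == pytest.approx(a0.fast)

    def test_anchors_independent_of_capacitance(self, model1):
        m = copy.deepcopy(model1)
        m.c_m *= 0.1
        a0, a1 = ts.timescale_anchors(model1), ts.timescale_anchors(m)
        assert a0.tau_m_cat == a1.tau_m_cat
        assert a0.fast == a1.fast
        assert a0.tau_h_cat == a1.tau_h_cat


class TestModelFiles:
    @pytest.mark.parametrize("model_id", ["1", "5", "6"])
    def test_yaml_roundtrip(self, model_id):
        m = ts.load_builtin(model_id)
        again = model_from_dict(model_to_dict(m))
        assert model_to_dict(again) == model_to_dict(m)

    def test_required_currents_enforced(self, model5):
        d = model_to_dict(model5)
        d["currents"] = [c for c in d["currents"] if c["name"] != "CaT"]
        with pytest.raises(ValueError):
            model_from_dict(d)

    def test_leak_must_have_no_gates(self, model5):
        d = model_to_dict(model5)
        for c in d["currents"]:
            if c["name"] == "leak":
                c["gates"] = d["currents"][0]["gates"]
        with pytest.raises(ValueError):
            model_from_dict(d)

    def test_unknown_model_rejected_with_listing(self):
        with pytest.raises(KeyError, match="available"):
            ts.load_builtin("nope")
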