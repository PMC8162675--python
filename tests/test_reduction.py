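"""Three-timescale reduction: weights, reduced dynamics, phase-plane tools."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize

import thalaswitch as ts
from thalaswitch import reduction_phase as rp
from thalaswitch.channel_models import membrane_rhs
from thalaswitch.workbench import make_fixtures


class ToyFold:
    """Fold normal form dV/dt = mu(V_u) + V^2 with linear mu; analytic SN."""

    c_m = 1.0

    def __init__(self, mu_slope=-0.1, mu_offset=-50.0):
        self.mu_slope = mu_slope
        self.mu_offset = mu_offset

    def dvdt(self, v, vs, vu, i_app=0.0):
        v = np.asarray(v, dtype=float)
        vu = np.asarray(vu, dtype=float)
        return self.mu_slope * (vu - self.mu_offset) - v**2 + i_app

    def tau_s(self, v):
        return 5.0


class TestTimescaleWeights:
    def test_printed_branches_exact_on_exhaustive_grid(self):
        """Every branch of the piecewise logarithmic-distance rule."""
        tf, ts_, tu = 0.1, 2.0, 100.0
        for tau_x in np.logspace(-3, 4, 400):
            w_fs, w_su = rp.timescale_weights(tau_x, tf, ts_, tu)
            if tau_x <= tf:
                exp = (1.0, 1.0)
            elif tau_x <= ts_:
                exp = (np.log(ts_ / tau_x) / np.log(ts_ / tf), 1.0)
            elif tau_x <= tu:
                exp = (0.0, np.log(tu / tau_x) / np.log(tu / ts_))
            else:
                exp = (0.0, 0.0)
            assert w_fs == pytest.approx(exp[0], abs=1e-12)
            assert w_su == pytest.approx(exp[1], abs=1e-12)

    def test_logarithmic_midpoints(self):
        w_fs, w_su = rp.timescale_weights(np.sqrt(0.1 * 2.0), 0.1, 2.0, 100.0)
        assert (w_fs, w_su) == (pytest.approx(0.5), 1.0)
        w_fs, w_su = rp.timescale_weights(np.sqrt(2.0 * 100.0), 0.1, 2.0, 100.0)
        assert (w_fs, w_su) == (0.0, pytest.approx(0.5))

    def test_continuity_at_branch_boundaries(self):
        tf, ts_, tu = 0.1, 2.0, 100.0
        for b in (tf, ts_, tu):
            below = rp.timescale_weights(b * (1 - 1e-9), tf, ts_, tu)
            above = rp.timescale_weights(b * (1 + 1e-9), tf, ts_, tu)
            assert below[0] == pytest.approx(above[0], abs=1e-6)
            assert below[1] == pytest.approx(above[1], abs=1e-6)

    @given(st.floats(1e-3, 1e4), st.floats(0.05, 0.5), st.floats(1.0, 10.0),
           st.floats(50.0, 500.0))
    @settings(max_examples=200, deadline=None)
    def test_weight_ordering_invariant(self, tau_x, tf, ts_, tu):
        w_fs, w_su = rp.timescale_weights(tau_x, tf, ts_, tu)
        assert 0.0 <= w_fs <= w_su <= 1.0

    def test_unordered_pacing_rejected(self):
        with pytest.raises(ValueError):
            rp.timescale_weights(1.0, 2.0, 1.0, 100.0)


class TestReducedGateValue:
    def test_fast_weights_give_instantaneous_value(self):
        f = lambda v: 1.0 / (1.0 + np.exp(-(v + 50.0) / 5.0))
        assert rp.reduced_gate_value(f, 1.0, 1.0, -40.0, -60.0, -80.0) == f(-40.0)

    def test_ultraslow_weights_give_vu_value(self):
        f = lambda v: 1.0 / (1.0 + np.exp(-(v + 50.0) / 5.0))
        assert rp.reduced_gate_value(f, 0.0, 0.0, -40.0, -60.0, -80.0) == f(-80.0)

    def test_collapsed_voltages_are_weight_independent(self):
        f = lambda v: 1.0 / (1.0 + np.exp(-(v + 50.0) / 5.0))
        for w_fs, w_su in [(0.3, 0.8), (0.0, 0.5), (1.0, 1.0)]:
            got = rp.reduced_gate_value(f, w_fs, w_su, -55.0, -55.0, -55.0)
            assert got == pytest.approx(f(-55.0))


class TestPacing:
    def test_model1_fast_timescale_is_sodium_activation(self, model1):
        *_, src = rp.pacing_time_constants(model1)
        assert src == "tau_mNa"

    def test_instantaneous_sodium_models_use_potassium_over_ten(self, model5, model5p):
        for m in (model5, model5p):
            tau_f, tau_s, _, src = rp.pacing_time_constants(m)
            assert src == "tau_mK/10"
            v = np.linspace(-100, 0, 50)
            np.testing.assert_allclose(tau_f(v), tau_s(v) / 10.0)

    def test_pacing_ordered_over_physiological_range(self, all_models):
        v = np.linspace(-95.0, -20.0, 60)
        for m in all_models.values():
            tau_f, tau_s, tau_u, _ = rp.pacing_time_constants(m)
            assert np.all(tau_f(v) < tau_s(v))
            assert np.all(tau_s(v) < tau_u(v))


class TestReducedRhs:
    def test_vanishes_at_independently_located_fixed_point(self, model1):
        red = rp.reduce_model(model1)
        g = lambda v: float(red.dvdt(v, v, v, -1.5))
        root = optimize.brentq(g, -90.0, -60.0)
        res = rp.reduced_rhs(red, [root, root, root], -1.5)
        assert np.max(np.abs(res)) < 1e-9

    def test_matches_full_model_on_the_diagonal_at_equilibrium(self, model1):
        y0 = model1.initial_state(-65.0)
        sol = optimize.root(lambda y: membrane_rhs(model1, y, 0.0), y0,
                            method="hybr", tol=1e-13)
        assert sol.success
        v_eq = sol.x[0]
        red = rp.reduce_model(model1)
        dv_red = float(red.dvdt(v_eq, v_eq, v_eq, 0.0))
        # at V = Vs = Vu every reduced gate equals its steady state, so the
        # reduced voltage derivative must match the full model's
        assert dv_red == pytest.approx(float(membrane_rhs(model1, sol.x, 0.0)[0]),
                                       abs=1e-6)

    def test_capacitance_scaling_touches_only_the_voltage_equation(self, model1):
        state = [-70.0, -72.0, -75.0]
        r1 = rp.reduced_rhs(rp.reduce_model(model1, 1.0), state, -1.5)
        r3 = rp.reduced_rhs(rp.reduce_model(model1, 1 / 3), state, -1.5)
        assert r3[0] == pytest.approx(3.0 * r1[0], rel=1e-12)
        assert r3[1] == r1[1]
        assert r3[2] == r1[2]


class TestPhasePlane:
    def test_toy_normal_form_saddle_node_recovered(self):
        fx = make_fixtures("toy_oracles")
        toy = ToyFold(fx["mu_slope"], fx["mu_offset"])
        sn = rp.saddle_node(toy, 0.0, v_window=(-40, 40), vu_window=(-80, -45))
        assert sn is not None
        assert sn.v == pytest.approx(fx["sn_v"], abs=1e-6)
        assert sn.v_u == pytest.approx(fx["sn_v_u"], abs=1e-6)
        assert sn.residual_dvdt < 1e-8 and sn.residual_det < 1e-8

    def test_nullcline_points_satisfy_the_defining_equation(self):
        toy = ToyFold()
        nc = rp.v_nullcline(toy, -60.0, 0.0, v_window=(-10, 10),
                            vs_window=(-10, 10), n_grid=200)
        # dV/dt = 0 at V = +-1 for mu = 1 at V_u = -60
        f = np.abs(toy.dvdt(nc.points[:, 1], nc.points[:, 0], -60.0, 0.0))
        assert nc.points.shape[0] > 0
        assert np.max(f) < 1e-2

    def test_toy_linear_system_single_stable_node(self, model1):
        class Linear:
            c_m = 1.0

            def dvdt(self, v, vs, vu, i_app=0.0):
                return -0.5 * (np.asarray(v, float) + 65.0)

            def tau_s(self, v):
                return 5.0

            def tau_u(self, v):
                return 50.0

        fps = rp.fixed_points(Linear(), 0.0, v_window=(-100, 0))
        assert len(fps) == 1
        assert fps[0].coords[0] == pytest.approx(-65.0, abs=1e-6)
        assert fps[0].stable and fps[0].kind == "node"

    def test_depolarized_regime_has_unstable_fixed_point(self, model1):
        red = rp.reduce_model(model1)
        i_dep = model1.presets["single_cell"]["i_depol"]
        fps = rp.fixed_points(red, i_dep)
        assert any((not f.stable) for f in fps)
        assert all(f.residual < 1e-8 for f in fps)

    def test_lower_branch_on_constructed_component_sets(self):
        from thalaswitch.reduction_phase import NullclineSet

        n_curve = np.column_stack([np.linspace(-80, -20, 50),
                                   np.linspace(-70, -30, 50)])
        one = NullclineSet(points=n_curve, components=[np.arange(50)],
                           v_u=-75.0, i_app=-1.0, grid_shape=(50, 50),
                           tolerance=1e-3)
        assert not rp.lower_branch_present(one, saddle_v=-50.0)
        arc = np.column_stack([np.linspace(-95, -70, 20),
                               np.full(20, -85.0)])
        two = NullclineSet(
            points=np.vstack([n_curve, arc]),
            components=[np.arange(50), np.arange(50, 70)],
            v_u=-75.0, i_app=-1.0, grid_shape=(50, 50), tolerance=1e-3,
        )
        assert rp.lower_branch_present(two, saddle_v=-50.0)
        assert not rp.lower_branch_present(
            NullclineSet(points=np.empty((0, 2)), components=[], v_u=0.0,
                         i_app=0.0, grid_shape=(0, 0), tolerance=1e-3),
            saddle_v=-50.0,
        )
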