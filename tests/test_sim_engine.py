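"""Euler engine, spike detection, firing-pattern and circuit classification."""

import copy

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import thalaswitch as ts
from thalaswitch.channel_models import membrane_rhs
from thalaswitch.sim_engine import (
    CIRCUIT_CLASSIFIER,
    SINGLE_CELL_CLASSIFIER,
    StepProtocol,
    burst_intervals,
    classify_cell,
    classify_circuit_transition,
    currentscape_shares,
    detect_spikes,
    epoch_patterns,
    integrate,
    pattern_metrics,
    single_cell_system,
    two_cell_circuit,
    window_spikes,
)
from thalaswitch.synapse_lfp import (
    NOMINAL_KINETICS,
    REVERSALS,
    SynapseState,
    synapse_rhs,
    transmitter_concentration,
)


def classify_brute_force(spike_times, ratio):
    """Independent restatement of the printed rule for property testing."""
    st_ = sorted(spike_times)
    if len(st_) < 3:
        return "silent"
    isis = [b - a for a, b in zip(st_, st_[1:])]
    return "burst" if max(isis) > ratio * min(isis) else "tonic"


class TestIntegrate:
    def test_passive_cell_follows_exact_euler_ramp(self, model5):
        m = copy.deepcopy(model5)
        for cur in m.currents:
            cur.g_max = 0.0
        dt, i_app = 0.01, 4.0
        proto = StepProtocol(i_app, i_app, 1.0, 1.0)
        res = integrate(single_cell_system(m), proto, dt, v0=-65.0)
        k = int(round(proto.duration / dt))
        assert res.final_state[0] == pytest.approx(-65.0 + k * dt * i_app / m.c_m,
                                                   rel=1e-12)

    def test_kernel_agrees_with_reference_rhs_single_cell(self, model1):
        """A few Euler steps of the compiled kernel match membrane_rhs."""
        dt = 0.05
        n = 4
        proto = StepProtocol(2.0, 2.0, n * dt / 2, n * dt / 2)
        res = integrate(single_cell_system(model1), proto, dt, v0=-65.0)
        y = model1.initial_state(-65.0)
        for _ in range(n):
            y = y + dt * membrane_rhs(model1, y, 2.0)
        np.testing.assert_allclose(res.final_state, y, rtol=1e-10, atol=1e-12)

    def test_kernel_agrees_with_reference_rhs_circuit(self, model5):
        """Coupled E-I update matches a hand-stepped reference implementation."""
        from thalaswitch.synapse_lfp import postsynaptic_current, SynapticWeights

        me, mi = copy.deepcopy(model5), copy.deepcopy(model5)
        ga, gb, gc = 0.3, 0.5, 1.0
        sys_ = two_cell_circuit(me, mi, ga, gb, gc)
        dt, n = 0.01, 5
        proto = StepProtocol(2.5, 2.5, n * dt / 2, n * dt / 2, targets=[1])
        res = integrate(sys_, proto, dt, v0=-70.0)

        ye = me.initial_state(-70.0)
        yi = mi.initial_state(-70.0)
        s_e = np.zeros(3)  # E presynaptic gating (ampa, gabaa, gabab)
        s_i = np.zeros(3)
        w_on_i = SynapticWeights(g_ampa=ga)
        w_on_e = SynapticWeights(g_gabaa=gb, g_gabab=gc)
        for _ in range(n):
            isyn_e = postsynaptic_current(SynapseState(*s_i), ye[0], w_on_e)
            isyn_i = postsynaptic_current(SynapseState(*s_e), yi[0], w_on_i)
            dye = membrane_rhs(me, ye, 0.0)
            dyi = membrane_rhs(mi, yi, 2.5)
            dse = synapse_rhs(SynapseState(*s_e), ye[0])
            dsi = synapse_rhs(SynapseState(*s_i), yi[0])
            dye[0] -= isyn_e / me.c_m
            dyi[0] -= isyn_i / mi.c_m
            ye = ye + dt * dye
            yi = yi + dt * dyi
            s_e = np.clip(s_e + dt * dse, 0, 1)
            s_i = np.clip(s_i + dt * dsi, 0, 1)
        ref = np.concatenate([ye, yi])
        np.testing.assert_allclose(res.final_state, ref, rtol=1e-9, atol=1e-11)

    def test_bitwise_deterministic_spike_times(self, model1):
        p = model1.presets["single_cell"]
        proto = StepProtocol(p["i_depol"], p["i_hyper"], 800.0, 800.0)
        r1 = integrate(single_cell_system(model1), proto, 0.05,
                       spike_threshold=-10.0)
        r2 = integrate(single_cell_system(model1), proto, 0.05,
                       spike_threshold=-10.0)
        np.testing.assert_array_equal(r1.spikes[0], r2.spikes[0])
        assert r1.spikes[0].size > 0

    def test_halving_dt_converges(self, model1):
        """Spike counts equal and final V close under dt halving.

        The protocol ends in a silent strongly-hyperpolarized hold so the
        final state is insensitive to spike-phase drift.
        """
        proto = StepProtocol(model1.presets["single_cell"]["i_depol"], -4.0,
                             500.0, 1000.0)
        results = []
        for dt in (0.05, 0.025):
            r = integrate(single_cell_system(model1), proto, dt,
                          spike_threshold=-10.0)
            results.append(r)
        # spike-phase drift of O(dt) can move one spike across the epoch edge
        assert abs(results[0].spikes[0].size - results[1].spikes[0].size) <= 1
        assert abs(results[0].final_state[0] - results[1].final_state[0]) < 0.5

    def test_dt_above_recommended_rejected(self, model5):
        with pytest.raises(ValueError, match="recommended_dt"):
            integrate(single_cell_system(model5), StepProtocol(1, -1, 10, 10), 0.05)

    def test_gates_bounded_and_voltage_physiological(self, all_models):
        for m in all_models.values():
            p = m.presets["single_cell"]
            proto = StepProtocol(p["i_depol"], p["i_hyper"], 500.0, 700.0)
            res = integrate(single_cell_system(m), proto, m.recommended_dt,
                            record_cells=[0], trace_dt=0.5)
            tr = res.cell_state_trace(0, single_cell_system(m))
            v = tr[0]
            assert v.min() > -150 and v.max() < 80
            n_gates = len(m.dynamic_gates())
            gates = tr[1:1 + n_gates]
            assert gates.min() >= 0.0 and gates.max() <= 1.0


class TestDetectSpikes:
    def test_subthreshold_trace_has_no_events(self):
        t = np.arange(0, 100.0, 0.1)
        assert detect_spikes(t, np.full(t.size, -65.0), -20.0).size == 0

    def test_single_triangular_excursion_is_one_event(self):
        t = np.arange(0, 10.0, 0.1)
        v = np.full(t.size, -65.0)
        v[40:50] = np.linspace(-20, 10, 10)  # sustained suprathreshold samples
        ev = detect_spikes(t, v, -20.0)
        assert ev.size == 1
        assert ev[0] == pytest.approx(t[40])

    def test_two_excursions_separated_by_dip(self):
        t = np.arange(0, 10.0, 0.1)
        v = np.full(t.size, -65.0)
        v[20:25] = 0.0
        v[60:65] = 0.0
        assert detect_spikes(t, v, -20.0).size == 2

    def test_transient_window_removes_early_events(self):
        t = np.arange(0, 10.0, 0.1)
        v = np.full(t.size, -65.0)
        v[10] = 0.0
        v[80] = 0.0
        ev = detect_spikes(t, v, -20.0, transient_skip=5.0)
        assert ev.size == 1 and ev[0] >= 5.0


class TestClassifyCell:
    def test_empty_is_silent(self):
        assert classify_cell([], 3.0) == "silent"

    def test_regular_train_is_tonic(self):
        assert classify_cell(np.arange(100) * 20.0, 3.0) == "tonic"

    def test_clustered_train_is_burst_at_both_ratios(self):
        spikes = []
        t = 0.0
        for _ in range(10):
            spikes += [t, t + 5, t + 10, t + 15]
            t += 215.0  # gap of 200 ms > 4 * 5 ms
        assert classify_cell(spikes, 3.0) == "burst"
        assert classify_cell(spikes, 4.0) == "burst"

    def test_two_spikes_classified_silent(self):
        assert classify_cell([100.0, 130.0], 4.0) == "silent"

    def test_ratio_must_exceed_one(self):
        with pytest.raises(ValueError):
            classify_cell([1, 2, 3], 1.0)

    @given(
        st.lists(st.floats(0.5, 500.0), min_size=0, max_size=40),
        st.sampled_from([3.0, 4.0]),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_on_random_isi_sequences(self, isis, ratio):
        spikes = np.cumsum([100.0] + isis)
        assert classify_cell(spikes, ratio) == classify_brute_force(spikes, ratio)


class TestCircuitTransition:
    def _bursts(self, n, period, start=0.0, spikes_per=4, isi=5.0):
        out = []
        t = start
        for _ in range(n):
            out += [t + k * isi for k in range(spikes_per)]
            t += period
        return np.array(out)

    def test_synchronous_switch_is_rhythmic(self):
        e = self._bursts(20, 300.0)
        i = self._bursts(20, 300.0, start=2.0)
        assert classify_circuit_transition(
            {"E": "silent", "I": "tonic"},
            {"E": "burst", "I": "burst"},
            {"E": e, "I": i},
        )

    def test_wrong_depolarized_pattern_fails(self):
        assert not classify_circuit_transition(
            {"E": "tonic", "I": "tonic"}, {"E": "burst", "I": "burst"}
        )

    def test_wrong_hyperpolarized_pattern_fails(self):
        assert not classify_circuit_transition(
            {"E": "silent", "I": "tonic"}, {"E": "tonic", "I": "burst"}
        )

    def test_antiphase_bursting_fails_synchrony(self):
        e = self._bursts(20, 300.0)
        i = self._bursts(20, 300.0, start=150.0)  # bursts fall in E's gaps
        assert not classify_circuit_transition(
            {"E": "silent", "I": "tonic"},
            {"E": "burst", "I": "burst"},
            {"E": e, "I": i},
        )

    def test_two_to_one_locking_counts_as_synchronous(self):
        e = self._bursts(10, 600.0)
        i = self._bursts(20, 300.0)  # every E burst coincides with an I burst
        assert classify_circuit_transition(
            {"E": "silent", "I": "tonic"},
            {"E": "burst", "I": "burst"},
            {"E": e, "I": i},
        )

    def test_requires_exactly_e_and_i(self):
        with pytest.raises(ValueError):
            classify_circuit_transition({"E": "silent"}, {"E": "burst"})


class TestPatternMetrics:
    def test_tonic_frequency_from_isi(self):
        m = pattern_metrics(np.arange(50) * 20.0, "tonic")
        assert m.tonic_frequency_hz == pytest.approx(50.0)
        assert m.intraburst_frequency_hz is None

    def test_burst_decomposition_metrics(self):
        # 20 bursts of 4 spikes at 5 ms ISI, onset-to-onset period 515 ms
        spikes = []
        t = 0.0
        for _ in range(20):
            spikes += [t, t + 5, t + 10, t + 15]
            t += 515.0
        spikes = np.array(spikes)
        m = pattern_metrics(spikes, "burst", ratio=4.0)
        assert m.intraburst_frequency_hz == pytest.approx(200.0)
        assert m.interburst_interval_ms == pytest.approx(500.0)
        # 20 bursts over the spike-train span (19 periods + one burst)
        span = spikes[-1] - spikes[0]
        assert m.bursts_per_second == pytest.approx(1000.0 * 20 / span)
        assert burst_intervals(spikes, 4.0)[0] == (0.0, 15.0)

    def test_degenerate_trains_have_no_metrics(self):
        for spikes in ([], [100.0], [100.0, 120.0]):
            m = pattern_metrics(spikes, "silent")
            assert m.tonic_frequency_hz is None
            assert m.bursts_per_second is None


class TestCurrentscape:
    def test_single_inward_current_owns_the_share(self):
        tr = {"Na": np.array([-5.0, -1.0]), "K": np.array([0.0, 0.0])}
        sh_in, sh_out, tot_in, tot_out = currentscape_shares(tr)
        np.testing.assert_allclose(sh_in["Na"], [100.0, 100.0])
        np.testing.assert_allclose(tot_in, [5.0, 1.0])
        np.testing.assert_allclose(tot_out, 0.0)

    def test_shares_sum_to_hundred_where_total_nonzero(self, rng):
        tr = {f"c{k}": rng.normal(size=300) for k in range(5)}
        sh_in, sh_out, tot_in, tot_out = currentscape_shares(tr)
        s_in = sum(sh_in.values())
        np.testing.assert_allclose(s_in[tot_in > 0], 100.0)
        s_out = sum(sh_out.values())
        np.testing.assert_allclose(s_out[tot_out > 0], 100.0)

    def test_equal_inward_currents_split_evenly(self):
        tr = {"a": np.array([-2.0]), "b": np.array([-2.0])}
        sh_in, *_ = currentscape_shares(tr)
        assert sh_in["a"][0] == pytest.approx(50.0)
        assert sh_in["b"][0] == pytest.approx(50.0)


def test_named_classifier_presets_match_protocols():
    assert (SINGLE_CELL_CLASSIFIER.spike_threshold,
            SINGLE_CELL_CLASSIFIER.isi_ratio,
            SINGLE_CELL_CLASSIFIER.transient_ms) == (-10.0, 3.0, 500.0)
    assert (CIRCUIT_CLASSIFIER.spike_threshold,
            CIRCUIT_CLASSIFIER.isi_ratio,
            CIRCUIT_CLASSIFIER.transient_ms) == (-20.0, 4.0, 1000.0)
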