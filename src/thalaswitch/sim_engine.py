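"""Simulation engine: Euler integration, spike detection and classification.

Systems (single cells, 2-cell E-I circuits, E-I networks) are integrated
with an explicit Euler scheme under a two-epoch step-current protocol
(depolarizing then hyperpolarizing, applied to the inhibitory cells).  The
resulting spike trains are classified into silent / tonic / burst firing by
the interspike-interval ratio rule, and circuit transitions into the
rhythmic switch (depolarized: E silent, I tonic; hyperpolarized: both cells
synchronously bursting) versus anything else.

Two named classifier presets follow the experimental protocols:

- single cell: spike threshold -10 mV, ISI ratio 3, 0.5 s transient skip;
- circuit / network cells: threshold -20 mV, ratio 4, 1 s transient skip.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from . import _kernel
from ._formulas import NPAR, SS_FAMILIES, TAU_FAMILIES
from .channel_models import NeuronModel
from .synapse_lfp import NOMINAL_KINETICS, RECEPTORS, REVERSALS, SynapseKinetics

__all__ = [
    "StepProtocol",
    "Synapse",
    "System",
    "SimulationResult",
    "ClassifierPreset",
    "SINGLE_CELL_CLASSIFIER",
    "CIRCUIT_CLASSIFIER",
    "integrate",
    "detect_spikes",
    "classify_cell",
    "classify_circuit_transition",
    "burst_intervals",
    "pattern_metrics",
    "PatternMetrics",
    "currentscape_shares",
    "two_cell_circuit",
    "single_cell_system",
]


@dataclass(frozen=True)
class StepProtocol:
    """Two-epoch step-current protocol (amplitudes in uA/cm^2, times in ms)."""

    i_depol: float
    i_hyper: float
    t_depol: float
    t_hyper: float
    targets: Optional[Sequence[int]] = None  # cell indices; None = all cells

    def __post_init__(self):
        if self.t_depol <= 0 or self.t_hyper <= 0:
            raise ValueError("protocol epoch durations must be positive")

    @property
    def duration(self) -> float:
        return self.t_depol + self.t_hyper


@dataclass(frozen=True)
class Synapse:
    """One directed connection: pre cell -> post cell through one receptor."""

    pre: int
    post: int
    receptor: str  # "ampa" | "gabaa" | "gabab"
    g: float

    def __post_init__(self):
        if self.receptor not in RECEPTORS:
            raise ValueError(f"unknown receptor {self.receptor!r}")
        if self.g < 0:
            raise ValueError("synaptic conductance must be >= 0")


@dataclass
class System:
    """A set of neuron models plus directed synapses between them."""

    cells: list[NeuronModel]
    synapses: list[Synapse] = field(default_factory=list)
    labels: list[str] = field(default_factory=list)  # "E" / "I" per cell
    kinetics: SynapseKinetics = field(default_factory=lambda: NOMINAL_KINETICS)

    def __post_init__(self):
        if not self.labels:
            self.labels = ["I"] * len(self.cells)
        if len(self.labels) != len(self.cells):
            raise ValueError("labels must match cells")
        for s in self.synapses:
            if not (0 <= s.pre < len(self.cells) and 0 <= s.post < len(self.cells)):
                raise ValueError("synapse endpoint out of range")

    def cells_labelled(self, label: str) -> list[int]:
        return [i for i, l in enumerate(self.labels) if l == label]


def single_cell_system(model: NeuronModel) -> System:
    return System(cells=[model], labels=["I"])


def two_cell_circuit(
    model_e: NeuronModel,
    model_i: NeuronModel,
    g_ampa: float,
    g_gabaa: float,
    g_gabab: float,
) -> System:
    """E-cell (index 0) -> AMPA -> I-cell (index 1) -> GABA_A + GABA_B -> E."""
    return System(
        cells=[model_e, model_i],
        labels=["E", "I"],
        synapses=[
            Synapse(0, 1, "ampa", g_ampa),
            Synapse(1, 0, "gabaa", g_gabaa),
            Synapse(1, 0, "gabab", g_gabab),
        ],
    )


# --------------------------------------------------------------------------
# compilation to kernel arrays
# --------------------------------------------------------------------------


class _Compiled:
    def __init__(self, system: System):
        cells = system.cells
        n_cells = len(cells)
        self.system = system
        self.n_cells = n_cells
        cell_v = np.zeros(n_cells, dtype=np.int64)
        cell_cm = np.zeros(n_cells)
        cell_ca = np.full(n_cells, -1, dtype=np.int64)
        ca_k = np.zeros(n_cells)
        ca_rate = np.zeros(n_cells)
        ca_rest = np.zeros(n_cells)
        ca_ext = np.ones(n_cells)
        ca_nernst = np.zeros(n_cells)
        cur_cell, cur_g, cur_erev, cur_nernst, cur_casrc = [], [], [], [], []
        gate_cur, gate_exp, gate_state, gate_cadep = [], [], [], []
        gate_ssfam, gate_sspar, gate_taufam, gate_taupar, gate_tauscale = (
            [], [], [], [], [],
        )
        self.state_offsets = []
        self.state_names: list[str] = []
        off = 0
        for i, m in enumerate(cells):
            self.state_offsets.append(off)
            cell_v[i] = off
            cell_cm[i] = m.c_m
            names = m.state_names()
            self.state_names.extend(f"c{i}:{n}" for n in names)
            dyn = {id(g): off + 1 + k for k, (_, g) in enumerate(m.dynamic_gates())}
            if m.calcium_pool:
                p = m.calcium_pool
                cell_ca[i] = off + m.n_state - 1
                ca_k[i] = p.influx_coupling
                ca_rate[i] = p.removal_rate
                ca_rest[i] = p.resting_level
                ca_ext[i] = p.external_level
                ca_nernst[i] = p.nernst_factor
            for cur in m.currents:
                ci = len(cur_g)
                cur_cell.append(i)
                cur_g.append(cur.g_max)
                nernst = isinstance(cur.reversal, str)
                cur_erev.append(0.0 if nernst else float(cur.reversal))
                cur_nernst.append(1 if nernst else 0)
                cur_casrc.append(1 if cur.calcium_source else 0)
                for g in cur.gates:
                    gate_cur.append(ci)
                    gate_exp.append(g.exponent)
                    gate_state.append(dyn.get(id(g), -1))
                    gate_cadep.append(1 if g.ca_dependent else 0)
                    gate_ssfam.append(g.steady_state.code(SS_FAMILIES))
                    gate_sspar.append(g.steady_state.packed())
                    if g.is_instantaneous:
                        gate_taufam.append(0)
                        gate_taupar.append(np.ones(NPAR))
                    else:
                        gate_taufam.append(g.time_constant.code(TAU_FAMILIES))
                        gate_taupar.append(g.time_constant.packed())
                    gate_tauscale.append(g.tau_scale)
            off += m.n_state
        self.n_state = off
        self.cell_v = cell_v
        self.cell_cm = cell_cm
        self.cell_ca = cell_ca
        self.ca_k, self.ca_rate, self.ca_rest = ca_k, ca_rate, ca_rest
        self.ca_ext, self.ca_nernst = ca_ext, ca_nernst
        self.cur_cell = np.array(cur_cell, dtype=np.int64)
        self.cur_g = np.array(cur_g)
        self.cur_erev = np.array(cur_erev)
        self.cur_nernst = np.array(cur_nernst, dtype=np.int8)
        self.cur_casrc = np.array(cur_casrc, dtype=np.int8)
        self.gate_cur = np.array(gate_cur, dtype=np.int64)
        self.gate_exp = np.array(gate_exp, dtype=np.int64)
        self.gate_state = np.array(gate_state, dtype=np.int64)
        self.gate_cadep = np.array(gate_cadep, dtype=np.int8)
        self.gate_ssfam = np.array(gate_ssfam, dtype=np.int64)
        self.gate_sspar = (
            np.vstack(gate_sspar) if gate_sspar else np.zeros((0, NPAR))
        )
        self.gate_taufam = np.array(gate_taufam, dtype=np.int64)
        self.gate_taupar = (
            np.vstack(gate_taupar) if gate_taupar else np.zeros((0, NPAR))
        )
        self.gate_tauscale = np.array(gate_tauscale)

        # synapse gating shared per (pre, receptor)
        kin = system.kinetics
        pairs: dict[tuple[int, str], int] = {}
        sgate_pre, sgate_rise, sgate_decay = [], [], []
        syn_sgate, syn_post, syn_g, syn_erev = [], [], [], []
        for syn in system.synapses:
            key = (syn.pre, syn.receptor)
            if key not in pairs:
                pairs[key] = len(sgate_pre)
                sgate_pre.append(syn.pre)
                sgate_rise.append(kin.rise[syn.receptor])
                sgate_decay.append(kin.decay[syn.receptor])
            syn_sgate.append(pairs[key])
            syn_post.append(syn.post)
            syn_g.append(syn.g)
            syn_erev.append(REVERSALS[syn.receptor])
        self.n_sgate = len(sgate_pre)
        self.sgate_pre = np.array(sgate_pre, dtype=np.int64)
        self.sgate_rise = np.array(sgate_rise)
        self.sgate_decay = np.array(sgate_decay)
        self.syn_sgate = np.array(syn_sgate, dtype=np.int64)
        self.syn_post = np.array(syn_post, dtype=np.int64)
        self.syn_g = np.array(syn_g)
        self.syn_erev = np.array(syn_erev)
        npre = np.zeros(n_cells, dtype=np.int64)
        for post in range(n_cells):
            pres = {s.pre for s in system.synapses if s.post == post}
            npre[post] = len(pres)
        self.post_npre = npre

    def initial_state(self, v0: float) -> np.ndarray:
        y = np.empty(self.n_state)
        for m, off in zip(self.system.cells, self.state_offsets):
            y[off : off + m.n_state] = m.initial_state(v0)
        return y


@dataclass
class SimulationResult:
    """Traces, spike times (ms) and metadata of one integration run."""

    dt: float
    protocol: StepProtocol
    labels: list[str]
    spikes: list[np.ndarray]
    t_states: np.ndarray
    states: np.ndarray  # (n_trace, n_recorded_state)
    recorded_state_names: list[str]
    t_lfp: np.ndarray
    isyn: np.ndarray  # (n_lfp, n_cells), per-post mean over presynaptic inputs
    final_state: np.ndarray
    state_offsets: list[int]

    def cell_state_trace(self, cell: int, system: System) -> np.ndarray:
        """(n_state_cell, T) trace of one cell's state (requires it recorded)."""
        m = system.cells[cell]
        prefix = f"c{cell}:"
        cols = [
            k for k, n in enumerate(self.recorded_state_names) if n.startswith(prefix)
        ]
        if len(cols) != m.n_state:
            raise KeyError(f"cell {cell} was not fully recorded")
        return self.states[:, cols].T

    def voltage_trace(self, cell: int) -> np.ndarray:
        name = f"c{cell}:V"
        try:
            col = self.recorded_state_names.index(name)
        except ValueError as e:
            raise KeyError(f"voltage of cell {cell} not recorded") from e
        return self.states[:, col]


def integrate(
    system: System,
    protocol: StepProtocol,
    dt: float,
    spike_threshold: float = -20.0,
    record_cells: Sequence[int] = (),
    trace_dt: float = 0.1,
    lfp_dt: float = 0.5,
    v0: float = -65.0,
    initial_state: Optional[np.ndarray] = None,
    max_spike_rate_hz: float = 600.0,
) -> SimulationResult:
    """Forward-Euler integration of a system under a step protocol.

    ``record_cells`` selects cells whose full state vectors are stored at
    ``trace_dt`` resolution; synaptic currents per postsynaptic cell are
    always stored at ``lfp_dt`` resolution (when synapses exist).  Spike
    times are logged inside the integration loop as upward crossings of
    ``spike_threshold``.
    """
    comp = _Compiled(system)
    for m in system.cells:
        if dt > m.recommended_dt * (1 + 1e-9):
            raise ValueError(
                f"dt={dt} exceeds recommended_dt={m.recommended_dt} of model {m.model_id}"
            )
    n_steps = int(round(protocol.duration / dt))
    n_dep = int(round(protocol.t_depol / dt))
    targets = (
        set(range(comp.n_cells)) if protocol.targets is None else set(protocol.targets)
    )
    i_dep = np.array(
        [protocol.i_depol if j in targets else 0.0 for j in range(comp.n_cells)],
        dtype=np.float64,
    )
    i_hyp = np.array(
        [protocol.i_hyper if j in targets else 0.0 for j in range(comp.n_cells)],
        dtype=np.float64,
    )

    trace_stride = max(1, int(round(trace_dt / dt))) if record_cells else 0
    lfp_stride = max(1, int(round(lfp_dt / dt))) if comp.n_sgate else 0
    rec_idx = []
    rec_names = []
    for c in record_cells:
        off = comp.state_offsets[c]
        n = system.cells[c].n_state
        rec_idx.extend(range(off, off + n))
        rec_names.extend(comp.state_names[off : off + n])
    rec_idx = np.array(rec_idx, dtype=np.int64)
    n_trace = (n_steps // trace_stride + 1) if trace_stride else 1
    state_rec = np.zeros((n_trace, len(rec_idx)))
    n_lfp = (n_steps // lfp_stride + 1) if lfp_stride else 1
    isyn_rec = np.zeros((n_lfp, comp.n_cells))
    max_spk = int(protocol.duration / 1000.0 * max_spike_rate_hz) + 16
    spk_t = np.zeros((comp.n_cells, max_spk))
    spk_n = np.zeros(comp.n_cells, dtype=np.int64)

    y0 = initial_state.copy() if initial_state is not None else comp.initial_state(v0)
    if y0.shape[0] != comp.n_state:
        raise ValueError("initial state dimension mismatch")
    s0 = np.zeros(comp.n_sgate)

    status, bad_cell, bad_step = _kernel.integrate_system(
        comp.n_cells, comp.cell_v, comp.cell_cm, comp.cell_ca,
        comp.ca_k, comp.ca_rate, comp.ca_rest, comp.ca_ext, comp.ca_nernst,
        comp.cur_cell, comp.cur_g, comp.cur_erev, comp.cur_nernst, comp.cur_casrc,
        comp.gate_cur, comp.gate_exp, comp.gate_state, comp.gate_cadep,
        comp.gate_ssfam, comp.gate_sspar, comp.gate_taufam, comp.gate_taupar,
        comp.gate_tauscale,
        comp.n_sgate, comp.sgate_pre, comp.sgate_rise, comp.sgate_decay,
        comp.syn_sgate, comp.syn_post, comp.syn_g, comp.syn_erev,
        system.kinetics.t_half, system.kinetics.t_slope,
        i_dep, i_hyp, n_dep,
        y0, s0, dt, n_steps,
        spike_threshold, spk_t, spk_n,
        rec_idx, trace_stride, state_rec,
        comp.post_npre, lfp_stride, isyn_rec,
    )
    if status == 1:
        raise RuntimeError(
            f"numerical blow-up in cell {bad_cell} at t={bad_step * dt:.3f} ms "
            f"(model {system.cells[bad_cell].model_id}, dt={dt})"
        )
    if status == 2:
        raise RuntimeError(
            f"spike buffer overflow in cell {bad_cell} at t={bad_step * dt:.3f} ms"
        )
    spikes = [spk_t[j, : spk_n[j]].copy() for j in range(comp.n_cells)]
    t_states = (
        np.arange(n_trace) * trace_stride * dt if trace_stride else np.zeros(1)
    )
    t_lfp = np.arange(n_lfp) * lfp_stride * dt if lfp_stride else np.zeros(1)
    return SimulationResult(
        dt=dt,
        protocol=protocol,
        labels=list(system.labels),
        spikes=spikes,
        t_states=t_states,
        states=state_rec,
        recorded_state_names=rec_names,
        t_lfp=t_lfp,
        isyn=isyn_rec,
        final_state=y0,
        state_offsets=list(comp.state_offsets),
    )


# --------------------------------------------------------------------------
# spike detection and classification
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ClassifierPreset:
    spike_threshold: float  # mV
    isi_ratio: float
    transient_ms: float


SINGLE_CELL_CLASSIFIER = ClassifierPreset(-10.0, 3.0, 500.0)
CIRCUIT_CLASSIFIER = ClassifierPreset(-20.0, 4.0, 1000.0)


def detect_spikes(t, v, threshold: float, transient_skip: float = 0.0) -> np.ndarray:
    """Upward threshold crossings of a voltage trace, after a transient window.

    Consecutive suprathreshold samples yield a single event, timed at the
    first suprathreshold sample.
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    if v.size == 0:
        raise ValueError("detect_spikes: empty trace")
    above = v >= threshold
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    times = t[crossings]
    return times[times >= transient_skip]


def classify_cell(spike_times, ratio: float) -> str:
    """silent / tonic / burst from the max-min interspike-interval rule.

    Fewer than two interspike intervals leave the ratio rule undefined; such
    spike trains are classified silent.
    """
    if ratio <= 1:
        raise ValueError("ISI ratio must exceed 1")
    st = np.asarray(spike_times, dtype=float)
    if st.size < 3:
        return "silent"
    isi = np.diff(st)
    return "burst" if isi.max() > ratio * isi.min() else "tonic"


def window_spikes(spike_times, t0: float, t1: float) -> np.ndarray:
    st = np.asarray(spike_times, dtype=float)
    return st[(st >= t0) & (st < t1)]


def epoch_patterns(
    result: SimulationResult, cell: int, preset: ClassifierPreset
) -> tuple[str, str]:
    """(depolarized-epoch, hyperpolarized-epoch) firing pattern of one cell."""
    p = result.protocol
    dep = window_spikes(result.spikes[cell], preset.transient_ms, p.t_depol)
    hyp = window_spikes(
        result.spikes[cell], p.t_depol + preset.transient_ms, p.duration
    )
    return classify_cell(dep, preset.isi_ratio), classify_cell(hyp, preset.isi_ratio)


def burst_intervals(spike_times, ratio: float) -> list[tuple[float, float]]:
    """Decompose a spike train into burst extents [(t_start, t_end), ...].

    An interspike interval larger than ratio * min(ISI) terminates a burst
    (the same statistic the classifier uses; no extra parameter).
    """
    st = np.asarray(spike_times, dtype=float)
    if st.size < 3:
        return []
    isi = np.diff(st)
    gap = ratio * isi.min()
    bursts = []
    start = st[0]
    for k in range(isi.size):
        if isi[k] > gap:
            bursts.append((start, st[k]))
            start = st[k + 1]
    bursts.append((start, st[-1]))
    return bursts


def _overlap_fraction(bursts_a, bursts_b) -> float:
    if not bursts_a:
        return 0.0
    hit = 0
    for a0, a1 in bursts_a:
        if any(b0 <= a1 and a0 <= b1 for b0, b1 in bursts_b):
            hit += 1
    return hit / len(bursts_a)


def classify_circuit_transition(
    depol_patterns: dict,
    hyper_patterns: dict,
    hyper_spikes: Optional[dict] = None,
    ratio: float = CIRCUIT_CLASSIFIER.isi_ratio,
    min_overlap: float = 0.5,
) -> bool:
    """True iff the circuit shows the rhythmic switch.

    Depolarized epoch: E silent, I tonic.  Hyperpolarized epoch: both cells
    bursting, and (when spike trains are given) synchronously so: the mean
    of the two burst-overlap fractions (share of each cell's bursts that
    overlap in time a burst of the other cell) must reach ``min_overlap``.
    The mean, rather than a per-cell requirement, keeps n:1 phase-locked
    rhythms — where every burst of the sparser cell coincides with a burst
    of the denser one — classified as synchronous, while antiphase
    (alternating) bursting still fails.
    """
    for d in (depol_patterns, hyper_patterns):
        if set(d) != {"E", "I"}:
            raise ValueError("patterns must be given for exactly one E and one I cell")
    if depol_patterns["E"] != "silent" or depol_patterns["I"] != "tonic":
        return False
    if hyper_patterns["E"] != "burst" or hyper_patterns["I"] != "burst":
        return False
    if hyper_spikes is not None:
        be = burst_intervals(hyper_spikes["E"], ratio)
        bi = burst_intervals(hyper_spikes["I"], ratio)
        sync = 0.5 * (_overlap_fraction(be, bi) + _overlap_fraction(bi, be))
        if sync < min_overlap:
            return False
    return True


@dataclass
class PatternMetrics:
    tonic_frequency_hz: Optional[float] = None
    intraburst_frequency_hz: Optional[float] = None
    interburst_interval_ms: Optional[float] = None
    bursts_per_second: Optional[float] = None


def pattern_metrics(
    spike_times, pattern: str, ratio: float = 4.0, window_ms: Optional[float] = None
) -> PatternMetrics:
    """Frequency metrics of a classified spike train.

    Silent trains have no metrics.  Tonic: firing rate from the mean ISI.
    Burst: intra-burst rate from within-burst ISIs, mean interval between
    consecutive burst onsets minus burst overlap (= gap between bursts), and
    burst rate over the analysis window (spike-train span when no window is
    given).
    """
    st = np.asarray(spike_times, dtype=float)
    m = PatternMetrics()
    if pattern == "silent" or st.size < 3:
        return m
    isi = np.diff(st)
    if pattern == "tonic":
        m.tonic_frequency_hz = 1000.0 / isi.mean()
        return m
    bursts = burst_intervals(st, ratio)
    gap = ratio * isi.min()
    within = isi[isi <= gap]
    between = isi[isi > gap]
    if within.size:
        m.intraburst_frequency_hz = 1000.0 / within.mean()
    if between.size:
        m.interburst_interval_ms = float(between.mean())
    span = window_ms if window_ms is not None else (st[-1] - st[0])
    if span > 0:
        m.bursts_per_second = 1000.0 * len(bursts) / span
    return m


# --------------------------------------------------------------------------
# currentscape
# --------------------------------------------------------------------------


def currentscape_shares(current_traces: dict):
    """Percentage contribution of each current to total inward/outward flow.

    ``current_traces`` maps current name -> signed trace (negative = inward
    by the membrane convention).  Returns (inward_shares, outward_shares,
    total_inward, total_outward); shares are 0 where the corresponding total
    vanishes.  Totals are returned in linear units (plot them logarithmically
    for display).
    """
    names = list(current_traces)
    arr = np.vstack([np.asarray(current_traces[n], dtype=float) for n in names])
    inward = np.where(arr < 0, -arr, 0.0)
    outward = np.where(arr > 0, arr, 0.0)
    tot_in = inward.sum(axis=0)
    tot_out = outward.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sh_in = np.where(tot_in > 0, inward / np.where(tot_in > 0, tot_in, 1.0), 0.0)
        sh_out = np.where(
            tot_out > 0, outward / np.where(tot_out > 0, tot_out, 1.0), 0.0
        )
    inward_shares = {n: 100.0 * sh_in[k] for k, n in enumerate(names)}
    outward_shares = {n: 100.0 * sh_out[k] for k, n in enumerate(names)}
    return inward_shares, outward_shares, tot_in, tot_out
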