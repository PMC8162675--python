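"""E-I population networks, LFP post-processing and mean-field switch detection.

The network mirrors the thalamic motif: a population of excitatory (relay)
cells all-to-all connected to a population of inhibitory (reticular) cells
through AMPA synapses, with the inhibitory cells projecting back GABA_A and
GABA_B synapses; no intra-population edges.  The applied current drives the
inhibitory population.  The local field potential is the double-normalized
sum of received postsynaptic currents of one population (the inhibitory one
by default), low-pass filtered at 100 Hz with a fourth-order Butterworth
filter, and inspected through a short-time-Fourier-transform spectrogram.
A mean-field switch is declared when low-frequency band power in the
hyperpolarized epoch dominates the depolarized epoch.

Nominal synaptic weights are divided by the presynaptic population size, so
that a homogeneous network of any size receives circuit-scale synaptic
drive; a 1+1-cell "network" is then exactly the 2-cell circuit.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .channel_models import NeuronModel, scale_cat_tau
from .sim_engine import (
    CIRCUIT_CLASSIFIER,
    StepProtocol,
    Synapse,
    System,
    integrate,
)
from .synapse_lfp import SynapticWeights, population_lfp
from .variability_sampling import (
    nominal_circuit_weights,
    sample_intrinsic,
    sample_synaptic,
)

__all__ = [
    "NetworkSpec",
    "NetworkResult",
    "build_network",
    "network_system",
    "simulate_network",
    "lowpass_lfp",
    "lfp_spectrogram",
    "detect_mean_field_switch",
    "calibrated_power_floor",
    "heterogeneity_tau_table",
]

#: default oscillation band (Hz) for switch detection
OSCILLATION_BAND = (1.0, 15.0)
#: hyperpolarized/depolarized band-power ratio declaring a switch
SWITCH_POWER_RATIO = 10.0


@dataclass
class NetworkSpec:
    """Cells and connection weights of one sampled E-I network."""

    n_e: int
    n_i: int
    cells_e: list  # NeuronModel per excitatory cell
    cells_i: list
    w_ampa: np.ndarray  # (n_e, n_i) E->I weights
    w_gabaa: np.ndarray  # (n_i, n_e) I->E weights
    w_gabab: np.ndarray  # (n_i, n_e)
    heterogeneity: float
    seed: Optional[int]
    model_id: str

    def __post_init__(self):
        assert self.w_ampa.shape == (self.n_e, self.n_i)
        assert self.w_gabaa.shape == (self.n_i, self.n_e)
        assert self.w_gabab.shape == (self.n_i, self.n_e)


@dataclass
class NetworkResult:
    t_lfp: np.ndarray  # ms
    lfp_raw: np.ndarray
    lfp_filtered: np.ndarray
    spec_f: np.ndarray  # Hz
    spec_t: np.ndarray  # ms
    spec_power: np.ndarray  # (n_f, n_t), >= 0
    switch: bool
    band_power_ratio: float
    spikes: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)


def build_network(
    model: NeuronModel,
    n_e: int,
    n_i: int,
    width: float,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> NetworkSpec:
    """Sample a network; ``width`` 0 gives the homogeneous network.

    Per-neuron conductances are drawn as in the intrinsic-variability rule,
    per-connection weights as in the synaptic-plasticity rule; nominal
    weights are divided by the presynaptic count (see module docstring).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    nominal = nominal_circuit_weights(model)
    scaled = SynapticWeights(
        g_ampa=nominal.g_ampa / n_e,
        g_gabaa=nominal.g_gabaa / n_i,
        g_gabab=nominal.g_gabab / n_i,
    )
    if width == 0:
        cells_e = [copy.deepcopy(model) for _ in range(n_e)]
        cells_i = [copy.deepcopy(model) for _ in range(n_i)]
        w_ampa = np.full((n_e, n_i), scaled.g_ampa)
        w_gabaa = np.full((n_i, n_e), scaled.g_gabaa)
        w_gabab = np.full((n_i, n_e), scaled.g_gabab)
    else:
        cells_e = [sample_intrinsic(model, width, rng) for _ in range(n_e)]
        cells_i = [sample_intrinsic(model, width, rng) for _ in range(n_i)]
        w_ampa = np.empty((n_e, n_i))
        w_gabaa = np.empty((n_i, n_e))
        w_gabab = np.empty((n_i, n_e))
        for i in range(n_e):
            for j in range(n_i):
                w_ampa[i, j] = sample_synaptic(scaled, rng).g_ampa
        for i in range(n_i):
            for j in range(n_e):
                ws = sample_synaptic(scaled, rng)
                w_gabaa[i, j] = ws.g_gabaa
                w_gabab[i, j] = ws.g_gabab
    return NetworkSpec(
        n_e=n_e, n_i=n_i, cells_e=cells_e, cells_i=cells_i,
        w_ampa=w_ampa, w_gabaa=w_gabaa, w_gabab=w_gabab,
        heterogeneity=width, seed=seed, model_id=model.model_id,
    )


def network_system(spec: NetworkSpec) -> System:
    """Flatten a NetworkSpec into a System (E cells first, then I cells)."""
    cells = list(spec.cells_e) + list(spec.cells_i)
    labels = ["E"] * spec.n_e + ["I"] * spec.n_i
    synapses = []
    for i in range(spec.n_e):
        for j in range(spec.n_i):
            synapses.append(Synapse(i, spec.n_e + j, "ampa", float(spec.w_ampa[i, j])))
    for i in range(spec.n_i):
        for j in range(spec.n_e):
            synapses.append(Synapse(spec.n_e + i, j, "gabaa", float(spec.w_gabaa[i, j])))
            synapses.append(Synapse(spec.n_e + i, j, "gabab", float(spec.w_gabab[i, j])))
    return System(cells=cells, synapses=synapses, labels=labels)


def default_network_protocol(model: NeuronModel, t_epoch: float = 21_000.0) -> StepProtocol:
    p = model.presets.get("circuit", {})
    return StepProtocol(
        i_depol=p.get("i_depol", 2.0),
        i_hyper=p.get("i_hyper", -1.0),
        t_depol=t_epoch,
        t_hyper=t_epoch,
        targets=None,  # resolved to the I population by simulate_network
    )


def simulate_network(
    spec: NetworkSpec,
    protocol: Optional[StepProtocol] = None,
    dt: Optional[float] = None,
    lfp_population: str = "I",
    band: tuple = OSCILLATION_BAND,
    power_ratio: float = SWITCH_POWER_RATIO,
    power_floor: float = 0.0,
    window_ms: float = 1000.0,
    overlap: float = 0.9,
    lfp_dt: float = 0.5,
) -> NetworkResult:
    """Integrate the network, compute the LFP chain and detect the switch."""
    model0 = spec.cells_i[0]
    if protocol is None:
        protocol = default_network_protocol(model0)
    if dt is None:
        dt = min(m.recommended_dt for m in spec.cells_e + spec.cells_i)
    system = network_system(spec)
    i_cells = [k for k, l in enumerate(system.labels) if l == "I"]
    protocol = StepProtocol(
        protocol.i_depol, protocol.i_hyper, protocol.t_depol, protocol.t_hyper,
        targets=i_cells,
    )
    res = integrate(
        system, protocol, dt,
        spike_threshold=CIRCUIT_CLASSIFIER.spike_threshold, lfp_dt=lfp_dt,
    )
    pop = [k for k, l in enumerate(system.labels) if l == lfp_population]
    # received synaptic current per postsynaptic cell, paper sign convention
    lfp = population_lfp(-res.isyn[:, pop].T)
    fs = 1000.0 / lfp_dt  # Hz
    filtered = lowpass_lfp(lfp, fs)
    f, t_s, power = lfp_spectrogram(filtered, fs, window_ms=window_ms, overlap=overlap)
    switch, ratio = detect_mean_field_switch(
        f, t_s * 1000.0, power, protocol.t_depol,
        band=band, power_ratio=power_ratio, power_floor=power_floor,
    )
    return NetworkResult(
        t_lfp=res.t_lfp,
        lfp_raw=lfp,
        lfp_filtered=filtered,
        spec_f=f,
        spec_t=t_s * 1000.0,
        spec_power=power,
        switch=switch,
        band_power_ratio=ratio,
        spikes=res.spikes,
        metadata={
            "model_id": spec.model_id,
            "n_e": spec.n_e, "n_i": spec.n_i,
            "heterogeneity": spec.heterogeneity,
            "seed": spec.seed, "dt": dt,
            "band": band, "power_ratio": power_ratio, "power_floor": power_floor,
        },
    )


def lowpass_lfp(
    lfp: np.ndarray,
    fs: float,
    cutoff: float = 100.0,
    order: int = 4,
    zero_phase: bool = True,
) -> np.ndarray:
    """Fourth-order Butterworth low-pass (zero-phase by default)."""
    if fs <= 2 * cutoff:
        raise ValueError(f"sampling rate {fs} Hz too low for a {cutoff} Hz cutoff")
    sos = signal.butter(order, cutoff, btype="low", fs=fs, output="sos")
    if zero_phase:
        return signal.sosfiltfilt(sos, lfp)
    return signal.sosfilt(sos, lfp)


def lfp_spectrogram(
    x: np.ndarray, fs: float, window_ms: float = 1000.0, overlap: float = 0.9
):
    """Short-time-Fourier-transform power of the filtered LFP.

    Returns (frequencies Hz, window centres s, power). Power is linear;
    display it on a log scale.
    """
    nper = max(16, int(round(window_ms / 1000.0 * fs)))
    nover = int(nper * overlap)
    f, t, sxx = signal.spectrogram(
        x - np.mean(x), fs=fs, window="hann", nperseg=nper, noverlap=nover,
        scaling="density", mode="psd",
    )
    return f, t, sxx


def detect_mean_field_switch(
    f: np.ndarray,
    t_ms: np.ndarray,
    power: np.ndarray,
    t_depol_ms: float,
    band: tuple = OSCILLATION_BAND,
    power_ratio: float = SWITCH_POWER_RATIO,
    power_floor: float = 0.0,
    transient_ms: float = 1000.0,
    guard_ms: float = 500.0,
):
    """Band-power comparison between the two protocol epochs.

    The switch flag is true iff the maximal oscillation-band power after the
    hyperpolarizing step exceeds ``power_ratio`` times the maximum during
    the depolarized epoch and the absolute ``power_floor``.  ``guard_ms``
    keeps spectrogram windows whose support straddles the step out of the
    depolarized epoch (half the default window length).
    Returns (flag, band_power_ratio).
    """
    in_band = (f >= band[0]) & (f <= band[1])
    if not np.any(in_band):
        raise ValueError("oscillation band empty for this spectrogram resolution")
    p_band = power[in_band].mean(axis=0)
    dep = (t_ms >= transient_ms) & (t_ms < t_depol_ms - guard_ms)
    hyp = t_ms >= t_depol_ms + transient_ms
    if not np.any(dep) or not np.any(hyp):
        raise ValueError("both protocol epochs must be present after transient removal")
    p_dep = float(p_band[dep].max())
    p_hyp = float(p_band[hyp].max())
    ratio = p_hyp / p_dep if p_dep > 0 else np.inf
    return bool(ratio >= power_ratio and p_hyp > power_floor), ratio


def calibrated_power_floor(
    model: NeuronModel,
    n_e: int,
    n_i: int,
    seed: int = 0,
    t_epoch: float = 21_000.0,
    fraction: float = 0.01,
) -> float:
    """Absolute band-power floor: ``fraction`` of the homogeneous nominal
    network's hyperpolarized-epoch oscillation power (the detector's own
    positive control)."""
    proto = default_network_protocol(model, t_epoch)
    res = simulate_network(build_network(model, n_e, n_i, 0.0, seed=seed), proto)
    in_band = (res.spec_f >= OSCILLATION_BAND[0]) & (res.spec_f <= OSCILLATION_BAND[1])
    hyp = res.spec_t >= proto.t_depol + 1000.0
    return fraction * float(res.spec_power[in_band][:, hyp].mean(axis=0).max())


def heterogeneity_tau_table(
    model: NeuronModel,
    widths: Sequence[float] = tuple(range(0, 55, 5)),
    etas: Sequence[float] = (1/8, 1/5, 1/4, 1/3, 1/2, 1, 2, 3, 4, 5, 8),
    n_e: int = 100,
    n_i: int = 100,
    seed: int = 0,
    t_epoch: float = 21_000.0,
    floor_fraction: float = 0.01,
) -> pd.DataFrame:
    """Largest heterogeneity width preserving the switch, per tau scaling.

    The absolute power floor is calibrated on the homogeneous nominal
    network (eta = 1, width 0): ``floor_fraction`` of its hyperpolarized
    band power.  For each eta, widths are scanned in increasing order until
    the first failure; the last switching width is reported (-1 when even
    the homogeneous network fails).
    """
    if not model.has_slow_cat_activation():
        raise ValueError("tau scaling requires a dynamic CaT activation")
    proto = default_network_protocol(model, t_epoch)
    floor = calibrated_power_floor(
        model, n_e, n_i, seed=seed, t_epoch=t_epoch, fraction=floor_fraction
    )
    rows = []
    for eta in etas:
        m_eta = scale_cat_tau(model, eta)
        dt = model.recommended_dt * min(1.0, max(eta, 0.1))
        largest = -1.0
        for width in sorted(widths):
            spec = build_network(
                m_eta, n_e, n_i, width,
                rng=np.random.default_rng(
                    np.random.SeedSequence(entropy=seed, spawn_key=(int(round(width)),))
                ),
            )
            res = simulate_network(spec, proto, dt=dt, power_floor=floor)
            if res.switch:
                largest = width
            else:
                break
        rows.append({"eta": eta, "largest_switching_width": largest})
    return pd.DataFrame(rows)
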