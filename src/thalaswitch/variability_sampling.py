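"""Monte-Carlo variability sampling and robustness screens.

Neuromodulation is emulated by drawing every maximal ionic conductance
uniformly in a band of +/- w% around its nominal value; synaptic plasticity
by drawing every synaptic weight uniformly in [g - g/8, g + g/8].  The
module provides the three robustness screens built on this sampling:

- ``capacitance_scan``: which membrane-capacitance scalings still allow the
  single-cell tonic-to-burst switch (searching over a small grid of applied
  currents at each scaling);
- ``circuit_switch_screen``: fraction of random 2-cell E-I circuits that
  keep the rhythmic transition (silent/tonic then synchronous bursting);
- ``tau_scaling_screen``: the same fixed set of random circuits re-simulated
  while the T-type calcium activation time constant is scaled by a factor
  eta, giving robustness as a function of the activation timescale.

Every screen derives per-circuit sub-seeds from a master seed with a counter
scheme, so results are reproducible and any single circuit can be replayed.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .channel_models import NeuronModel, TimescaleAnchors, scale_cat_tau, timescale_anchors
from .sim_engine import (
    CIRCUIT_CLASSIFIER,
    SINGLE_CELL_CLASSIFIER,
    ClassifierPreset,
    StepProtocol,
    System,
    classify_circuit_transition,
    epoch_patterns,
    integrate,
    single_cell_system,
    two_cell_circuit,
    window_spikes,
)
from .synapse_lfp import SynapticWeights

__all__ = [
    "VariabilitySpec",
    "ScreenResult",
    "sample_intrinsic",
    "sample_synaptic",
    "nominal_circuit_weights",
    "build_circuit",
    "circuit_protocol",
    "simulate_and_classify_circuit",
    "capacitance_scan",
    "circuit_switch_screen",
    "tau_scaling_screen",
    "normalized_log_position",
]

SYNAPTIC_HALFWIDTH = 1.0 / 8.0  # printed plasticity rule: +/- g/8

#: full-scale epoch durations (ms) of the circuit experiments
FULL_EPOCH_MS = 41_000.0


@dataclass(frozen=True)
class VariabilitySpec:
    """Sampling conditions of a robustness screen.

    ``intrinsic_width`` is a percentage (10 means +/-10%); epochs can be
    shortened for desk-scale runs (transients are preserved by the circuit
    classifier preset regardless of epoch length).
    """

    intrinsic_width: float
    n_samples: int
    seed: int
    t_depol: float = FULL_EPOCH_MS
    t_hyper: float = FULL_EPOCH_MS
    independent_cells: bool = True  # sample E and I conductances independently

    def __post_init__(self):
        if self.intrinsic_width < 0:
            raise ValueError("variability width must be >= 0")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


@dataclass
class ScreenResult:
    """Tabular outcome of a robustness screen."""

    condition_name: str
    conditions: list
    rhythmic: list  # count per condition
    totals: list
    seed: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        for r, t in zip(self.rhythmic, self.totals):
            if not (0 <= r <= t):
                raise ValueError("rhythmic counts must lie in [0, total]")

    @property
    def percent(self) -> np.ndarray:
        return 100.0 * np.asarray(self.rhythmic) / np.asarray(self.totals)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                self.condition_name: self.conditions,
                "rhythmic": self.rhythmic,
                "total": self.totals,
                "percent": self.percent,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path) -> None:
        payload = {
            "condition_name": self.condition_name,
            "conditions": list(self.conditions),
            "rhythmic": [int(x) for x in self.rhythmic],
            "totals": [int(x) for x in self.totals],
            "seed": int(self.seed),
            "metadata": self.metadata,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


# --------------------------------------------------------------------------
# sampling
# --------------------------------------------------------------------------


def sample_intrinsic(model: NeuronModel, width: float, rng: np.random.Generator) -> NeuronModel:
    """Draw each maximal conductance uniformly in +/- ``width``% of nominal."""
    if width < 0:
        raise ValueError("width must be >= 0")
    w = width / 100.0
    new = copy.deepcopy(model)
    for cur in new.currents:
        cur.g_max = cur.g_max * (1.0 + w * (2.0 * rng.random() - 1.0))
    return new


def sample_synaptic(nominal: SynapticWeights, rng: np.random.Generator) -> SynapticWeights:
    """Draw each synaptic weight uniformly in [g - g/8, g + g/8]."""
    draw = lambda g: g * (1.0 + SYNAPTIC_HALFWIDTH * (2.0 * rng.random() - 1.0))
    return SynapticWeights(
        g_ampa=draw(nominal.g_ampa),
        g_gabaa=draw(nominal.g_gabaa),
        g_gabab=draw(nominal.g_gabab),
    )


def _subseed_rng(master_seed: int, counter: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=master_seed, spawn_key=(counter,)))


# --------------------------------------------------------------------------
# circuit assembly and classification
# --------------------------------------------------------------------------


def nominal_circuit_weights(model: NeuronModel) -> SynapticWeights:
    w = model.presets.get("circuit", {}).get("weights", {})
    return SynapticWeights.from_dict(w)


def build_circuit(
    model_e: NeuronModel, model_i: NeuronModel, weights: SynapticWeights
) -> System:
    return two_cell_circuit(
        model_e, model_i, weights.g_ampa, weights.g_gabaa, weights.g_gabab
    )


def circuit_protocol(model: NeuronModel, t_depol: float, t_hyper: float) -> StepProtocol:
    p = model.presets.get("circuit", {})
    return StepProtocol(
        i_depol=p.get("i_depol", 2.0),
        i_hyper=p.get("i_hyper", -1.0),
        t_depol=t_depol,
        t_hyper=t_hyper,
        targets=[1],  # the applied current drives the inhibitory cell only
    )


def simulate_and_classify_circuit(
    system: System,
    protocol: StepProtocol,
    dt: float,
    preset: ClassifierPreset = CIRCUIT_CLASSIFIER,
) -> bool:
    """Integrate a 2-cell circuit and apply the rhythmic-transition test."""
    try:
        res = integrate(system, protocol, dt, spike_threshold=preset.spike_threshold)
    except RuntimeError:
        return False  # numerical blow-up of an extreme sample: not rhythmic
    depE, hypE = epoch_patterns(res, 0, preset)
    depI, hypI = epoch_patterns(res, 1, preset)
    hyper_spikes = {
        "E": window_spikes(
            res.spikes[0], protocol.t_depol + preset.transient_ms, protocol.duration
        ),
        "I": window_spikes(
            res.spikes[1], protocol.t_depol + preset.transient_ms, protocol.duration
        ),
    }
    return classify_circuit_transition(
        {"E": depE, "I": depI},
        {"E": hypE, "I": hypI},
        hyper_spikes,
        preset.isi_ratio,
    )


# --------------------------------------------------------------------------
# screens
# --------------------------------------------------------------------------


def capacitance_scan(
    model: NeuronModel,
    factors: Sequence[float],
    i_app_multipliers: Sequence[float] = (0.5, 1.0, 2.0),
    t_depol: float = 1_500.0,
    t_hyper: float = 5_500.0,
    preset: ClassifierPreset = SINGLE_CELL_CLASSIFIER,
) -> dict:
    """Which capacitance scalings support the tonic-to-burst switch.

    For each factor, the cell is simulated under the single-cell two-epoch
    protocol for every (depolarizing, hyperpolarizing) amplitude pair in the
    grid preset_amplitudes x ``i_app_multipliers``; the factor is supported
    iff any pair classifies tonic then burst.  The time step is shrunk
    proportionally for small capacitance factors (explicit-Euler stability).

    Returns {"factors", "supported", "interval"} where interval is the
    largest contiguous supported factor range containing 1 (or None).
    """
    factors = list(factors)
    if min(factors) <= 0:
        raise ValueError("capacitance factors must be positive")
    p = model.presets.get("single_cell", {})
    i_dep0 = p.get("i_depol", 2.0)
    i_hyp0 = p.get("i_hyper", -1.0)
    supported = []
    for f in factors:
        m = copy.deepcopy(model)
        m.c_m *= f
        dt = model.recommended_dt * min(1.0, max(f, 0.02))
        m.recommended_dt = dt
        good = False
        for kd in i_app_multipliers:
            for kh in i_app_multipliers:
                proto = StepProtocol(kd * i_dep0, kh * i_hyp0, t_depol, t_hyper)
                try:
                    res = integrate(
                        single_cell_system(m), proto, dt,
                        spike_threshold=preset.spike_threshold,
                    )
                except RuntimeError:
                    continue
                dep, hyp = epoch_patterns(res, 0, preset)
                if dep == "tonic" and hyp == "burst":
                    good = True
                    break
            if good:
                break
        supported.append(good)
    interval = _contiguous_interval(factors, supported, around=1.0)
    if interval is None:
        raise RuntimeError(
            f"model {model.model_id}: nominal capacitance (factor 1) unsupported — "
            "model/preset inconsistency"
        )
    return {"factors": factors, "supported": supported, "interval": interval}


def _contiguous_interval(factors, supported, around=1.0):
    pairs = sorted(zip(factors, supported))
    runs = []
    run = []
    for f, s in pairs:
        if s:
            run.append(f)
        else:
            if run:
                runs.append(run)
            run = []
    if run:
        runs.append(run)
    lo = max((f for f, _ in pairs if f <= around), default=None)
    for r in runs:
        if r[0] <= around <= r[-1] or (lo is not None and lo in r):
            return (r[0], r[-1])
    return None


def _sampled_circuit(model: NeuronModel, width: float, rng, independent=True):
    me = sample_intrinsic(model, width, rng)
    mi = sample_intrinsic(model, width, rng) if independent else copy.deepcopy(me)
    w = sample_synaptic(nominal_circuit_weights(model), rng)
    return me, mi, w


def circuit_switch_screen(model: NeuronModel, spec: VariabilitySpec) -> ScreenResult:
    """Fraction of random E-I circuits keeping the rhythmic transition."""
    proto = circuit_protocol(model, spec.t_depol, spec.t_hyper)
    n_ok = 0
    for k in range(spec.n_samples):
        rng = _subseed_rng(spec.seed, k)
        me, mi, w = _sampled_circuit(
            model, spec.intrinsic_width, rng, spec.independent_cells
        )
        ok = simulate_and_classify_circuit(
            build_circuit(me, mi, w), proto, model.recommended_dt
        )
        n_ok += int(ok)
    return ScreenResult(
        condition_name="intrinsic_width_percent",
        conditions=[spec.intrinsic_width],
        rhythmic=[n_ok],
        totals=[spec.n_samples],
        seed=spec.seed,
        metadata={
            "model_id": model.model_id,
            "dt": model.recommended_dt,
            "t_depol": spec.t_depol,
            "t_hyper": spec.t_hyper,
        },
    )


def tau_scaling_screen(
    model: NeuronModel, etas: Sequence[float], spec: VariabilitySpec
) -> ScreenResult:
    """Re-simulate the same sampled circuits at each activation-tau scaling.

    The circuit sample (conductances + weights) is drawn once from the seed;
    each eta is applied to the T-type calcium activation time constant of
    both cells of every circuit.
    """
    if not model.has_slow_cat_activation():
        raise ValueError(
            f"model {model.model_id}: tau scaling requires a dynamic CaT activation"
        )
    proto = circuit_protocol(model, spec.t_depol, spec.t_hyper)
    draws = [
        _sampled_circuit(model, spec.intrinsic_width, _subseed_rng(spec.seed, k),
                         spec.independent_cells)
        for k in range(spec.n_samples)
    ]
    rhythmic = []
    for eta in etas:
        n_ok = 0
        for me, mi, w in draws:
            sys_k = build_circuit(scale_cat_tau(me, eta), scale_cat_tau(mi, eta), w)
            # slow kinetics scaled toward the fast limit stiffen the gating ODE
            dt = model.recommended_dt * min(1.0, max(eta, 0.1))
            n_ok += int(simulate_and_classify_circuit(sys_k, proto, dt))
        rhythmic.append(n_ok)
    return ScreenResult(
        condition_name="eta",
        conditions=list(etas),
        rhythmic=rhythmic,
        totals=[spec.n_samples] * len(etas),
        seed=spec.seed,
        metadata={
            "model_id": model.model_id,
            "intrinsic_width_percent": spec.intrinsic_width,
            "dt": model.recommended_dt,
            "t_depol": spec.t_depol,
            "t_hyper": spec.t_hyper,
        },
    )


#: tau multipliers of the circuit-level timescale screen
TAU_SCREEN_ETAS = (
    1 / 100, 1 / 50, 1 / 20, 1 / 10, 1 / 8, 1 / 5, 1 / 4, 1 / 3, 1 / 2, 1 / 1.5,
    1, 1.5, 2, 3, 4, 5, 8, 10, 20, 50, 100,
)


def normalized_log_position(anchors: TimescaleAnchors, eta: float) -> float:
    """Position of the scaled activation tau on the normalized log axis.

    0 at the fast anchor (sodium activation), 1 at the ultraslow anchor
    (T-type calcium inactivation); logarithmic in between and monotone in
    eta.
    """
    if eta <= 0:
        raise ValueError("eta must be positive")
    fast, ultra = anchors.fast, anchors.ultraslow
    if not (np.isfinite(fast) and np.isfinite(ultra)) or fast <= 0 or ultra <= fast:
        raise ValueError("anchors must be finite, positive and ordered")
    return float(
        (np.log(eta * anchors.tau_m_cat) - np.log(fast)) / (np.log(ultra) - np.log(fast))
    )
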