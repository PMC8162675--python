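"""Declarative single-compartment conductance-based neuron models.

A neuron model is a membrane capacitance plus a list of ionic currents

    C_m dV/dt = -sum_i I_i + I_app,
    I_i = g_max_i * m_i^p_i * h_i^q_i * (V - E_i),

where each gating variable either relaxes to its voltage-dependent steady
state with a voltage-dependent time constant,

    dX/dt = (X_inf(V) - X) / tau_X(V),

or is declared *instantaneous* and substituted algebraically by ``X_inf(V)``
at every right-hand-side evaluation (never integrated).  Calcium-gated
channels read a first-order intracellular calcium pool instead of voltage.

Units are fixed repo-wide: mV, ms, uA/cm^2, mS/cm^2, uF/cm^2, and uM for
calcium concentration.

The module also implements the two kinetic transformations this package is
built to study: restoring a slow, voltage-dependent activation time constant
to a T-type calcium channel that was simplified to instantaneous activation
(``make_restored_variant``), and scaling that time constant by a
multiplicative factor eta (``scale_cat_tau``).
"""

from __future__ import annotations

import copy
import math
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
import yaml

from ._formulas import Formula

__all__ = [
    "GatingSpec",
    "IonCurrentSpec",
    "CalciumPoolSpec",
    "NeuronModel",
    "TimescaleAnchors",
    "evaluate_gate",
    "membrane_rhs",
    "ionic_currents",
    "make_restored_variant",
    "scale_cat_tau",
    "timescale_anchors",
    "load_model",
    "load_builtin",
    "save_model",
    "available_models",
]

INSTANTANEOUS = "instantaneous"
CALCIUM_NERNST = "calcium-nernst"


@dataclass
class GatingSpec:
    """One activation or inactivation gate of an ionic current."""

    name: str
    kind: str  # "activation" | "inactivation"
    exponent: int
    steady_state: Formula
    time_constant: Union[Formula, str]  # Formula or "instantaneous"
    tau_scale: float = 1.0
    ca_dependent: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("activation", "inactivation"):
            raise ValueError(f"gate kind must be activation|inactivation, got {self.kind!r}")
        if self.exponent not in (1, 2, 3, 4):
            raise ValueError(f"gate exponent must be in 1..4, got {self.exponent}")
        if self.tau_scale <= 0:
            raise ValueError("tau_scale must be positive")
        if isinstance(self.time_constant, str) and self.time_constant != INSTANTANEOUS:
            raise ValueError(f"bad time_constant sentinel {self.time_constant!r}")

    @property
    def is_instantaneous(self) -> bool:
        return isinstance(self.time_constant, str)


@dataclass
class IonCurrentSpec:
    """A voltage-gated (or calcium-gated) ionic current."""

    name: str
    g_max: float
    reversal: Union[float, str]  # mV, or "calcium-nernst"
    gates: list[GatingSpec] = field(default_factory=list)
    calcium_source: bool = False  # contributes to calcium-pool influx

    def __post_init__(self) -> None:
        if self.g_max < 0:
            raise ValueError(f"g_max of {self.name} must be >= 0")
        if isinstance(self.reversal, str) and self.reversal != CALCIUM_NERNST:
            raise ValueError(f"bad reversal tag {self.reversal!r}")

    @property
    def calcium_dependent(self) -> bool:
        return any(g.ca_dependent for g in self.gates)


@dataclass
class CalciumPoolSpec:
    """First-order intracellular calcium dynamics.

    d[Ca]/dt = -influx_coupling * sum(I_Ca) - removal_rate * ([Ca] - resting_level)

    with [Ca] clamped at zero from below during integration.  ``external_level``
    and ``nernst_factor`` (RT/2F in mV) only matter for currents whose reversal
    is tagged "calcium-nernst".
    """

    influx_coupling: float
    removal_rate: float  # 1/ms
    resting_level: float  # uM
    external_level: float = 2000.0  # uM
    nernst_factor: float = 12.84  # mV (RT/2F near body temperature)


@dataclass
class NeuronModel:
    model_id: str
    c_m: float  # uF/cm^2
    currents: list[IonCurrentSpec]
    calcium_pool: Optional[CalciumPoolSpec] = None
    recommended_dt: float = 0.05  # ms
    # per-model threshold voltages at which timescale anchors are evaluated
    thresholds: dict = field(default_factory=dict)
    # per-model experiment presets (applied currents, synaptic weights, ...)
    presets: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = {c.name for c in self.currents}
        for required in ("Na", "K", "CaT", "leak"):
            if required not in names:
                raise ValueError(f"model {self.model_id}: missing required current {required}")
        leak = self.current("leak")
        if leak.gates:
            raise ValueError("leak current must have zero gates")
        if any(isinstance(c.reversal, str) for c in self.currents) and self.calcium_pool is None:
            raise ValueError("calcium-nernst reversal requires a calcium pool")
        if any(c.calcium_dependent for c in self.currents) and self.calcium_pool is None:
            raise ValueError("calcium-gated current requires a calcium pool")

    # ---- state layout: V, dynamic gates (model order), then [Ca] ---------

    def current(self, name: str) -> IonCurrentSpec:
        for c in self.currents:
            if c.name == name:
                return c
        raise KeyError(f"model {self.model_id} has no current {name!r}")

    def dynamic_gates(self) -> list[tuple[IonCurrentSpec, GatingSpec]]:
        return [(c, g) for c in self.currents for g in c.gates if not g.is_instantaneous]

    @property
    def n_state(self) -> int:
        return 1 + len(self.dynamic_gates()) + (1 if self.calcium_pool else 0)

    def state_names(self) -> list[str]:
        names = ["V"] + [g.name for _, g in self.dynamic_gates()]
        if self.calcium_pool:
            names.append("Ca")
        return names

    def initial_state(self, v0: float = -65.0) -> np.ndarray:
        """State with every dynamic gate at its steady value for ``v0``."""
        y = np.empty(self.n_state)
        y[0] = v0
        for k, (_, g) in enumerate(self.dynamic_gates()):
            x = g.steady_state(self.calcium_pool.resting_level if g.ca_dependent else v0)
            y[1 + k] = float(x)
        if self.calcium_pool:
            y[-1] = self.calcium_pool.resting_level
        return y

    def has_slow_cat_activation(self) -> bool:
        cat = self.current("CaT")
        act = _activation_gate(cat)
        return not act.is_instantaneous


@dataclass
class TimescaleAnchors:
    """Gating time constants evaluated at the model's threshold voltages.

    ``tau_m_na`` is None when sodium activation is instantaneous; the missing
    boundary is then substituted per ``substitute``:

    - "fast" (default): the fast anchor is taken as tau_m_cat / 100, reading
      the substituted boundary as the left (fast) one;
    - "ultraslow": the literal alternative, replacing the right boundary by
      tau_m_cat / 100 instead.
    """

    tau_m_na: Optional[float]
    tau_m_cat: float
    tau_h_cat: float
    v_th_act: float
    v_th_inact: float
    v_th_na: float
    substitute: str = "fast"

    @property
    def fast(self) -> float:
        if self.tau_m_na is None and self.substitute == "fast":
            return self.tau_m_cat / 100.0
        if self.tau_m_na is None:
            return self.tau_m_cat / 10000.0  # keeps ordering under the literal reading
        return self.tau_m_na

    @property
    def ultraslow(self) -> float:
        if self.tau_m_na is None and self.substitute == "ultraslow":
            return self.tau_m_cat / 100.0
        return self.tau_h_cat


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------


def evaluate_gate(spec: GatingSpec, v):
    """Return (steady_state, tau) of a gate at membrane voltage ``v`` (mV).

    ``tau`` is the sentinel "instantaneous" for instantaneous gates, otherwise
    the voltage-dependent time constant multiplied by the gate's tau_scale.
    """
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("evaluate_gate: membrane voltage must be finite")
    ss = spec.steady_state(v)
    if spec.is_instantaneous:
        return ss, INSTANTANEOUS
    return ss, spec.time_constant(v) * spec.tau_scale


def _gate_value(model: NeuronModel, cur: IonCurrentSpec, gate: GatingSpec, state, dyn_index):
    if gate.is_instantaneous:
        x = state[-1] if (gate.ca_dependent and model.calcium_pool) else state[0]
        return gate.steady_state(x)
    return state[1 + dyn_index[id(gate)]]


def _dyn_index(model: NeuronModel) -> dict:
    return {id(g): k for k, (_, g) in enumerate(model.dynamic_gates())}


def ionic_currents(model: NeuronModel, state) -> dict[str, np.ndarray]:
    """Per-current values at a state (or at a (n_state, T) array of states)."""
    state = np.asarray(state, dtype=float)
    v = state[0]
    idx = _dyn_index(model)
    out = {}
    for cur in model.currents:
        if isinstance(cur.reversal, str):
            pool = model.calcium_pool
            ca = np.maximum(state[-1], 1e-6)
            erev = pool.nernst_factor * np.log(pool.external_level / ca)
        else:
            erev = cur.reversal
        i = cur.g_max * (v - erev)
        for g in cur.gates:
            i = i * _gate_value(model, cur, g, state, idx) ** g.exponent
        out[cur.name] = i
    return out


def membrane_rhs(model: NeuronModel, state, i_app: float = 0.0) -> np.ndarray:
    """Time derivative of the full state vector (reference implementation).

    The compiled integration kernel in :mod:`thalaswitch.sim_engine` follows
    exactly this definition; this version is kept simple for root solving,
    cross-checking and small exploratory integrations.
    """
    state = np.asarray(state, dtype=float)
    if state.shape[0] != model.n_state:
        raise ValueError(
            f"state dimension {state.shape[0]} does not match model "
            f"{model.model_id} (expected {model.n_state})"
        )
    v = state[0]
    currents = ionic_currents(model, state)
    dy = np.zeros_like(state)
    dy[0] = (-sum(currents.values()) + i_app) / model.c_m
    for k, (_, g) in enumerate(model.dynamic_gates()):
        x = state[1 + k]
        drive = state[-1] if (g.ca_dependent and model.calcium_pool) else v
        ss, tau = evaluate_gate(g, drive)
        dy[1 + k] = (ss - x) / tau
    if model.calcium_pool:
        pool = model.calcium_pool
        i_ca = sum(currents[c.name] for c in model.currents if c.calcium_source)
        dy[-1] = -pool.influx_coupling * i_ca - pool.removal_rate * (
            state[-1] - pool.resting_level
        )
    return dy


def _activation_gate(cur: IonCurrentSpec) -> GatingSpec:
    for g in cur.gates:
        if g.kind == "activation":
            return g
    raise ValueError(f"current {cur.name} has no activation gate")


def _inactivation_gate(cur: IonCurrentSpec) -> GatingSpec:
    for g in cur.gates:
        if g.kind == "inactivation":
            return g
    raise ValueError(f"current {cur.name} has no inactivation gate")


def make_restored_variant(
    model: NeuronModel, tau_formula: Optional[Formula] = None
) -> NeuronModel:
    """Replace an instantaneous T-type calcium activation by a slow dynamic one.

    The steady-state activation curve is left untouched; only a differential
    equation dm/dt = (m_inf(V) - m)/tau(V) is attached.  When no explicit
    ``tau_formula`` is given, a bell-shaped time constant is constructed whose
    value at the calcium activation threshold is the geometric mean of the
    model's fast and ultraslow timescale anchors, i.e. squarely inside the
    slow band between sodium activation and T-type calcium inactivation.
    """
    cat = model.current("CaT")
    act = _activation_gate(cat)
    if not act.is_instantaneous:
        warnings.warn(
            f"model {model.model_id}: CaT activation already dynamic; returning a copy"
        )
        return copy.deepcopy(model)
    new = copy.deepcopy(model)
    if tau_formula is None:
        anchors = timescale_anchors(model)
        peak = math.sqrt(anchors.fast * anchors.ultraslow)
        v_th = model.thresholds.get("v_th_act", -60.0)
        tau_formula = Formula("gaussian", (0.2 * peak, 0.8 * peak, v_th, 30.0))
    new_cat = new.current("CaT")
    new_act = _activation_gate(new_cat)
    new_act.time_constant = tau_formula
    new.model_id = f"{model.model_id}p"
    return new


def scale_cat_tau(model: NeuronModel, eta: float) -> NeuronModel:
    """Scale the T-type calcium activation time constant by ``eta`` (> 0)."""
    if eta <= 0:
        raise ValueError("eta must be positive")
    act = _activation_gate(model.current("CaT"))
    if act.is_instantaneous:
        raise ValueError(
            f"model {model.model_id}: CaT activation is instantaneous; "
            "restore it before scaling its time constant"
        )
    new = copy.deepcopy(model)
    _activation_gate(new.current("CaT")).tau_scale = act.tau_scale * eta
    return new


def timescale_anchors(model: NeuronModel, substitute: str = "fast") -> TimescaleAnchors:
    """Fast / slow / ultraslow gating time constants at the threshold voltages.

    The comparison voltages are model configuration (``model.thresholds``):
    sodium activation is evaluated at the spike-initiation voltage, calcium
    activation at the spike-upstroke onset, calcium inactivation at the onset
    of the calcium spike.
    """
    th = model.thresholds
    v_na = th.get("v_th_na", -45.0)
    v_act = th.get("v_th_act", -60.0)
    v_inact = th.get("v_th_inact", -75.0)
    na_act = _activation_gate(model.current("Na"))
    cat = model.current("CaT")
    cat_act = _activation_gate(cat)
    cat_inact = _inactivation_gate(cat)
    tau_m_na = None
    if not na_act.is_instantaneous:
        tau_m_na = float(evaluate_gate(na_act, v_na)[1])
    if cat_act.is_instantaneous:
        # anchor of the *restored* kinetics band midpoint is undefined for the
        # instantaneous model; fall back to the inactivation anchor / 20 so the
        # anchors stay ordered and the fast substitution remains meaningful.
        tau_m_cat = float(evaluate_gate(cat_inact, v_inact)[1]) / 20.0
    else:
        tau_m_cat = float(evaluate_gate(cat_act, v_act)[1])
    tau_h_cat = float(evaluate_gate(cat_inact, v_inact)[1])
    return TimescaleAnchors(
        tau_m_na=tau_m_na,
        tau_m_cat=tau_m_cat,
        tau_h_cat=tau_h_cat,
        v_th_act=v_act,
        v_th_inact=v_inact,
        v_th_na=v_na,
        substitute=substitute,
    )


# --------------------------------------------------------------------------
# model description files
# --------------------------------------------------------------------------


def _gate_to_dict(g: GatingSpec) -> dict:
    d = {
        "name": g.name,
        "kind": g.kind,
        "exponent": g.exponent,
        "steady_state": g.steady_state.to_dict(),
        "time_constant": (
            INSTANTANEOUS if g.is_instantaneous else g.time_constant.to_dict()
        ),
    }
    if g.tau_scale != 1.0:
        d["tau_scale"] = g.tau_scale
    if g.ca_dependent:
        d["ca_dependent"] = True
    return d


def _gate_from_dict(d: dict) -> GatingSpec:
    tc = d["time_constant"]
    return GatingSpec(
        name=d["name"],
        kind=d["kind"],
        exponent=int(d["exponent"]),
        steady_state=Formula.from_dict(d["steady_state"]),
        time_constant=INSTANTANEOUS if tc == INSTANTANEOUS else Formula.from_dict(tc),
        tau_scale=float(d.get("tau_scale", 1.0)),
        ca_dependent=bool(d.get("ca_dependent", False)),
    )


def model_to_dict(model: NeuronModel) -> dict:
    d = {
        "format": "thalaswitch-model/1",
        "model_id": model.model_id,
        "c_m": model.c_m,
        "recommended_dt": model.recommended_dt,
        "thresholds": dict(model.thresholds),
        "currents": [
            {
                "name": c.name,
                "g_max": c.g_max,
                "reversal": c.reversal,
                **({"calcium_source": True} if c.calcium_source else {}),
                "gates": [_gate_to_dict(g) for g in c.gates],
            }
            for c in model.currents
        ],
        "presets": copy.deepcopy(model.presets),
    }
    if model.calcium_pool:
        p = model.calcium_pool
        d["calcium_pool"] = {
            "influx_coupling": p.influx_coupling,
            "removal_rate": p.removal_rate,
            "resting_level": p.resting_level,
            "external_level": p.external_level,
            "nernst_factor": p.nernst_factor,
        }
    return d


def model_from_dict(d: dict) -> NeuronModel:
    pool = None
    if "calcium_pool" in d:
        pool = CalciumPoolSpec(**d["calcium_pool"])
    return NeuronModel(
        model_id=str(d["model_id"]),
        c_m=float(d["c_m"]),
        currents=[
            IonCurrentSpec(
                name=c["name"],
                g_max=float(c["g_max"]),
                reversal=(
                    c["reversal"] if isinstance(c["reversal"], str) else float(c["reversal"])
                ),
                gates=[_gate_from_dict(g) for g in c.get("gates", [])],
                calcium_source=bool(c.get("calcium_source", False)),
            )
            for c in d["currents"]
        ],
        calcium_pool=pool,
        recommended_dt=float(d.get("recommended_dt", 0.05)),
        thresholds=dict(d.get("thresholds", {})),
        presets=dict(d.get("presets", {})),
    )


def save_model(model: NeuronModel, path) -> None:
    Path(path).write_text(yaml.safe_dump(model_to_dict(model), sort_keys=False))


def load_model(path) -> NeuronModel:
    return model_from_dict(yaml.safe_load(Path(path).read_text()))


def available_models() -> list[str]:
    pkg = resources.files("thalaswitch") / "models"
    return sorted(p.name[: -len(".yml")] for p in pkg.iterdir() if p.name.endswith(".yml"))


def load_builtin(model_id: str) -> NeuronModel:
    """Load a shipped model; ids ending in "p" are restored variants built on
    the fly from their instantaneous-activation parent."""
    pkg = resources.files("thalaswitch") / "models"
    f = pkg / f"model{model_id}.yml"
    if f.is_file():
        return model_from_dict(yaml.safe_load(f.read_text()))
    if model_id.endswith("p"):
        parent = load_builtin(model_id[:-1])
        return make_restored_variant(parent)
    raise KeyError(
        f"unknown model {model_id!r}; available: {available_models()} (+ 'p' variants)"
    )
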