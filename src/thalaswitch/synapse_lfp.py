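"""Kinetic AMPA / GABA_A / GABA_B synapses and the population LFP.

Each receptor follows first-order transmitter-driven kinetics

    ds/dt = rise * T_m(V_pre) * (1 - s) - decay * s,

with the transmitter-release sigmoid T_m(V_pre) = 1/(1 + exp(-(V_pre-2)/5)).
Rate constants (1/ms): AMPA 1.1 / 0.19, GABA_A 0.53 / 0.18, GABA_B
0.016 / 0.0047.  The postsynaptic current of receptor k is
g_k * s_k * (V_post - E_k) with reversals 0 mV (AMPA), -70 mV (chloride,
GABA_A) and -85 mV (potassium, GABA_B).

The local field potential of a population is the double-normalized sum of
received postsynaptic currents: each postsynaptic neuron's synaptic current is
the mean over its N presynaptic inputs, and the LFP is the mean of those over
the M postsynaptic neurons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RECEPTORS",
    "REVERSALS",
    "SynapseKinetics",
    "SynapseState",
    "SynapticWeights",
    "transmitter_concentration",
    "synapse_rhs",
    "postsynaptic_current",
    "population_lfp",
]

RECEPTORS = ("ampa", "gabaa", "gabab")

#: receptor reversal potentials (mV): AMPA 0, GABA_A at V_Cl, GABA_B at V_K
REVERSALS = {"ampa": 0.0, "gabaa": -70.0, "gabab": -85.0}


@dataclass(frozen=True)
class SynapseKinetics:
    """Rise/decay rate constants (1/ms) and transmitter sigmoid parameters."""

    rise: dict = field(
        default_factory=lambda: {"ampa": 1.1, "gabaa": 0.53, "gabab": 0.016}
    )
    decay: dict = field(
        default_factory=lambda: {"ampa": 0.19, "gabaa": 0.18, "gabab": 0.0047}
    )
    t_half: float = 2.0  # mV
    t_slope: float = 5.0  # mV

    def __post_init__(self):
        for r in RECEPTORS:
            if self.rise[r] <= 0 or self.decay[r] <= 0:
                raise ValueError("synaptic rate constants must be positive")

    def fixed_point(self, receptor: str, t_m: float = 1.0) -> float:
        """Steady gating fraction under sustained transmitter level t_m."""
        a = self.rise[receptor] * t_m
        return a / (a + self.decay[receptor])


NOMINAL_KINETICS = SynapseKinetics()


@dataclass
class SynapseState:
    s_ampa: float = 0.0
    s_gabaa: float = 0.0
    s_gabab: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.s_ampa, self.s_gabaa, self.s_gabab])


@dataclass
class SynapticWeights:
    """Maximal synaptic conductances (mS/cm^2) of the three receptors."""

    g_ampa: float = 0.0
    g_gabaa: float = 0.0
    g_gabab: float = 0.0

    def __post_init__(self):
        if min(self.g_ampa, self.g_gabaa, self.g_gabab) < 0:
            raise ValueError("synaptic conductances must be >= 0")

    def as_dict(self) -> dict:
        return {"ampa": self.g_ampa, "gabaa": self.g_gabaa, "gabab": self.g_gabab}

    @classmethod
    def from_dict(cls, d: dict) -> "SynapticWeights":
        return cls(
            g_ampa=float(d.get("ampa", 0.0)),
            g_gabaa=float(d.get("gabaa", 0.0)),
            g_gabab=float(d.get("gabab", 0.0)),
        )


def transmitter_concentration(v_pre, kinetics: SynapseKinetics = NOMINAL_KINETICS):
    """Released-transmitter fraction as a sigmoid of presynaptic voltage."""
    v_pre = np.asarray(v_pre, dtype=float)
    return 1.0 / (1.0 + np.exp(-(v_pre - kinetics.t_half) / kinetics.t_slope))


def synapse_rhs(
    state: SynapseState, v_pre: float, kinetics: SynapseKinetics = NOMINAL_KINETICS
) -> np.ndarray:
    """Derivatives (ds_AMPA, ds_GABAA, ds_GABAB)/dt for one presynaptic cell."""
    t_m = transmitter_concentration(v_pre, kinetics)
    s = state.as_array()
    rise = np.array([kinetics.rise[r] for r in RECEPTORS])
    decay = np.array([kinetics.decay[r] for r in RECEPTORS])
    return rise * t_m * (1.0 - s) - decay * s


def postsynaptic_current(
    state: SynapseState, v_post: float, weights: SynapticWeights
) -> float:
    """Total receptor current onto a postsynaptic cell (positive = outward)."""
    s = state.as_array()
    g = np.array([weights.g_ampa, weights.g_gabaa, weights.g_gabab])
    erev = np.array([REVERSALS[r] for r in RECEPTORS])
    return float(np.sum(g * s * (v_post - erev)))


def population_lfp(per_neuron_synaptic_currents) -> np.ndarray:
    """LFP trace from the received synaptic current of each postsynaptic cell.

    ``per_neuron_synaptic_currents`` is an (M, T) array where row j is neuron
    j's synaptic current already averaged over its N presynaptic inputs; the
    LFP is the mean over the M postsynaptic neurons.
    """
    arr = np.atleast_2d(np.asarray(per_neuron_synaptic_currents, dtype=float))
    if arr.shape[0] == 0 or arr.size == 0:
        raise ValueError("population_lfp: empty population")
    return arr.mean(axis=0)
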