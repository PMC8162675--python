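"""Parametric formula families used by gating variables.

Model description files declare steady-state and time-constant curves as
named members of a small, versioned set of parametric families, so that model
files stay portable across implementations.  Each family has a fixed-length
parameter vector (padded with zeros) and an integer code shared with the
compiled integration kernel.

Steady-state families (argument: membrane voltage in mV, or calcium
concentration for calcium-gated channels):

``boltzmann(v_half, slope)``
    ``1 / (1 + exp((V - v_half)/slope))``.  A negative slope gives a curve
    increasing with depolarization (activation); a positive slope gives an
    inactivation-shaped curve.
``hill(k_half, n)``
    ``x^n / (x^n + k_half^n)`` — saturating dependence on intracellular
    calcium, used by calcium-gated potassium channels.

Time-constant families (argument: membrane voltage in mV; output in ms):

``constant(tau)``
``gaussian(base, amp, v_peak, width)``
    ``base + amp * exp(-((V - v_peak)/width)^2)`` — the generic bell shape.
``biexp(base, amp, v1, k1, v2, k2)``
    ``base + amp / (exp((V - v1)/k1) + exp(-(V - v2)/k2))`` — the classic
    double-exponential bell used for T-type calcium activation kinetics.
``sigmoid(base, amp, v_half, slope)``
    ``base + amp / (1 + exp((V - v_half)/slope))`` — monotone time constants
    (e.g. inactivation recovery that slows with hyperpolarization).
``gauss2(base, a1, v1, w1, a2, v2, w2)``
    Sum of two Gaussian bells — time constants with a subthreshold and a
    hyperpolarized peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["Formula", "SS_FAMILIES", "TAU_FAMILIES", "NPAR"]

# fixed parameter-vector length in the compiled kernel
NPAR = 8

SS_FAMILIES = {"boltzmann": 0, "hill": 1}
TAU_FAMILIES = {"constant": 0, "gaussian": 1, "biexp": 2, "sigmoid": 3, "gauss2": 4}

_ARITY = {
    "boltzmann": 2,
    "hill": 2,
    "constant": 1,
    "gaussian": 4,
    "biexp": 6,
    "sigmoid": 4,
    "gauss2": 7,
}


@dataclass(frozen=True)
class Formula:
    """A named parametric curve, callable on scalars or arrays."""

    family: str
    params: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.family not in _ARITY:
            raise ValueError(f"unknown formula family {self.family!r}")
        if len(self.params) != _ARITY[self.family]:
            raise ValueError(
                f"family {self.family!r} takes {_ARITY[self.family]} "
                f"parameters, got {len(self.params)}"
            )
        object.__setattr__(self, "params", tuple(float(p) for p in self.params))

    def __call__(self, x):
        p = self.params
        x = np.asarray(x, dtype=float)
        if self.family == "boltzmann":
            return 1.0 / (1.0 + np.exp((x - p[0]) / p[1]))
        if self.family == "hill":
            xn = np.maximum(x, 0.0) ** p[1]
            return xn / (xn + p[0] ** p[1])
        if self.family == "constant":
            return np.broadcast_to(np.float64(p[0]), x.shape).copy() if x.shape else np.float64(p[0])
        if self.family == "gaussian":
            return p[0] + p[1] * np.exp(-(((x - p[2]) / p[3]) ** 2))
        if self.family == "biexp":
            return p[0] + p[1] / (np.exp((x - p[2]) / p[3]) + np.exp(-(x - p[4]) / p[5]))
        if self.family == "sigmoid":
            return p[0] + p[1] / (1.0 + np.exp((x - p[2]) / p[3]))
        if self.family == "gauss2":
            return (
                p[0]
                + p[1] * np.exp(-(((x - p[2]) / p[3]) ** 2))
                + p[4] * np.exp(-(((x - p[5]) / p[6]) ** 2))
            )
        raise AssertionError(self.family)

    # ---- kernel packing -------------------------------------------------

    def code(self, table: dict[str, int]) -> int:
        return table[self.family]

    def packed(self) -> np.ndarray:
        out = np.zeros(NPAR)
        out[: len(self.params)] = self.params
        return out

    # ---- (de)serialization ----------------------------------------------

    def to_dict(self) -> dict:
        return {"family": self.family, "params": list(self.params)}

    @classmethod
    def from_dict(cls, d: dict | Sequence) -> "Formula":
        return cls(family=d["family"], params=tuple(d["params"]))
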