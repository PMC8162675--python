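"""Three-timescale model reduction and slow-fast phase-portrait analysis.

Any shipped conductance-based model is reduced to three variables: the
membrane voltage V, a slow filtered voltage V_s and an ultraslow filtered
voltage V_u,

    C_m dV/dt  = -sum_i I_i(V, V_s, V_u) + I_app
        dV_s/dt = (V - V_s) / tau_s(V)
        dV_u/dt = (V - V_u) / tau_u(V)

where the potassium activation time constant paces the slow variable
(tau_s = tau_mK) and the T-type calcium inactivation paces the ultraslow one
(tau_u = tau_hCaT).  The fast timescale is paced by sodium activation
(tau_f = tau_mNa), or by tau_mK/10 in models whose sodium activation is
instantaneous.  Each gating variable X is replaced by a weighted sum

    X = w_fs X_inf(V) + (w_su - w_fs) X_inf(V_s) + (1 - w_su) X_inf(V_u)

whose voltage-dependent weights are the logarithmic distances of the gate's
own time constant tau_X(V) to the three pacing time constants:

    tau_X <= tau_f          -> w_fs = 1,                      w_su = 1
    tau_f < tau_X <= tau_s  -> w_fs = log(tau_s/tau_X)/log(tau_s/tau_f), w_su = 1
    tau_s < tau_X <= tau_u  -> w_fs = 0, w_su = log(tau_u/tau_X)/log(tau_u/tau_s)
    tau_X > tau_u           -> w_fs = 0,                      w_su = 0

The slow-fast phase portrait lives in the (V_s, V) plane at frozen V_u: the
V-nullcline is the zero set of dV/dt, the V_s-nullcline the diagonal
V_s = V.  The saddle-node bifurcation of the fast-slow subsystem is located
as the fold of the equilibrium curve (dV/dt = 0 on the diagonal) where the
determinant of the 2-variable Jacobian vanishes.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import optimize

from .channel_models import (
    NeuronModel,
    _activation_gate,
    _inactivation_gate,
    evaluate_gate,
)
from .sim_engine import StepProtocol

__all__ = [
    "ReducedModel",
    "NullclineSet",
    "FixedPoint",
    "SaddleNodeSolution",
    "pacing_time_constants",
    "timescale_weights",
    "reduced_gate_value",
    "reduce_model",
    "reduced_rhs",
    "integrate_reduced",
    "v_nullcline",
    "fixed_points",
    "saddle_node",
    "lower_branch_present",
]


def pacing_time_constants(model: NeuronModel):
    """(tau_f, tau_s, tau_u) callables of membrane voltage.

    tau_s = potassium activation, tau_u = T-type calcium inactivation,
    tau_f = sodium activation when dynamic, else tau_mK/10.
    """
    k_act = _activation_gate(model.current("K"))
    cat_inact = _inactivation_gate(model.current("CaT"))
    if k_act.is_instantaneous:
        raise ValueError("reduction requires a dynamic potassium activation")
    if cat_inact.is_instantaneous:
        raise ValueError("reduction requires a dynamic T-type calcium inactivation")
    tau_s = lambda v: np.asarray(k_act.time_constant(v)) * k_act.tau_scale
    tau_u = lambda v: np.asarray(cat_inact.time_constant(v)) * cat_inact.tau_scale
    na_act = _activation_gate(model.current("Na"))
    if na_act.is_instantaneous:
        tau_f = lambda v: tau_s(v) / 10.0
        fast_source = "tau_mK/10"
    else:
        tau_f = lambda v: np.asarray(na_act.time_constant(v)) * na_act.tau_scale
        fast_source = "tau_mNa"
    return tau_f, tau_s, tau_u, fast_source


def timescale_weights(tau_x, tau_f, tau_s, tau_u):
    """The printed four-branch logarithmic-distance weight rule (vectorized).

    Requires tau_f <= tau_s <= tau_u elementwise.  Returns (w_fs, w_su).
    """
    tau_x, tau_f, tau_s, tau_u = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in (tau_x, tau_f, tau_s, tau_u))
    )
    if np.any(tau_f > tau_s * (1 + 1e-12)) or np.any(tau_s > tau_u * (1 + 1e-12)):
        raise ValueError("pacing time constants must satisfy tau_f <= tau_s <= tau_u")
    with np.errstate(divide="ignore", invalid="ignore"):
        w_fs_mid = np.log(tau_s / tau_x) / np.log(tau_s / tau_f)
        w_su_mid = np.log(tau_u / tau_x) / np.log(tau_u / tau_s)
    w_fs = np.select(
        [tau_x <= tau_f, tau_x <= tau_s], [1.0, w_fs_mid], default=0.0
    )
    w_su = np.select(
        [tau_x <= tau_s, tau_x <= tau_u], [1.0, w_su_mid], default=0.0
    )
    w_fs = np.clip(np.nan_to_num(w_fs, nan=1.0), 0.0, 1.0)
    w_su = np.clip(np.nan_to_num(w_su, nan=1.0), 0.0, 1.0)
    if w_fs.ndim == 0:
        return float(w_fs), float(w_su)
    return w_fs, w_su


def reduced_gate_value(x_inf: Callable, w_fs, w_su, v, v_s, v_u):
    """Convex three-timescale combination of a gating steady-state curve."""
    return w_fs * x_inf(v) + (w_su - w_fs) * x_inf(v_s) + (1.0 - w_su) * x_inf(v_u)


@dataclass
class ReducedModel:
    """A model reduced to (V, V_s, V_u); evaluates dV/dt on numpy arrays."""

    source: NeuronModel
    c_m: float
    tau_f: Callable
    tau_s: Callable
    tau_u: Callable
    fast_source: str = "tau_mNa"

    @classmethod
    def from_model(cls, model: NeuronModel, cm_scale: float = 1.0) -> "ReducedModel":
        tau_f, tau_s, tau_u, fast_source = pacing_time_constants(model)
        return cls(
            source=copy.deepcopy(model),
            c_m=model.c_m * cm_scale,
            tau_f=tau_f, tau_s=tau_s, tau_u=tau_u,
            fast_source=fast_source,
        )

    # -- calcium handling: pool at quasi-equilibrium of the ultraslow voltage
    def _calcium_at(self, v_u):
        pool = self.source.calcium_pool
        if pool is None:
            return None
        i_ca = 0.0
        for cur in self.source.currents:
            if not cur.calcium_source:
                continue
            g = 1.0
            for gate in cur.gates:
                g = g * gate.steady_state(v_u) ** gate.exponent
            erev = 120.0 if isinstance(cur.reversal, str) else cur.reversal
            i_ca = i_ca + cur.g_max * g * (v_u - erev)
        ca = pool.resting_level - pool.influx_coupling * i_ca / pool.removal_rate
        return np.maximum(ca, 0.0)

    def gate_value(self, gate, v, v_s, v_u, ca=None):
        if gate.ca_dependent:
            return gate.steady_state(ca if ca is not None else self._calcium_at(v_u))
        if gate.is_instantaneous:
            return gate.steady_state(v)
        tau_x = np.asarray(gate.time_constant(v)) * gate.tau_scale
        w_fs, w_su = timescale_weights(
            tau_x, self.tau_f(v), self.tau_s(v), self.tau_u(v)
        )
        return reduced_gate_value(gate.steady_state, w_fs, w_su, v, v_s, v_u)

    def ionic_sum(self, v, v_s, v_u):
        v, v_s, v_u = np.broadcast_arrays(
            *(np.asarray(a, dtype=float) for a in (v, v_s, v_u))
        )
        ca = self._calcium_at(v_u)
        total = np.zeros(v.shape)
        for cur in self.source.currents:
            g = np.full(v.shape, cur.g_max)
            for gate in cur.gates:
                g = g * self.gate_value(gate, v, v_s, v_u, ca) ** gate.exponent
            if isinstance(cur.reversal, str):
                pool = self.source.calcium_pool
                erev = pool.nernst_factor * np.log(
                    pool.external_level / np.maximum(ca, 1e-6)
                )
            else:
                erev = cur.reversal
            total = total + g * (v - erev)
        return total

    def dvdt(self, v, v_s, v_u, i_app=0.0):
        return (-self.ionic_sum(v, v_s, v_u) + i_app) / self.c_m


def reduce_model(model: NeuronModel, cm_scale: float = 1.0) -> ReducedModel:
    return ReducedModel.from_model(model, cm_scale)


def reduced_rhs(reduced: ReducedModel, state, i_app: float = 0.0) -> np.ndarray:
    """(dV/dt, dV_s/dt, dV_u/dt) at a state (V, V_s, V_u)."""
    v, v_s, v_u = (float(x) for x in state)
    return np.array(
        [
            float(reduced.dvdt(v, v_s, v_u, i_app)),
            (v - v_s) / float(reduced.tau_s(v)),
            (v - v_u) / float(reduced.tau_u(v)),
        ]
    )


def integrate_reduced(
    reduced: ReducedModel,
    protocol: StepProtocol,
    dt: float,
    v0: float = -65.0,
    record_dt: float = 1.0,
) -> dict:
    """Forward-Euler trajectory of the reduced model under a step protocol."""
    from . import _reduced_kernel
    from ._formulas import SS_FAMILIES, TAU_FAMILIES

    src = reduced.source
    cur_g, cur_erev, cur_casrc = [], [], []
    gate_cur, gate_exp, gate_inst, gate_cadep = [], [], [], []
    gate_ssfam, gate_sspar, gate_taufam, gate_taupar, gate_tauscale = (
        [], [], [], [], [],
    )
    for ci, cur in enumerate(src.currents):
        cur_g.append(cur.g_max)
        if isinstance(cur.reversal, str):
            raise ValueError(
                "reduced integration supports fixed reversal potentials only"
            )
        cur_erev.append(float(cur.reversal))
        cur_casrc.append(1 if cur.calcium_source else 0)
        for g in cur.gates:
            gate_cur.append(ci)
            gate_exp.append(g.exponent)
            gate_inst.append(1 if g.is_instantaneous else 0)
            gate_cadep.append(1 if g.ca_dependent else 0)
            gate_ssfam.append(g.steady_state.code(SS_FAMILIES))
            gate_sspar.append(g.steady_state.packed())
            if g.is_instantaneous:
                gate_taufam.append(0)
                gate_taupar.append(np.ones(len(g.steady_state.packed())))
            else:
                gate_taufam.append(g.time_constant.code(TAU_FAMILIES))
                gate_taupar.append(g.time_constant.packed())
            gate_tauscale.append(g.tau_scale)

    k_act = _activation_gate(src.current("K"))
    cat_inact = _inactivation_gate(src.current("CaT"))
    na_act = _activation_gate(src.current("Na"))
    if na_act.is_instantaneous:
        tf_gate, tf_div = k_act, 10.0
    else:
        tf_gate, tf_div = na_act, 1.0
    pool = src.calcium_pool
    ca_k = pool.influx_coupling if pool else -1.0
    ca_rate = pool.removal_rate if pool else 1.0
    ca_rest = pool.resting_level if pool else 0.0

    n_steps = int(round(protocol.duration / dt))
    n_dep = int(round(protocol.t_depol / dt))
    stride = max(1, int(round(record_dt / dt)))
    n_rec = n_steps // stride + 1
    out = np.empty((n_rec, 3))
    status, bad_step = _reduced_kernel.integrate_reduced_kernel(
        reduced.c_m,
        np.array(cur_g), np.array(cur_erev), np.array(cur_casrc, dtype=np.int8),
        np.array(gate_cur, dtype=np.int64), np.array(gate_exp, dtype=np.int64),
        np.array(gate_inst, dtype=np.int8), np.array(gate_cadep, dtype=np.int8),
        np.array(gate_ssfam, dtype=np.int64), np.vstack(gate_sspar),
        np.array(gate_taufam, dtype=np.int64), np.vstack(gate_taupar),
        np.array(gate_tauscale),
        tf_gate.time_constant.code(TAU_FAMILIES), tf_gate.time_constant.packed(),
        tf_gate.tau_scale, tf_div,
        k_act.time_constant.code(TAU_FAMILIES), k_act.time_constant.packed(),
        k_act.tau_scale,
        cat_inact.time_constant.code(TAU_FAMILIES), cat_inact.time_constant.packed(),
        cat_inact.tau_scale,
        ca_k, ca_rate, ca_rest,
        protocol.i_depol, protocol.i_hyper, n_dep,
        v0, dt, n_steps, stride,
        out,
    )
    if status != 0:
        raise RuntimeError(f"reduced-model blow-up at t={bad_step * dt:.1f} ms")
    t = np.arange(n_rec) * stride * dt
    return {"t": t, "V": out[:, 0], "Vs": out[:, 1], "Vu": out[:, 2], "dt": dt}


# --------------------------------------------------------------------------
# phase-plane objects
# --------------------------------------------------------------------------


@dataclass
class NullclineSet:
    """Zero set of dV/dt in the (V_s, V) plane at fixed V_u and I_app."""

    points: np.ndarray  # (n, 2): columns (V_s, V)
    components: list  # list of index arrays into points
    v_u: float
    i_app: float
    grid_shape: tuple
    tolerance: float

    @property
    def n_components(self) -> int:
        return len(self.components)


@dataclass
class FixedPoint:
    coords: np.ndarray  # (V, V_s, V_u)
    eigenvalues: np.ndarray
    stable: bool
    kind: str  # node | saddle | focus
    residual: float


@dataclass
class SaddleNodeSolution:
    v: float
    v_u: float
    residual_dvdt: float
    residual_det: float

    @property
    def v_s(self) -> float:
        return self.v


def v_nullcline(
    reduced,
    v_u: float,
    i_app: float,
    v_window: tuple = (-100.0, 20.0),
    vs_window: tuple = (-100.0, 20.0),
    n_grid: int = 600,
    refine_tol: float = 1e-3,
) -> NullclineSet:
    """Locate the V-nullcline by marching squares + bisection refinement.

    ``reduced`` needs a vectorized ``dvdt(V, Vs, Vu, i_app)``.  The zero
    contour of dV/dt on an (V, V_s) grid is traced with marching squares
    (scikit-image), which yields the connected components directly; each
    contour point is then polished by bisection along the V axis (falling
    back to the V_s axis for near-vertical segments) to ``refine_tol`` mV.
    """
    from skimage import measure

    vs_grid = np.linspace(*vs_window, n_grid)
    v_grid = np.linspace(*v_window, n_grid)
    dv = v_grid[1] - v_grid[0]
    dvs = vs_grid[1] - vs_grid[0]
    vv, ss = np.meshgrid(v_grid, vs_grid, indexing="ij")
    f = np.asarray(reduced.dvdt(vv, ss, v_u, i_app))
    contours = measure.find_contours(f, 0.0)
    points = []
    components = []
    k0 = 0
    for cont in contours:
        comp_pts = []
        for iv, ivs in cont[:: max(1, len(cont) // 2000)]:
            v = v_window[0] + iv * dv
            vs = vs_window[0] + ivs * dvs
            v, vs = _polish_point(reduced, v, vs, v_u, i_app, dv, dvs, refine_tol)
            comp_pts.append((vs, v))
        if comp_pts:
            points.extend(comp_pts)
            components.append(np.arange(k0, k0 + len(comp_pts)))
            k0 += len(comp_pts)
    points = np.array(points) if points else np.empty((0, 2))
    return NullclineSet(
        points=points,
        components=components,
        v_u=v_u,
        i_app=i_app,
        grid_shape=(n_grid, n_grid),
        tolerance=refine_tol,
    )


def _polish_point(reduced, v, vs, v_u, i_app, dv, dvs, tol):
    """Bisect to the exact zero of dV/dt near a marching-squares vertex."""
    def fv(x):
        return float(reduced.dvdt(x, vs, v_u, i_app))

    def fvs(x):
        return float(reduced.dvdt(v, x, v_u, i_app))

    for fun, x0, h, axis in ((fv, v, dv, "v"), (fvs, vs, dvs, "vs")):
        lo, hi = x0 - 1.5 * h, x0 + 1.5 * h
        flo, fhi = fun(lo), fun(hi)
        if (flo < 0) == (fhi < 0):
            continue
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            fm = fun(mid)
            if (fm < 0) == (flo < 0):
                lo, flo = mid, fm
            else:
                hi = mid
            if hi - lo < tol:
                break
        root = 0.5 * (lo + hi)
        return (root, vs) if axis == "v" else (v, root)
    return v, vs


def _jacobian(fun, x, eps=1e-5):
    x = np.asarray(x, dtype=float)
    f0 = np.asarray(fun(x))
    jac = np.empty((f0.size, x.size))
    for k in range(x.size):
        step = eps * max(1.0, abs(x[k]))
        xp = x.copy(); xp[k] += step
        xm = x.copy(); xm[k] -= step
        jac[:, k] = (np.asarray(fun(xp)) - np.asarray(fun(xm))) / (2 * step)
    return jac


def fixed_points(
    reduced: ReducedModel,
    i_app: float,
    v_window: tuple = (-100.0, 20.0),
    n_scan: int = 2000,
    tol: float = 1e-8,
) -> list:
    """All equilibria on the diagonal V = V_s = V_u, with stability labels."""
    v_grid = np.linspace(*v_window, n_scan)
    g = np.asarray(reduced.dvdt(v_grid, v_grid, v_grid, i_app))
    roots = []
    for k in np.flatnonzero(np.signbit(g[:-1]) != np.signbit(g[1:])):
        r = optimize.brentq(
            lambda v: float(reduced.dvdt(v, v, v, i_app)),
            v_grid[k], v_grid[k + 1], xtol=1e-12,
        )
        roots.append(r)
    out = []
    for r in roots:
        coords = np.array([r, r, r])
        rhs = lambda x: reduced_rhs(reduced, x, i_app)
        jac = _jacobian(rhs, coords)
        eig = np.linalg.eigvals(jac)
        stable = bool(np.all(eig.real < 0))
        if np.any(np.abs(eig.imag) > 1e-9):
            kind = "focus"
        elif np.any(eig.real > 0) and np.any(eig.real < 0):
            kind = "saddle"
        else:
            kind = "node"
        out.append(
            FixedPoint(
                coords=coords,
                eigenvalues=eig,
                stable=stable,
                kind=kind,
                residual=float(np.max(np.abs(rhs(coords)))),
            )
        )
    return out


def _fast_slow_det(reduced, v, v_u, i_app, eps=1e-5):
    """Determinant of the (V, V_s) Jacobian of the fast-slow subsystem."""
    def f2(x):
        vv, vs = x
        return np.array(
            [
                float(reduced.dvdt(vv, vs, v_u, i_app)),
                (vv - vs) / float(reduced.tau_s(vv)),
            ]
        )
    jac = _jacobian(f2, np.array([v, v]), eps)
    return float(np.linalg.det(jac))


def saddle_node(
    reduced,
    i_app: float,
    v_window: tuple = (-100.0, 0.0),
    vu_window: tuple = (-100.0, -40.0),
    n_scan: int = 400,
    tol: float = 1e-8,
) -> Optional[SaddleNodeSolution]:
    """Locate the saddle-node of the fast-slow subsystem over V_u.

    The equilibrium curve of the fast-slow subsystem (dV/dt = 0 with
    V_s = V, at frozen V_u) gains or loses a pair of roots at a fold as V_u
    varies; the fold is located by bisection on V_u and polished on the
    system {dV/dt = 0, det J_2 = 0}.  When several folds exist, the one with
    the most hyperpolarized V (burst-onset knee) is returned.  Returns None
    when no fold lies in the window.
    """
    v_grid = np.linspace(*v_window, n_scan)

    def roots_at(v_u):
        g = np.asarray(reduced.dvdt(v_grid, v_grid, v_u, i_app))
        rr = []
        for k in np.flatnonzero(np.signbit(g[:-1]) != np.signbit(g[1:])):
            rr.append(
                optimize.brentq(
                    lambda v: float(reduced.dvdt(v, v, v_u, i_app)),
                    v_grid[k], v_grid[k + 1], xtol=1e-12,
                )
            )
        return rr

    vu_grid = np.linspace(*vu_window, n_scan)
    counts = [len(roots_at(vu)) for vu in vu_grid]
    folds = []
    for k in range(len(vu_grid) - 1):
        if counts[k] != counts[k + 1]:
            lo, hi = vu_grid[k], vu_grid[k + 1]
            n_lo = counts[k]
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                if len(roots_at(mid)) == n_lo:
                    lo = mid
                else:
                    hi = mid
            # the merging pair: roots present on the richer side, closest pair
            rich = roots_at(lo) if counts[k] > counts[k + 1] else roots_at(hi)
            poor = roots_at(hi) if counts[k] > counts[k + 1] else roots_at(lo)
            merged = _merging_root(rich, poor)
            if merged is not None:
                folds.append((merged, 0.5 * (lo + hi)))
    if not folds:
        return None
    # polish each candidate on {dvdt = 0, det = 0} and keep the most
    # hyperpolarized V
    best = None
    for v0, vu0 in folds:
        def sys2(x):
            v, vu = x
            return np.array(
                [
                    float(reduced.dvdt(v, v, vu, i_app)),
                    _fast_slow_det(reduced, v, vu, i_app),
                ]
            )
        sol = optimize.root(sys2, np.array([v0, vu0]), method="hybr", tol=1e-12)
        v_star, vu_star = (sol.x if sol.success else (v0, vu0))
        res = sys2(np.array([v_star, vu_star]))
        cand = SaddleNodeSolution(
            v=float(v_star),
            v_u=float(vu_star),
            residual_dvdt=abs(float(res[0])),
            residual_det=abs(float(res[1])),
        )
        if best is None or cand.v < best.v:
            best = cand
    return best


def _merging_root(rich, poor):
    """Root(s) of the richer side that disappear on the poorer side."""
    if not rich:
        return None
    lost = [r for r in rich if not poor or min(abs(r - p) for p in poor) > 0.5]
    if lost:
        return float(np.mean(lost))
    # fall back: closest pair midpoint
    if len(rich) >= 2:
        rr = sorted(rich)
        gaps = np.diff(rr)
        k = int(np.argmin(gaps))
        return float(0.5 * (rr[k] + rr[k + 1]))
    return float(rich[0])


def lower_branch_present(nullcline: NullclineSet, saddle_v: float) -> bool:
    """A disjoint hyperpolarized branch of the V-nullcline?

    True iff some connected component, distinct from the component
    containing the most depolarized (spiking upper-branch) points, reaches
    below ``saddle_v``.  Such a branch separates the silent hyperpolarized
    region from the spiking region; a plain N-shaped (single-component)
    nullcline has no such branch.  (The branch may fold back above the
    saddle: what matters is that it is disjoint from the spiking branch and
    carries the hyperpolarized rest.)
    """
    if nullcline.points.shape[0] == 0 or len(nullcline.components) < 2:
        return False
    v_vals = nullcline.points[:, 1]
    upper_comp = None
    v_max = -np.inf
    for k, comp in enumerate(nullcline.components):
        m = v_vals[comp].max()
        if m > v_max:
            v_max = m
            upper_comp = k
    for k, comp in enumerate(nullcline.components):
        if k == upper_comp:
            continue
        if np.any(v_vals[comp] < saddle_v):
            return True
    return False
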