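"""Compiled Euler loop for the 3-variable reduced models.

Mirrors ``reduction_phase.reduced_rhs``: gating variables are replaced by
their three-timescale weighted combination at every step, the calcium pool
(when present) is held at the quasi-equilibrium implied by the ultraslow
voltage, and (V, V_s, V_u) are advanced by forward Euler.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from ._kernel import _ss_eval, _tau_eval


@njit(cache=True)
def _weights(tau_x, tf, ts, tu):
    if tau_x <= tf:
        return 1.0, 1.0
    if tau_x <= ts:
        return np.log(ts / tau_x) / np.log(ts / tf), 1.0
    if tau_x <= tu:
        return 0.0, np.log(tu / tau_x) / np.log(tu / ts)
    return 0.0, 0.0


@njit(cache=True)
def integrate_reduced_kernel(
    c_m,
    # per current
    cur_g, cur_erev, cur_casrc,
    # per gate
    gate_cur, gate_exp, gate_inst, gate_cadep,
    gate_ssfam, gate_sspar, gate_taufam, gate_taupar, gate_tauscale,
    # pacing tau formulas
    tf_fam, tf_par, tf_scale, tf_div,
    ts_fam, ts_par, ts_scale,
    tu_fam, tu_par, tu_scale,
    # calcium pool (k<0 disables)
    ca_k, ca_rate, ca_rest,
    # protocol
    i_dep, i_hyp, n_dep_steps,
    v0, dt, n_steps, rec_stride,
    out,  # (n_rec, 3)
):
    nc = cur_g.shape[0]
    ng = gate_cur.shape[0]
    v = v0
    vs = v0
    vu = v0
    out[0, 0] = v
    out[0, 1] = vs
    out[0, 2] = vu
    row = 1
    for step in range(n_steps):
        tf = _tau_eval(tf_fam, tf_par, v) * tf_scale / tf_div
        ts_ = _tau_eval(ts_fam, ts_par, v) * ts_scale
        tu_ = _tau_eval(tu_fam, tu_par, v) * tu_scale
        # calcium at quasi-equilibrium of the ultraslow voltage
        ca = -1.0
        if ca_k >= 0.0:
            i_ca = 0.0
            for c in range(nc):
                if cur_casrc[c] == 1:
                    gprod = 1.0
                    for g in range(ng):
                        if gate_cur[g] == c:
                            x = _ss_eval(gate_ssfam[g], gate_sspar[g], vu)
                            for _ in range(gate_exp[g]):
                                gprod *= x
                    i_ca += cur_g[c] * gprod * (vu - cur_erev[c])
            ca = ca_rest - ca_k * i_ca / ca_rate
            if ca < 0.0:
                ca = 0.0
        total = 0.0
        for c in range(nc):
            gprod = 1.0
            for g in range(ng):
                if gate_cur[g] != c:
                    continue
                if gate_cadep[g] == 1:
                    x = _ss_eval(gate_ssfam[g], gate_sspar[g], ca)
                elif gate_inst[g] == 1:
                    x = _ss_eval(gate_ssfam[g], gate_sspar[g], v)
                else:
                    tau_x = _tau_eval(gate_taufam[g], gate_taupar[g], v) * gate_tauscale[g]
                    wfs, wsu = _weights(tau_x, tf, ts_, tu_)
                    x = (
                        wfs * _ss_eval(gate_ssfam[g], gate_sspar[g], v)
                        + (wsu - wfs) * _ss_eval(gate_ssfam[g], gate_sspar[g], vs)
                        + (1.0 - wsu) * _ss_eval(gate_ssfam[g], gate_sspar[g], vu)
                    )
                xe = 1.0
                for _ in range(gate_exp[g]):
                    xe *= x
                gprod *= xe
            total += cur_g[c] * gprod * (v - cur_erev[c])
        i_app = i_dep if step < n_dep_steps else i_hyp
        dv = (-total + i_app) / c_m
        dvs = (v - vs) / ts_
        dvu = (v - vu) / tu_
        v += dt * dv
        vs += dt * dvs
        vu += dt * dvu
        if not np.isfinite(v) or v > 200.0 or v < -200.0:
            return 1, step
        t1 = step + 1
        if t1 % rec_stride == 0 and row < out.shape[0]:
            out[row, 0] = v
            out[row, 1] = vs
            out[row, 2] = vu
            row += 1
    return 0, -1
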