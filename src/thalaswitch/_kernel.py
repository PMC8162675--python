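"""Compiled forward-Euler integration kernel.

The declarative model descriptions of :mod:`thalaswitch.channel_models` are
flattened into plain numeric arrays (one row per current, per gate, per
synapse) and integrated by a single numba-compiled loop, so that circuits and
networks of arbitrary composition share one code path.  The reference
semantics are defined by ``channel_models.membrane_rhs`` and
``synapse_lfp.synapse_rhs``; this kernel must agree with them step for step.

Synaptic gating is shared per (presynaptic cell, receptor) pair: the gating
ODE depends only on the presynaptic voltage, so identical postsynaptic
targets can reuse one state variable (exactly equivalent to per-pair states).
"""

from __future__ import annotations

import numpy as np
from numba import njit

# steady-state family codes (see _formulas)
_SS_BOLTZMANN = 0
_SS_HILL = 1
# tau family codes
_TAU_CONST = 0
_TAU_GAUSS = 1
_TAU_BIEXP = 2
_TAU_SIGMOID = 3
_TAU_GAUSS2 = 4


@njit(cache=True)
def _ss_eval(fam, p, x):
    if fam == _SS_BOLTZMANN:
        return 1.0 / (1.0 + np.exp((x - p[0]) / p[1]))
    # hill on calcium
    xx = x if x > 0.0 else 0.0
    xn = xx ** p[1]
    return xn / (xn + p[0] ** p[1])


@njit(cache=True)
def _tau_eval(fam, p, v):
    if fam == _TAU_CONST:
        return p[0]
    if fam == _TAU_GAUSS:
        z = (v - p[2]) / p[3]
        return p[0] + p[1] * np.exp(-z * z)
    if fam == _TAU_BIEXP:
        return p[0] + p[1] / (np.exp((v - p[2]) / p[3]) + np.exp(-(v - p[4]) / p[5]))
    if fam == _TAU_GAUSS2:
        z1 = (v - p[2]) / p[3]
        z2 = (v - p[5]) / p[6]
        return p[0] + p[1] * np.exp(-z1 * z1) + p[4] * np.exp(-z2 * z2)
    return p[0] + p[1] / (1.0 + np.exp((v - p[2]) / p[3]))


@njit(cache=True)
def integrate_system(
    # --- layout ---
    n_cells,
    cell_v,        # (n_cells,) state index of V per cell
    cell_cm,       # (n_cells,)
    cell_ca,       # (n_cells,) state index of [Ca] or -1
    ca_k,          # (n_cells,) influx coupling
    ca_rate,       # (n_cells,) removal rate 1/ms
    ca_rest,       # (n_cells,)
    ca_ext,        # (n_cells,) external level (nernst)
    ca_nernst,     # (n_cells,) RT/2F factor
    # --- currents (flattened over cells) ---
    cur_cell,      # (nc,)
    cur_g,         # (nc,)
    cur_erev,      # (nc,)  (ignored when cur_nernst)
    cur_nernst,    # (nc,) bool int8
    cur_casrc,     # (nc,) bool int8: contributes to calcium influx
    # --- gates (flattened) ---
    gate_cur,      # (ng,) current index
    gate_exp,      # (ng,)
    gate_state,    # (ng,) state index or -1 if instantaneous
    gate_cadep,    # (ng,) int8
    gate_ssfam, gate_sspar,      # (ng,), (ng, NPAR)
    gate_taufam, gate_taupar,    # idem
    gate_tauscale,               # (ng,)
    # --- synapses ---
    n_sgate,
    sgate_pre,     # (nsg,) presynaptic cell
    sgate_rise, sgate_decay,     # (nsg,)
    syn_sgate,     # (ns,) index into synapse gates
    syn_post,      # (ns,) postsynaptic cell
    syn_g,         # (ns,)
    syn_erev,      # (ns,)
    t_half, t_slope,
    # --- protocol ---
    i_dep, i_hyp,  # (n_cells,)
    n_dep_steps,
    # --- integration ---
    y0,            # (n_state,) initial neuron state
    s0,            # (nsg,) initial synaptic gating
    dt,
    n_steps,
    # --- recording ---
    spike_thresh,
    spk_t,         # (n_cells, max_spk) out
    spk_n,         # (n_cells,) out
    rec_state_idx, # (nrs,) state indices to record densely
    trace_stride,
    state_rec,     # (n_trace, nrs) out
    post_npre,     # (n_cells,) distinct presynaptic count (0 -> 1 for div)
    lfp_stride,
    isyn_rec,      # (n_lfp, n_cells) out: per-post mean-over-presyn current
):
    """Integrate the whole system; returns (status, bad_cell, bad_step).

    status 0 = ok, 1 = numerical blow-up, 2 = spike buffer overflow.
    """
    nc = cur_g.shape[0]
    ng = gate_cur.shape[0]
    ns = syn_g.shape[0]
    y = y0.copy()
    s = s0.copy()
    dy = np.zeros_like(y)
    ds = np.zeros_like(s)
    cur_prod = np.ones(nc)
    cur_val = np.zeros(nc)
    cell_ion = np.zeros(n_cells)
    cell_ica = np.zeros(n_cells)
    cell_isyn = np.zeros(n_cells)
    max_spk = spk_t.shape[1]

    # initial recording sample
    if trace_stride > 0:
        for r in range(rec_state_idx.shape[0]):
            state_rec[0, r] = y[rec_state_idx[r]]
    if lfp_stride > 0:
        for j in range(n_cells):
            isyn_rec[0, j] = 0.0

    for step in range(n_steps):
        # ---- synaptic currents from the old state -----------------------
        for j in range(n_cells):
            cell_isyn[j] = 0.0
        for k in range(ns):
            post = syn_post[k]
            vpost = y[cell_v[post]]
            cell_isyn[post] += syn_g[k] * s[syn_sgate[k]] * (vpost - syn_erev[k])

        # ---- ionic currents ---------------------------------------------
        for c in range(nc):
            cur_prod[c] = 1.0
        for g in range(ng):
            c = gate_cur[g]
            st = gate_state[g]
            if st >= 0:
                x = y[st]
            else:
                cell = cur_cell[c]
                if gate_cadep[g] == 1:
                    drive = y[cell_ca[cell]]
                else:
                    drive = y[cell_v[cell]]
                x = _ss_eval(gate_ssfam[g], gate_sspar[g], drive)
            e = gate_exp[g]
            xe = x
            for _ in range(e - 1):
                xe *= x
            cur_prod[c] *= xe
        for j in range(n_cells):
            cell_ion[j] = 0.0
            cell_ica[j] = 0.0
        for c in range(nc):
            cell = cur_cell[c]
            v = y[cell_v[cell]]
            if cur_nernst[c] == 1:
                ca = y[cell_ca[cell]]
                if ca < 1e-6:
                    ca = 1e-6
                erev = ca_nernst[cell] * np.log(ca_ext[cell] / ca)
            else:
                erev = cur_erev[c]
            ival = cur_g[c] * cur_prod[c] * (v - erev)
            cur_val[c] = ival
            cell_ion[cell] += ival
            if cur_casrc[c] == 1:
                cell_ica[cell] += ival

        # ---- derivatives -------------------------------------------------
        i_applied = i_dep if step < n_dep_steps else i_hyp
        for j in range(n_cells):
            dy[cell_v[j]] = (-cell_ion[j] - cell_isyn[j] + i_applied[j]) / cell_cm[j]
            cidx = cell_ca[j]
            if cidx >= 0:
                dy[cidx] = -ca_k[j] * cell_ica[j] - ca_rate[j] * (y[cidx] - ca_rest[j])
        for g in range(ng):
            st = gate_state[g]
            if st >= 0:
                cell = cur_cell[gate_cur[g]]
                v = y[cell_v[cell]]
                if gate_cadep[g] == 1:
                    drive = y[cell_ca[cell]]
                else:
                    drive = v
                ss = _ss_eval(gate_ssfam[g], gate_sspar[g], drive)
                tau = _tau_eval(gate_taufam[g], gate_taupar[g], v) * gate_tauscale[g]
                dy[st] = (ss - y[st]) / tau
        for k in range(n_sgate):
            vpre = y[cell_v[sgate_pre[k]]]
            tm = 1.0 / (1.0 + np.exp(-(vpre - t_half) / t_slope))
            ds[k] = sgate_rise[k] * tm * (1.0 - s[k]) - sgate_decay[k] * s[k]

        # ---- Euler update ------------------------------------------------
        for j in range(n_cells):
            vold = y[cell_v[j]]
            vnew = vold + dt * dy[cell_v[j]]
            if not np.isfinite(vnew) or vnew > 200.0 or vnew < -200.0:
                return 1, j, step
            y[cell_v[j]] = vnew
            if vold < spike_thresh and vnew >= spike_thresh:
                n = spk_n[j]
                if n >= max_spk:
                    return 2, j, step
                spk_t[j, n] = (step + 1) * dt
                spk_n[j] = n + 1
            cidx = cell_ca[j]
            if cidx >= 0:
                ca = y[cidx] + dt * dy[cidx]
                y[cidx] = ca if ca > 0.0 else 0.0
        for g in range(ng):
            st = gate_state[g]
            if st >= 0:
                x = y[st] + dt * dy[st]
                if x < 0.0:
                    x = 0.0
                elif x > 1.0:
                    x = 1.0
                y[st] = x
        for k in range(n_sgate):
            sv = s[k] + dt * ds[k]
            if sv < 0.0:
                sv = 0.0
            elif sv > 1.0:
                sv = 1.0
            s[k] = sv

        # ---- recording ---------------------------------------------------
        t1 = step + 1
        if trace_stride > 0 and t1 % trace_stride == 0:
            row = t1 // trace_stride
            if row < state_rec.shape[0]:
                for r in range(rec_state_idx.shape[0]):
                    state_rec[row, r] = y[rec_state_idx[r]]
        if lfp_stride > 0 and t1 % lfp_stride == 0:
            row = t1 // lfp_stride
            if row < isyn_rec.shape[0]:
                for j in range(n_cells):
                    npre = post_npre[j]
                    if npre < 1:
                        npre = 1
                    isyn_rec[row, j] = cell_isyn[j] / npre

    # final state back into y0/s0 buffers for the caller
    for i in range(y.shape[0]):
        y0[i] = y[i]
    for k in range(n_sgate):
        s0[k] = s[k]
    return 0, -1, -1
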