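"""Numba time-stepping kernel for the compartmental model.

The reduced morphology is an unbranched chain (distal dendrite - proximal
dendrite - soma - AIS - distal axon - node), so the implicit cable system
is tridiagonal and solved per step with the Thomas algorithm.  Voltage
uses backward Euler (unconditionally stable); gating uses Rush-Larsen
exponential updates with per-dt lookup tables of the steady states and
relaxation factors (0.05 mV grid, linear interpolation is unnecessary at
that resolution); drug block uses an explicit update, which is accurate
because binding/unbinding rates are many orders of magnitude slower than
the time step.

Units: mV, ms, nA, µS, nF, MΩ (1/µS).  Channel order in the conductance
arrays: 0 NaV1.2, 1 NaV1.6, 2 fast Kv, 3 slow (dendritic) Kv.  Gate order:
0 m12, 1 h12, 2 m16, 3 h16, 4 n_fast, 5 n_slow.
"""

from __future__ import annotations

import numpy as np
from numba import njit

VGRID_MIN = -130.0
VGRID_MAX = 80.0
VGRID_STEP = 0.05
N_VGRID = int(round((VGRID_MAX - VGRID_MIN) / VGRID_STEP)) + 1

N_GATES = 6
N_CHAN = 4
GATE_OF_CHAN_M = (0, 2, 4, 5)  # activation gate row per channel
GATE_OF_CHAN_H = (1, 3, -1, -1)  # inactivation gate row (-1: none)


def voltage_grid() -> np.ndarray:
    return VGRID_MIN + VGRID_STEP * np.arange(N_VGRID)


@njit(cache=True, fastmath=False)
def _vidx(v):
    i = int((v - VGRID_MIN) / VGRID_STEP + 0.5)
    if i < 0:
        i = 0
    elif i >= N_VGRID:
        i = N_VGRID - 1
    return i


@njit(cache=True)
def run_chain(
    v,              # (n,) voltages, updated in place
    gates,          # (6, n) gating variables, updated in place
    b,              # (2, n) blocked fraction per Na isoform, in place
    gch,            # (4, n) max conductances µS (already scaled/per-seg)
    mpow,           # (4,) integer activation-gate powers
    erev,           # (4,) channel reversal potentials mV
    gleak,          # (n,) leak conductance µS
    eleak,          # leak reversal mV
    ga,             # (n-1,) axial conductances µS
    cm,             # (n,) capacitances nF
    inf_tab,        # (6, N_VGRID) gate steady states
    ex_tab,         # (6, N_VGRID) 1-exp(-dt/tau)
    koff_tab,       # (N_VGRID,) drug unbinding rate 1/ms
    kon,            # (2,) conc*k_on per isoform, 1/ms
    dt,
    nsteps,
    stim_mode,      # 0 none, 1 constant, 2 per-step
    stim_seg,
    istim,          # stimulus nA; len 1 (constant) or nsteps
    clamp_mode,     # 0 none, 1 constant, 2 per-step
    clamp_seg,
    vclamp,         # command mV; len 1 or nsteps
    record_every,
    rec_idx,        # (nrec,) segment indices to record
    out_v,          # (nrec, nout)
    out_ic,         # (nout,) clamp current nA (0 when unclamped)
    out_bk,         # (2, nout) conductance-weighted mean blocked fraction
    use_cn,         # 1: Crank-Nicolson (implicit half-step + extrapolation,
                    # second order); 0: backward Euler (first order, used
                    # for clamped phases where damping is preferable)
):
    n = v.shape[0]
    diag = np.empty(n)
    rhs = np.empty(n)
    cpr = np.empty(n)
    dpr = np.empty(n)
    vold = np.empty(n)
    cn = use_cn if clamp_mode == 0 else 0
    dt_solve = dt * 0.5 if cn == 1 else dt

    # conductance weights for the mean-block report
    w12 = 0.0
    w16 = 0.0
    for i in range(n):
        w12 += gch[0, i]
        w16 += gch[1, i]
    if w12 <= 0.0:
        w12 = 1.0
    if w16 <= 0.0:
        w16 = 1.0

    out_ptr = 0
    for step in range(nsteps):
        # --- gating (Rush-Larsen at current voltage) -------------------
        for i in range(n):
            k = _vidx(v[i])
            for g in range(N_GATES):
                x = gates[g, i]
                gates[g, i] = x + (inf_tab[g, k] - x) * ex_tab[g, k]

        # --- drug block (explicit; rates ~1e-6 per ms) -----------------
        for i in range(n):
            k = _vidx(v[i])
            koff = koff_tab[k]
            inact12 = 1.0 - gates[1, i]
            inact16 = 1.0 - gates[3, i]
            b[0, i] += dt * (kon[0] * inact12 * (1.0 - b[0, i]) - koff * b[0, i])
            b[1, i] += dt * (kon[1] * inact16 * (1.0 - b[1, i]) - koff * b[1, i])
            if b[0, i] < 0.0:
                b[0, i] = 0.0
            elif b[0, i] > 1.0:
                b[0, i] = 1.0
            if b[1, i] < 0.0:
                b[1, i] = 0.0
            elif b[1, i] > 1.0:
                b[1, i] = 1.0

        # --- assemble implicit system ---------------------------------
        for i in range(n):
            gsum = gleak[i]
            esum = gleak[i] * eleak
            for c in range(N_CHAN):
                gmax = gch[c, i]
                if gmax <= 0.0:
                    continue
                m = gates[GATE_OF_CHAN_M[c], i]
                p = mpow[c]
                mp = m
                for _ in range(p - 1):
                    mp *= m
                go = gmax * mp
                if c == 0:
                    go *= gates[1, i] * (1.0 - b[0, i])
                elif c == 1:
                    go *= gates[3, i] * (1.0 - b[1, i])
                gsum += go
                esum += go * erev[c]
            diag[i] = cm[i] / dt_solve + gsum
            rhs[i] = cm[i] / dt_solve * v[i] + esum
            vold[i] = v[i]

        if stim_mode == 1:
            rhs[stim_seg] += istim[0]
        elif stim_mode == 2:
            rhs[stim_seg] += istim[step]

        # axial terms
        for i in range(n - 1):
            diag[i] += ga[i]
            diag[i + 1] += ga[i]

        vc = 0.0
        if clamp_mode == 1:
            vc = vclamp[0]
        elif clamp_mode == 2:
            vc = vclamp[step]

        # --- Thomas solve (lower off-diag = upper off-diag = -ga) ------
        diag_save = 0.0
        v_old_clamp = 0.0
        if clamp_mode != 0:
            # Dirichlet row for the clamped segment
            i = clamp_seg
            v_old_clamp = v[i]
            rhs[i] = vc
            diag_save = diag[i]
            diag[i] = 1.0

        # forward sweep
        if clamp_mode != 0 and clamp_seg == 0:
            cpr[0] = 0.0
            dpr[0] = vc
        else:
            cpr[0] = -ga[0] / diag[0] if n > 1 else 0.0
            dpr[0] = rhs[0] / diag[0]
        for i in range(1, n):
            if clamp_mode != 0 and clamp_seg == i:
                cpr[i] = 0.0
                dpr[i] = vc
            else:
                low = -ga[i - 1]
                denom = diag[i] - low * cpr[i - 1]
                upper = -ga[i] if i < n - 1 else 0.0
                cpr[i] = upper / denom
                dpr[i] = (rhs[i] - low * dpr[i - 1]) / denom

        v[n - 1] = dpr[n - 1]
        for i in range(n - 2, -1, -1):
            v[i] = dpr[i] - cpr[i] * v[i + 1]
        if cn == 1:
            # implicit half-step solved; extrapolate to the full step
            for i in range(n):
                v[i] = 2.0 * v[i] - vold[i]

        ic = 0.0
        if clamp_mode != 0:
            # electrode current = capacitive + ionic - axial inflow
            i = clamp_seg
            diag[i] = diag_save
            gsum = gleak[i]
            esum = gleak[i] * eleak
            for c in range(N_CHAN):
                gmax = gch[c, i]
                if gmax <= 0.0:
                    continue
                m = gates[GATE_OF_CHAN_M[c], i]
                p = mpow[c]
                mp = m
                for _ in range(p - 1):
                    mp *= m
                go = gmax * mp
                if c == 0:
                    go *= gates[1, i] * (1.0 - b[0, i])
                elif c == 1:
                    go *= gates[3, i] * (1.0 - b[1, i])
                gsum += go
                esum += go * erev[c]
            ic = cm[i] * (v[i] - v_old_clamp) / dt + gsum * v[i] - esum
            if i > 0:
                ic -= ga[i - 1] * (v[i - 1] - v[i])
            if i < n - 1:
                ic -= ga[i] * (v[i + 1] - v[i])

        # --- record ----------------------------------------------------
        if (step + 1) % record_every == 0 and out_ptr < out_v.shape[1]:
            for r in range(rec_idx.shape[0]):
                out_v[r, out_ptr] = v[rec_idx[r]]
            out_ic[out_ptr] = ic
            s12 = 0.0
            s16 = 0.0
            for i in range(n):
                s12 += gch[0, i] * b[0, i]
                s16 += gch[1, i] * b[1, i]
            out_bk[0, out_ptr] = s12 / w12
            out_bk[1, out_ptr] = s16 / w16
            out_ptr += 1

    return out_ptr
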