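"""Numerical core: implicit integration of the branched cable equation.

The spatial discretization yields a tree of compartments; backward Euler in
time gives, per step, a symmetric linear system whose matrix has the tree's
sparsity.  It is solved exactly in linear time by elimination from the leaves
toward the root (a Hines solve), which is unconditionally stable on the stiff
spiking dynamics.  Gating variables use a staggered update: each is relaxed
exponentially toward its voltage-dependent steady state using the voltage at
the start of the step (exact for frozen voltage).

Channel family (fixed structure, constants supplied by the caller):
Na = ḡ·m³·h, Kdr = ḡ·n, KA = ḡ·a·b, H = ḡ·l.  Gate order in all arrays:
[m, h, n, a, b, l].

Units: mV, ms, µS, nF, nA.  (nF/ms ≡ µS; µS·mV ≡ nA.)
"""

import numpy as np
from numba import njit

N_GATES = 6
# gate -> channel: m,h -> Na(0); n -> Kdr(1); a,b -> KA(2); l -> H(3)
GATE_CHANNEL = np.array([0, 0, 1, 2, 2, 3], dtype=np.int64)
# +1 if steady state increases with V, -1 otherwise
GATE_SIGN = np.array([1, -1, 1, 1, -1, -1], dtype=np.float64)


@njit(cache=True)
def gate_inf_tau(gp, sign, V):
    """Steady states and time constants of all six gates at voltages V.

    gp: (6, 6) array of [vhalf, k, tau_min, tau_amp, tau_vhalf, tau_k].
    Returns (xinf, tau), each (6, len(V)).
    """
    n = V.shape[0]
    xinf = np.empty((N_GATES, n))
    tau = np.empty((N_GATES, n))
    for g in range(N_GATES):
        vh, k, tmin, tamp, tvh, tk = gp[g, 0], gp[g, 1], gp[g, 2], gp[g, 3], gp[g, 4], gp[g, 5]
        for i in range(n):
            xinf[g, i] = 1.0 / (1.0 + np.exp(-sign[g] * (V[i] - vh) / k))
            tau[g, i] = tmin + tamp / (1.0 + np.exp((V[i] - tvh) / tk))
    return xinf, tau


@njit(cache=True)
def hines_solve(parent, g_ax, d, rhs, v):
    """Solve the tree-structured linear system in place.

    Matrix: M[i,i] = d[i]; M[i,parent[i]] = M[parent[i],i] = -g_ax[i].
    Compartments are topologically ordered (parent[i] < i, parent[0] = -1).
    """
    n = d.shape[0]
    for i in range(n - 1, 0, -1):
        p = parent[i]
        piv = g_ax[i] / d[i]
        d[p] -= g_ax[i] * piv
        rhs[p] += rhs[i] * piv
    v[0] = rhs[0] / d[0]
    for i in range(1, n):
        v[i] = (rhs[i] + g_ax[i] * v[parent[i]]) / d[i]


@njit(cache=True)
def integrate(
    n_steps,
    dt,
    parent,
    g_ax,
    c_dt,
    g_leak,
    e_leak,
    gbar,      # (4, N) µS: Na, Kdr, KA, H
    e_rev,     # (4,) mV
    gp,        # (6, 6) gate constants
    sign,      # (6,)
    V,         # (N,) in/out: voltage state
    X,         # (6, N) in/out: gate states
    syn_A,     # (N,) in/out synaptic rise state
    syn_B,     # (N,) in/out synaptic decay state
    dec_r,
    dec_d,
    e_syn,
    ev_step,   # (E,) sorted event step indices
    ev_comp,
    ev_w,      # (E,) µS increments (already peak-normalized)
    stim_comp,  # (M,)
    stim_I,     # (M, n_steps) nA
    rec_idx,    # (R,)
    v_out,      # (R, n_steps + 1)
    snap_step,  # (S,) step indices at which to snapshot all compartments
    v_snap,     # (S, N)
):
    """Advance the model n_steps; record voltages; return -1 or failing step."""
    n = V.shape[0]
    d = np.empty(n)
    rhs = np.empty(n)
    v_new = np.empty(n)
    for r in range(rec_idx.shape[0]):
        v_out[r, 0] = V[rec_idx[r]]
    ev = 0
    n_ev = ev_step.shape[0]
    for step in range(n_steps):
        # synaptic conductance states advance to the end of this step
        for i in range(n):
            syn_A[i] *= dec_r
            syn_B[i] *= dec_d
        while ev < n_ev and ev_step[ev] <= step:
            syn_A[ev_comp[ev]] += ev_w[ev]
            syn_B[ev_comp[ev]] += ev_w[ev]
            ev += 1
        # staggered gate update from start-of-step voltage
        xinf, tau = gate_inf_tau(gp, sign, V)
        for g in range(N_GATES):
            for i in range(n):
                X[g, i] = xinf[g, i] + (X[g, i] - xinf[g, i]) * np.exp(-dt / tau[g, i])
        # assemble diagonal and right-hand side
        for i in range(n):
            m = X[0, i]
            g_na = gbar[0, i] * m * m * m * X[1, i]
            g_kdr = gbar[1, i] * X[2, i]
            g_ka = gbar[2, i] * X[3, i] * X[4, i]
            g_h = gbar[3, i] * X[5, i]
            g_syn = syn_B[i] - syn_A[i]
            if g_syn < 0.0:
                g_syn = 0.0
            g_mem = g_leak[i] + g_na + g_kdr + g_ka + g_h + g_syn
            d[i] = c_dt[i] + g_mem
            rhs[i] = (
                c_dt[i] * V[i]
                + g_leak[i] * e_leak[i]
                + g_na * e_rev[0]
                + g_kdr * e_rev[1]
                + g_ka * e_rev[2]
                + g_h * e_rev[3]
                + g_syn * e_syn
            )
        for m_i in range(stim_comp.shape[0]):
            rhs[stim_comp[m_i]] += stim_I[m_i, step]
        for i in range(1, n):
            d[i] += g_ax[i]
            d[parent[i]] += g_ax[i]
        hines_solve(parent, g_ax, d, rhs, v_new)
        for i in range(n):
            V[i] = v_new[i]
            if not np.isfinite(V[i]):
                return step
        for r in range(rec_idx.shape[0]):
            v_out[r, step + 1] = V[rec_idx[r]]
        for s in range(snap_step.shape[0]):
            if snap_step[s] == step:
                for i in range(n):
                    v_snap[s, i] = V[i]
    return -1
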