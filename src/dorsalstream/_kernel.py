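"""Numba-jitted fixed-step Euler kernel for the delayed stochastic system.

The kernel is a fused, array-index version of the reference drift in
:mod:`dorsalstream.model`; the two are held equal by tests (noise-free
trajectories agree to floating-point round-off).  State layout matches
``model.STATE_DIM``: per area (y_p, x_p, y_e, x_e, y_s, x_s, y_f, x_f),
then the six projection channels (k21, k51, k52, k12, k15, k25) as
(y, x) pairs.

Delayed pyramidal rates come from a per-step history array; steps before
t = 0 read a zero history, consistent with the zero initial state since
S(0) = 0.
"""

import numpy as np
from numba import njit

#: projection channel wiring: source area index and target area index
#: for (k21, k51, k52, k12, k15, k25); areas ordered (v1, v2, v5)
PROJ_SRC = np.array([1, 2, 2, 0, 0, 1], dtype=np.int64)
PROJ_TGT = np.array([0, 0, 1, 1, 2, 2], dtype=np.int64)


@njit(cache=True)
def _sig(v, e0, r):
    return 2.0 * e0 / (1.0 + np.exp(-r * v)) - e0


@njit(cache=True)
def euler_run(state, n_steps, dt, delay_steps, e0, r,
              H, a, c, k, noise, proj_src, proj_tgt,
              out_vp, out_full, record_full):
    """Advance ``state`` (length 36, modified in place) by ``n_steps``.

    H, a : (3, 4) per-area, per-channel gain and rate constant
    c    : (3, 8) intra-area weights (c_pe, c_pf, c_ps, c_ep, c_fp, c_fs, c_sp, c_sf)
    k    : (6,) projection strengths
    noise: (n_steps, 3) exogenous drive samples p_i
    out_vp: (n_steps, 3) pyramidal potentials sampled before each step
    out_full: (n_steps, 36) optional full-state record

    Returns -1 on success, else the index of the first step at which a
    pyramidal potential became non-finite.
    """
    zhist = np.zeros((n_steps, 3))
    deriv = np.empty(36)
    for i in range(n_steps):
        # projection outputs
        y21 = state[24]; y51 = state[26]; y52 = state[28]
        y12 = state[30]; y15 = state[32]; y25 = state[34]
        desc0 = y21 + y51
        # pyramidal membrane potentials (recorded sample at t_i)
        vp = np.empty(3)
        for aa in range(3):
            ye = state[aa * 8 + 2]; ys = state[aa * 8 + 4]; yf = state[aa * 8 + 6]
            vp[aa] = c[aa, 3] * ye - c[aa, 4] * yf - c[aa, 6] * ys
        vp[0] += desc0
        vp[1] += y52
        out_vp[i, 0] = vp[0]; out_vp[i, 1] = vp[1]; out_vp[i, 2] = vp[2]
        if record_full:
            for q in range(36):
                out_full[i, q] = state[q]
        if not (np.isfinite(vp[0]) and np.isfinite(vp[1]) and np.isfinite(vp[2])):
            return i
        # pyramidal firing rates and their history
        for aa in range(3):
            zhist[i, aa] = _sig(vp[aa], e0, r)
        j = i - delay_steps
        zd0 = zhist[j, 0] if j >= 0 else 0.0
        zd1 = zhist[j, 1] if j >= 0 else 0.0
        zd2 = zhist[j, 2] if j >= 0 else 0.0
        zdel = (zd0, zd1, zd2)
        # population channel derivatives
        for aa in range(3):
            yp = state[aa * 8 + 0]
            ys = state[aa * 8 + 4]; yf = state[aa * 8 + 6]
            asc = 0.0
            if aa == 1:
                asc = y12
            elif aa == 2:
                asc = y15 + y25
            dsc = desc0 if aa == 0 else (y52 if aa == 1 else 0.0)
            u_p = zhist[i, aa]
            u_e = _sig(c[aa, 0] * yp + asc, e0, r) + noise[i, aa] / c[aa, 3]
            u_s = _sig(c[aa, 2] * yp - c[aa, 5] * yf, e0, r)
            # fIN also receives the descending projections inside its rate argument
            u_f = _sig(c[aa, 1] * yp - c[aa, 7] * ys + dsc, e0, r)
            u = (u_p, u_e, u_s, u_f)
            for m in range(4):
                idx = aa * 8 + 2 * m
                y = state[idx]; x = state[idx + 1]
                deriv[idx] = x
                deriv[idx + 1] = H[aa, m] * a[aa, m] * u[m] - 2.0 * a[aa, m] * x - a[aa, m] * a[aa, m] * y
        # projection channel derivatives (excitatory kernel of the target area)
        for ch in range(6):
            tgt = proj_tgt[ch]
            He = H[tgt, 0]; ae = a[tgt, 0]
            idx = 24 + 2 * ch
            y = state[idx]; x = state[idx + 1]
            u = k[ch] * zdel[proj_src[ch]]
            deriv[idx] = x
            deriv[idx + 1] = He * ae * u - 2.0 * ae * x - ae * ae * y
        # explicit Euler update
        for q in range(36):
            state[q] += dt * deriv[q]
    return -1
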