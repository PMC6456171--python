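"""Numba core for the stochastic compartment permeability simulation.

The amount of substance obeys a linear ODE whose coefficients are
piecewise-constant over each 1-s state interval.  Intact sections carry no
flux, so during an interval only the small clusters of compartments joined
by currently-broken sections evolve; everything else is frozen.  Each
cluster system is symmetrizable (similarity by diag(1/sqrt(A_i))), so the
interval is propagated *exactly* with an eigendecomposition, including the
constant inflow from the clamped basal reservoir and the exact time
integral of every compartment amount (used to accumulate apical influx and
the basal exchange for mass-balance accounting).  This is unconditionally
stable against the stiff transfer rates (~10^2..10^3 s^-1).

State update: one uniform draw per section per step, synchronously
(intact -> broken with prob p_break*l, broken -> intact with prob p_seal),
so a given seed yields a bit-reproducible trajectory.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Node labels must match geometry.BASAL / geometry.APICAL.
_BASAL = -1
_APICAL = -2


@njit(cache=True)
def _find(parent, i):
    r = i
    while parent[r] != r:
        r = parent[r]
    while parent[i] != r:
        nxt = parent[i]
        parent[i] = r
        i = nxt
    return r


@njit(cache=True)
def _phi(x):
    # (e^x - 1) / x, phi(0) = 1
    if abs(x) < 1e-8:
        return 1.0 + x / 2.0 + x * x / 6.0
    return np.expm1(x) / x


@njit(cache=True)
def _psi(x):
    # (phi(x) - 1) / x, psi(0) = 1/2
    if abs(x) < 1e-8:
        return 0.5 + x / 6.0 + x * x / 24.0
    return (np.expm1(x) / x - 1.0) / x


@njit(cache=True)
def run_replicate(sec_u, sec_v, sec_pb, sec_pstat, p_seal,
                  area, a_basal, q_basal, k_coef,
                  q0, n_steps, dt, seed, accum_from):
    """Simulate one replicate; returns trace and mass accounting.

    Parameters
    ----------
    sec_u, sec_v : int64 section endpoints (compartment id, -1 basal, -2 apical)
    sec_pb       : per-step break probability per section
    sec_pstat    : stationary broken probability per section (initial draw)
    area         : compartment areas (m^2)
    a_basal      : basal compartment area (m^2)
    q_basal      : clamped basal amount (m^-1)
    k_coef       : l_break * P_break (m^2 s^-1); k_ij = k_coef / A_i
    q0           : initial compartment amounts
    accum_from   : step index from which compartment amounts are averaged
                   (for equilibrium-profile estimation)

    Returns
    -------
    trace, q, q_mean, q_apical, in_basal, out_basal
    """
    np.random.seed(seed)
    S = sec_u.shape[0]
    n_comp = area.shape[0]

    broken = np.empty(S, np.bool_)
    for s in range(S):
        broken[s] = np.random.random() < sec_pstat[s]

    q = q0.copy()
    trace = np.zeros(n_steps + 1)
    q_ap = 0.0
    in_bas = 0.0
    out_bas = 0.0
    q_accum = np.zeros(n_comp)
    n_accum = 0

    inv_sqrt = 1.0 / np.sqrt(area)
    sqrt_a = np.sqrt(area)

    parent = np.empty(n_comp, np.int64)
    cl_of = np.empty(n_comp, np.int64)
    loc = np.empty(n_comp, np.int64)
    bidx = np.empty(S, np.int64)

    for t in range(n_steps):
        nb = 0
        for s in range(S):
            if broken[s]:
                bidx[nb] = s
                nb += 1
        if nb > 0:
            # ---- cluster the compartments touched by broken sections
            for i in range(n_comp):
                parent[i] = -9
            for b in range(nb):
                s = bidx[b]
                u = sec_u[s]
                v = sec_v[s]
                if u >= 0 and parent[u] == -9:
                    parent[u] = u
                if v >= 0 and parent[v] == -9:
                    parent[v] = v
                if u >= 0 and v >= 0:
                    ru = _find(parent, u)
                    rv = _find(parent, v)
                    if ru != rv:
                        parent[ru] = rv
            ncl = 0
            for i in range(n_comp):
                cl_of[i] = -1
            for i in range(n_comp):
                if parent[i] != -9:
                    r = _find(parent, i)
                    if cl_of[r] == -1:
                        cl_of[r] = ncl
                        ncl += 1
            csize = np.zeros(ncl, np.int64)
            for i in range(n_comp):
                if parent[i] != -9:
                    csize[cl_of[_find(parent, i)]] += 1
            offs = np.zeros(ncl + 1, np.int64)
            for c in range(ncl):
                offs[c + 1] = offs[c] + csize[c]
            nodes_flat = np.empty(offs[ncl], np.int64)
            fill = offs[:ncl].copy()
            for i in range(n_comp):
                if parent[i] != -9:
                    c = cl_of[_find(parent, i)]
                    nodes_flat[fill[c]] = i
                    loc[i] = fill[c] - offs[c]
                    fill[c] += 1

            # ---- propagate each cluster exactly over [t, t + dt)
            for c in range(ncl):
                k = csize[c]
                o = offs[c]
                A = np.zeros((k, k))
                bq = np.zeros(k)
                wap = np.zeros(k)
                wbas = np.zeros(k)
                for b in range(nb):
                    s = bidx[b]
                    u = sec_u[s]
                    v = sec_v[s]
                    iu = u if u >= 0 else v
                    if cl_of[_find(parent, iu)] != c:
                        continue
                    if u >= 0 and v >= 0:
                        i = loc[u]
                        j = loc[v]
                        A[i, i] -= k_coef / area[u]
                        A[j, j] -= k_coef / area[v]
                        off = k_coef * inv_sqrt[u] * inv_sqrt[v]
                        A[i, j] += off
                        A[j, i] += off
                    else:
                        bnd = u if u < 0 else v
                        ii = loc[iu]
                        A[ii, ii] -= k_coef / area[iu]
                        if bnd == _BASAL:
                            bq[ii] += k_coef / a_basal * q_basal
                            wbas[ii] += k_coef / area[iu]
                        else:
                            wap[ii] += k_coef / area[iu]

                if k == 1:
                    g = nodes_flat[o]
                    lam = A[0, 0] * dt
                    y0 = q[g] * inv_sqrt[g]
                    by = bq[0] * inv_sqrt[g]
                    y1 = np.exp(lam) * y0 + dt * _phi(lam) * by
                    Iy = dt * _phi(lam) * y0 + dt * dt * _psi(lam) * by
                    q[g] = y1 * sqrt_a[g]
                    Iq = Iy * sqrt_a[g]
                    q_ap += wap[0] * Iq
                    out_bas += wbas[0] * Iq
                    in_bas += bq[0] * dt
                else:
                    y0 = np.empty(k)
                    by = np.empty(k)
                    for i in range(k):
                        g = nodes_flat[o + i]
                        y0[i] = q[g] * inv_sqrt[g]
                        by[i] = bq[i] * inv_sqrt[g]
                    if k == 2:
                        # closed-form eigensystem of the symmetric 2x2
                        vals = np.empty(2)
                        vecs = np.empty((2, 2))
                        half = 0.5 * (A[0, 0] + A[1, 1])
                        dh = 0.5 * (A[0, 0] - A[1, 1])
                        rad = np.sqrt(dh * dh + A[0, 1] * A[0, 1])
                        vals[0] = half - rad
                        vals[1] = half + rad
                        if rad < 1e-300:
                            vecs[0, 0] = 1.0; vecs[1, 0] = 0.0
                            vecs[0, 1] = 0.0; vecs[1, 1] = 1.0
                        else:
                            # eigenvector for vals[1]: (c, rad - dh) direction
                            vx = A[0, 1]
                            vy = rad - dh
                            nrm = np.sqrt(vx * vx + vy * vy)
                            if nrm < 1e-300:
                                vx, vy, nrm = 1.0, 0.0, 1.0
                            vx /= nrm
                            vy /= nrm
                            vecs[0, 1] = vx; vecs[1, 1] = vy
                            vecs[0, 0] = -vy; vecs[1, 0] = vx
                    else:
                        vals, vecs = np.linalg.eigh(A)
                    cv = vecs.T.copy() @ y0
                    bv = vecs.T.copy() @ by
                    y1 = np.zeros(k)
                    Iy = np.zeros(k)
                    for m in range(k):
                        lam = vals[m] * dt
                        e = np.exp(lam)
                        ph = _phi(lam)
                        ps = _psi(lam)
                        am = e * cv[m] + dt * ph * bv[m]
                        im = dt * ph * cv[m] + dt * dt * ps * bv[m]
                        for i in range(k):
                            y1[i] += vecs[i, m] * am
                            Iy[i] += vecs[i, m] * im
                    for i in range(k):
                        g = nodes_flat[o + i]
                        q[g] = y1[i] * sqrt_a[g]
                        Iq = Iy[i] * sqrt_a[g]
                        q_ap += wap[i] * Iq
                        out_bas += wbas[i] * Iq
                        in_bas += bq[i] * dt

        trace[t + 1] = q_ap
        if t >= accum_from:
            for i in range(n_comp):
                q_accum[i] += q[i]
            n_accum += 1

        # ---- synchronous state update on the 1-s grid
        for s in range(S):
            u = np.random.random()
            if broken[s]:
                if u < p_seal:
                    broken[s] = False
            else:
                if u < sec_pb[s]:
                    broken[s] = True

    q_mean = q_accum / n_accum if n_accum > 0 else q_accum
    return trace, q, q_mean, q_ap, in_bas, out_bas
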