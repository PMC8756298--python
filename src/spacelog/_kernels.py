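"""Numba inner loops for the coordinate-descent solvers.

These kernels implement active shooting: one full coordinate sweep, then
iteration over the currently nonzero (active) coordinates until stable, then
another full sweep, repeated until a full sweep moves no coordinate by more
than ``tol``.

For the joint (space) solver a coordinate is an unordered gene pair (i, j);
its single stored value rho_ij enters both gene i's and gene j's regressions,
so the update aggregates both partial residuals before soft-thresholding:

    c   = w_i a_ij <Y_j, r_i + rho_ij a_ij Y_j> + w_j a_ji <Y_i, r_j + rho_ij a_ji Y_i>
    V   = w_i a_ij^2 |Y_j|^2 + w_j a_ji^2 |Y_i|^2
    rho <- S(c, thr_ij) / V,      a_ij = sqrt(d_j / d_i),  d_i = sigma^{ii}

where S is the soft-threshold operator and thr_ij the per-pair linear penalty
level (the thresholds are constants during one inner solve, so the inner
problem is a weighted lasso).
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _space_sweep(Y, csq, R, rho, w, d, thr, ii, jj):
    """One pass of pair updates over (ii, jj); returns max |change|."""
    n = Y.shape[0]
    maxch = 0.0
    for p in range(ii.shape[0]):
        i = ii[p]
        j = jj[p]
        a = np.sqrt(d[j] / d[i])
        b = np.sqrt(d[i] / d[j])
        rij = rho[i, j]
        dot_ij = 0.0
        dot_ji = 0.0
        for t in range(n):
            dot_ij += Y[t, j] * R[t, i]
            dot_ji += Y[t, i] * R[t, j]
        c = w[i] * a * (dot_ij + rij * a * csq[j]) + w[j] * b * (
            dot_ji + rij * b * csq[i]
        )
        V = w[i] * a * a * csq[j] + w[j] * b * b * csq[i]
        t_ij = thr[i, j]
        ac = abs(c)
        if ac <= t_ij:
            new = 0.0
        else:
            new = np.sign(c) * (ac - t_ij) / V
        delta = new - rij
        if delta != 0.0:
            rho[i, j] = new
            rho[j, i] = new
            da = delta * a
            db = delta * b
            for t in range(n):
                R[t, i] -= da * Y[t, j]
                R[t, j] -= db * Y[t, i]
            ad = abs(delta)
            if ad > maxch:
                maxch = ad
    return maxch


@njit(cache=True)
def space_active_shooting(Y, csq, R, rho, w, d, thr, tol, max_sweeps):
    """Active shooting over all unordered pairs; mutates rho and R in place.

    Returns (number of sweeps used, converged flag).
    """
    m = rho.shape[0]
    total = m * (m - 1) // 2
    fi = np.empty(total, np.int64)
    fj = np.empty(total, np.int64)
    k = 0
    for i in range(m):
        for j in range(i + 1, m):
            fi[k] = i
            fj[k] = j
            k += 1
    sweeps = 0
    while sweeps < max_sweeps:
        ch = _space_sweep(Y, csq, R, rho, w, d, thr, fi, fj)
        sweeps += 1
        if ch <= tol:
            return sweeps, True
        # iterate the active (nonzero) set until it is stable
        while sweeps < max_sweeps:
            cnt = 0
            for p in range(total):
                if rho[fi[p], fj[p]] != 0.0:
                    cnt += 1
            if cnt == 0:
                break
            ai = np.empty(cnt, np.int64)
            aj = np.empty(cnt, np.int64)
            q = 0
            for p in range(total):
                if rho[fi[p], fj[p]] != 0.0:
                    ai[q] = fi[p]
                    aj[q] = fj[p]
                    q += 1
            ch2 = _space_sweep(Y, csq, R, rho, w, d, thr, ai, aj)
            sweeps += 1
            if ch2 <= tol:
                break
    return sweeps, False


@njit(cache=True)
def _ns_sweep(X, csq, r, beta, thr, idx):
    """One pass of single-coefficient lasso updates; returns max |change|."""
    n = X.shape[0]
    maxch = 0.0
    for p in range(idx.shape[0]):
        j = idx[p]
        bj = beta[j]
        dot = 0.0
        for t in range(n):
            dot += X[t, j] * r[t]
        c = dot + bj * csq[j]
        ac = abs(c)
        if ac <= thr[j]:
            new = 0.0
        else:
            new = np.sign(c) * (ac - thr[j]) / csq[j]
        delta = new - bj
        if delta != 0.0:
            beta[j] = new
            for t in range(n):
                r[t] -= delta * X[t, j]
            ad = abs(delta)
            if ad > maxch:
                maxch = ad
    return maxch


@njit(cache=True)
def ns_active_shooting(X, csq, r, beta, thr, tol, max_sweeps):
    """Active shooting for one penalized regression; mutates beta and r."""
    p = beta.shape[0]
    full = np.arange(p)
    sweeps = 0
    while sweeps < max_sweeps:
        ch = _ns_sweep(X, csq, r, beta, thr, full)
        sweeps += 1
        if ch <= tol:
            return sweeps, True
        while sweeps < max_sweeps:
            cnt = 0
            for j in range(p):
                if beta[j] != 0.0:
                    cnt += 1
            if cnt == 0:
                break
            act = np.empty(cnt, np.int64)
            q = 0
            for j in range(p):
                if beta[j] != 0.0:
                    act[q] = j
                    q += 1
            ch2 = _ns_sweep(X, csq, r, beta, thr, act)
            sweeps += 1
            if ch2 <= tol:
                break
    return sweeps, False
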