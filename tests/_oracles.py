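"""Independent reference implementations used only to check the solvers.

These deliberately avoid the package's internal helpers: the objective is
assembled gene by gene from the model definition, the weighted-lasso problem
is solved by proximal gradient (ISTA with backtracking) on the vector of
upper-triangular pair values, and the one-dimensional coordinate subproblem
is minimized by brute-force grid search.
"""

from __future__ import annotations

import numpy as np


def space_objective(Y, rho, d, w, pair_penalty):
    """Penalized loss assembled from scratch.

    ``pair_penalty[i, j]`` is the effective linear penalty on |rho_ij| for
    the unordered pair (i, j) (counted once per pair).
    """
    n, m = Y.shape
    obj = 0.0
    for i in range(m):
        pred = np.zeros(n)
        for j in range(m):
            if j != i:
                pred += rho[i, j] * np.sqrt(d[j] / d[i]) * Y[:, j]
        r = Y[:, i] - pred
        obj += 0.5 * w[i] * (r @ r)
    for i in range(m):
        for j in range(i + 1, m):
            obj += pair_penalty[i, j] * abs(rho[i, j])
    return obj


def prox_grad_space(Y, d, w, pair_penalty, max_iter=50000, tol=1e-13):
    """Proximal-gradient (ISTA + backtracking) minimizer of space_objective.

    Returns the symmetric rho matrix at the minimum.
    """
    n, m = Y.shape
    iu = np.triu_indices(m, k=1)
    npair = len(iu[0])
    x = np.zeros(npair)
    lam = np.array([pair_penalty[i, j] for i, j in zip(*iu)])

    def unpack(x):
        rho = np.zeros((m, m))
        rho[iu] = x
        return rho + rho.T

    def smooth_val_grad(x):
        rho = unpack(x)
        val = 0.0
        resid = np.zeros((n, m))
        for i in range(m):
            pred = np.zeros(n)
            for j in range(m):
                if j != i:
                    pred += rho[i, j] * np.sqrt(d[j] / d[i]) * Y[:, j]
            resid[:, i] = Y[:, i] - pred
            val += 0.5 * w[i] * (resid[:, i] @ resid[:, i])
        grad = np.zeros(npair)
        for p, (i, j) in enumerate(zip(*iu)):
            a = np.sqrt(d[j] / d[i])
            b = np.sqrt(d[i] / d[j])
            grad[p] = -w[i] * a * (Y[:, j] @ resid[:, i]) - w[j] * b * (
                Y[:, i] @ resid[:, j]
            )
        return val, grad

    def soft(v, t):
        return np.sign(v) * np.maximum(np.abs(v) - t, 0.0)

    step = 1.0 / (np.linalg.norm(Y, ord=2) ** 2 * (np.max(w) + 1e-12))
    fval, grad = smooth_val_grad(x)
    for _ in range(max_iter):
        while True:
            x_new = soft(x - step * grad, step * lam)
            f_new, g_new = smooth_val_grad(x_new)
            diff = x_new - x
            quad = fval + grad @ diff + (diff @ diff) / (2 * step)
            if f_new <= quad + 1e-12:
                break
            step *= 0.5
        if np.max(np.abs(x_new - x)) < tol:
            x, fval, grad = x_new, f_new, g_new
            break
        x, fval, grad = x_new, f_new, g_new
        step *= 1.2  # allow the step to grow back
    return unpack(x)


def grid_minimize_coordinate(z, V, threshold, n_points=10**4):
    """Brute-force minimizer of the 1-D pair objective.

    h(r) = V/2 (r - z)^2 + threshold * |r|  (up to a constant this is the
    per-pair subproblem with aggregated inner product c = z*V).  The
    minimizer always lies in [-|z|, |z|].
    """
    lo, hi = -abs(z), abs(z)
    grid = np.linspace(lo, hi, n_points)
    vals = 0.5 * V * (grid - z) ** 2 + threshold * np.abs(grid)
    return float(grid[np.argmin(vals)])


def partial_correlation_by_schur(precision):
    """Partial correlations via population regression on the complement.

    For each pair (i, j), the conditional covariance of (Y_i, Y_j) given the
    rest is the Schur complement Sigma_AA - Sigma_AB Sigma_BB^{-1} Sigma_BA of
    the covariance Sigma = precision^{-1}; its off-diagonal, standardized,
    is the partial correlation.  Independent of the concentration-matrix
    identity used by the implementation.
    """
    sigma = np.linalg.inv(precision)
    m = sigma.shape[0]
    rho = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            a = [i, j]
            b = [k for k in range(m) if k not in a]
            saa = sigma[np.ix_(a, a)]
            if b:
                sab = sigma[np.ix_(a, b)]
                sbb = sigma[np.ix_(b, b)]
                cond = saa - sab @ np.linalg.solve(sbb, sab.T)
            else:
                cond = saa
            r = cond[0, 1] / np.sqrt(cond[0, 0] * cond[1, 1])
            rho[i, j] = rho[j, i] = r
    return rho
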