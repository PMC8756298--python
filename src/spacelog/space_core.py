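"""Joint sparse partial-correlation estimation (space) with lasso or log penalty.

The model: expression of m genes is multivariate Gaussian N(0, Sigma) with
concentration matrix Sigma^{-1} = (sigma^{ij}).  The partial correlation
rho_ij = -sigma^{ij}/sqrt(sigma^{ii} sigma^{jj}) satisfies, for every gene i,

    Y_i = sum_{j != i} rho_ij sqrt(sigma^{jj}/sigma^{ii}) Y_j + eps_i,

so all pairwise partial correlations can be estimated jointly by minimizing
one penalized, weighted least-squares loss over the symmetric matrix rho:

    f(rho; sigma) = 1/2 sum_i w_i | Y_i - sum_{j != i} rho_ij
                    sqrt(sigma^{jj}/sigma^{ii}) Y_j |^2
                    + sum_{i != j} p(|rho_ij|)

with p(|rho|) = lambda |rho| (space-lasso) or lambda log(|rho| + tau)
(space-log).  Because rho_ij = rho_ji, the penalty sum over ordered pairs
counts each pair twice; a single value is stored per unordered pair and the
effective per-pair penalty is 2 p(|rho|), so lambda is on the same scale as
the ordered-sum convention.

The lasso problem is solved directly by active-shooting coordinate descent.
The nonconvex log penalty is handled by Local Linear Approximation (LLA):
starting from the space-lasso solution at the same lambda, each LLA iteration
replaces the log penalty by its tangent at the current estimate, giving
per-pair linear penalty levels 2 lambda / (|rho^(k)_ij| + tau), and solves the
resulting weighted-lasso problem by active shooting.  Since the log penalty is
concave in |rho|, this is a majorize-minimize scheme and the objective is
non-increasing across LLA iterations.

Residual precisions sigma^{ii} are re-estimated from the current fit between
outer iterations (sigma_hat^{ii} = 1 / mean squared residual of gene i), and
the regression weights w_i follow one of three schemes: uniform (w_i = 1),
residual (w_i = sigma_hat^{ii}) or degree (w_i = current number of neighbors
of gene i, floored at 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._kernels import space_active_shooting

logger = logging.getLogger(__name__)

__all__ = [
    "PenaltySpec",
    "WEIGHT_SCHEMES",
    "CoordinateState",
    "SpaceFit",
    "soft_threshold_update",
    "log_penalty_derivative",
    "compute_partial_residual",
    "active_shooting",
    "fit_space",
    "update_sigma",
    "update_weights",
    "objective_value",
    "beta_to_rho",
    "edge_support",
    "EDGE_EPS",
]

WEIGHT_SCHEMES = ("uniform", "residual", "degree")

#: |rho_ij| above this counts as an edge.  Exact zeros are produced by the
#: soft threshold, so this only guards float noise.
EDGE_EPS = 1e-8


@dataclass(frozen=True)
class PenaltySpec:
    """Penalty p(|rho|): ``lasso`` -> lam*|rho|; ``log`` -> lam*log(|rho|+tau)."""

    kind: str
    lam: float
    tau: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("lasso", "log"):
            raise ValueError(f"penalty kind must be 'lasso' or 'log', got {self.kind!r}")
        if self.lam < 0:
            raise ValueError(f"lambda must be nonnegative, got {self.lam}")
        if self.kind == "log" and (self.tau is None or self.tau <= 0):
            raise ValueError("log penalty requires tau > 0")

    def value(self, rho_abs: np.ndarray | float) -> np.ndarray | float:
        if self.kind == "lasso":
            return self.lam * np.abs(rho_abs)
        return self.lam * np.log(np.abs(rho_abs) + self.tau)


@dataclass(frozen=True)
class CoordinateState:
    """State of one pair-coordinate update.

    ``z`` is the V-normalized aggregated partial-residual inner product,
    ``V`` the aggregated squared predictor norm and ``threshold`` the
    effective linear penalty level for the pair (compared against |z|*V).
    """

    z: float
    V: float
    threshold: float

    def __post_init__(self) -> None:
        if self.V <= 0:
            raise ValueError(f"predictor squared norm must be positive, got {self.V}")


@dataclass
class SpaceFit:
    """Result of a joint partial-correlation fit."""

    rho: np.ndarray
    sigma_inv_diag: np.ndarray
    weights: np.ndarray
    penalty: PenaltySpec
    n_outer_iterations: int = 0
    converged: bool = True
    final_objective: float = np.nan
    objective_trace: list[float] = field(default_factory=list)
    n_sweeps: int = 0

    @property
    def m(self) -> int:
        return self.rho.shape[0]

    def edges(self) -> frozenset[tuple[int, int]]:
        iu, ju = np.nonzero(np.triu(np.abs(self.rho) > EDGE_EPS, k=1))
        return frozenset((int(i), int(j)) for i, j in zip(iu, ju))


def soft_threshold_update(state: CoordinateState) -> float:
    """Closed-form minimizer of the one-dimensional pair subproblem.

    Returns 0 when |z| <= threshold/V, else sign(z) (|z| - threshold/V);
    continuous in z, and |result| <= |z|.
    """
    level = state.threshold / state.V
    if abs(state.z) <= level:
        return 0.0
    return float(np.sign(state.z) * (abs(state.z) - level))


def log_penalty_derivative(rho_current: float, lam: float, tau: float) -> float:
    """Magnitude of the log-penalty derivative, lambda / (|rho| + tau)."""
    if tau <= 0:
        raise ValueError(f"tau must be positive, got {tau}")
    return lam / (abs(rho_current) + tau)


def beta_to_rho(beta_ij: float, beta_ji: float) -> float:
    """Symmetrize a pair of regression coefficients into a partial correlation.

    rho_ij = sign(beta_ij) sqrt(beta_ij beta_ji); zero if either coefficient
    is zero.  A sign conflict (one positive, one negative) yields 0 with a
    logged note — the pair is not called an edge.
    """
    if beta_ij == 0.0 or beta_ji == 0.0:
        return 0.0
    if beta_ij * beta_ji < 0:
        logger.info(
            "sign conflict beta_ij=%g, beta_ji=%g; returning rho=0", beta_ij, beta_ji
        )
        return 0.0
    return float(np.sign(beta_ij) * np.sqrt(beta_ij * beta_ji))


# ---------------------------------------------------------------------------
# input handling


def _as_centered_matrix(Y) -> np.ndarray:
    """Coerce a DataFrame/array to a mean-centered float64 Fortran array."""
    vals = Y.to_numpy(dtype=float) if isinstance(Y, pd.DataFrame) else np.asarray(Y, float)
    if vals.ndim != 2:
        raise ValueError(f"expression matrix must be 2-D, got shape {vals.shape}")
    n, m = vals.shape
    if m < 2:
        raise ValueError(f"need at least 2 genes, got {m}")
    if n < 2:
        raise ValueError(f"need at least 2 samples, got {n}")
    if not np.all(np.isfinite(vals)):
        raise ValueError("expression matrix contains non-finite values")
    vals = vals - vals.mean(axis=0)
    csq = np.einsum("ij,ij->j", vals, vals)
    if np.any(csq <= 0):
        bad = int(np.argmin(csq))
        raise ValueError(f"gene column {bad} is constant (zero variance)")
    return np.asfortranarray(vals)


def _initial_state(Y: np.ndarray, weight_scheme: str):
    """Initial sigma^{ii} (1/mean-square) and weights for a zero-rho start."""
    n = Y.shape[0]
    csq = np.einsum("ij,ij->j", Y, Y)
    d0 = n / csq
    if weight_scheme == "residual":
        w0 = d0.copy()
    else:  # uniform; degree with empty support floors to 1
        w0 = np.ones_like(d0)
    return csq, d0, w0


def _residuals(Y: np.ndarray, rho: np.ndarray, d: np.ndarray) -> np.ndarray:
    """R[:, i] = Y_i - sum_j rho_ij sqrt(d_j/d_i) Y_j."""
    s = np.sqrt(d[None, :] / d[:, None])  # s[i, j] = sqrt(d_j / d_i)
    coef = rho * s
    np.fill_diagonal(coef, 0.0)
    return np.asfortranarray(Y - Y @ coef.T)


def compute_partial_residual(
    Y,
    rho: np.ndarray,
    sigma_inv_diag: np.ndarray,
    i: int,
    j: int,
    weights: np.ndarray | None = None,
    threshold: float = 0.0,
) -> CoordinateState:
    """Assemble the coordinate state (z, V) for the pair (i, j).

    rho_ij appears in both gene i's and gene j's regressions; z and V
    aggregate both partial residuals, weighted by w_i and w_j.
    """
    Yc = _as_centered_matrix(Y)
    m = Yc.shape[1]
    if not (0 <= i < m and 0 <= j < m) or i == j:
        raise ValueError(f"invalid pair ({i}, {j}) for m={m}")
    d = np.asarray(sigma_inv_diag, float)
    w = np.ones(m) if weights is None else np.asarray(weights, float)
    csq = np.einsum("ij,ij->j", Yc, Yc)
    R = _residuals(Yc, np.asarray(rho, float), d)
    a = np.sqrt(d[j] / d[i])
    b = np.sqrt(d[i] / d[j])
    rij = float(rho[i, j])
    c = w[i] * a * (Yc[:, j] @ R[:, i] + rij * a * csq[j]) + w[j] * b * (
        Yc[:, i] @ R[:, j] + rij * b * csq[i]
    )
    V = w[i] * a * a * csq[j] + w[j] * b * b * csq[i]
    return CoordinateState(z=float(c / V), V=float(V), threshold=threshold)


# ---------------------------------------------------------------------------
# solvers


def active_shooting(
    Y,
    penalty_weights: np.ndarray,
    weights: np.ndarray,
    init: SpaceFit,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> SpaceFit:
    """Solve the weighted-lasso inner problem with fixed per-pair thresholds.

    ``penalty_weights`` is the m x m matrix of effective per-pair linear
    penalty levels (2*lambda for a plain lasso, 2*lambda/(|rho^(k)|+tau)
    inside an LLA iteration).  sigma^{ii} and the weights are held fixed.
    """
    Yc = _as_centered_matrix(Y)
    csq = np.einsum("ij,ij->j", Yc, Yc)
    rho = np.array(init.rho, dtype=float)
    d = np.asarray(init.sigma_inv_diag, float)
    w = np.asarray(weights, float)
    thr = np.ascontiguousarray(penalty_weights, dtype=float)
    R = _residuals(Yc, rho, d)
    sweeps, converged = space_active_shooting(
        Yc, csq, R, rho, w, d, thr, tol, max_iter
    )
    if not converged:
        logger.warning("active shooting hit max_iter=%d sweeps without converging", max_iter)
    fit = SpaceFit(
        rho=rho,
        sigma_inv_diag=d.copy(),
        weights=w.copy(),
        penalty=init.penalty,
        n_outer_iterations=init.n_outer_iterations,
        converged=converged,
        n_sweeps=sweeps,
    )
    fit.final_objective = objective_value(Yc, fit)
    return fit


def update_sigma(
    Y, rho: np.ndarray, sigma_inv_diag: np.ndarray | None = None, floor: float = 1e-10
) -> np.ndarray:
    """Re-estimate sigma^{ii} = 1 / mean squared residual of gene i's regression.

    The residuals use the current rho and the previous sigma^{ii} (which set
    the predictor scaling sqrt(sigma^{jj}/sigma^{ii})).
    """
    Yc = _as_centered_matrix(Y)
    n, m = Yc.shape
    d = np.ones(m) if sigma_inv_diag is None else np.asarray(sigma_inv_diag, float)
    R = _residuals(Yc, np.asarray(rho, float), d)
    msr = np.einsum("ij,ij->j", R, R) / n
    if np.any(msr < floor):
        logger.warning("near-zero residual variance; flooring at %g", floor)
        msr = np.maximum(msr, floor)
    return 1.0 / msr


def update_weights(
    scheme: str, sigma_inv_diag: np.ndarray, rho: np.ndarray
) -> np.ndarray:
    """Regression weights: uniform -> 1; residual -> sigma^{ii}; degree ->
    current neighbor count floored at 1."""
    if scheme not in WEIGHT_SCHEMES:
        raise ValueError(f"unknown weight scheme {scheme!r}; choose from {WEIGHT_SCHEMES}")
    m = len(sigma_inv_diag)
    if scheme == "uniform":
        return np.ones(m)
    if scheme == "residual":
        return np.asarray(sigma_inv_diag, float).copy()
    deg = (np.abs(rho) > EDGE_EPS).sum(axis=1).astype(float)
    return np.maximum(deg, 1.0)


def objective_value(Y, fit: SpaceFit) -> float:
    """Penalized loss f(rho; sigma) at the fit's rho, sigma^{ii} and weights.

    Residual term 1/2 sum_i w_i |r_i|^2 plus the penalty summed over ordered
    pairs (i.e. 2 p(|rho_ij|) per unordered pair).
    """
    Yc = _as_centered_matrix(Y)
    R = _residuals(Yc, fit.rho, fit.sigma_inv_diag)
    rss = float(np.einsum("ij,ij->j", R, R) @ fit.weights)
    iu = np.triu_indices(fit.m, k=1)
    pen = 2.0 * float(np.sum(fit.penalty.value(np.abs(fit.rho[iu]))))
    return 0.5 * rss + pen


def fit_space(
    Y,
    penalty: PenaltySpec,
    weights: str = "uniform",
    n_lla: int = 3,
    n_sigma_updates: int = 3,
    tol: float = 1e-6,
    max_iter: int = 1000,
    rho_init: np.ndarray | None = None,
    lasso_init: SpaceFit | None = None,
    seed: int | None = None,
) -> SpaceFit:
    """Fit the joint space model with a lasso or log penalty.

    lasso: alternates active shooting with sigma^{ii}/weight re-estimation
    ``n_sigma_updates`` times.  log: starts from the space-lasso solution at
    the same lambda (computed here unless ``lasso_init`` is given), then runs
    up to ``n_lla`` LLA iterations with per-pair thresholds
    2 lambda / (|rho^(k)_ij| + tau), stopping early when the support is
    unchanged and the largest entry change is below ``tol``.

    ``rho_init`` warm-starts the first inner coordinate descent only; the
    sigma/weight schedule does not depend on it, so warm and cold starts
    converge to the same fit.  The fit is deterministic; ``seed`` is accepted
    for interface uniformity and unused.
    """
    del seed
    Yc = _as_centered_matrix(Y)
    n, m = Yc.shape
    if weights not in WEIGHT_SCHEMES:
        raise ValueError(f"unknown weight scheme {weights!r}; choose from {WEIGHT_SCHEMES}")

    csq, d, w = _initial_state(Yc, weights)
    rho = np.zeros((m, m)) if rho_init is None else np.array(rho_init, dtype=float)

    if penalty.kind == "log" and lasso_init is not None:
        lasso_fit = lasso_init
    else:
        # space-lasso phase (also the warm start for the log penalty)
        lam_here = penalty.lam
        lasso_pen = PenaltySpec("lasso", lam_here)
        total_sweeps = 0
        converged = True
        for t in range(n_sigma_updates):
            thr = np.full((m, m), 2.0 * lam_here)
            R = _residuals(Yc, rho, d)
            sweeps, conv = space_active_shooting(
                Yc, csq, R, rho, w, d, thr, tol, max_iter
            )
            total_sweeps += sweeps
            converged = converged and conv
            if t < n_sigma_updates - 1:
                d = update_sigma(Yc, rho, d)
                w = update_weights(weights, d, rho)
        if not converged:
            logger.warning("space-lasso inner solves hit the sweep cap")
        lasso_fit = SpaceFit(
            rho=rho,
            sigma_inv_diag=d,
            weights=w,
            penalty=lasso_pen,
            n_outer_iterations=n_sigma_updates,
            converged=converged,
            n_sweeps=total_sweeps,
        )
        lasso_fit.final_objective = objective_value(Yc, lasso_fit)
        lasso_fit.objective_trace = [lasso_fit.final_objective]
        if penalty.kind == "lasso":
            return lasso_fit

    # --- LLA iterations for the log penalty, sigma and weights held fixed ---
    lam, tau = penalty.lam, penalty.tau
    rho = np.array(lasso_fit.rho, dtype=float)
    d = np.asarray(lasso_fit.sigma_inv_diag, float)
    w = np.asarray(lasso_fit.weights, float)
    fit = SpaceFit(rho=rho, sigma_inv_diag=d, weights=w, penalty=penalty)
    fit.objective_trace = [objective_value(Yc, fit)]
    total_sweeps = int(lasso_fit.n_sweeps)
    converged = bool(lasso_fit.converged)
    n_done = 0
    for k in range(n_lla):
        thr = 2.0 * lam / (np.abs(rho) + tau)
        support_before = np.abs(rho) > EDGE_EPS
        rho_before = rho.copy()
        R = _residuals(Yc, rho, d)
        sweeps, conv = space_active_shooting(Yc, csq, R, rho, w, d, thr, tol, max_iter)
        total_sweeps += sweeps
        converged = converged and conv
        n_done = k + 1
        fit.objective_trace.append(objective_value(Yc, fit))
        support_after = np.abs(rho) > EDGE_EPS
        if (
            np.array_equal(support_before, support_after)
            and np.max(np.abs(rho - rho_before)) < tol
        ):
            break
    fit.n_outer_iterations = n_done
    fit.converged = converged
    fit.n_sweeps = total_sweeps
    fit.final_objective = fit.objective_trace[-1]
    if not converged:
        logger.warning("space-log inner solves hit the sweep cap")
    return fit


def edge_support(rho: np.ndarray) -> frozenset[tuple[int, int]]:
    """Unordered pairs with |rho_ij| above the edge-call epsilon."""
    iu, ju = np.nonzero(np.triu(np.abs(rho) > EDGE_EPS, k=1))
    return frozenset((int(i), int(j)) for i, j in zip(iu, ju))
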