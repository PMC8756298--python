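"""Tuning-parameter selection over a (lambda, tau) grid.

The default criterion is the extended BIC (extBIC) in its Gaussian-regression
form

    extBIC = N log(RSS/N) + k log N + 2 gamma k log M,

where RSS is the (weighted) residual sum of squares, k the number of selected
parameters, N the effective number of observations and M the number of
candidate parameters.  For the joint space estimator N = n*m, k counts
nonzero unordered pairs and M = m(m-1)/2; for a single neighborhood-selection
regression N = n, k counts nonzero coefficients and M = m-1.  gamma = 0
reduces exactly to the plain BIC; gamma = 0.5 (the default) is the mid-range
choice with selection consistency when the number of genes grows with n.

An "oracle" criterion — pick the grid point maximizing F1 against a known
truth graph — is supported for simulation studies, as an upper bound on what
any data-driven criterion can achieve.

The lambda grid is log-spaced below lambda_max, the smallest lambda at which
the fitted model is empty.  For the log penalty, tau values are anchored at
the scale of the lasso solution at the same lambda: tau = multiplier *
max(|rho_lasso|) with multipliers {1e-4, 1e-3, 1e-2, 1e-1} by default, and
(lambda, tau) are searched jointly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .graph_simulator import Graph
from .ns_core import NeighborhoodFit, fit_single_regression
from .space_core import (
    EDGE_EPS,
    PenaltySpec,
    SpaceFit,
    _as_centered_matrix,
    _initial_state,
    _residuals,
    fit_space,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TuningGrid",
    "SelectionResult",
    "lambda_max",
    "ns_lambda_max",
    "default_grid",
    "ext_bic",
    "select_model",
]

DEFAULT_TAU_MULTIPLIERS = (1e-4, 1e-3, 1e-2, 1e-1)


@dataclass(frozen=True)
class TuningGrid:
    """Joint (lambda, tau) search grid.

    ``lambdas`` must be strictly decreasing with the first value at the
    empty-model bound.  For the log penalty either explicit ``taus`` or
    ``tau_multipliers`` (anchored at each lasso solution's scale) are used.
    """

    kind: str
    lambdas: tuple[float, ...]
    taus: tuple[float, ...] | None = None
    tau_multipliers: tuple[float, ...] = DEFAULT_TAU_MULTIPLIERS
    gamma: float = 0.5

    def __post_init__(self) -> None:
        if self.kind not in ("lasso", "log"):
            raise ValueError(f"kind must be 'lasso' or 'log', got {self.kind!r}")
        lams = tuple(float(x) for x in self.lambdas)
        if len(lams) == 0:
            raise ValueError("empty lambda grid")
        if any(x <= 0 for x in lams):
            raise ValueError("lambdas must be positive")
        if any(b >= a for a, b in zip(lams, lams[1:])):
            raise ValueError("lambdas must be strictly decreasing")
        object.__setattr__(self, "lambdas", lams)
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError(f"gamma must be in [0,1], got {self.gamma}")

    def taus_for(self, scale: float) -> tuple[float, ...]:
        """tau values for one lambda, given the lasso solution's scale."""
        if self.kind == "lasso":
            return (None,)
        if self.taus is not None:
            return tuple(self.taus)
        anchor = max(float(scale), 1e-6)
        return tuple(mult * anchor for mult in self.tau_multipliers)


@dataclass
class SelectionResult:
    """Outcome of a grid search: the winning point and the full criterion table."""

    best_lambda: float
    best_tau: float | None
    criterion_value: float
    criterion_table: pd.DataFrame
    best_fit: SpaceFit | NeighborhoodFit = None
    best_graph: Graph | None = None
    oracle_best_f1: float = np.nan
    extras: dict = field(default_factory=dict)


def lambda_max(Y, weights: str = "uniform") -> float:
    """Smallest lambda at which the joint space fit is exactly empty.

    From a zero start the first coordinate sweep leaves every pair at zero
    iff |z_ij| * V_ij <= 2*lambda for all pairs, with z and V evaluated at
    the fit's initial sigma^{ii} and weights; lambda_max is half the largest
    initial |z|*V.
    """
    Yc = _as_centered_matrix(Y)
    csq, d0, w0 = _initial_state(Yc, weights)
    g = Yc.T @ Yc  # gram matrix; g[i, j] = <Y_i, Y_j>
    s = np.sqrt(d0[None, :] / d0[:, None])  # s[i, j] = sqrt(d_j/d_i)
    c = w0[:, None] * s * g + (w0[:, None] * s * g).T
    iu = np.triu_indices(Yc.shape[1], k=1)
    return float(np.max(np.abs(c[iu])) / 2.0)


def ns_lambda_max(Y) -> float:
    """Smallest lambda making every neighborhood-selection regression empty.

    Regression i is empty iff max_j |<Y_j, Y_i>| <= n*lambda; the shared
    bound is the largest off-diagonal absolute gram entry over n.
    """
    Yc = _as_centered_matrix(Y)
    n = Yc.shape[0]
    g = Yc.T @ Yc
    np.fill_diagonal(g, 0.0)
    return float(np.max(np.abs(g)) / n)


def default_grid(
    Y,
    kind: str,
    weights: str = "uniform",
    n_lambda: int = 30,
    lambda_min_ratio: float = 0.01,
    gamma: float = 0.5,
    for_ns: bool = False,
    tau_multipliers: tuple[float, ...] = DEFAULT_TAU_MULTIPLIERS,
) -> TuningGrid:
    """Log-spaced lambda grid over [ratio*lambda_max, lambda_max], decreasing."""
    lmax = ns_lambda_max(Y) if for_ns else lambda_max(Y, weights)
    lams = np.geomspace(lmax, lambda_min_ratio * lmax, n_lambda)
    return TuningGrid(
        kind=kind, lambdas=tuple(lams), gamma=gamma, tau_multipliers=tau_multipliers
    )


# ---------------------------------------------------------------------------
# extBIC


def _ext_bic_terms(rss: float, k: int, n_obs: int, n_candidates: int, gamma: float) -> float:
    if k >= n_obs:
        raise ValueError(f"degenerate model: k={k} >= N={n_obs}")
    rss = max(rss, 1e-300)
    crit = n_obs * np.log(rss / n_obs) + k * np.log(n_obs)
    if gamma > 0 and n_candidates > 1:
        crit += 2.0 * gamma * k * np.log(n_candidates)
    return float(crit)


def ext_bic(Y, fit: SpaceFit | NeighborhoodFit, gamma: float = 0.5) -> float:
    """Extended BIC of a fitted model; gamma=0 gives the plain BIC.

    For a SpaceFit: one criterion over the joint fit (weighted RSS, k =
    nonzero pairs).  For a NeighborhoodFit: the sum of the m per-regression
    criteria.
    """
    Yc = _as_centered_matrix(Y)
    n, m = Yc.shape
    if isinstance(fit, SpaceFit):
        R = _residuals(Yc, fit.rho, fit.sigma_inv_diag)
        rss = float(np.einsum("ij,ij->j", R, R) @ fit.weights)
        k = int(np.count_nonzero(np.abs(fit.rho[np.triu_indices(m, k=1)]) > EDGE_EPS))
        return _ext_bic_terms(rss, k, n * m, m * (m - 1) // 2, gamma)
    total = 0.0
    for i in range(m):
        others = [j for j in range(m) if j != i]
        r = Yc[:, i] - Yc[:, others] @ fit.beta[i, others]
        rss = float(r @ r)
        k = int(np.count_nonzero(np.abs(fit.beta[i, others]) > EDGE_EPS))
        total += _ext_bic_terms(rss, k, n, m - 1, gamma)
    return total


# ---------------------------------------------------------------------------
# per-regression selection for neighborhood selection


def _select_ns_regression(
    y: np.ndarray,
    X: np.ndarray,
    grid: TuningGrid,
    criterion: str,
    tol: float = 1e-6,
    max_iter: int = 1000,
):
    """Pick (lambda, tau) for one regression by extBIC/BIC over the grid.

    Returns (best coefficient vector, PenaltySpec used).  Ties break toward
    the sparser model, then the larger lambda.
    """
    n, p = X.shape
    gamma = grid.gamma if criterion == "extbic" else 0.0
    best = None
    warm = np.zeros(p)
    for lam in grid.lambdas:
        lasso_pen = PenaltySpec("lasso", lam)
        warm = fit_single_regression(
            y, X, lasso_pen, tol=tol, max_iter=max_iter, beta_init=warm
        )
        candidates = []
        if grid.kind == "lasso":
            candidates.append((warm.copy(), lasso_pen))
        else:
            scale = float(np.max(np.abs(warm))) if np.any(warm) else 0.0
            for tau in grid.taus_for(scale):
                pen = PenaltySpec("log", lam, tau)
                coef = fit_single_regression(
                    y, X, pen, tol=tol, max_iter=max_iter, lasso_init=warm
                )
                candidates.append((coef, pen))
        for coef, pen in candidates:
            r = y - X @ coef
            rss = float(r @ r)
            k = int(np.count_nonzero(np.abs(coef) > EDGE_EPS))
            crit = _ext_bic_terms(rss, k, n, p, gamma)
            key = (crit, k, -pen.lam)
            if best is None or key < best[0]:
                best = (key, coef, pen)
    _, coef, pen = best
    return coef, pen


# ---------------------------------------------------------------------------
# grid search


def _space_grid_search(
    Y,
    kind: str,
    grid: TuningGrid,
    criterion: str,
    truth: Graph | None,
    weights: str,
    n_lla: int,
    n_sigma_updates: int,
    tol: float,
    max_iter: int,
):
    from .evaluation import compare_edges

    Yc = _as_centered_matrix(Y)
    m = Yc.shape[1]
    gamma = grid.gamma if criterion == "extbic" else 0.0
    rows = []
    best_key = None
    best = None  # (fit, lam, tau, crit)
    best_f1 = -1.0
    best_oracle = None
    warm_rho = None
    for lam in grid.lambdas:
        lasso_fit = fit_space(
            Yc,
            PenaltySpec("lasso", lam),
            weights=weights,
            n_sigma_updates=n_sigma_updates,
            tol=tol,
            max_iter=max_iter,
            rho_init=warm_rho,
        )
        warm_rho = lasso_fit.rho
        if kind == "lasso":
            candidates = [(lasso_fit, None)]
        else:
            iu = np.triu_indices(m, k=1)
            scale = float(np.max(np.abs(lasso_fit.rho[iu]))) if m > 1 else 0.0
            candidates = []
            for tau in grid.taus_for(scale):
                log_fit = fit_space(
                    Yc,
                    PenaltySpec("log", lam, tau),
                    weights=weights,
                    n_lla=n_lla,
                    tol=tol,
                    max_iter=max_iter,
                    lasso_init=lasso_fit,
                )
                candidates.append((log_fit, tau))
        for fit, tau in candidates:
            crit = ext_bic(Yc, fit, gamma)
            est = Graph(m=m, edges=fit.edges())
            k = est.n_edges
            f1 = np.nan
            if truth is not None:
                f1 = compare_edges(truth, est).f1
            rows.append(
                {
                    "lambda": lam,
                    "tau": np.nan if tau is None else tau,
                    "n_edges": k,
                    "rss": np.nan,
                    "criterion": crit,
                    "f1": f1,
                }
            )
            key = (crit, k, -lam)
            if criterion in ("extbic", "bic"):
                if best_key is None or key < best_key:
                    best_key = key
                    best = (fit, lam, tau, crit, est)
            if truth is not None and f1 > best_f1:
                best_f1 = f1
                best_oracle = (fit, lam, tau, crit, est)
    if criterion == "oracle":
        if best_oracle is None:
            raise ValueError("oracle criterion requires a truth graph")
        best = best_oracle
    fit, lam, tau, crit, est = best
    table = pd.DataFrame(rows)
    return SelectionResult(
        best_lambda=lam,
        best_tau=tau,
        criterion_value=crit,
        criterion_table=table,
        best_fit=fit,
        best_graph=est,
        oracle_best_f1=best_f1 if truth is not None else np.nan,
    )


def select_model(
    Y,
    method: str,
    grid: TuningGrid | None = None,
    criterion: str = "extbic",
    truth: Graph | None = None,
    weights: str = "uniform",
    symmetrize_rule: str = "OR",
    n_lambda: int = 30,
    gamma: float = 0.5,
    n_lla: int = 3,
    n_sigma_updates: int = 3,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> SelectionResult:
    """Grid search for one method, warm-started along decreasing lambda.

    ``method`` is one of space-lasso, space-log, ns-lasso, ns-log.  extBIC
    and BIC pick the criterion minimizer (for NS methods, each of the m
    regressions selects its own grid point); the oracle criterion picks the
    grid point maximizing F1 against ``truth`` (for NS methods one shared
    (lambda, tau) is applied to all regressions).  Ties break toward the
    sparser model, then the larger lambda.
    """
    method = method.lower()
    if method not in ("space-lasso", "space-log", "ns-lasso", "ns-log"):
        raise ValueError(f"unknown method {method!r}")
    if criterion not in ("extbic", "bic", "oracle"):
        raise ValueError(f"unknown criterion {criterion!r}")
    if criterion == "oracle" and truth is None:
        raise ValueError("oracle criterion requires truth=")
    kind = "log" if method.endswith("log") else "lasso"
    is_ns = method.startswith("ns")
    if grid is None:
        grid = default_grid(
            Y, kind, weights=weights, n_lambda=n_lambda, gamma=gamma, for_ns=is_ns
        )

    if not is_ns:
        return _space_grid_search(
            Y, kind, grid, criterion, truth, weights, n_lla, n_sigma_updates, tol, max_iter
        )

    from .evaluation import compare_edges
    from .ns_core import fit_ns

    Yc = _as_centered_matrix(Y)
    n, m = Yc.shape
    if criterion in ("extbic", "bic"):
        eff_grid = grid if criterion == "extbic" else TuningGrid(
            kind=grid.kind,
            lambdas=grid.lambdas,
            taus=grid.taus,
            tau_multipliers=grid.tau_multipliers,
            gamma=0.0,
        )
        fit, graph = fit_ns(
            Yc, criterion="extbic", grid=eff_grid, symmetrize_rule=symmetrize_rule,
            tol=tol, max_iter=max_iter,
        )
        rows = [
            {
                "gene": i,
                "lambda": pen.lam,
                "tau": np.nan if pen.tau is None else pen.tau,
                "n_edges": int(np.count_nonzero(np.abs(fit.beta[i]) > EDGE_EPS)),
            }
            for i, pen in enumerate(fit.penalties)
        ]
        total_crit = ext_bic(Yc, fit, gamma=grid.gamma if criterion == "extbic" else 0.0)
        f1 = compare_edges(truth, graph).f1 if truth is not None else np.nan
        return SelectionResult(
            best_lambda=np.nan,
            best_tau=np.nan,
            criterion_value=total_crit,
            criterion_table=pd.DataFrame(rows),
            best_fit=fit,
            best_graph=graph,
            extras={"f1": f1},
        )

    # oracle for NS: one shared (lambda, tau) across all regressions
    rows = []
    best = None
    best_f1 = -1.0
    for lam in grid.lambdas:
        taus = (None,) if kind == "lasso" else None
        if taus is None:
            # anchor tau at the largest lasso coefficient across regressions
            pen0 = PenaltySpec("lasso", lam)
            fit0, _ = fit_ns(
                Yc, penalty=pen0, symmetrize_rule=symmetrize_rule, tol=tol,
                max_iter=max_iter,
            )
            scale = float(np.max(np.abs(fit0.beta)))
            taus = grid.taus_for(scale)
        for tau in taus:
            pen = PenaltySpec(kind, lam, tau)
            fit, graph = fit_ns(
                Yc, penalty=pen, symmetrize_rule=symmetrize_rule, tol=tol,
                max_iter=max_iter,
            )
            f1 = compare_edges(truth, graph).f1
            rows.append(
                {
                    "lambda": lam,
                    "tau": np.nan if tau is None else tau,
                    "n_edges": graph.n_edges,
                    "f1": f1,
                }
            )
            if f1 > best_f1:
                best_f1 = f1
                best = (fit, graph, lam, tau)
    fit, graph, lam, tau = best
    return SelectionResult(
        best_lambda=lam,
        best_tau=tau,
        criterion_value=-best_f1,
        criterion_table=pd.DataFrame(rows),
        best_fit=fit,
        best_graph=graph,
        oracle_best_f1=best_f1,
    )
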