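"""Neighborhood-selection baselines (NS-lasso, NS-log).

Each gene is regressed on all the others by a penalized regression

    beta_hat = argmin { 1/2 |Y_i - Y_{-i} beta|^2 + n sum_j p(|beta_j|) }

with p either the lasso penalty lambda*|beta| or the log penalty
lambda*log(|beta|+tau), the latter solved by LLA around the lasso solution
(per-coefficient thresholds n*lambda/(|beta^(k)|+tau)).  Note the n factor
multiplying the penalty, which puts NS lambda values on a different scale
from the joint space estimator's.

Gene i may select gene j while gene j does not select gene i; the edge set is
formed by a symmetrization rule — OR (edge if either coefficient is nonzero,
the default) or AND (both).  The reported edge weight is
sign(beta_ij) sqrt(beta_ij beta_ji) when both coefficients are nonzero with
agreeing signs, else the single nonzero coefficient (OR rule).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._kernels import ns_active_shooting
from .graph_simulator import Graph
from .space_core import EDGE_EPS, PenaltySpec, _as_centered_matrix, beta_to_rho

logger = logging.getLogger(__name__)

__all__ = ["NeighborhoodFit", "fit_single_regression", "fit_ns"]


@dataclass
class NeighborhoodFit:
    """Coefficients of the m per-gene regressions.

    ``beta[i, j]`` is the coefficient of gene j in gene i's regression
    (diagonal exactly zero).  ``penalties[i]`` records the penalty used for
    regression i (these differ when each regression is tuned separately).
    """

    beta: np.ndarray
    symmetrize_rule: str
    penalties: list[PenaltySpec]
    converged: bool = True

    @property
    def m(self) -> int:
        return self.beta.shape[0]

    def edge_weights(self) -> np.ndarray:
        """Symmetric matrix of edge weights under the fit's symmetrize rule."""
        m = self.m
        wmat = np.zeros((m, m))
        for i in range(m):
            for j in range(i + 1, m):
                bij, bji = self.beta[i, j], self.beta[j, i]
                both = abs(bij) > EDGE_EPS and abs(bji) > EDGE_EPS
                if both:
                    w = beta_to_rho(bij, bji)
                elif self.symmetrize_rule == "OR":
                    w = bij if abs(bij) > EDGE_EPS else bji
                    if abs(w) <= EDGE_EPS:
                        w = 0.0
                else:  # AND: requires both
                    w = 0.0
                wmat[i, j] = wmat[j, i] = w
        return wmat

    def graph(self) -> Graph:
        edges = set()
        for i in range(self.m):
            for j in range(i + 1, self.m):
                sel_ij = abs(self.beta[i, j]) > EDGE_EPS
                sel_ji = abs(self.beta[j, i]) > EDGE_EPS
                hit = (sel_ij or sel_ji) if self.symmetrize_rule == "OR" else (
                    sel_ij and sel_ji
                )
                if hit:
                    edges.add((i, j))
        return Graph(m=self.m, edges=frozenset(edges))


def fit_single_regression(
    y: np.ndarray,
    X: np.ndarray,
    penalty: PenaltySpec,
    tol: float = 1e-6,
    max_iter: int = 1000,
    n_lla: int = 3,
    beta_init: np.ndarray | None = None,
    lasso_init: np.ndarray | None = None,
) -> np.ndarray:
    """One penalized regression of a centered response on centered predictors.

    lasso: coordinate descent with threshold n*lambda per coefficient.
    log: LLA around the lasso solution at the same lambda, thresholds
    n*lambda/(|beta^(k)|+tau); the penalized objective is non-increasing
    across LLA iterations.  ``beta_init`` warm-starts the inner solver only.
    """
    y = np.asarray(y, float)
    X = np.asfortranarray(np.asarray(X, float))
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(X))):
        raise ValueError("non-finite values in regression input")
    n, p = X.shape
    csq = np.einsum("ij,ij->j", X, X)
    if np.any(csq <= 0):
        raise ValueError("predictor with zero variance")

    if penalty.kind == "log" and lasso_init is not None:
        beta = np.array(lasso_init, float)
    else:
        beta = np.zeros(p) if beta_init is None else np.array(beta_init, float)
        thr = np.full(p, n * penalty.lam)
        r = y - X @ beta
        _, conv = ns_active_shooting(X, csq, r, beta, thr, tol, max_iter)
        if not conv:
            logger.warning("lasso regression hit the sweep cap")
        if penalty.kind == "lasso":
            return beta

    lam, tau = penalty.lam, penalty.tau
    for _ in range(n_lla):
        thr = n * lam / (np.abs(beta) + tau)
        before = beta.copy()
        r = y - X @ beta
        _, conv = ns_active_shooting(X, csq, r, beta, thr, tol, max_iter)
        if not conv:
            logger.warning("LLA regression hit the sweep cap")
        same_support = np.array_equal(np.abs(beta) > EDGE_EPS, np.abs(before) > EDGE_EPS)
        if same_support and np.max(np.abs(beta - before)) < tol:
            break
    return beta


def fit_ns(
    Y,
    penalty: PenaltySpec | None = None,
    symmetrize_rule: str = "OR",
    criterion: str | None = None,
    grid=None,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> tuple[NeighborhoodFit, Graph]:
    """Neighborhood selection over all m genes.

    With an explicit ``penalty``, every regression uses that (lambda, tau).
    With ``criterion`` ("extbic" or "bic") instead, each regression selects
    its own (lambda, tau) over the shared tuning grid (built from the data
    when ``grid`` is None); the penalty ``kind`` is then taken from ``grid``.
    """
    if symmetrize_rule not in ("OR", "AND"):
        raise ValueError(f"symmetrize_rule must be 'OR' or 'AND', got {symmetrize_rule!r}")
    if (penalty is None) == (criterion is None):
        raise ValueError("give exactly one of penalty= or criterion=")
    Yc = _as_centered_matrix(Y)
    n, m = Yc.shape

    beta = np.zeros((m, m))
    penalties: list[PenaltySpec] = []
    if penalty is not None:
        for i in range(m):
            others = [j for j in range(m) if j != i]
            coef = fit_single_regression(
                Yc[:, i], Yc[:, others], penalty, tol=tol, max_iter=max_iter
            )
            beta[i, others] = coef
            penalties.append(penalty)
    else:
        from .tuning import _select_ns_regression

        if grid is None:
            raise ValueError("criterion-based fit_ns requires a TuningGrid")
        for i in range(m):
            others = [j for j in range(m) if j != i]
            try:
                coef, pen = _select_ns_regression(
                    Yc[:, i], Yc[:, others], grid, criterion, tol=tol, max_iter=max_iter
                )
            except Exception as exc:  # annotate which regression failed
                raise RuntimeError(f"regression for gene {i} failed: {exc}") from exc
            beta[i, others] = coef
            penalties.append(pen)

    fit = NeighborhoodFit(beta=beta, symmetrize_rule=symmetrize_rule, penalties=penalties)
    return fit, fit.graph()
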