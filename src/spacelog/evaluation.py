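"""Edge-recovery metrics and batch simulation scenario runners.

An estimated network is scored against the true skeleton as sets of
unordered, unsigned gene pairs: false positives (FP), false negatives (FN),
their sum ("Errors"), F1 score, false discovery rate and true positive rate
(power).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .graph_simulator import Graph, SimulationScenario, simulate_scenario

logger = logging.getLogger(__name__)

__all__ = ["MetricReport", "compare_edges", "run_scenario", "DATA_SEED_OFFSET"]

#: replicate r draws its graph with seed master+r and its Gaussian samples
#: with seed master+r+DATA_SEED_OFFSET, so every method within a replicate
#: sees identical data.
DATA_SEED_OFFSET = 10**6


@dataclass(frozen=True)
class MetricReport:
    """Confusion counts and derived rates for one estimated edge set."""

    tp: int
    fp: int
    fn: int

    @property
    def fp_plus_fn(self) -> int:
        return self.fp + self.fn

    @property
    def n_discoveries(self) -> int:
        return self.tp + self.fp

    @property
    def f1(self) -> float:
        denom = 2 * self.tp + self.fp + self.fn
        return 2 * self.tp / denom if denom else 0.0

    @property
    def fdr(self) -> float:
        return self.fp / max(self.tp + self.fp, 1)

    @property
    def tpr(self) -> float:
        return self.tp / max(self.tp + self.fn, 1)

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "fp_plus_fn": self.fp_plus_fn,
            "n_discoveries": self.n_discoveries,
            "f1": self.f1,
            "fdr": self.fdr,
            "tpr": self.tpr,
        }


def compare_edges(truth: Graph, estimate: Graph) -> MetricReport:
    """Score an estimated edge set against the truth (unordered pairs)."""
    if truth.m != estimate.m:
        raise ValueError(
            f"gene universes differ: truth m={truth.m}, estimate m={estimate.m}"
        )
    t, e = truth.edges, estimate.edges
    tp = len(t & e)
    return MetricReport(tp=tp, fp=len(e - t), fn=len(t - e))


def run_scenario(
    scenario: SimulationScenario,
    methods: list[str],
    n_replicates: int,
    seed: int,
    weight_schemes: tuple[str, ...] = ("uniform",),
    criterion: str = "extbic",
    n_lambda: int = 30,
    gamma: float = 0.5,
    symmetrize_rule: str = "OR",
    track_oracle: bool = False,
) -> pd.DataFrame:
    """Monte Carlo evaluation of several methods on one simulation scenario.

    Each replicate simulates graph -> precision -> expression, runs every
    method with the requested tuning criterion, and scores the selected
    network against the truth.  Weight schemes apply to the joint (space)
    methods only; NS methods ignore them.  With ``track_oracle`` the table
    also records, for the space methods, the best F1 attainable on the grid
    (truth-aware "oracle" selection).

    Rows are keyed by (method, weights, replicate); the table is
    deterministic given ``seed``.
    """
    from .tuning import select_model

    rows = []
    for r in range(n_replicates):
        graph_seed = seed + r
        data_seed = seed + r + DATA_SEED_OFFSET
        data = simulate_scenario(scenario, graph_seed=graph_seed, data_seed=data_seed)
        truth = data.graph
        Y = data.expression
        for method in methods:
            is_space = method.startswith("space")
            schemes = weight_schemes if is_space else ("uniform",)
            for scheme in schemes:
                base = {
                    "method": method,
                    "weights": scheme if is_space else "n/a",
                    "replicate": r,
                    "graph_seed": graph_seed,
                    "data_seed": data_seed,
                    "n_true_edges": truth.n_edges,
                }
                try:
                    res = select_model(
                        Y,
                        method,
                        criterion=criterion,
                        truth=truth if (track_oracle and is_space) else None,
                        weights=scheme,
                        symmetrize_rule=symmetrize_rule,
                        n_lambda=n_lambda,
                        gamma=gamma,
                    )
                    report = compare_edges(truth, res.best_graph)
                    row = {
                        **base,
                        **report.as_dict(),
                        "selected_lambda": res.best_lambda,
                        "selected_tau": res.best_tau,
                        "oracle_f1": res.oracle_best_f1,
                        "error": "",
                    }
                except Exception as exc:  # record, don't abort the batch
                    logger.warning(
                        "replicate %d, method %s failed: %s", r, method, exc
                    )
                    row = {**base, "error": str(exc)}
                rows.append(row)
    return pd.DataFrame(rows)
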