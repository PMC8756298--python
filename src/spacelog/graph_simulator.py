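"""Simulation of gene-gene network skeletons and Gaussian expression data.

The generative pipeline mirrors the Monte Carlo design used to benchmark
sparse partial-correlation estimators:

1. draw an undirected network skeleton, either by preferential attachment
   (BA model, hub-dominated) or as an Erdos-Renyi random graph (ER model);
2. convert the skeleton into a symmetric positive-definite precision
   (concentration) matrix whose off-diagonal zero pattern matches the
   non-edges exactly;
3. sample n i.i.d. expression profiles from N(0, Sigma) with
   Sigma = precision^{-1}.

The nonzero precision magnitudes are not identifiable from a skeleton alone;
the construction here draws them uniformly from +/-[0.1, 0.4], rescales each
row to strict diagonal dominance, symmetrizes, and sets the diagonal to 1 —
the standard recipe in the sparse partial-correlation literature, which
guarantees positive definiteness for any simple graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Graph",
    "SimulationScenario",
    "simulate_ba_graph",
    "simulate_er_graph",
    "graph_to_precision",
    "precision_to_partial_correlation",
    "sample_expression",
    "simulate_scenario",
]


@dataclass(frozen=True)
class Graph:
    """Undirected simple graph on ``m`` genes.

    Edges are stored as a frozenset of sorted index pairs ``(i, j)`` with
    ``i < j``; gene indices are 0-based.
    """

    m: int
    edges: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError(f"gene count must be positive, got {self.m}")
        canon = set()
        for i, j in self.edges:
            if i == j:
                raise ValueError(f"self-loop at gene {i}")
            if not (0 <= i < self.m and 0 <= j < self.m):
                raise ValueError(f"edge ({i},{j}) outside [0,{self.m})")
            canon.add((min(i, j), max(i, j)))
        object.__setattr__(self, "edges", frozenset(canon))

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degree(self) -> np.ndarray:
        deg = np.zeros(self.m, dtype=np.int64)
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    def adjacency(self) -> np.ndarray:
        a = np.zeros((self.m, self.m), dtype=bool)
        for i, j in self.edges:
            a[i, j] = a[j, i] = True
        return a

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.m))
        g.add_edges_from(self.edges)
        return g


@dataclass(frozen=True)
class SimulationScenario:
    """One cell of the simulation grid: model, size and sparsity level."""

    model: str  # "BA" or "ER"
    m: int
    n: int
    e: int | None = None  # BA: edges added per new gene
    p_edge: float | None = None  # ER: independent edge probability
    seed: int = 0

    def __post_init__(self) -> None:
        model = self.model.upper()
        object.__setattr__(self, "model", model)
        if model not in ("BA", "ER"):
            raise ValueError(f"model must be 'BA' or 'ER', got {self.model!r}")
        if model == "BA" and (self.e is None or self.p_edge is not None):
            raise ValueError("BA scenario requires e and forbids p_edge")
        if model == "ER" and (self.p_edge is None or self.e is not None):
            raise ValueError("ER scenario requires p_edge and forbids e")

    def simulate_graph(self, seed: int | None = None) -> Graph:
        s = self.seed if seed is None else seed
        if self.model == "BA":
            return simulate_ba_graph(self.m, self.e, s)
        return simulate_er_graph(self.m, self.p_edge, s)


def simulate_ba_graph(m: int, e: int, seed: int) -> Graph:
    """Grow a preferential-attachment (BA) graph from a single gene.

    The initial graph has one gene and no edge.  Each new gene connects to
    ``min(e, k)`` distinct existing genes (k = number of old genes), drawn
    sequentially without replacement with probability proportional to current
    degree; while all existing degrees are zero the draw is uniform.

    The edge count is exactly ``sum_{k=1}^{m-1} min(e, k)``.
    """
    if m < 2:
        raise ValueError(f"m must be >= 2, got {m}")
    if e < 1:
        raise ValueError(f"e must be >= 1, got {e}")
    rng = np.random.default_rng(seed)
    deg = np.zeros(m, dtype=np.float64)
    edges: set[tuple[int, int]] = set()
    for new in range(1, m):
        n_add = min(e, new)
        avail = list(range(new))
        for _ in range(n_add):
            w = deg[avail]
            tot = w.sum()
            if tot <= 0:
                probs = np.full(len(avail), 1.0 / len(avail))
            else:
                probs = w / tot
            pick = avail[rng.choice(len(avail), p=probs)]
            avail.remove(pick)
            edges.add((pick, new))
            deg[pick] += 1
            deg[new] += 1
    return Graph(m=m, edges=frozenset(edges))


def simulate_er_graph(m: int, p_edge: float, seed: int) -> Graph:
    """Erdos-Renyi graph: each of the m(m-1)/2 pairs is an edge w.p. p_edge."""
    if m < 2:
        raise ValueError(f"m must be >= 2, got {m}")
    if not 0.0 <= p_edge <= 1.0:
        raise ValueError(f"p_edge must be in [0,1], got {p_edge}")
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(m, k=1)
    keep = rng.random(iu.shape[0]) < p_edge
    edges = frozenset(
        (int(i), int(j)) for i, j in zip(iu[keep], ju[keep])
    )
    return Graph(m=m, edges=edges)


def graph_to_precision(
    graph: Graph,
    magnitude_range: tuple[float, float] = (0.1, 0.4),
    diag_boost: float = 1.5,
    seed: int = 0,
    max_retries: int = 5,
) -> np.ndarray:
    """Build a symmetric positive-definite precision matrix on a skeleton.

    Off-diagonal entries are nonzero exactly on the graph's edges.  Magnitudes
    are uniform on ``magnitude_range`` with random sign; each row's
    off-diagonals are divided by ``diag_boost`` times the absolute row sum
    (rows with no edges are skipped), the matrix is symmetrized by averaging
    with its transpose and the diagonal set to 1.  With ``diag_boost > 1``
    the result is strictly diagonally dominant, hence positive definite; if a
    numerical check still fails, ``diag_boost`` is grown by 1.5x up to
    ``max_retries`` times.
    """
    lo, hi = magnitude_range
    if not (0.0 < lo <= hi <= 1.0):
        raise ValueError(f"magnitude_range must lie in (0, 1], got {magnitude_range}")
    m = graph.m
    rng = np.random.default_rng(seed)
    base = np.zeros((m, m))
    for i, j in sorted(graph.edges):
        mag = rng.uniform(lo, hi)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        base[i, j] = base[j, i] = sign * mag

    boost = float(diag_boost)
    for _ in range(max_retries):
        a = base.copy()
        row_sum = np.abs(a).sum(axis=1)
        nz = row_sum > 0
        a[nz] /= (boost * row_sum[nz])[:, None]
        a = 0.5 * (a + a.T)
        np.fill_diagonal(a, 1.0)
        if np.linalg.eigvalsh(a)[0] > 0:
            return a
        boost *= 1.5
    raise ValueError(
        f"could not reach positive definiteness after {max_retries} retries"
    )


def precision_to_partial_correlation(precision: np.ndarray) -> np.ndarray:
    """Partial correlations from a precision matrix.

    rho_ij = -sigma^ij / sqrt(sigma^ii sigma^jj) off-diagonal; the diagonal is
    set to zero by convention.
    """
    precision = np.asarray(precision, dtype=float)
    d = np.diag(precision)
    if np.any(d <= 0):
        raise ValueError("precision matrix has non-positive diagonal entries")
    inv_sd = 1.0 / np.sqrt(d)
    rho = -precision * np.outer(inv_sd, inv_sd)
    np.fill_diagonal(rho, 0.0)
    return rho


def sample_expression(
    precision: np.ndarray,
    n: int,
    seed: int,
    gene_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Draw n i.i.d. samples from N(0, precision^{-1}).

    Returns a samples x genes DataFrame; columns default to ``g1..gm``
    (sampling uses the Cholesky factor of the precision matrix, so results
    are bit-reproducible for a fixed seed).
    """
    if n < 2:
        raise ValueError(f"need n >= 2 samples, got {n}")
    precision = np.asarray(precision, dtype=float)
    m = precision.shape[0]
    try:
        chol = np.linalg.cholesky(precision)
    except np.linalg.LinAlgError as exc:
        raise ValueError("precision matrix is not positive definite") from exc
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, m))
    # X^T = L^{-T} Z^T  =>  cov(X) = (L L^T)^{-1} = precision^{-1}
    from scipy.linalg import solve_triangular

    x = solve_triangular(chol, z.T, lower=True, trans="T").T
    if gene_ids is None:
        gene_ids = [f"g{i + 1}" for i in range(m)]
    return pd.DataFrame(
        x, columns=gene_ids, index=[f"s{i + 1}" for i in range(n)]
    )


@dataclass
class SimulatedDataset:
    """Everything one replicate of the simulation study produces."""

    graph: Graph
    precision: np.ndarray
    partial_correlation: np.ndarray = field(repr=False)
    expression: pd.DataFrame = field(repr=False)


def simulate_scenario(
    scenario: SimulationScenario,
    graph_seed: int | None = None,
    data_seed: int | None = None,
) -> SimulatedDataset:
    """Run the full pipeline graph -> precision -> expression for a scenario."""
    gs = scenario.seed if graph_seed is None else graph_seed
    ds = gs + 1 if data_seed is None else data_seed
    graph = scenario.simulate_graph(seed=gs)
    prec = graph_to_precision(graph, seed=gs)
    rho = precision_to_partial_correlation(prec)
    expr = sample_expression(prec, scenario.n, seed=ds)
    return SimulatedDataset(
        graph=graph, precision=prec, partial_correlation=rho, expression=expr
    )
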