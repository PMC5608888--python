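"""Sparsity thresholding, small-world metrics, null-model normalization, AUC.

This is the computational core of the pipeline. A correlation matrix is
binarized at a *sparsity* level S (fraction of realized edges out of
N(N-1)/2, keeping the strongest correlations), and five properties are
computed per level:

* ``gamma``  — clustering coefficient Cp normalized by degree-matched random
  networks (network segregation),
* ``lambda`` — characteristic path length Lp normalized the same way
  (network integration),
* ``sigma``  — small-worldness gamma/lambda (> 1 indicates small-world
  organization),
* ``e_glob`` — global efficiency (Latora–Marchiori mean inverse shortest
  path; disconnected pairs contribute 0),
* ``e_loc``  — local efficiency (mean over nodes of the global efficiency of
  the neighbor-induced subgraph).

Curves over an ascending sparsity grid are summarized per metric by the area
under the curve (AUC), the threshold-independent scalar used as the dependent
variable downstream.

Conventions (see docs/methods.md for rationale): edges are ranked by
absolute correlation with lexicographic pair-order tie-break; Lp averages
over connected pairs only; the random reference is a Maslov–Sneppen
double-edge-swap ensemble; the AUC uses the rectangular rule by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import _graph_core as _core
from .connectivity import ConnectivityMatrix
from .errors import (
    DegenerateNullError,
    DegenerateThresholdError,
    InvalidParameterError,
    NoValidRangeError,
    UndefinedPathError,
)

__all__ = [
    "BinaryGraph",
    "RandomEnsemble",
    "MetricCurves",
    "AUCSummary",
    "METRIC_NAMES",
    "sparsity_grid",
    "threshold_at_sparsity",
    "clustering_coefficient",
    "characteristic_path_length",
    "global_efficiency",
    "local_efficiency",
    "random_reference_ensemble",
    "normalized_metrics",
    "select_sparsity_range",
    "metric_curves",
    "auc",
    "auc_summary",
]

#: the five per-level network properties, in reporting order
METRIC_NAMES = ("gamma", "lambda", "sigma", "e_glob", "e_loc")

#: all stored curve series (the two unnormalized ingredients plus the five)
CURVE_NAMES = ("cp", "lp") + METRIC_NAMES


@dataclass
class BinaryGraph:
    """Undirected, unweighted graph as a symmetric 0/1 adjacency matrix."""

    adjacency: np.ndarray
    sparsity: float

    def __post_init__(self):
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise InvalidParameterError("adjacency must be square")
        a = (a != 0).astype(np.uint8)
        if np.any(np.diag(a)):
            raise InvalidParameterError("adjacency must have a zero diagonal")
        if not np.array_equal(a, a.T):
            raise InvalidParameterError("adjacency must be symmetric")
        self.adjacency = a

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def degree_sequence(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)


@dataclass
class RandomEnsemble:
    """Degree-preserving random reference graphs for one source graph."""

    graphs: list[BinaryGraph]
    n_random: int
    rewires_per_edge: int
    seed: int


@dataclass
class MetricCurves:
    """Per-sparsity-level metric values on an ascending, constant-step grid."""

    sparsity_grid: np.ndarray
    values: dict[str, np.ndarray]
    n_nodes: int

    def __post_init__(self):
        g = np.asarray(self.sparsity_grid, dtype=float)
        if g.size < 1 or np.any(np.diff(g) <= 0):
            raise InvalidParameterError("sparsity grid must be strictly ascending")
        if g.size > 2 and not np.allclose(np.diff(g), g[1] - g[0], atol=1e-9):
            raise InvalidParameterError("sparsity grid must have a constant step")
        self.sparsity_grid = g

    def __getitem__(self, name: str) -> np.ndarray:
        return self.values[name]

    @property
    def delta_s(self) -> float:
        if self.sparsity_grid.size < 2:
            raise InvalidParameterError("single-level grid has no step")
        return float(self.sparsity_grid[1] - self.sparsity_grid[0])


@dataclass
class AUCSummary:
    """Area under each metric curve over the sparsity grid."""

    auc: dict[str, float]
    s1: float
    sn: float
    delta_s: float


def sparsity_grid(s1: float = 0.25, sn: float = 0.48, delta_s: float = 0.01) -> np.ndarray:
    """Ascending grid s1, s1+ΔS, ..., sn (inclusive; 24 levels at the defaults)."""
    if not (0 < s1 <= sn <= 1) or delta_s <= 0:
        raise InvalidParameterError("need 0 < s1 <= sn <= 1 and delta_s > 0")
    n_levels = int(round((sn - s1) / delta_s)) + 1
    grid = s1 + delta_s * np.arange(n_levels)
    return np.round(grid, 10)


def _as_adjacency(graph: BinaryGraph | np.ndarray) -> np.ndarray:
    if isinstance(graph, BinaryGraph):
        return graph.adjacency
    return BinaryGraph(np.asarray(graph), sparsity=1.0).adjacency


def threshold_at_sparsity(
    C: ConnectivityMatrix | np.ndarray,
    sparsity: float,
    edge_rank: str = "abs",
) -> BinaryGraph:
    """Binarize a correlation matrix keeping the K strongest pairs.

    K = round(S * N(N-1)/2) (round-half-even). Pairs are ranked by absolute
    correlation (``edge_rank='abs'``) or by signed correlation
    (``edge_rank='positive'``); exact ties at the cutoff are resolved by
    lexicographic (i, j) pair order, so the result is deterministic.
    """
    values = C.values if isinstance(C, ConnectivityMatrix) else np.asarray(C, dtype=float)
    n = values.shape[0]
    if not 0 < sparsity <= 1:
        raise InvalidParameterError("sparsity must be in (0, 1]")
    if edge_rank not in ("abs", "positive"):
        raise InvalidParameterError("edge_rank must be 'abs' or 'positive'")
    n_pairs = n * (n - 1) // 2
    k = int(np.rint(sparsity * n_pairs))
    if k == 0:
        raise DegenerateThresholdError(
            f"sparsity {sparsity} keeps zero of {n_pairs} edges"
        )
    iu, ju = np.triu_indices(n, k=1)
    strength = values[iu, ju]
    if edge_rank == "abs":
        strength = np.abs(strength)
    # primary key: descending strength; ties: ascending (i, j)
    order = np.lexsort((ju, iu, -strength))
    keep = order[:k]
    adj = np.zeros((n, n), dtype=np.uint8)
    adj[iu[keep], ju[keep]] = 1
    adj |= adj.T
    return BinaryGraph(adj, sparsity=float(sparsity))


def clustering_coefficient(graph: BinaryGraph | np.ndarray) -> float:
    """Watts–Strogatz mean node-wise clustering (degree < 2 contributes 0)."""
    adj = _as_adjacency(graph)
    cp, _, _, _ = _summary(adj)
    return cp


def characteristic_path_length(graph: BinaryGraph | np.ndarray) -> float:
    """Mean shortest-path length over connected ordered pairs."""
    adj = _as_adjacency(graph)
    if adj.sum() == 0:
        raise UndefinedPathError("path length undefined for an edgeless graph")
    _, lp, _, _ = _summary(adj)
    return lp


def global_efficiency(graph: BinaryGraph | np.ndarray) -> float:
    """Mean inverse shortest-path length; disconnected pairs contribute 0."""
    adj = _as_adjacency(graph)
    _, _, _, eg = _summary(adj)
    return eg


def local_efficiency(graph: BinaryGraph | np.ndarray) -> float:
    """Mean over nodes of the neighbor-subgraph global efficiency."""
    adj = _as_adjacency(graph)
    if adj.shape[0] <= _core.BITSET_MAX_NODES:
        return float(_core.local_efficiency_bits(_core.to_masks(adj), adj.shape[0]))
    return float(_core.local_efficiency_kernel(adj))


def _summary(adj: np.ndarray) -> tuple[float, float, int, float]:
    if adj.shape[0] <= _core.BITSET_MAX_NODES:
        cp, lp, npairs, eg = _core.graph_summary_bits(_core.to_masks(adj), adj.shape[0])
    else:
        cp, lp, npairs, eg = _core.graph_summary(adj)
    return float(cp), float(lp), int(npairs), float(eg)


def random_reference_ensemble(
    graph: BinaryGraph | np.ndarray,
    n_random: int = 100,
    rewires_per_edge: int = 10,
    seed: int = 0,
) -> RandomEnsemble:
    """Degree-preserving Maslov–Sneppen random references of ``graph``.

    Each member applies ``rewires_per_edge * n_edges`` attempted double-edge
    swaps to a copy of the source; rejected swaps (self-loop/multi-edge) are
    skipped, so a swap-resistant source (e.g. a star) simply receives fewer
    effective swaps and the degree sequence is never altered.
    """
    adj = _as_adjacency(graph)
    sparsity = graph.sparsity if isinstance(graph, BinaryGraph) else 1.0
    edges = _core.adjacency_to_edges(adj)
    if edges.shape[0] < 2:
        raise InvalidParameterError("need at least 2 edges to rewire")
    if n_random < 1 or rewires_per_edge < 1:
        raise InvalidParameterError("n_random and rewires_per_edge must be >= 1")
    graphs = []
    n_attempts = rewires_per_edge * edges.shape[0]
    starved = 0
    for r in range(n_random):
        a = adj.copy()
        e = edges.copy()
        applied = _core.double_edge_swap_kernel(a, e, n_attempts, seed + r)
        starved += applied == 0
        graphs.append(BinaryGraph(a, sparsity=sparsity))
    if starved:
        import warnings

        warnings.warn(
            f"{starved}/{n_random} reference graphs accepted no swaps (swap-"
            "resistant source); degree sequences are preserved regardless",
            stacklevel=2,
        )
    return RandomEnsemble(graphs, n_random, rewires_per_edge, seed)


def normalized_metrics(
    graph: BinaryGraph | np.ndarray,
    ensemble: RandomEnsemble,
) -> tuple[float, float, float]:
    """(gamma, lambda, sigma): Cp and Lp relative to the random-ensemble means."""
    if not ensemble.graphs:
        raise InvalidParameterError("ensemble is empty")
    adj = _as_adjacency(graph)
    cp, lp, _, _ = _summary(adj)
    cps = np.array([_summary(g.adjacency)[0] for g in ensemble.graphs])
    lps = np.array([_summary(g.adjacency)[1] for g in ensemble.graphs])
    return _normalize(cp, lp, cps, lps)


def _normalize(cp, lp, cps, lps) -> tuple[float, float, float]:
    cp_rand = float(np.mean(cps))
    lp_rand = float(np.mean(lps))
    if not (cp_rand > 0 and lp_rand > 0) or not np.isfinite(lp_rand):
        raise DegenerateNullError(
            f"random ensemble means degenerate: <Cp>={cp_rand}, <Lp>={lp_rand}"
        )
    gamma = cp / cp_rand
    lam = lp / lp_rand
    return gamma, lam, gamma / lam


def metric_curves(
    C: ConnectivityMatrix | np.ndarray,
    grid: Sequence[float] | np.ndarray | None = None,
    n_random: int = 100,
    rewires_per_edge: int = 10,
    seed: int = 0,
    edge_rank: str = "abs",
) -> MetricCurves:
    """All seven curve series (Cp, Lp, gamma, lambda, sigma, E_glob, E_loc).

    The null ensemble at grid level i is seeded deterministically from
    ``seed`` and i, so curves are reproducible level by level.
    """
    grid = sparsity_grid() if grid is None else np.asarray(grid, dtype=float)
    values = {name: np.empty(grid.size) for name in CURVE_NAMES}
    n_nodes = (C.values if isinstance(C, ConnectivityMatrix) else np.asarray(C)).shape[0]
    use_bits = n_nodes <= _core.BITSET_MAX_NODES
    for i, s in enumerate(grid):
        g = threshold_at_sparsity(C, float(s), edge_rank=edge_rank)
        adj = g.adjacency
        cp, lp, _, eg = _summary(adj)
        level_seed = _level_seed(seed, i)
        if use_bits:
            masks = _core.to_masks(adj)
            edges = _core.adjacency_to_edges(adj)
            cps, lps = _core.null_cp_lp_bits(
                masks, n_nodes, edges, n_random, rewires_per_edge, level_seed
            )
        else:
            ens = random_reference_ensemble(g, n_random, rewires_per_edge, level_seed)
            cps = np.array([_summary(m.adjacency)[0] for m in ens.graphs])
            lps = np.array([_summary(m.adjacency)[1] for m in ens.graphs])
        gamma, lam, sigma = _normalize(cp, lp, cps, lps)
        values["cp"][i] = cp
        values["lp"][i] = lp
        values["gamma"][i] = gamma
        values["lambda"][i] = lam
        values["sigma"][i] = sigma
        values["e_glob"][i] = eg
        values["e_loc"][i] = local_efficiency(g)
    return MetricCurves(grid, values, n_nodes)


def _level_seed(seed: int, level_index: int) -> int:
    """Deterministic, well-separated per-level seed stream."""
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, level_index])
    return int(ss.generate_state(1)[0] & 0x3FFFFFFF)


def auc(values: Sequence[float] | np.ndarray, delta_s: float, rule: str = "rect") -> float:
    """Area under a metric curve on a constant-step grid.

    ``rect`` (default) is ΔS * sum(values) — the threshold-AUC convention of
    the standard brain-connectivity toolboxes; ``trapezoid`` is available as
    an alternative.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise InvalidParameterError("need at least one value")
    if delta_s <= 0:
        raise InvalidParameterError("delta_s must be positive")
    if rule == "rect":
        return float(delta_s * v.sum())
    if rule == "trapezoid":
        return float(np.trapezoid(v, dx=delta_s))
    raise InvalidParameterError("rule must be 'rect' or 'trapezoid'")


def auc_summary(curves: MetricCurves, rule: str = "rect") -> AUCSummary:
    """Per-metric AUC over the curves' grid."""
    delta = curves.delta_s
    aucs = {name: auc(curves[name], delta, rule) for name in METRIC_NAMES}
    return AUCSummary(
        aucs,
        s1=float(curves.sparsity_grid[0]),
        sn=float(curves.sparsity_grid[-1]),
        delta_s=delta,
    )


def select_sparsity_range(
    curves_by_subject: Sequence[MetricCurves],
    sigma_floor: float = 1.1,
) -> tuple[float, float]:
    """Data-driven (s_min, s_max) from a cohort of candidate-grid curves.

    s_min is the smallest grid level whose implied mean degree S(N-1) exceeds
    2 ln N (sparse-connectivity criterion); s_max is the largest grid level at
    which the group-mean small-worldness stays above ``sigma_floor``. Raises
    :class:`NoValidRangeError` when the two constraints cross.
    """
    if not curves_by_subject:
        raise InvalidParameterError("need at least one subject's curves")
    grid = curves_by_subject[0].sparsity_grid
    n_nodes = curves_by_subject[0].n_nodes
    for c in curves_by_subject[1:]:
        if not np.allclose(c.sparsity_grid, grid) or c.n_nodes != n_nodes:
            raise InvalidParameterError("curves must share one grid and node count")
    degree_ok = grid * (n_nodes - 1) > 2.0 * math.log(n_nodes)
    mean_sigma = np.mean([c["sigma"] for c in curves_by_subject], axis=0)
    sigma_ok = mean_sigma > sigma_floor
    if not degree_ok.any() or not sigma_ok.any():
        raise NoValidRangeError(
            f"no valid range: degree criterion satisfied at {int(degree_ok.sum())} "
            f"levels, sigma > {sigma_floor} at {int(sigma_ok.sum())} levels"
        )
    s_min = float(grid[np.argmax(degree_ok)])
    s_max = float(grid[np.where(sigma_ok)[0][-1]])
    if not s_min < s_max:
        raise NoValidRangeError(
            f"degree criterion gives s_min={s_min} but sigma > {sigma_floor} "
            f"last holds at s_max={s_max}"
        )
    return s_min, s_max
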