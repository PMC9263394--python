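"""Proportional thresholding and weighted graph indicators.

For each sparsity level s in {10%, 15%, ..., 50%} the strongest
round(s * n_pairs) Fisher-z edges (signed ranking; ties broken by ascending
(i, j) index for determinism) are retained with their z-values as weights,
giving an undirected weighted graph without self-loops.  Any negative weight
that survives thresholding is dropped and counted, since the cube-root
triple-product clustering and the reciprocal-weight path lengths are not
defined for negative weights.  Weights are used raw (no rescaling to max 1).

Indicators
----------
- C: average weighted clustering coefficient,
  c_i = sum_{j,k} (w_ij w_jk w_ki)^(1/3) / (k_i (k_i - 1)), C = mean_i c_i
- E: global efficiency, E = mean over ordered pairs of 1/d_ij with d_ij the
  shortest path on edge lengths 1/w (disconnected pairs contribute 0)
- K-inter: existing edges between the two 13-node hemisphere sets / 13^2
- K-intra(S): existing edges within a 16-node hemisphere set / (16*15/2)

AUC summaries integrate each indicator over the sparsity range with the
trapezoid rule on fractional sparsity (a constant curve v gives 0.40 * v).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .connectivity import FCMatrix
from .montage import ProbeMontage, hemisphere_node_sets

DEFAULT_SPARSITIES = np.round(np.arange(0.10, 0.501, 0.05), 2)

INDICATORS = ("C", "E", "K-inter", "K-intra.L", "K-intra.R")


@dataclass
class ThresholdedGraph:
    """Undirected weighted graph retained at one sparsity level.

    ``weights`` is symmetric with non-negative entries and a zero diagonal;
    ``adjacency[i, j] = weights[i, j] > 0``.  Node i corresponds to channel
    i + 1 of the montage.
    """

    weights: np.ndarray
    sparsity: float
    n_dropped_negative: int = 0

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def adjacency(self) -> np.ndarray:
        return self.weights > 0

    @property
    def degree(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)


@dataclass
class MetricCurve:
    sparsities: np.ndarray
    values: dict[str, np.ndarray]  # indicator -> values per sparsity

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"indicator": ind, "sparsity": s, "value": v}
            for ind, vals in self.values.items()
            for s, v in zip(self.sparsities, vals)
        ]
        return pd.DataFrame(rows)


def proportional_threshold(
    fc: FCMatrix | np.ndarray, sparsity: float, rank_by: str = "signed"
) -> ThresholdedGraph:
    """Retain the top round(sparsity * n_pairs) edges of the z-matrix.

    ``rank_by="signed"`` ranks the raw z values (strongest positive first);
    ``"absolute"`` ranks |z|.  Retained negative weights are removed (set to
    zero) and counted in ``n_dropped_negative``.
    """
    if not 0 < sparsity <= 1:
        raise ValueError(f"sparsity must be in (0, 1], got {sparsity}")
    z = fc.z if isinstance(fc, FCMatrix) else np.asarray(fc, dtype=float)
    n = z.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    vals = z[iu, ju]
    key = vals if rank_by == "signed" else np.abs(vals)
    if rank_by not in ("signed", "absolute"):
        raise ValueError(f"rank_by must be 'signed' or 'absolute', got {rank_by!r}")
    # descending key; ties broken by ascending (i, j)
    order = np.lexsort((ju, iu, -key))
    n_keep = int(np.round(sparsity * vals.size))
    keep = order[:n_keep]
    w = np.zeros_like(z)
    w[iu[keep], ju[keep]] = vals[keep]
    w[ju[keep], iu[keep]] = vals[keep]
    n_neg = int(np.count_nonzero(w[iu, ju] < 0))
    w[w < 0] = 0.0
    np.fill_diagonal(w, 0.0)
    return ThresholdedGraph(weights=w, sparsity=float(sparsity),
                            n_dropped_negative=n_neg)


def weighted_clustering(graph: ThresholdedGraph) -> tuple[float, np.ndarray]:
    """Average weighted clustering coefficient and per-node values.

    The triple sum runs over ordered neighbour pairs (j, k); nodes of degree
    < 2 contribute 0.  C averages over all N nodes.
    """
    w = graph.weights
    if np.any(w < 0):
        raise ValueError("clustering is undefined for negative weights")
    m = np.cbrt(w)
    triples = np.diagonal(m @ m @ m)  # sum over ordered (j, k) per node
    k = graph.degree.astype(float)
    denom = k * (k - 1)
    c = np.where(denom > 0, triples / np.where(denom > 0, denom, 1.0), 0.0)
    return float(c.mean()), c


def shortest_path_lengths(
    graph: ThresholdedGraph, distance: str = "shortest_path"
) -> np.ndarray:
    """Pairwise d_ij on edge lengths 1/w.

    ``distance="shortest_path"`` (default) minimises the summed reciprocal
    weights along paths; ``"direct"`` reads the reciprocal of the direct edge
    only (infinite when absent).
    """
    w = graph.weights
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), np.inf)
    if distance == "direct":
        d = lengths.copy()
    elif distance == "shortest_path":
        d = dijkstra(csr_matrix(np.where(np.isinf(lengths), 0.0, lengths)),
                     directed=False)
    else:
        raise ValueError(f"unknown distance mode {distance!r}")
    np.fill_diagonal(d, np.inf)  # self-pairs excluded downstream
    return d


def global_efficiency(
    graph: ThresholdedGraph, distance: str = "shortest_path"
) -> tuple[float, np.ndarray]:
    """Global efficiency and the pairwise shortest-path length matrix."""
    d = shortest_path_lengths(graph, distance=distance)
    n = graph.n_nodes
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d), 1.0 / d, 0.0)
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1))), d


def density_between(
    adjacency: np.ndarray, set_a: Iterable[int], set_b: Iterable[int]
) -> float:
    """Fraction of existing edges among all |A| x |B| cross pairs (1-based)."""
    a = [i - 1 for i in sorted(set_a)]
    b = [j - 1 for j in sorted(set_b)]
    sub = adjacency[np.ix_(a, b)]
    return float(sub.sum() / (len(a) * len(b)))


def density_within(adjacency: np.ndarray, node_set: Iterable[int]) -> float:
    """Fraction of existing edges among the n(n-1)/2 within-set pairs (1-based)."""
    s = [i - 1 for i in sorted(node_set)]
    sub = adjacency[np.ix_(s, s)]
    n = len(s)
    return float(np.triu(sub, k=1).sum() / (n * (n - 1) / 2))


def inter_density(graph: ThresholdedGraph, montage: ProbeMontage) -> float:
    """Edge density between the two midline-free 13-node hemisphere sets."""
    left, right = hemisphere_node_sets(montage, "inter")
    return density_between(graph.adjacency, left, right)


def intra_density(
    graph: ThresholdedGraph, montage: ProbeMontage, hemisphere: str
) -> float:
    """Edge density within one 16-node hemisphere set (midline included)."""
    left, right = hemisphere_node_sets(montage, "intra")
    node_set = left if hemisphere == "left" else right
    return density_within(graph.adjacency, node_set)


def sparsity_sweep(
    fc: FCMatrix | np.ndarray,
    montage: ProbeMontage,
    sparsities: np.ndarray = DEFAULT_SPARSITIES,
    rank_by: str = "signed",
    distance: str = "shortest_path",
) -> MetricCurve:
    """All five indicators at each sparsity of the 10-50% grid (9 levels)."""
    sparsities = np.asarray(sparsities, dtype=float)
    vals: dict[str, list[float]] = {ind: [] for ind in INDICATORS}
    for s in sparsities:
        g = proportional_threshold(fc, s, rank_by=rank_by)
        vals["C"].append(weighted_clustering(g)[0])
        vals["E"].append(global_efficiency(g, distance=distance)[0])
        vals["K-inter"].append(inter_density(g, montage))
        vals["K-intra.L"].append(intra_density(g, montage, "left"))
        vals["K-intra.R"].append(intra_density(g, montage, "right"))
    return MetricCurve(sparsities=sparsities,
                       values={k: np.asarray(v) for k, v in vals.items()})


def auc(curve: MetricCurve) -> dict[str, float]:
    """Trapezoid-rule area under each indicator curve on fractional sparsity."""
    return {
        ind: float(np.trapezoid(v, curve.sparsities))
        for ind, v in curve.values.items()
    }
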