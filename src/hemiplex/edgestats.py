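"""Edge-level statistics: input fractions, the bilateral reproducibility
threshold, weight distributions, multigraph reciprocity and the multiplex
overlap null model.

The central filter is the *symmetric threshold*: an edge is considered
strong and reproducible only if it is observed between homologous partners
in both hemispheres and the mean of its two input fractions is at least the
threshold (1 % of the target's dendritic input by default).  A 0.5 % and a
2 % connection average to 1.25 % and pass.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import EDGE_TYPES, MultiplexConnectome, PairMap, canonical_edge_type

__all__ = [
    "dendritic_input_fractions",
    "symmetric_threshold",
    "ThresholdedGraph",
    "weight_distribution",
    "edge_reciprocity",
    "expected_overlap_counts",
    "observed_overlap_counts",
    "OverlapPattern",
]


def dendritic_input_fractions(conn: MultiplexConnectome, layer: str = "ad") -> np.ndarray:
    """Per-edge fraction of the target's total in-weight on one layer.

    ``F[i, j] = w(i -> j) / sum_k w(k -> j)``.  Columns of nodes with zero
    input are NaN (fractions undefined).  For the default a-d layer the
    denominator is the target's total dendritic input.
    """
    a = conn.layer(layer).astype(float)
    col = a.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(col > 0, a / col, np.nan)
    return frac


@dataclass
class ThresholdedGraph:
    """Strong, bilaterally reproducible edges of one layer.

    ``edges`` has one row per retained directed edge with the input
    fraction on each side and their mean; ``adjacency`` is the boolean
    retained-edge matrix in the connectome's node order.
    """

    nodes: list[str]
    adjacency: np.ndarray
    edges: pd.DataFrame
    layer: str = "ad"
    threshold: float = 0.01
    index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.index = {v: i for i, v in enumerate(self.nodes)}

    def in_degree(self) -> np.ndarray:
        """Distinct strong presynaptic partners per node."""
        return self.adjacency.sum(axis=0)

    def out_degree(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for i, j in zip(*np.nonzero(self.adjacency)):
            g.add_edge(self.nodes[i], self.nodes[j])
        return g


def symmetric_threshold(
    conn: MultiplexConnectome,
    pairs: PairMap,
    threshold: float = 0.01,
    layer: str = "ad",
) -> ThresholdedGraph:
    """Keep edges present in both hemispheres with mean fraction >= threshold.

    For an edge between paired nodes, the homologous edge is the one
    obtained by swapping both endpoints for their partners; both instances
    must exist (weight > 0) and their mean input fraction must reach the
    threshold, in which case both are retained.  Edges touching an
    unpaired node are exempt from the both-hemispheres requirement and kept
    whenever their own fraction reaches the threshold.
    """
    layer = canonical_edge_type(layer)
    a = conn.layer(layer)
    frac = dendritic_input_fractions(conn, layer)
    n = conn.n_nodes
    keep = np.zeros((n, n), dtype=bool)
    rows = []
    idx = conn.index
    for i, j in zip(*np.nonzero(a)):
        u, v = conn.nodes[i], conn.nodes[j]
        pu, pv = pairs.partner(u), pairs.partner(v)
        f = frac[i, j]
        if pu is None or pv is None:
            # unpaired endpoint: judged on its own fraction
            if f >= threshold:
                keep[i, j] = True
                rows.append((u, v, f, np.nan, f))
            continue
        if pu not in idx or pv not in idx:
            continue
        mi, mj = idx[pu], idx[pv]
        if a[mi, mj] == 0:
            continue
        fm = frac[mi, mj]
        mean = (f + fm) / 2.0
        if mean >= threshold:
            keep[i, j] = True
            rows.append((u, v, f, fm, mean))
    edges = pd.DataFrame(rows, columns=["pre", "post", "fraction", "mirror_fraction", "mean_fraction"])
    return ThresholdedGraph(list(conn.nodes), keep, edges, layer, threshold)


def weight_distribution(conn: MultiplexConnectome, layer: str) -> dict:
    """Histogram and weak/strong summaries of one layer's edge weights.

    Weak edges carry 1-2 synapses, strong edges >= 5.  Returns both edge
    fractions and the share of total synapses carried by each class; all
    summaries are NaN for an empty layer.
    """
    a = conn.layer(layer)
    w = a[a > 0]
    if w.size == 0:
        return {"histogram": {}, "n_edges": 0, "weak_edge_fraction": np.nan,
                "strong_edge_fraction": np.nan, "weak_synapse_share": np.nan,
                "strong_synapse_share": np.nan}
    values, counts = np.unique(w, return_counts=True)
    total = float(w.sum())
    return {
        "histogram": {int(v): int(c) for v, c in zip(values, counts)},
        "n_edges": int(w.size),
        "weak_edge_fraction": float((w <= 2).mean()),
        "strong_edge_fraction": float((w >= 5).mean()),
        "weak_synapse_share": float(w[w <= 2].sum() / total),
        "strong_synapse_share": float(w[w >= 5].sum() / total),
    }


def edge_reciprocity(a_source: np.ndarray, a_target: np.ndarray) -> float:
    """Conditional probability of the reverse edge in the target layer.

    ``r = sum_ij S_ij T_ji / sum_ij S_ij`` on unweighted, loopless
    adjacencies: of the edges present in the source layer, the fraction
    whose reversed counterpart is present in the target layer.  NaN when
    the source layer is empty.
    """
    s = (np.asarray(a_source) > 0).astype(np.int64)
    t = (np.asarray(a_target) > 0).astype(np.int64)
    if s.shape != t.shape:
        raise ValueError("adjacencies must share the node set")
    np.fill_diagonal(s, 0)
    np.fill_diagonal(t, 0)
    denom = s.sum()
    if denom == 0:
        return float("nan")
    return float((s * t.T).sum() / denom)


@dataclass(frozen=True)
class OverlapPattern:
    """One of the 16 on/off combinations of the four connection types."""

    pattern: tuple[int, int, int, int]  # over (ad, aa, da, dd)
    observed: int
    expected: float


#: Edge-type order used by the overlap pattern vectors.
OVERLAP_TYPE_ORDER = ("ad", "aa", "da", "dd")


def expected_overlap_counts(n: int, p: np.ndarray) -> dict[tuple[int, ...], float]:
    """Independent-layer (Erdos-Renyi) expectation for each pattern.

    ``m(x) = n^2 * prod_k p_k^x_k (1 - p_k)^(1 - x_k)`` where ``p_k`` is
    each layer's global density ``sum(A_k) / n^2``.  Sums to ``n^2``
    exactly over the 16 patterns.
    """
    p = np.asarray(p, dtype=float)
    if p.shape != (4,):
        raise ValueError("p must be a 4-vector")
    out = {}
    for x in itertools.product((0, 1), repeat=4):
        xv = np.array(x)
        out[x] = float(n**2 * np.prod(np.where(xv == 1, p, 1.0 - p)))
    return out


def observed_overlap_counts(conn: MultiplexConnectome) -> list[OverlapPattern]:
    """Count ordered node pairs per connection-type combination.

    Every ordered pair (including i == j and unconnected pairs, which fall
    in the all-zero pattern) lands in exactly one of the 16 patterns, so
    observed counts sum to n^2.  Expected counts come from the
    independent-layer null model with densities ``p_k = sum(A_k) / n^2``.
    """
    n = conn.n_nodes
    present = [conn.layer(t) > 0 for t in OVERLAP_TYPE_ORDER]
    code = np.zeros((n, n), dtype=np.int64)
    for k, m in enumerate(present):
        code += m.astype(np.int64) << k
    counts = np.bincount(code.ravel(), minlength=16)
    p = np.array([m.sum() / n**2 for m in present])
    expected = expected_overlap_counts(n, p)
    patterns = []
    for x in itertools.product((0, 1), repeat=4):
        c = sum(b << k for k, b in enumerate(x))
        patterns.append(OverlapPattern(x, int(counts[c]), expected[x]))
    return patterns
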