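"""Signal-flow sorting of a directed network from inputs to outputs.

Each node gets a scalar score z minimizing

    sum_ij  w_ij * (z_i - z_j - 1)^2

so that every weighted edge prefers to drop one level from source to
target.  High scores sit near the network's inputs, low scores near its
outputs.  The minimizer solves the Laplacian system
``(D - (W + W^T)) z = d_out - d_in`` and is defined up to an additive
constant, fixed here by mean-centering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import spearmanr

__all__ = ["SignalFlowScores", "signal_flow", "sorting_correlation", "classify_edge_direction"]


@dataclass
class SignalFlowScores:
    """Mean-centered per-node scores plus the nodes they cover."""

    nodes: list[str]
    scores: np.ndarray
    isolated: list[str]

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.nodes, map(float, self.scores)))


def signal_flow(adjacency: np.ndarray, nodes: list[str] | None = None) -> SignalFlowScores:
    """Solve the signal-flow quadratic for one weighted directed graph.

    Isolated nodes (no in- or out-edges) are excluded and reported; the
    remaining system is solved with the Laplacian pseudo-inverse, which
    also handles several weakly connected components (each is centered
    independently by the least-squares solution).
    """
    w = np.asarray(adjacency, dtype=float)
    n = w.shape[0]
    if n == 0 or w.sum() == 0:
        raise ValueError("signal flow needs a nonempty graph")
    if nodes is None:
        nodes = [str(i) for i in range(n)]
    deg = w.sum(axis=1) + w.sum(axis=0)
    active = deg > 0
    isolated = [nodes[i] for i in np.nonzero(~active)[0]]
    wa = w[np.ix_(active, active)]
    sym = wa + wa.T
    lap = np.diag(sym.sum(axis=1)) - sym
    b = wa.sum(axis=1) - wa.sum(axis=0)  # out-strength minus in-strength
    z = np.linalg.pinv(lap) @ b
    z = z - z.mean()
    return SignalFlowScores([nodes[i] for i in np.nonzero(active)[0]], z, isolated)


def sorting_correlation(a: SignalFlowScores, b: SignalFlowScores) -> float:
    """Spearman rank correlation between two sortings on shared nodes.

    NaN when fewer than three nodes are shared (the correlation is not
    meaningful there).
    """
    da, db = a.as_dict(), b.as_dict()
    shared = [v for v in da if v in db]
    if len(shared) < 3:
        return float("nan")
    rho, _ = spearmanr([da[v] for v in shared], [db[v] for v in shared])
    return float(rho)


def classify_edge_direction(
    adjacency: np.ndarray,
    scores: SignalFlowScores,
    nodes: list[str] | None = None,
) -> dict:
    """Split edges into feedforward / feedback by the score gradient.

    An edge i -> j is feedforward when z_i > z_j (it points from nearer
    the sensory periphery toward the outputs), feedback when z_i < z_j,
    and a tie when the scores are equal.  Fractions are reported both per
    edge and weighted by synapse count.
    """
    w = np.asarray(adjacency, dtype=float)
    n = w.shape[0]
    if nodes is None:
        nodes = [str(i) for i in range(n)]
    z = scores.as_dict()
    counts = {"feedforward": 0, "feedback": 0, "tie": 0}
    synapses = {"feedforward": 0.0, "feedback": 0.0, "tie": 0.0}
    labels: dict[tuple[str, str], str] = {}
    for i, j in zip(*np.nonzero(w)):
        u, v = nodes[i], nodes[j]
        if u not in z or v not in z:
            raise KeyError(f"scores do not cover edge {u}->{v}")
        if z[u] > z[v]:
            lab = "feedforward"
        elif z[u] < z[v]:
            lab = "feedback"
        else:
            lab = "tie"
        labels[(u, v)] = lab
        counts[lab] += 1
        synapses[lab] += w[i, j]
    total_syn = sum(synapses.values())
    total_edges = sum(counts.values())
    frac = {k: (synapses[k] / total_syn if total_syn else float("nan")) for k in synapses}
    efrac = {k: (counts[k] / total_edges if total_edges else float("nan")) for k in counts}
    return {"labels": labels, "edge_counts": counts,
            "edge_fractions": efrac, "synapse_fractions": frac}
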