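"""Stochastic signal cascades and the metrics derived from them.

The propagation model is a modified independent-cascade process on a
weighted directed graph.  A start set is active at hop 0.  At every hop,
each synapse from an active non-stop node to a not-yet-activated node
transmits independently with probability ``p`` (0.05 by default); a node
with at least one successful incoming transmission becomes active at the
next hop.  Nodes deactivate after being active for one hop and can never
activate again within a run, so activation hops record the earliest
arrival of signal.  Stop ("end") nodes may become active but do not
propagate.  Repeating the process over many runs yields per-node, per-hop
activation probabilities.

A whole-edge transmission is drawn as Bernoulli(1 - (1-p)^w) for an edge of
weight w, which is distributionally identical to w independent
per-synapse Bernoulli(p) trials but much faster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CascadeSpec", "CascadeResult", "run_cascade", "receives_signal",
    "modality_integration", "lateralization", "recurrence_fraction",
    "RecurrenceResult", "cluster_flow_matrix", "efference_copy_reach",
]


@dataclass(frozen=True)
class CascadeSpec:
    """Start/stop sets and propagation parameters for one cascade batch."""

    start: tuple[str, ...]
    stop: tuple[str, ...] = ()
    p: float = 0.05
    max_hops: int = 8
    iterations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.p < 1.0:
            raise ValueError("transmission probability must be in (0, 1)")
        if self.max_hops < 1:
            raise ValueError("max_hops must be >= 1")
        object.__setattr__(self, "start", tuple(self.start))
        object.__setattr__(self, "stop", tuple(self.stop))


@dataclass
class CascadeResult:
    """Per-node per-hop activation frequencies over repeated runs.

    ``activation[:, t]`` is the fraction of runs in which each node first
    became active exactly at hop t; since a node activates at most once per
    run, rows sum to at most 1.  ``visit_probability`` is the fraction of
    runs with any activation.
    """

    nodes: list[str]
    activation: np.ndarray  # (n_nodes, max_hops + 1)
    visit_probability: np.ndarray
    spec: CascadeSpec
    index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.index = {v: i for i, v in enumerate(self.nodes)}

    def visit(self, node: str) -> float:
        return float(self.visit_probability[self.index[node]])


def run_cascade(adjacency: np.ndarray, spec: CascadeSpec, nodes: list[str] | None = None) -> CascadeResult:
    """Run repeated cascades and tabulate activation frequencies.

    Randomness is drawn from one independent substream per run, spawned
    deterministically from ``spec.seed``, so results are bit-reproducible
    and insensitive to any parallel scheduling of runs.
    """
    w = np.asarray(adjacency, dtype=float)
    n = w.shape[0]
    if nodes is None:
        nodes = [str(i) for i in range(n)]
    index = {v: i for i, v in enumerate(nodes)}
    try:
        start_idx = np.array([index[v] for v in spec.start], dtype=int)
    except KeyError as e:
        raise KeyError(f"start node {e} not in graph") from None
    stop_mask = np.zeros(n, dtype=bool)
    for v in spec.stop:
        if v in index:
            stop_mask[index[v]] = True

    # log of per-edge non-transmission probability; 0 where no edge
    log_q = w * np.log1p(-spec.p)

    counts = np.zeros((n, spec.max_hops + 1), dtype=np.int64)
    visits = np.zeros(n, dtype=np.int64)
    streams = np.random.SeedSequence(spec.seed).spawn(spec.iterations)
    for ss in streams:
        rng = np.random.default_rng(ss)
        active = np.zeros(n, dtype=bool)
        ever = np.zeros(n, dtype=bool)
        active[start_idx] = True
        ever[start_idx] = True
        counts[start_idx, 0] += 1
        for t in range(1, spec.max_hops + 1):
            sources = active & ~stop_mask
            if not sources.any():
                break
            total_log_q = log_q[sources].sum(axis=0)
            p_act = -np.expm1(total_log_q)  # 1 - prod of non-transmission
            new = (rng.random(n) < p_act) & ~ever
            if not new.any():
                break
            counts[new, t] += 1
            ever |= new
            active = new
        visits += ever
    return CascadeResult(list(nodes), counts / spec.iterations, visits / spec.iterations, spec)


def receives_signal(result: CascadeResult, threshold: float = 0.5) -> dict[str, bool]:
    """Nodes visited in most runs (strict majority by default)."""
    return {v: bool(result.visit_probability[i] > threshold)
            for v, i in result.index.items()}


def modality_integration(
    results: dict[str, CascadeResult], threshold: float = 0.5
) -> pd.DataFrame:
    """Classify nodes as unimodal / multimodal / none across input cascades.

    ``results`` maps each sensory modality to the cascade started from that
    modality's input neurons.  A node is unimodal when exactly one
    modality's cascade reaches it (by the majority-visit rule), multimodal
    for two or more, and none otherwise.
    """
    if len(results) < 2:
        raise ValueError("need cascades from at least two modalities")
    modalities = sorted(results)
    received = {m: receives_signal(results[m], threshold) for m in modalities}
    nodes = results[modalities[0]].nodes
    rows = []
    for v in nodes:
        combo = tuple(m for m in modalities if received[m].get(v, False))
        label = {0: "none", 1: "unimodal"}.get(len(combo), "multimodal")
        rows.append((v, label, combo, len(combo)))
    return pd.DataFrame(rows, columns=["node", "label", "modalities", "n_modalities"]).set_index("node")


def lateralization(
    left_result: CascadeResult, right_result: CascadeResult, threshold: float = 0.5
) -> pd.DataFrame:
    """Left/right signal balance from side-specific input cascades.

    ``ratio`` is left visit probability over the left+right total
    (0.5 = perfectly balanced).  A node is ``lateralized`` when only one
    side's cascade reaches it, ``integrative`` when both do, ``no signal``
    when neither does.
    """
    left_ok = receives_signal(left_result, threshold)
    right_ok = receives_signal(right_result, threshold)
    rows = []
    for v in left_result.nodes:
        lv = left_result.visit(v)
        rv = right_result.visit(v) if v in right_result.index else 0.0
        total = lv + rv
        ratio = lv / total if total > 0 else np.nan
        l, r = left_ok.get(v, False), right_ok.get(v, False)
        flag = "integrative" if (l and r) else ("lateralized" if (l or r) else "no signal")
        rows.append((v, ratio, flag))
    return pd.DataFrame(rows, columns=["node", "ratio", "flag"]).set_index("node")


@dataclass
class RecurrenceResult:
    """Recurrence of one source neuron."""

    neuron: str
    downstream: list[str]
    returning: list[str]
    fraction: float
    return_path_lengths: dict[str, int]  # distinct return-path hop counts per partner


def recurrence_fraction(
    adjacency: np.ndarray,
    nodes: list[str],
    neuron: str,
    hops: int = 5,
    p: float = 0.05,
    iterations: int = 1000,
    threshold: float = 0.5,
    seed: int = 0,
) -> RecurrenceResult:
    """Fraction of a neuron's polysynaptic downstream partners that loop back.

    Downstream partners are the nodes reached (majority-visit rule) by a
    cascade of up to ``hops`` hops seeded at the neuron; each partner then
    seeds its own cascade, and it counts as returning when the source
    neuron is reached.  The number of distinct hop counts at which return
    signal arrives is recorded per returning partner.  The fraction is NaN
    when there are no downstream partners.
    """
    fwd = run_cascade(adjacency, CascadeSpec((neuron,), p=p, max_hops=hops,
                                             iterations=iterations, seed=seed), nodes)
    ok = receives_signal(fwd, threshold)
    downstream = [v for v in nodes if v != neuron and ok[v]]
    returning = []
    path_lengths: dict[str, int] = {}
    for k, partner in enumerate(downstream):
        sub = (seed * 1_000_003 + 1 + k) % (2**31 - 1)
        back = run_cascade(adjacency, CascadeSpec((partner,), p=p, max_hops=hops,
                                                  iterations=iterations, seed=sub), nodes)
        if receives_signal(back, threshold)[neuron]:
            returning.append(partner)
            arrival = back.activation[back.index[neuron], 1:]
            path_lengths[partner] = int((arrival > 0).sum())
    frac = len(returning) / len(downstream) if downstream else float("nan")
    return RecurrenceResult(neuron, downstream, returning, frac, path_lengths)


def cluster_flow_matrix(
    adjacency: np.ndarray,
    nodes: list[str],
    clusters: list[list[str]],
    hops: int = 2,
    p: float = 0.05,
    iterations: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Cluster-to-cluster mean cascade signal, forward above the diagonal.

    ``clusters`` must already be sorted from inputs to outputs (e.g. by
    mean signal-flow score).  Entry (s, t) is the mean visit probability of
    cluster t's members under a cascade started at all of cluster s's
    members; with that ordering, above-diagonal entries are forward signal
    and below-diagonal entries backward signal.
    """
    k = len(clusters)
    index = {v: i for i, v in enumerate(nodes)}
    out = np.zeros((k, k))
    for s, members in enumerate(clusters):
        res = run_cascade(adjacency, CascadeSpec(tuple(members), p=p, max_hops=hops,
                                                 iterations=iterations, seed=seed + s), nodes)
        for t, targets in enumerate(clusters):
            if t == s:
                continue
            out[s, t] = float(np.mean([res.visit_probability[index[v]] for v in targets]))
    return out


def _reach_within(adjacency: np.ndarray, sources: np.ndarray, hops: int) -> np.ndarray:
    """Boolean mask of nodes reachable from ``sources`` in 1..hops steps."""
    a = np.asarray(adjacency) > 0
    frontier = sources.copy()
    reached = np.zeros(a.shape[0], dtype=bool)
    for _ in range(hops):
        frontier = (a[frontier].any(axis=0)) & ~reached
        reached |= frontier
        if not frontier.any():
            break
    return reached


def efference_copy_reach(
    adjacency: np.ndarray,
    nodes: list[str],
    output_neurons: list[str],
    hops: int = 2,
) -> pd.DataFrame:
    """Brain partners downstream of output neurons, recurrent vs parallel.

    For each output neuron, its within-brain partners at 1 and up to
    ``hops`` hops downstream of its axon are found; a partner is
    *recurrent* when it is itself (directly or in <= ``hops`` hops)
    upstream of the same output neuron, and *parallel* otherwise.
    """
    a = np.asarray(adjacency) > 0
    index = {v: i for i, v in enumerate(nodes)}
    rows = []
    for out_node in output_neurons:
        i = index[out_node]
        src = np.zeros(len(nodes), dtype=bool)
        src[i] = True
        down1 = _reach_within(a, src, 1)
        down = _reach_within(a, src, hops)
        upstream = _reach_within(a.T, src, hops)  # nodes that reach the output
        down[i] = down1[i] = False
        partners = np.nonzero(down)[0]
        recurrent = [nodes[j] for j in partners if upstream[j]]
        parallel = [nodes[j] for j in partners if not upstream[j]]
        rows.append({
            "output": out_node,
            "n_direct": int(down1.sum()),
            "n_within_hops": int(down.sum()),
            "recurrent": recurrent,
            "parallel": parallel,
            "n_recurrent": len(recurrent),
            "n_parallel": len(parallel),
        })
    return pd.DataFrame(rows).set_index("output")
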