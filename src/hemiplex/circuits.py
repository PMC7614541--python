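"""Circuit-level metrics on the thresholded connectome.

All operations here are deterministic functions of the strong,
bilaterally reproducible graph (see :mod:`hemiplex.edgestats`) and node
metadata: hub classification, sensory processing orders and layers, local
neuron types, simple-pathway enumeration, axon laterality classes,
bilateral partner similarity, reciprocal homolog loops, group connection
probabilities and descending-ascending zigzag motifs.
"""

from __future__ import annotations

import random
from collections import deque
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import PairMap
from .edgestats import ThresholdedGraph

__all__ = [
    "hub_classification", "degree_threshold_from_stats", "sensory_orders",
    "local_neuron_classification", "enumerate_pathways", "axon_laterality",
    "bilateral_partner_similarity", "homolog_reciprocal_loops",
    "group_connection_probability", "zigzag_motifs", "MotifInstance",
]


def degree_threshold_from_stats(degrees: np.ndarray, n_sd: float = 1.5) -> float:
    """Hub degree cutoff as mean + n_sd standard deviations."""
    d = np.asarray(degrees, float)
    return float(d.mean() + n_sd * d.std())


def hub_classification(
    graph: ThresholdedGraph, in_thresh: int = 20, out_thresh: int = 20
) -> pd.DataFrame:
    """Label in-, out- and in-out hubs by distinct strong partner counts.

    Degrees count distinct partners on the thresholded graph, not
    synapses; thresholds are inclusive (a node with exactly 20 partners is
    a hub).  The default cutoff of 20 corresponds to the mean plus 1.5 SD
    of the a-d degree distribution in the larval brain.
    """
    ind = graph.in_degree()
    outd = graph.out_degree()
    cls = []
    for i in range(len(graph.nodes)):
        is_in = ind[i] >= in_thresh
        is_out = outd[i] >= out_thresh
        cls.append("in-out" if (is_in and is_out) else "in" if is_in else "out" if is_out else "none")
    return pd.DataFrame({"node": graph.nodes, "in_degree": ind, "out_degree": outd,
                         "hub_class": cls}).set_index("node")


def _bfs_hops(adjacency: np.ndarray, sources: list[int]) -> np.ndarray:
    """Minimum hop count from a source set along directed edges (-1 = unreachable)."""
    n = adjacency.shape[0]
    dist = np.full(n, -1, dtype=int)
    dq = deque()
    for s in sources:
        dist[s] = 0
        dq.append(s)
    targets = [np.nonzero(adjacency[i])[0] for i in range(n)]
    while dq:
        u = dq.popleft()
        for v in targets[u]:
            if dist[v] < 0:
                dist[v] = dist[u] + 1
                dq.append(v)
    return dist


def sensory_orders(
    graph: ThresholdedGraph, input_sets: dict[str, list[str]]
) -> pd.DataFrame:
    """Per-modality hop counts from input neurons and the overall order.

    A neuron's order for one modality is 1 + its minimum hop distance from
    that modality's input set (the inputs themselves are 1st order, their
    direct targets 2nd order).  The overall order uses the lowest-order
    input over all modalities; neurons unreachable from every input set
    are uncategorized (order NaN).
    """
    per_mod = {}
    for mod, members in input_sets.items():
        idx = [graph.index[v] for v in members]
        dist = _bfs_hops(graph.adjacency, idx)
        per_mod[mod] = np.where(dist >= 0, dist + 1, np.nan)
    df = pd.DataFrame(per_mod, index=graph.nodes)
    df["order"] = df.min(axis=1)
    return df


def sensory_layers(orders: pd.DataFrame, modality: str) -> dict[int, list[str]]:
    """Group nodes into layers (order value -> members) for one modality."""
    col = orders[modality]
    layers: dict[int, list[str]] = {}
    for node, o in col.items():
        if np.isfinite(o):
            layers.setdefault(int(o), []).append(node)
    return layers


def local_neuron_classification(
    graph: ThresholdedGraph,
    orders: pd.DataFrame,
    modalities: list[str] | None = None,
) -> pd.DataFrame:
    """Classify nodes as type 1 / type 2 local neurons, PNs or non-LN.

    Type 1 LNs send a strict majority of their strong output to their own
    sensory layer or to the layer directly upstream (same modality, order
    minus one).  Type 2 LNs receive a strict majority of input from and
    send a strict majority of output to one sensory layer they do not
    belong to.  Remaining 2nd-order neurons are projection neurons (PNs)
    by exclusion; everything else is non-LN.  Majorities are over counts
    of distinct strong partners.
    """
    modalities = [c for c in orders.columns if c != "order"] if modalities is None else modalities
    adj = graph.adjacency
    n = len(graph.nodes)
    layer_members: dict[tuple[str, int], set[int]] = {}
    for mod in modalities:
        for o, members in sensory_layers(orders, mod).items():
            layer_members[(mod, o)] = {graph.index[v] for v in members}

    labels = []
    for i, node in enumerate(graph.nodes):
        out_idx = set(np.nonzero(adj[i])[0])
        in_idx = set(np.nonzero(adj[:, i])[0])
        n_out, n_in = len(out_idx), len(in_idx)
        label = "non-LN"
        # type 1: majority of output into own layer (or directly upstream layer)
        if n_out:
            for mod in modalities:
                o = orders.loc[node, mod]
                if not np.isfinite(o):
                    continue
                own = layer_members.get((mod, int(o)), set())
                upstream = layer_members.get((mod, int(o) - 1), set())
                if len(out_idx & (own | upstream)) * 2 > n_out:
                    label = "type1 LN"
                    break
        # type 2: majority input AND output to a layer the node is outside of
        if label == "non-LN" and n_out and n_in:
            for (mod, o), members in layer_members.items():
                if i in members:
                    continue
                if len(out_idx & members) * 2 > n_out and len(in_idx & members) * 2 > n_in:
                    label = "type2 LN"
                    break
        if label == "non-LN" and orders.loc[node, "order"] == 2:
            label = "PN"
        labels.append(label)
    out = orders.copy()
    out["ln_class"] = labels
    return out


def enumerate_pathways(
    graph: ThresholdedGraph,
    sources: list[str],
    targets: list[str],
    max_hops: int = 6,
    sample_cap: int | None = None,
    seed: int = 0,
) -> tuple[list[list[str]], int]:
    """All simple directed source-to-target paths with at most ``max_hops`` edges.

    Returns (paths, total_count).  When the total exceeds ``sample_cap``, a
    uniform random sample of that size is returned (reservoir sampling)
    together with the exact total count.
    """
    if set(sources) & set(targets):
        raise ValueError("sources and targets must be disjoint")
    adj = graph.adjacency
    src = [graph.index[v] for v in sources]
    tgt = {graph.index[v] for v in targets}
    succ = [np.nonzero(adj[i])[0] for i in range(len(graph.nodes))]
    rng = random.Random(seed)
    kept: list[list[int]] = []
    total = 0

    def visit(path: list[int], on_path: set[int]) -> None:
        nonlocal total
        u = path[-1]
        if u in tgt:
            total += 1
            if sample_cap is None or len(kept) < sample_cap:
                kept.append(list(path))
            else:  # reservoir replacement keeps the sample uniform
                k = rng.randrange(total)
                if k < sample_cap:
                    kept[k] = list(path)
            return
        if len(path) - 1 >= max_hops:
            return
        for v in succ[u]:
            if v not in on_path:
                path.append(int(v))
                on_path.add(int(v))
                visit(path, on_path)
                on_path.discard(int(v))
                path.pop()

    for s in src:
        visit([s], {s})
    return [[graph.nodes[i] for i in p] for p in kept], total


def axon_laterality(
    contralateral_fraction: pd.Series | dict[str, float],
    ipsi_cutoff: float = 0.2,
    contra_cutoff: float = 0.8,
) -> pd.Series:
    """Classify axons by their fraction of contralateral presynaptic sites.

    ``<= ipsi_cutoff`` -> ipsilateral, ``>= contra_cutoff`` ->
    contralateral, in between -> bilateral; NaN (no presynaptic sites) ->
    unlabeled.
    """
    s = pd.Series(contralateral_fraction, dtype=float)
    if ((s < 0) | (s > 1)).any():
        raise ValueError("fractions must lie in [0, 1]")
    out = pd.Series("bilateral", index=s.index, dtype=object)
    out[s <= ipsi_cutoff] = "ipsilateral"
    out[s >= contra_cutoff] = "contralateral"
    out[s.isna()] = "unlabeled"
    return out


def contralateral_output_fraction(
    graph_or_weights: np.ndarray, nodes: list[str], hemisphere: pd.Series
) -> pd.Series:
    """Per-node fraction of outgoing synaptic weight onto the opposite hemisphere."""
    a = np.asarray(graph_or_weights, float)
    hemi = hemisphere.reindex(nodes).to_numpy()
    out = {}
    for i, v in enumerate(nodes):
        w = a[i]
        total = w.sum()
        if total == 0 or hemi[i] not in ("left", "right"):
            out[v] = np.nan
            continue
        other = hemi != hemi[i]
        out[v] = float(w[other].sum() / total)
    return pd.Series(out)


def bilateral_partner_similarity(
    graph: ThresholdedGraph, pairs: PairMap, neuron: str
) -> float:
    """Cosine similarity between a neuron's two hemispheres' output patterns.

    The ipsilateral and contralateral output vectors are indexed by
    homolog-pair identity, so targeting pair k on both sides contributes to
    the same coordinate.  NaN when either vector is zero (the neuron does
    not project to both hemispheres).
    """
    i = graph.index[neuron]
    row = graph.adjacency[i].astype(float)
    pair_list = pairs.pairs()
    pair_index = {l: k for k, (l, _) in enumerate(pair_list)}
    pair_index.update({r: k for k, (_, r) in enumerate(pair_list)})
    side_of = {l: "left" for l, _ in pair_list}
    side_of.update({r: "right" for _, r in pair_list})
    my_side = side_of.get(neuron)
    if my_side is None:
        raise ValueError(f"{neuron} is unpaired; bilateral similarity undefined")
    ipsi = np.zeros(len(pair_list))
    contra = np.zeros(len(pair_list))
    for j in np.nonzero(row)[0]:
        tgt = graph.nodes[j]
        if tgt not in pair_index:
            continue
        vec = ipsi if side_of[tgt] == my_side else contra
        vec[pair_index[tgt]] += row[j]
    ni, nc = np.linalg.norm(ipsi), np.linalg.norm(contra)
    if ni == 0 or nc == 0:
        return float("nan")
    return float(ipsi @ contra / (ni * nc))


def homolog_reciprocal_loops(
    graph: ThresholdedGraph, pairs: PairMap
) -> dict[str, list]:
    """Reciprocal loops between homologous left-right partners.

    A *pair loop* is a homolog pair (L, R) with edges L->R and R->L.  Pair
    loops linked by any edge between their member neurons form connected
    components: components of two pair loops are *double loops*, of three
    or more *super loops*.
    """
    adj = graph.adjacency
    idx = graph.index
    loops = []
    for l, r in pairs.pairs():
        if l in idx and r in idx and adj[idx[l], idx[r]] and adj[idx[r], idx[l]]:
            loops.append((l, r))
    # connect pair loops sharing an inter-pair edge
    parent = list(range(len(loops)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a in range(len(loops)):
        for b in range(a + 1, len(loops)):
            members_a = [idx[v] for v in loops[a]]
            members_b = [idx[v] for v in loops[b]]
            if any(adj[u, v] or adj[v, u] for u in members_a for v in members_b):
                parent[find(a)] = find(b)
    comps: dict[int, list[tuple[str, str]]] = {}
    for k in range(len(loops)):
        comps.setdefault(find(k), []).append(loops[k])
    groups = list(comps.values())
    return {
        "pair_loops": loops,
        "double_loops": [g for g in groups if len(g) == 2],
        "super_loops": [g for g in groups if len(g) >= 3],
    }


def group_connection_probability(
    graph: ThresholdedGraph, group_of: dict[str, str]
) -> pd.DataFrame:
    """Observed edges over possible ordered pairs, between and within groups.

    Within a group, self-pairs are excluded from the denominator.  Rows and
    columns of empty groups are NaN.
    """
    groups = sorted(set(group_of.values()))
    members = {g: [graph.index[v] for v in graph.nodes if group_of.get(v) == g] for g in groups}
    adj = graph.adjacency
    out = pd.DataFrame(np.nan, index=groups, columns=groups, dtype=float)
    for g1 in groups:
        for g2 in groups:
            m1, m2 = members[g1], members[g2]
            if not m1 or not m2:
                continue
            possible = len(m1) * len(m2) - (len(m1) if g1 == g2 else 0)
            if possible == 0:
                continue
            observed = int(adj[np.ix_(m1, m2)].sum())
            if g1 == g2:
                observed -= int(np.diag(adj[np.ix_(m1, m1)]).sum())
            out.loc[g1, g2] = observed / possible
    return out


@dataclass(frozen=True)
class MotifInstance:
    """One ordered motif occurrence."""

    nodes: tuple[str, ...]
    kind: str  # zigzag | reciprocal_loop


def zigzag_motifs(
    graph: ThresholdedGraph,
    descending: list[str],
    ascending: list[str],
    max_intermediate: int = 3,
) -> dict[str, list[MotifInstance]]:
    """Descending -> ascending -> different-descending zigzag motifs.

    The base motif is DN1 -> AN -> DN2 with DN1 != DN2.  Extended variants
    replace either leg by a short path through nodes outside the DN and AN
    sets, with at most ``max_intermediate`` nodes between the two DNs (the
    AN included), i.e. motifs of 3 to 2 + max_intermediate nodes.
    Reciprocal DN <-> AN loops (both edges between the same DN and AN) are
    searched separately and reported under ``reciprocal_loops``; they never
    count as zigzags.
    """
    adj = graph.adjacency
    idx = graph.index
    dn = [idx[v] for v in descending if v in idx]
    an = [idx[v] for v in ascending if v in idx]
    dn_set, an_set = set(dn), set(an)

    budget = max_intermediate - 1  # intermediates besides the AN, shared by the two legs

    def upstream_legs(a_idx: int) -> dict[int, list[tuple[int, ...]]]:
        """DN -> list of intermediate-node paths DN -> ... -> a (forward order)."""
        found: dict[int, list[tuple[int, ...]]] = {}

        def walk_back(u: int, inter: list[int]) -> None:
            for s in np.nonzero(adj[:, u])[0]:
                s = int(s)
                if s in dn_set:
                    found.setdefault(s, []).append(tuple(inter))
                elif s not in an_set and s not in inter and len(inter) < budget:
                    walk_back(s, [s] + inter)

        walk_back(a_idx, [])
        return found

    def downstream_legs(a_idx: int) -> dict[int, list[tuple[int, ...]]]:
        """DN -> list of intermediate-node paths a -> ... -> DN (forward order)."""
        found: dict[int, list[tuple[int, ...]]] = {}

        def walk_fwd(u: int, inter: list[int]) -> None:
            for s in np.nonzero(adj[u])[0]:
                s = int(s)
                if s in dn_set:
                    found.setdefault(s, []).append(tuple(inter))
                elif s not in an_set and s not in inter and len(inter) < budget:
                    walk_fwd(s, inter + [s])

        walk_fwd(a_idx, [])
        return found

    zigzags: list[MotifInstance] = []
    for a in an:
        up = upstream_legs(a)
        down = downstream_legs(a)
        for d1, ups in up.items():
            for d2, downs in down.items():
                if d1 == d2:
                    continue
                for pu in ups:
                    for pd_ in downs:
                        if len(pu) + len(pd_) > budget:
                            continue
                        if set(pu) & set(pd_):
                            continue
                        nodes = (graph.nodes[d1], *[graph.nodes[x] for x in pu],
                                 graph.nodes[a], *[graph.nodes[x] for x in pd_], graph.nodes[d2])
                        zigzags.append(MotifInstance(nodes, "zigzag"))

    loops = []
    for d in dn:
        for a in an:
            if adj[d, a] and adj[a, d]:
                loops.append(MotifInstance((graph.nodes[d], graph.nodes[a]), "reciprocal_loop"))
    return {"zigzags": zigzags, "reciprocal_loops": loops}
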