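"""Neuronal skeletons and axon/dendrite splitting via synapse flow centrality.

Insect neurons are typically polarized into a presynapse-rich axon and a
postsynapse-rich dendrite, joined by a synapse-free linker segment.  Synapse
flow centrality (SFC) locates that linker: for every (presynaptic site,
postsynaptic site) pair, the unique tree path between them is traced, and
each arbor edge is scored by the number of such paths crossing it.  The
linker is the synapse-free run of maximal-score edges, and the split point
is placed at its soma-proximal end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

__all__ = ["SkeletonTree", "CompartmentSplit", "synapse_flow_centrality", "compartment_labels"]


@dataclass
class SkeletonTree:
    """Rooted neuronal arbor with synapse-site annotations.

    ``parent[v]`` is the parent of node ``v`` (the root, conventionally the
    soma, maps to ``None``).  ``presynapses`` / ``postsynapses`` give the
    number of presynaptic / postsynaptic sites attached to each node.
    """

    neuron_id: str
    parent: dict[str, str | None]
    presynapses: dict[str, int] = field(default_factory=dict)
    postsynapses: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        roots = [v for v, p in self.parent.items() if p is None]
        if len(roots) != 1:
            raise ValueError(f"skeleton must have exactly one root, found {len(roots)}")
        self.root = roots[0]
        for v, p in self.parent.items():
            if p is not None and p not in self.parent:
                raise ValueError(f"parent {p!r} of node {v!r} is not in the tree")
        for site_map in (self.presynapses, self.postsynapses):
            for v in site_map:
                if v not in self.parent:
                    raise ValueError(f"synapse attached to unknown node {v!r}")
        # verify acyclicity / connectivity by walking every node to the root
        order = self.topological_order()
        if len(order) != len(self.parent):
            raise ValueError("skeleton contains a cycle or disconnected part")

    @property
    def nodes(self) -> list[str]:
        return list(self.parent)

    def children(self) -> dict[str, list[str]]:
        ch: dict[str, list[str]] = {v: [] for v in self.parent}
        for v, p in self.parent.items():
            if p is not None:
                ch[p].append(v)
        return ch

    def topological_order(self) -> list[str]:
        """Nodes ordered root-first (parents before children)."""
        ch = self.children()
        order, stack = [], [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(ch[v])
        return order

    def depth(self) -> dict[str, int]:
        d = {self.root: 0}
        for v in self.topological_order()[1:]:
            d[v] = d[self.parent[v]] + 1
        return d

    def n_presynapses(self) -> int:
        return sum(self.presynapses.values())

    def n_postsynapses(self) -> int:
        return sum(self.postsynapses.values())


@dataclass(frozen=True)
class CompartmentSplit:
    """Axon/dendrite split decision for one neuron.

    ``split_node`` is the soma-proximal end of the linker segment; the axon
    comprises its strict descendants, the dendrite everything else
    (including the soma).  ``polarity`` is ``'polarized'``, ``'unpolarized'``
    (synapses present but no axon identifiable) or ``'immature'`` (no
    synapses at all).
    """

    neuron_id: str
    split_node: str | None
    polarity: str


def synapse_flow_centrality(
    skeleton: SkeletonTree,
) -> tuple[dict[str, int], CompartmentSplit]:
    """Score arbor edges by presynapse-to-postsynapse path flow and split.

    Returns
    -------
    centrality : dict
        Keyed by child node ``v``; the value is the number of
        (presynaptic site, postsynaptic site) tree paths that traverse the
        edge ``v -- parent(v)``, counting site multiplicities.
    split : CompartmentSplit
        The axon/dendrite split.  Neurons without presynapses or without
        postsynapses are ``unpolarized`` (``immature`` when they have no
        synapses at all); so are neurons whose maximal-centrality edges
        form no synapse-free segment.
    """
    order = skeleton.topological_order()
    total_pre = skeleton.n_presynapses()
    total_post = skeleton.n_postsynapses()

    # subtree synapse sums, leaves-first
    sub_pre = {v: skeleton.presynapses.get(v, 0) for v in skeleton.parent}
    sub_post = {v: skeleton.postsynapses.get(v, 0) for v in skeleton.parent}
    for v in reversed(order):
        p = skeleton.parent[v]
        if p is not None:
            sub_pre[p] += sub_pre[v]
            sub_post[p] += sub_post[v]

    centrality: dict[str, int] = {}
    for v in order:
        if skeleton.parent[v] is None:
            continue
        below_pre, below_post = sub_pre[v], sub_post[v]
        above_pre, above_post = total_pre - below_pre, total_post - below_post
        centrality[v] = below_pre * above_post + above_pre * below_post

    if total_pre == 0 and total_post == 0:
        return centrality, CompartmentSplit(skeleton.neuron_id, None, "immature")
    if total_pre == 0 or total_post == 0:
        return centrality, CompartmentSplit(skeleton.neuron_id, None, "unpolarized")

    split_node = _find_linker_split(skeleton, centrality)
    if split_node is None:
        return centrality, CompartmentSplit(skeleton.neuron_id, None, "unpolarized")
    return centrality, CompartmentSplit(skeleton.neuron_id, split_node, "polarized")


def _find_linker_split(skeleton: SkeletonTree, centrality: Mapping[str, int]) -> str | None:
    """Locate the linker domain and return its most proximal node.

    Maximal-centrality edges are grouped into connected segments; a segment
    qualifies as a linker when every node strictly interior to it carries no
    synapses.  Among qualifying segments the one nearest the soma wins, and
    within it the node nearest the soma is the split point.
    """
    if not centrality:
        return None
    cmax = max(centrality.values())
    if cmax <= 0:
        return None
    max_edges = {v for v, c in centrality.items() if c == cmax}  # edge v--parent(v)

    # group max edges into segments: union of nodes touched, connected via shared nodes
    seg_of: dict[str, int] = {}
    segments: list[set[str]] = []
    for v in skeleton.topological_order():
        if v not in max_edges:
            continue
        p = skeleton.parent[v]
        if p in seg_of:
            idx = seg_of[p]
        else:
            idx = len(segments)
            segments.append(set())
        segments[idx].update((v, p))
        seg_of[v] = idx
        seg_of[p] = seg_of.get(p, idx)

    depth = skeleton.depth()
    has_syn = lambda v: skeleton.presynapses.get(v, 0) + skeleton.postsynapses.get(v, 0) > 0

    candidates = []
    for seg in segments:
        # interior nodes: touched by >= 2 max edges within the segment
        touch = {v: 0 for v in seg}
        for v in seg:
            if v in max_edges and skeleton.parent[v] in seg:
                touch[v] += 1
                touch[skeleton.parent[v]] += 1
        interior = [v for v, k in touch.items() if k >= 2]
        if any(has_syn(v) for v in interior):
            continue
        proximal = min(seg, key=lambda v: (depth[v], v))
        candidates.append((depth[proximal], proximal))
    if not candidates:
        return None
    return min(candidates)[1]


def compartment_labels(skeleton: SkeletonTree, split: CompartmentSplit) -> dict[str, str]:
    """Per-node ``'axon'`` / ``'dendrite'`` labels implied by a split.

    The axon is the set of strict descendants of the split node; the
    dendrite is the rest of the arbor and always contains the soma.  Raises
    for non-polarized neurons.
    """
    if split.polarity != "polarized" or split.split_node is None:
        raise ValueError(f"neuron {split.neuron_id} is {split.polarity}; no compartments defined")
    labels = {}
    ch = skeleton.children()
    axon: set[str] = set()
    stack = list(ch[split.split_node])
    while stack:
        v = stack.pop()
        axon.add(v)
        stack.extend(ch[v])
    for v in skeleton.parent:
        labels[v] = "axon" if v in axon else "dendrite"
    return labels
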