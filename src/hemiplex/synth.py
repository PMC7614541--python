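"""Synthetic bilateral multiplex connectomes with planted ground truth.

The generator emulates the structural features of an insect-brain
connectome that the downstream analyses are sensitive to:

* a mirrored two-hemisphere node set with homolog pairs plus a minority of
  unpaired neurons,
* four overlapping directed connection-type layers with skewed,
  mostly-weak integer synapse counts (a truncated geometric weight law),
* ordered block structure with a feedforward gradient from sensory input
  classes to descending output classes,
* imperfect mirror symmetry (an edge present on one side is missing on the
  other with probability ``mirror_noise``),
* per-neuron axon laterality (ipsilateral / bilateral / contralateral
  projection targets),
* planted hubs, recurrent loops, homolog pair loops and zigzag motifs,
  all registered in a ground-truth record.

Everything is a deterministic function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .core import (
    EDGE_TYPES,
    MultiplexConnectome,
    NodeMeta,
    PairMap,
    SynapseRecord,
    build_multiplex,
)
from .skeleton import SkeletonTree

__all__ = ["GeneratorConfig", "GroundTruth", "generate_connectome", "generate_skeleton"]

_SITE = {"ad": ("axon", "dendrite"), "aa": ("axon", "axon"),
         "dd": ("dendrite", "dendrite"), "da": ("dendrite", "axon")}

#: Default per-layer edge densities.  The a-d layer dominates, with a-a
#: second and d-d/d-a sparse, mirroring the observed ordering of the four
#: connection types by synapse share (~67/26/6/2 %).
_DEFAULT_DENSITIES = {"ad": 0.028, "aa": 0.016, "dd": 0.004, "da": 0.002}

_MODALITIES = ("olfactory", "gustatory", "visual", "mechanosensory")


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic connectome.

    ``weak_edge_fraction`` is the target probability that an edge carries 1
    or 2 synapses (about two thirds of edges in real data are weak);
    weights follow a geometric law truncated at ``max_weight``.
    ``axon_side_probs`` are the ipsilateral/bilateral/contralateral axon
    proportions, defaulting to the 61/24/15 % split observed in the larval
    brain.  ``feedforward_bias`` is the probability mass of edges pointing
    down the planted sensory-to-output block order.
    """

    n_pairs: int = 300
    n_unpaired: int = 20
    n_blocks: int = 8
    block_connectivity: Mapping[str, np.ndarray] | None = None
    weak_edge_fraction: float = 0.66
    max_weight: int = 30
    mirror_noise: float = 0.05
    layer_densities: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_DENSITIES))
    feedforward_bias: float = 0.8
    within_block_boost: float = 4.0
    axon_side_probs: tuple[float, float, float] = (0.61, 0.24, 0.15)
    n_hubs: int = 4
    hub_degree: int = 25
    n_recurrent_loops: int = 4
    n_pair_loops: int = 3
    n_zigzag: int = 4
    planted_weight: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mirror_noise", "weak_edge_fraction", "feedforward_bias"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if abs(sum(self.axon_side_probs) - 1.0) > 1e-9:
            raise ValueError("axon_side_probs must sum to 1")
        if self.n_pairs < self.n_blocks:
            raise ValueError("need n_pairs >= n_blocks")

    @property
    def geometric_p(self) -> float:
        """Geometric parameter matching the weak-edge fraction.

        For W ~ Geometric(p), P(W <= 2) = 1 - (1-p)^2, so
        p = 1 - sqrt(1 - weak_edge_fraction).
        """
        return 1.0 - float(np.sqrt(1.0 - self.weak_edge_fraction))


@dataclass
class GroundTruth:
    """Registry of everything the generator planted."""

    pair_map: PairMap
    block_of: dict[str, int]
    hubs: list[str]
    recurrent_nodes: list[str]
    pair_loops: list[tuple[str, str]]
    zigzags: list[tuple[str, str, str]]
    laterality: dict[str, str]
    modality_of: dict[str, str]
    type_counts: dict[str, int]


def _default_block_matrix(cfg: GeneratorConfig, density: float) -> np.ndarray:
    """Ordered-block connectivity with a feedforward gradient.

    Forward block pairs (lower block index to higher) share the bias mass,
    everything else the remainder; within-block entries are boosted; the
    matrix is rescaled so that the expected edge density equals ``density``.
    """
    b = cfg.n_blocks
    # fraction of ordered node pairs falling in forward block pairs
    frac_fwd = (b - 1) / (2 * b)
    frac_rest = 1.0 - frac_fwd
    p_fwd = density * cfg.feedforward_bias / frac_fwd
    p_rest = density * (1.0 - cfg.feedforward_bias) / frac_rest
    P = np.full((b, b), p_rest)
    P[np.triu_indices(b, k=1)] = p_fwd
    P[np.diag_indices(b)] = p_rest * cfg.within_block_boost
    # renormalize expected density (blocks are near-equal sized)
    expected = (np.sum(P) - np.trace(P)) * (1 / b**2) + np.trace(P) / b**2
    P *= density / expected
    return np.clip(P, 0.0, 1.0)


def _truncated_geometric(rng: np.random.Generator, p: float, size: int, max_weight: int) -> np.ndarray:
    w = rng.geometric(p, size=size)
    return np.minimum(w, max_weight).astype(np.int64)


def generate_connectome(config: GeneratorConfig) -> tuple[MultiplexConnectome, GroundTruth]:
    """Sample a bilateral multiplex connectome and its ground truth."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_pairs

    left = [f"L{i:04d}" for i in range(n)]
    right = [f"R{i:04d}" for i in range(n)]
    unpaired = [f"U{i:04d}" for i in range(cfg.n_unpaired)]
    pair_map = PairMap(dict(zip(left, right)), set(unpaired))

    block = (np.arange(n) * cfg.n_blocks) // n  # pair index -> block
    classes = _block_classes(cfg.n_blocks)

    # infeasibility checks before any sampling
    inter_blocks = [b for b, c in enumerate(classes) if c not in ("SN", "AN", "DN_VNC")]
    inter_pairs = [i for i in range(n) if block[i] in inter_blocks]
    need = cfg.n_hubs + 2 * cfg.n_recurrent_loops
    if need > len(inter_pairs):
        raise ValueError(f"cannot plant {cfg.n_hubs} hubs and {cfg.n_recurrent_loops} loops "
                         f"with only {len(inter_pairs)} interneuron pairs")
    dn_pairs = [i for i in range(n) if classes[block[i]] == "DN_VNC"]
    an_pairs = [i for i in range(n) if classes[block[i]] == "AN"]
    if cfg.n_zigzag > 0 and (len(dn_pairs) < 2 or len(an_pairs) < 1):
        raise ValueError("not enough output/ascending pairs to plant zigzag motifs")

    # per-pair axon laterality; mirrored by construction
    lat_choices = rng.choice(3, size=n, p=cfg.axon_side_probs)
    lat_name = np.array(["ipsilateral", "bilateral", "contralateral"])[lat_choices]

    layers: dict[str, dict[tuple[str, str], int]] = {t: {} for t in EDGE_TYPES}

    for t in EDGE_TYPES:
        density = cfg.layer_densities[t]
        if cfg.block_connectivity is not None and t in cfg.block_connectivity:
            P = np.asarray(cfg.block_connectivity[t], dtype=float)
        else:
            P = _default_block_matrix(cfg, density)
        probs = P[block[:, None], block[None, :]]
        template = rng.random((n, n)) < probs
        np.fill_diagonal(template, False)
        ii, jj = np.nonzero(template)
        weights = _truncated_geometric(rng, cfg.geometric_p, len(ii), cfg.max_weight)
        # mirror noise: drop the edge from one randomly chosen side
        drop = rng.random(len(ii)) < cfg.mirror_noise
        drop_side = rng.random(len(ii)) < 0.5  # True: drop left copy
        axonal = t in ("ad", "aa")
        for k in range(len(ii)):
            i, j, w = int(ii[k]), int(jj[k]), int(weights[k])
            sides = []
            if not (drop[k] and drop_side[k]):
                sides.append("L")
            if not (drop[k] and not drop_side[k]):
                sides.append("R")
            for side in sides:
                src = (left if side == "L" else right)[i]
                same = left if side == "L" else right
                other = right if side == "L" else left
                if axonal and lat_choices[i] == 2:  # contralateral axon
                    targets = [other[j]]
                elif axonal and lat_choices[i] == 1:  # bilateral axon
                    targets = [same[j], other[j]]
                else:
                    targets = [same[j]]
                for dst in targets:
                    layers[t][(src, dst)] = layers[t].get((src, dst), 0) + w

    # unpaired neurons: sparse ipsilateral a-d connectivity
    up_hemi = ["left" if i % 2 == 0 else "right" for i in range(cfg.n_unpaired)]
    for ui, u in enumerate(unpaired):
        pool = left if up_hemi[ui] == "left" else right
        k_out = rng.binomial(n, cfg.layer_densities["ad"])
        k_in = rng.binomial(n, cfg.layer_densities["ad"])
        for j in rng.choice(n, size=k_out, replace=False):
            layers["ad"][(u, pool[j])] = int(_truncated_geometric(rng, cfg.geometric_p, 1, cfg.max_weight)[0])
        for j in rng.choice(n, size=k_in, replace=False):
            layers["ad"][(pool[j], u)] = int(_truncated_geometric(rng, cfg.geometric_p, 1, cfg.max_weight)[0])

    # ---- planted structures (a-d layer, strong weights, mirrored) --------
    picks = rng.permutation(inter_pairs)
    hub_pairs = [int(v) for v in picks[: cfg.n_hubs]]
    loop_pairs = [int(v) for v in picks[cfg.n_hubs: cfg.n_hubs + 2 * cfg.n_recurrent_loops]]

    w0 = cfg.planted_weight
    hubs: list[str] = []
    for hp in hub_pairs:
        partners = rng.choice([i for i in range(n) if i != hp],
                              size=cfg.hub_degree, replace=False)
        for side, pool in (("L", left), ("R", right)):
            for q in partners:
                layers["ad"][(pool[q], pool[hp])] = max(
                    layers["ad"].get((pool[q], pool[hp]), 0), w0)
            hubs.append(pool[hp])

    recurrent_nodes: list[str] = []
    for k in range(cfg.n_recurrent_loops):
        a, b = loop_pairs[2 * k], loop_pairs[2 * k + 1]
        for pool in (left, right):
            layers["ad"][(pool[a], pool[b])] = w0
            layers["ad"][(pool[b], pool[a])] = w0
            recurrent_nodes.extend((pool[a], pool[b]))

    contra_pairs = [i for i in range(n) if lat_choices[i] == 2 and classes[block[i]] not in ("SN",)]
    pair_loops: list[tuple[str, str]] = []
    for i in [int(v) for v in rng.permutation(contra_pairs)[: cfg.n_pair_loops]]:
        layers["ad"][(left[i], right[i])] = w0
        layers["ad"][(right[i], left[i])] = w0
        pair_loops.append((left[i], right[i]))

    zigzags: list[tuple[str, str, str]] = []
    for _ in range(cfg.n_zigzag):
        d1, d2 = [int(v) for v in rng.choice(dn_pairs, size=2, replace=False)]
        a = int(rng.choice(an_pairs))
        for pool in (left, right):
            layers["ad"][(pool[d1], pool[a])] = w0
            layers["ad"][(pool[a], pool[d2])] = w0
            zigzags.append((pool[d1], pool[a], pool[d2]))

    # ---- assemble --------------------------------------------------------
    records = []
    for t in EDGE_TYPES:
        pre_site, post_site = _SITE[t]
        for (src, dst), w in layers[t].items():
            if src != dst:
                records.append(SynapseRecord(src, dst, pre_site, post_site, int(w)))

    meta = []
    modality_of: dict[str, str] = {}
    block_of: dict[str, int] = {}
    laterality: dict[str, str] = {}
    for i in range(n):
        cls = classes[block[i]]
        modality = _MODALITIES[i % len(_MODALITIES)] if cls == "SN" else (
            "somatosensory" if cls == "AN" else None)
        for node, hemi in ((left[i], "left"), (right[i], "right")):
            meta.append(NodeMeta(node, hemi, cls, modality,
                                 is_input=cls in ("SN", "AN"),
                                 is_output=cls == "DN_VNC"))
            block_of[node] = int(block[i])
            laterality[node] = str(lat_name[i])
            if modality:
                modality_of[node] = modality
    for ui, u in enumerate(unpaired):
        meta.append(NodeMeta(u, up_hemi[ui], "KC"))
        block_of[u] = -1

    conn = build_multiplex(records, meta)
    truth = GroundTruth(
        pair_map=pair_map,
        block_of=block_of,
        hubs=hubs,
        recurrent_nodes=recurrent_nodes,
        pair_loops=pair_loops,
        zigzags=zigzags,
        laterality=laterality,
        modality_of=modality_of,
        type_counts={t: int(sum(layers[t].values())) for t in EDGE_TYPES},
    )
    return conn, truth


def _block_classes(n_blocks: int) -> list[str]:
    """Cell class per ordered block: inputs first, outputs last."""
    classes = ["other"] * n_blocks
    classes[0] = "SN"
    if n_blocks >= 4:
        classes[1] = "AN"
    if n_blocks >= 5:
        classes[2] = "PN"
    if n_blocks >= 6:
        classes[3] = "LHN"
    if n_blocks >= 3:
        classes[-2] = "pre-DN"
    classes[-1] = "DN_VNC"
    return classes


def generate_skeleton(
    n_nodes: int, n_pre: int, n_post: int, seed: int = 0
) -> tuple[SkeletonTree, str | None]:
    """Random skeleton with a designated synapse-free linker.

    The backbone is soma -> D -> M -> A with all postsynaptic sites on D
    (proximal) and all presynaptic sites on A (distal); M is the
    synapse-free linker interior.  Remaining nodes are synapse-free
    branches attached uniformly at random.  Returns the tree and the true
    split node (``'D'``), or ``None`` when the neuron is not polarized.
    """
    if n_nodes < n_pre + n_post + 2:
        raise ValueError("need n_nodes >= n_pre + n_post + 2")
    rng = np.random.default_rng(seed)
    parent: dict[str, str | None] = {"soma": None, "D": "soma", "M": "D", "A": "M"}
    attachable = ["soma", "D", "A"]
    for k in range(max(0, n_nodes - 4)):
        v = f"b{k}"
        parent[v] = str(rng.choice(attachable))
        attachable.append(v)
    pre = {"A": n_pre} if n_pre else {}
    post = {"D": n_post} if n_post else {}
    tree = SkeletonTree(f"synthetic-{seed}", parent, pre, post)
    true_split = "D" if (n_pre and n_post) else None
    return tree, true_split
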