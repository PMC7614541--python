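"""Core domain types: synapse records, node metadata, the multiplex connectome.

A connectome here is four directed, integer-weighted graphs (one per
connection type) over a single shared, canonically ordered node set, plus a
metadata table.  Connection types are named by the presynaptic and
postsynaptic compartment: ``ad`` (axo-dendritic), ``aa`` (axo-axonic),
``dd`` (dendro-dendritic) and ``da`` (dendro-axonic).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical connection-type keys, ordered as (a-d, a-a, d-d, d-a).
EDGE_TYPES: tuple[str, ...] = ("ad", "aa", "dd", "da")

_COMPARTMENTS = ("axon", "dendrite")

_ALIASES = {
    "ad": "ad", "a-d": "ad", "axo-dendritic": "ad",
    "aa": "aa", "a-a": "aa", "axo-axonic": "aa",
    "dd": "dd", "d-d": "dd", "dendro-dendritic": "dd",
    "da": "da", "d-a": "da", "dendro-axonic": "da",
}


def canonical_edge_type(name: str) -> str:
    """Normalize an edge-type name (``'a-d'`` -> ``'ad'`` etc.)."""
    try:
        return _ALIASES[name.lower()]
    except KeyError:
        raise ValueError(f"unknown edge type {name!r}; expected one of {EDGE_TYPES}") from None


@dataclass(frozen=True)
class SynapseRecord:
    """One aggregated synaptic contact between two neurons.

    Parameters
    ----------
    pre_id, post_id
        Identifiers of the presynaptic and postsynaptic neuron.
    pre_site, post_site
        Compartment carrying the synapse on each side, ``'axon'`` or
        ``'dendrite'``; ``None`` when the compartment is unknown.
    count
        Number of synaptic contacts (>= 1).
    """

    pre_id: str
    post_id: str
    pre_site: str | None = None
    post_site: str | None = None
    count: int = 1

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError(f"synapse count must be >= 1, got {self.count}")
        for site in (self.pre_site, self.post_site):
            if site is not None and site not in _COMPARTMENTS:
                raise ValueError(f"compartment must be one of {_COMPARTMENTS}, got {site!r}")


@dataclass(frozen=True)
class NodeMeta:
    """Per-neuron annotation.

    ``hemisphere`` is ``'left'``, ``'right'`` or ``'center'``;
    ``cell_class`` is a free label (SN, AN, PN, LHN, KC, MBON, DN_VNC, ...);
    ``modality`` is set for sensory input neurons only.
    """

    node_id: str
    hemisphere: str = "center"
    cell_class: str = "other"
    modality: str | None = None
    is_input: bool = False
    is_output: bool = False

    def __post_init__(self) -> None:
        if self.hemisphere not in ("left", "right", "center"):
            raise ValueError(f"hemisphere must be left/right/center, got {self.hemisphere!r}")


@dataclass
class BuildReport:
    """Bookkeeping from :func:`build_multiplex`."""

    n_records: int = 0
    n_synapses: int = 0
    self_loops_removed: int = 0
    self_loop_synapses: int = 0
    unclassified: list[SynapseRecord] = field(default_factory=list)

    @property
    def unclassified_synapses(self) -> int:
        return sum(r.count for r in self.unclassified)


class MultiplexConnectome:
    """Four directed integer-weighted graphs over one shared node set.

    Attributes
    ----------
    nodes : list of str
        Canonical (sorted) node order; all layer matrices follow it.
    layers : dict mapping edge type to (n, n) integer ndarray
        ``layers[t][i, j]`` is the synapse count from ``nodes[i]`` to
        ``nodes[j]`` through connection type ``t``.  Diagonals are zero.
    meta : pandas.DataFrame
        Indexed by node id with columns hemisphere, cell_class, modality,
        is_input, is_output.
    """

    def __init__(
        self,
        nodes: Sequence[str],
        layers: Mapping[str, np.ndarray],
        meta: pd.DataFrame,
        report: BuildReport | None = None,
    ) -> None:
        self.nodes: list[str] = list(nodes)
        n = len(self.nodes)
        if len(set(self.nodes)) != n:
            raise ValueError("duplicate node ids")
        self.index: dict[str, int] = {v: i for i, v in enumerate(self.nodes)}
        self.layers: dict[str, np.ndarray] = {}
        for t in EDGE_TYPES:
            a = np.asarray(layers.get(t, np.zeros((n, n), dtype=np.int64)))
            if a.shape != (n, n):
                raise ValueError(f"layer {t} has shape {a.shape}, expected {(n, n)}")
            if (a < 0).any():
                raise ValueError(f"layer {t} has negative weights")
            if np.diagonal(a).any():
                raise ValueError(f"layer {t} has self-loops")
            self.layers[t] = a.astype(np.int64)
        missing = [v for v in self.nodes if v not in meta.index]
        if missing:
            raise ValueError(f"nodes missing metadata: {missing[:10]}")
        self.meta = meta.loc[self.nodes]
        self.report = report if report is not None else BuildReport()

    # -- accessors ---------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def layer(self, name: str) -> np.ndarray:
        return self.layers[canonical_edge_type(name)]

    def summed(self, types: Iterable[str] | None = None) -> np.ndarray:
        """Sum of the requested layers (all four by default)."""
        types = EDGE_TYPES if types is None else [canonical_edge_type(t) for t in types]
        return sum(self.layers[t] for t in types)

    def nodes_of_class(self, *classes: str) -> list[str]:
        mask = self.meta["cell_class"].isin(classes)
        return list(self.meta.index[mask])

    def hemisphere_nodes(self, hemisphere: str) -> list[str]:
        return list(self.meta.index[self.meta["hemisphere"] == hemisphere])

    def total_synapses(self) -> int:
        return int(sum(a.sum() for a in self.layers.values()))

    def to_networkx(self, layer: str):
        """Export one layer as a weighted :class:`networkx.DiGraph`."""
        import networkx as nx

        a = self.layer(layer)
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for i, j in zip(*np.nonzero(a)):
            g.add_edge(self.nodes[i], self.nodes[j], weight=int(a[i, j]))
        return g

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        dens = {t: float((a > 0).mean()) for t, a in self.layers.items()}
        return f"MultiplexConnectome(n={self.n_nodes}, densities={dens})"


@dataclass
class PairMap:
    """Partial bijection between left and right hemisphere node ids."""

    left_to_right: dict[str, str]
    unpaired: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        rights = list(self.left_to_right.values())
        if len(set(rights)) != len(rights):
            raise ValueError("pair map is not injective")
        self.right_to_left = {r: l for l, r in self.left_to_right.items()}

    def partner(self, node: str) -> str | None:
        """The homolog of ``node``, or ``None`` if unpaired."""
        return self.left_to_right.get(node) or self.right_to_left.get(node)

    def pairs(self) -> list[tuple[str, str]]:
        return sorted(self.left_to_right.items())

    def is_paired(self, node: str) -> bool:
        return node in self.left_to_right or node in self.right_to_left

    def __len__(self) -> int:
        return len(self.left_to_right)


def classify_synapse(record: SynapseRecord) -> str | None:
    """Map a synapse record to its connection type.

    (axon, dendrite) -> ``'ad'``, (axon, axon) -> ``'aa'``,
    (dendrite, dendrite) -> ``'dd'``, (dendrite, axon) -> ``'da'``.
    Returns ``None`` when either compartment is unknown; callers must route
    such records to an unclassified bucket rather than drop them.
    """
    if record.pre_site is None or record.post_site is None:
        return None
    pre = "a" if record.pre_site == "axon" else "d"
    post = "d" if record.post_site == "dendrite" else "a"
    return pre + post


def build_multiplex(
    records: Iterable[SynapseRecord],
    meta: Iterable[NodeMeta] | pd.DataFrame,
) -> MultiplexConnectome:
    """Assemble a :class:`MultiplexConnectome` from synapse records.

    Weights are summed per (pre, post, type).  Self-loops are excluded and
    counted in the build report; records lacking compartment labels go to
    the report's unclassified bucket.  Unknown endpoints are a hard error.
    """
    if isinstance(meta, pd.DataFrame):
        meta_df = meta.copy()
    else:
        meta_df = pd.DataFrame(
            [
                {
                    "node_id": m.node_id,
                    "hemisphere": m.hemisphere,
                    "cell_class": m.cell_class,
                    "modality": m.modality,
                    "is_input": m.is_input,
                    "is_output": m.is_output,
                }
                for m in meta
            ]
        ).set_index("node_id")
    if meta_df.index.has_duplicates:
        raise ValueError("duplicate node ids in metadata")

    nodes = sorted(meta_df.index)
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    layers = {t: np.zeros((n, n), dtype=np.int64) for t in EDGE_TYPES}
    report = BuildReport()

    unknown: set[str] = set()
    for rec in records:
        report.n_records += 1
        report.n_synapses += rec.count
        if rec.pre_id not in index or rec.post_id not in index:
            unknown.update(v for v in (rec.pre_id, rec.post_id) if v not in index)
            continue
        if rec.pre_id == rec.post_id:
            report.self_loops_removed += 1
            report.self_loop_synapses += rec.count
            logger.debug("excluding self-loop on %s (%d synapses)", rec.pre_id, rec.count)
            continue
        t = classify_synapse(rec)
        if t is None:
            report.unclassified.append(rec)
            continue
        layers[t][index[rec.pre_id], index[rec.post_id]] += rec.count
    if unknown:
        raise KeyError(f"synapse records reference nodes absent from metadata: {sorted(unknown)[:20]}")
    if report.self_loops_removed:
        logger.info("excluded %d self-loop records (%d synapses)",
                    report.self_loops_removed, report.self_loop_synapses)

    return MultiplexConnectome(nodes, layers, meta_df, report)
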