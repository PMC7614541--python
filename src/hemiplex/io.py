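"""Reading and writing the package's plain-text exchange formats.

* synapse tables / edge lists: CSV with header
  ``pre_id,post_id,pre_site,post_site,count``
* node metadata: CSV with header
  ``node_id,hemisphere,cell_class,modality,is_input,is_output``
* adjacency matrices: one dense CSV per layer, first row/column node ids
* skeletons: SWC-like CSV (``node_id,parent_id,x,y,z,radius``) plus a
  synapse CSV (``node_id,kind,count`` with kind in {pre, post})
* pair maps: CSV ``left,right``
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .core import EDGE_TYPES, MultiplexConnectome, PairMap, SynapseRecord, build_multiplex
from .skeleton import SkeletonTree

__all__ = [
    "read_synapse_table", "write_synapse_table",
    "read_node_meta", "write_node_meta",
    "read_connectome", "write_connectome",
    "read_adjacency_csv", "write_adjacency_csv", "write_graphml",
    "read_skeleton", "read_pair_map", "write_pair_map",
]


def read_synapse_table(path: str | os.PathLike) -> list[SynapseRecord]:
    df = pd.read_csv(path, dtype={"pre_id": str, "post_id": str})
    records = []
    for row in df.itertuples(index=False):
        pre_site = None if pd.isna(row.pre_site) else str(row.pre_site)
        post_site = None if pd.isna(row.post_site) else str(row.post_site)
        records.append(SynapseRecord(str(row.pre_id), str(row.post_id),
                                     pre_site, post_site, int(row.count)))
    return records


def write_synapse_table(records: Iterable[SynapseRecord], path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        [(r.pre_id, r.post_id, r.pre_site, r.post_site, r.count) for r in records],
        columns=["pre_id", "post_id", "pre_site", "post_site", "count"],
    )
    df.to_csv(path, index=False)


def read_node_meta(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"node_id": str}).set_index("node_id")
    df["modality"] = df["modality"].where(pd.notna(df["modality"]), None)
    df["is_input"] = df["is_input"].astype(bool)
    df["is_output"] = df["is_output"].astype(bool)
    return df


def write_node_meta(meta: pd.DataFrame, path: str | os.PathLike) -> None:
    meta.to_csv(path, index_label="node_id")


def connectome_to_records(conn: MultiplexConnectome) -> list[SynapseRecord]:
    """Flatten a connectome back to per-type synapse records."""
    site = {"ad": ("axon", "dendrite"), "aa": ("axon", "axon"),
            "dd": ("dendrite", "dendrite"), "da": ("dendrite", "axon")}
    records = []
    for t in EDGE_TYPES:
        a = conn.layers[t]
        pre_site, post_site = site[t]
        for i, j in zip(*np.nonzero(a)):
            records.append(SynapseRecord(conn.nodes[i], conn.nodes[j],
                                         pre_site, post_site, int(a[i, j])))
    return records


def write_connectome(conn: MultiplexConnectome, directory: str | os.PathLike) -> None:
    """Write edge list + metadata CSVs into ``directory``."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_synapse_table(connectome_to_records(conn), d / "edges.csv")
    write_node_meta(conn.meta, d / "nodes.csv")


def read_connectome(directory: str | os.PathLike) -> MultiplexConnectome:
    d = Path(directory)
    return build_multiplex(read_synapse_table(d / "edges.csv"), read_node_meta(d / "nodes.csv"))


def write_adjacency_csv(conn: MultiplexConnectome, layer: str, path: str | os.PathLike) -> None:
    """Dense adjacency of one layer; header row/column carry node ids."""
    pd.DataFrame(conn.layer(layer), index=conn.nodes, columns=conn.nodes).to_csv(path)


def read_adjacency_csv(path: str | os.PathLike) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if list(df.index) != list(df.columns):
        raise ValueError("adjacency CSV row and column ids disagree")
    return list(df.index), df.to_numpy(dtype=np.int64)


def write_graphml(conn: MultiplexConnectome, layer: str, path: str | os.PathLike) -> None:
    import networkx as nx

    nx.write_graphml(conn.to_networkx(layer), path)


def read_skeleton(
    swc_path: str | os.PathLike,
    synapse_path: str | os.PathLike | None = None,
    neuron_id: str | None = None,
) -> SkeletonTree:
    """Read an SWC-like CSV (+ optional synapse CSV) into a SkeletonTree.

    The root is the node whose ``parent_id`` is -1 or empty.
    """
    df = pd.read_csv(swc_path, dtype={"node_id": str})
    parent: dict[str, str | None] = {}
    for row in df.itertuples(index=False):
        p = row.parent_id
        if pd.isna(p) or str(p) in ("-1", "-1.0", ""):
            parent[str(row.node_id)] = None
        else:
            parent[str(row.node_id)] = str(int(p)) if not isinstance(p, str) else str(p)
    pre: dict[str, int] = {}
    post: dict[str, int] = {}
    if synapse_path is not None:
        syn = pd.read_csv(synapse_path, dtype={"node_id": str})
        for row in syn.itertuples(index=False):
            target = pre if row.kind == "pre" else post
            target[str(row.node_id)] = target.get(str(row.node_id), 0) + int(row.count)
    if neuron_id is None:
        neuron_id = Path(swc_path).stem
    return SkeletonTree(neuron_id, parent, pre, post)


def read_pair_map(path: str | os.PathLike, unpaired: Iterable[str] = ()) -> PairMap:
    df = pd.read_csv(path, dtype=str)
    return PairMap(dict(zip(df["left"], df["right"])), set(unpaired))


def write_pair_map(pairs: PairMap, path: str | os.PathLike) -> None:
    pd.DataFrame(pairs.pairs(), columns=["left", "right"]).to_csv(path, index=False)
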