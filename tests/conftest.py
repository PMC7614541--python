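"""Shared fixtures and deterministic hypothesis settings."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from hemiplex.core import NodeMeta, PairMap, SynapseRecord, build_multiplex


def make_connectome(edges, nodes=None, hemis=None):
    """Build a small connectome from (pre, post, type, weight) tuples."""
    site = {"ad": ("axon", "dendrite"), "aa": ("axon", "axon"),
            "dd": ("dendrite", "dendrite"), "da": ("dendrite", "axon")}
    records = [SynapseRecord(u, v, *site[t], w) for u, v, t, w in edges]
    if nodes is None:
        nodes = sorted({u for u, *_ in edges} | {v for _, v, *_ in edges})
    hemis = hemis or {}
    meta = [NodeMeta(v, hemis.get(v, "center")) for v in nodes]
    return build_multiplex(records, meta)


@pytest.fixture
def mirror_connectome():
    """Perfectly mirrored 2-pair toy connectome and its pair map."""
    edges = [
        ("L0", "L1", "ad", 4), ("R0", "R1", "ad", 4),
        ("L1", "L0", "aa", 2), ("R1", "R0", "aa", 2),
        ("L0", "R0", "ad", 3), ("R0", "L0", "ad", 3),
    ]
    hemis = {"L0": "left", "L1": "left", "R0": "right", "R1": "right"}
    conn = make_connectome(edges, hemis=hemis)
    pm = PairMap({"L0": "R0", "L1": "R1"})
    return conn, pm


def random_tree(rng: np.random.Generator, n: int):
    """Random rooted tree as a parent dict over node names '0'..'n-1'."""
    parent = {"0": None}
    for k in range(1, n):
        parent[str(k)] = str(rng.integers(0, k))
    return parent
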