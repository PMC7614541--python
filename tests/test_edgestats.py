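"""Input fractions, bilateral threshold, weights, reciprocity, overlap."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from hemiplex.core import PairMap
from hemiplex.edgestats import (
    OVERLAP_TYPE_ORDER,
    dendritic_input_fractions,
    edge_reciprocity,
    expected_overlap_counts,
    observed_overlap_counts,
    symmetric_threshold,
    weight_distribution,
)

from conftest import make_connectome


def test_input_fractions_normalize_columns():
    conn = make_connectome([("a", "c", "ad", 1), ("b", "c", "ad", 3)])
    f = dendritic_input_fractions(conn)
    i, j, k = conn.index["a"], conn.index["b"], conn.index["c"]
    assert f[i, k] == 0.25 and f[j, k] == 0.75
    assert np.isnan(f[:, i]).all()  # no input to a -> undefined


def test_threshold_mean_rule_half_and_two_percent_passes():
    """An 0.5% edge whose mirror is 2% has mean 1.25% and is kept."""
    hemis = {"L0": "left", "L1": "left", "R0": "right", "R1": "right",
             "Lx": "left", "Rx": "right"}
    edges = [
        ("L0", "L1", "ad", 1), ("Lx", "L1", "ad", 199),   # 0.5% of L1 input
        ("R0", "R1", "ad", 2), ("Rx", "R1", "ad", 98),    # 2% of R1 input
    ]
    conn = make_connectome(edges, hemis=hemis)
    pm = PairMap({"L0": "R0", "L1": "R1", "Lx": "Rx"})
    tg = symmetric_threshold(conn, pm, 0.01)
    assert tg.adjacency[conn.index["L0"], conn.index["L1"]]
    assert tg.adjacency[conn.index["R0"], conn.index["R1"]]
    row = tg.edges.set_index(["pre", "post"]).loc[("L0", "L1")]
    assert row["mean_fraction"] == pytest.approx(0.0125)


def test_threshold_requires_both_hemispheres():
    hemis = {"L0": "left", "L1": "left", "R0": "right", "R1": "right"}
    edges = [("L0", "L1", "ad", 50), ("R1", "R0", "ad", 50)]  # no homolog edge
    conn = make_connectome(edges, hemis=hemis)
    pm = PairMap({"L0": "R0", "L1": "R1"})
    tg = symmetric_threshold(conn, pm, 0.01)
    assert not tg.adjacency.any()


def test_threshold_mean_below_cutoff_drops_both():
    hemis = {"L0": "left", "L1": "left", "R0": "right", "R1": "right",
             "Lx": "left", "Rx": "right"}
    edges = [("L0", "L1", "ad", 1), ("Lx", "L1", "ad", 199),
             ("R0", "R1", "ad", 1), ("Rx", "R1", "ad", 199)]  # 0.5% both sides
    conn = make_connectome(edges, hemis=hemis)
    pm = PairMap({"L0": "R0", "L1": "R1", "Lx": "Rx"})
    tg = symmetric_threshold(conn, pm, 0.01)
    assert not tg.adjacency[conn.index["L0"], conn.index["L1"]]
    assert not tg.adjacency[conn.index["R0"], conn.index["R1"]]


def test_threshold_unpaired_endpoint_judged_alone():
    hemis = {"U0": "left", "L1": "left", "R1": "right"}
    edges = [("U0", "L1", "ad", 5), ("R1", "L1", "ad", 95)]
    conn = make_connectome(edges, hemis=hemis)
    pm = PairMap({"L1": "R1"}, unpaired={"U0"})
    tg = symmetric_threshold(conn, pm, 0.01)
    assert tg.adjacency[conn.index["U0"], conn.index["L1"]]  # 5% alone passes


def test_threshold_degrees_count_partners():
    hemis = {"L0": "left", "L1": "left", "L2": "left",
             "R0": "right", "R1": "right", "R2": "right"}
    edges = [("L0", "L2", "ad", 10), ("R0", "R2", "ad", 10),
             ("L1", "L2", "ad", 10), ("R1", "R2", "ad", 10)]
    conn = make_connectome(edges, hemis=hemis)
    pm = PairMap({"L0": "R0", "L1": "R1", "L2": "R2"})
    tg = symmetric_threshold(conn, pm, 0.01)
    assert tg.in_degree()[conn.index["L2"]] == 2
    assert tg.out_degree()[conn.index["L0"]] == 1


def test_weight_distribution_classes():
    conn = make_connectome([("a", "b", "ad", 1), ("a", "c", "ad", 2),
                            ("b", "c", "ad", 5), ("c", "a", "ad", 10)])
    d = weight_distribution(conn, "ad")
    assert d["n_edges"] == 4
    assert d["weak_edge_fraction"] == 0.5
    assert d["strong_edge_fraction"] == 0.5
    assert d["weak_synapse_share"] == pytest.approx(3 / 18)
    assert d["strong_synapse_share"] == pytest.approx(15 / 18)
    assert np.isnan(weight_distribution(conn, "dd")["weak_edge_fraction"])


def test_reciprocity_hand_example():
    a = np.zeros((3, 3))
    a[0, 1] = a[1, 0] = a[1, 2] = 1  # 3 edges; reversed present for 2 of them
    assert edge_reciprocity(a, a) == pytest.approx(2 / 3)
    assert np.isnan(edge_reciprocity(np.zeros((2, 2)), a[:2, :2]))


def test_reciprocity_cross_layer():
    s = np.zeros((2, 2)); s[0, 1] = 1          # d-a style edge
    t = np.zeros((2, 2)); t[1, 0] = 7          # reverse edge in other layer
    assert edge_reciprocity(s, t) == 1.0
    assert edge_reciprocity(t, s) == 1.0


@given(arrays(np.int8, (6, 6), elements=st.integers(0, 1)),
       arrays(np.int8, (6, 6), elements=st.integers(0, 1)))
def test_reciprocity_matches_double_loop_oracle(s, t):
    n = s.shape[0]
    num = den = 0
    for i in range(n):
        for j in range(n):
            if i != j and s[i, j]:
                den += 1
                num += bool(t[j, i])
    got = edge_reciprocity(s, t)
    if den == 0:
        assert np.isnan(got)
    else:
        assert got == pytest.approx(num / den)


def test_expected_overlap_sums_to_n_squared():
    p = np.array([0.3, 0.1, 0.05, 0.01])
    m = expected_overlap_counts(10, p)
    assert len(m) == 16
    assert sum(m.values()) == pytest.approx(100.0, abs=1e-9)
    # hand value for the all-off pattern
    assert m[(0, 0, 0, 0)] == pytest.approx(100 * 0.7 * 0.9 * 0.95 * 0.99)
    assert m[(1, 1, 1, 1)] == pytest.approx(100 * 0.3 * 0.1 * 0.05 * 0.01)


def test_observed_overlap_partitions_all_pairs():
    conn = make_connectome([("a", "b", "ad", 1), ("a", "b", "aa", 1),
                            ("b", "c", "da", 2)])
    pats = observed_overlap_counts(conn)
    n = conn.n_nodes
    assert sum(p.observed for p in pats) == n * n
    by = {p.pattern: p.observed for p in pats}
    assert OVERLAP_TYPE_ORDER == ("ad", "aa", "da", "dd")
    assert by[(1, 1, 0, 0)] == 1  # a->b carries ad and aa
    assert by[(0, 0, 1, 0)] == 1  # b->c carries da only


def test_overlap_calibration_on_independent_layers():
    """Independently sampled layers match the null expectation within 3 SD."""
    rng = np.random.default_rng(11)
    n = 60
    p = np.array([0.2, 0.1, 0.05, 0.02])
    layers = {}
    for k, t in enumerate(OVERLAP_TYPE_ORDER):
        layers[t] = (rng.random((n, n)) < p[k]).astype(np.int64)
        np.fill_diagonal(layers[t], 0)
    import pandas as pd

    from hemiplex.core import MultiplexConnectome, NodeMeta

    meta = pd.DataFrame([{"node_id": str(i), "hemisphere": "center",
                          "cell_class": "other", "modality": None,
                          "is_input": False, "is_output": False}
                         for i in range(n)]).set_index("node_id")
    conn = MultiplexConnectome([str(i) for i in range(n)], layers, meta)
    for pat in observed_overlap_counts(conn):
        if pat.expected < 5:  # SD test meaningless for near-zero expectation
            continue
        sd = np.sqrt(pat.expected)
        assert abs(pat.observed - pat.expected) <= 3 * sd + 3
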