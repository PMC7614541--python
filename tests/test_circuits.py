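"""Circuit metrics: hubs, orders, local neurons, pathways, motifs."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from hemiplex.circuits import (
    axon_laterality,
    bilateral_partner_similarity,
    contralateral_output_fraction,
    degree_threshold_from_stats,
    enumerate_pathways,
    group_connection_probability,
    homolog_reciprocal_loops,
    hub_classification,
    local_neuron_classification,
    sensory_orders,
    zigzag_motifs,
)
from hemiplex.core import PairMap
from hemiplex.edgestats import ThresholdedGraph


def make_tg(nodes, edges):
    idx = {v: i for i, v in enumerate(nodes)}
    adj = np.zeros((len(nodes), len(nodes)), dtype=bool)
    for u, v in edges:
        adj[idx[u], idx[v]] = True
    return ThresholdedGraph(list(nodes), adj, pd.DataFrame(
        [(u, v) for u, v in edges], columns=["pre", "post"]))


def test_degree_threshold_from_stats():
    d = np.array([0, 10, 20, 30])
    expect = d.mean() + 1.5 * d.std()
    assert degree_threshold_from_stats(d) == pytest.approx(expect)


def test_hub_classification_inclusive_boundary():
    sources = [f"s{i}" for i in range(20)]
    targets = [f"t{i}" for i in range(19)]
    nodes = sources + targets + ["hub"]
    edges = [(s, "hub") for s in sources] + [("hub", t) for t in targets]
    tg = make_tg(nodes, edges)
    cls = hub_classification(tg)
    assert cls.loc["hub", "hub_class"] == "in"       # exactly 20 in, 19 out
    assert cls.loc["s0", "hub_class"] == "none"
    tg2 = make_tg(nodes, edges + [("hub", "s0")])    # 20 out too
    assert hub_classification(tg2).loc["hub", "hub_class"] == "in-out"


def test_sensory_orders_min_rule():
    nodes = ["S", "T", "A", "B"]
    edges = [("S", "A"), ("A", "B"), ("T", "B")]
    tg = make_tg(nodes, edges)
    orders = sensory_orders(tg, {"smell": ["S"], "taste": ["T"]})
    assert orders.loc["S", "smell"] == 1
    assert orders.loc["A", "smell"] == 2
    assert orders.loc["B", "smell"] == 3
    assert orders.loc["B", "taste"] == 2
    assert orders.loc["B", "order"] == 2            # min over modalities
    assert np.isnan(orders.loc["S", "taste"])       # unreachable from taste
    assert np.isnan(orders.loc["T", "order"]) or orders.loc["T", "order"] == 1


def test_local_neuron_classification_hand_cases():
    nodes = ["S", "A", "B", "N", "P", "Q"]
    edges = [("S", "A"), ("S", "B"), ("S", "N"),
             ("A", "P"), ("A", "Q"),            # A: PN to 3rd order
             ("B", "A"),                        # B: type1 (out to own layer)
             ("P", "N"), ("Q", "N"),            # N input from layer 3
             ("N", "P"), ("N", "Q")]            # N output to layer 3
    tg = make_tg(nodes, edges)
    orders = sensory_orders(tg, {"smell": ["S"]})
    out = local_neuron_classification(tg, orders)
    assert out.loc["B", "ln_class"] == "type1 LN"
    assert out.loc["N", "ln_class"] == "type2 LN"
    assert out.loc["A", "ln_class"] == "PN"
    assert out.loc["S", "ln_class"] == "non-LN"


def test_enumerate_pathways_matches_networkx_oracle():
    rng = np.random.default_rng(0)
    for trial in range(10):
        n = 12
        nodes = [str(i) for i in range(n)]
        adj = rng.random((n, n)) < 0.2
        np.fill_diagonal(adj, False)
        edges = [(nodes[i], nodes[j]) for i, j in zip(*np.nonzero(adj))]
        tg = make_tg(nodes, edges)
        sources, targets = ["0", "1"], ["10", "11"]
        paths, total = enumerate_pathways(tg, sources, targets, max_hops=4)
        g = nx.DiGraph(edges)
        g.add_nodes_from(nodes)
        expect = set()
        for s in sources:
            for t in targets:
                for p in nx.all_simple_paths(g, s, t, cutoff=4):
                    # enumerate_pathways stops at the first target reached,
                    # so targets never appear as intermediate nodes
                    if not any(v in targets for v in p[1:-1]):
                        expect.add(tuple(p))
        assert total == len(expect)
        assert {tuple(p) for p in paths} == expect


def test_enumerate_pathways_sampling_cap():
    nodes = ["s", "a", "b", "c", "t"]
    edges = [("s", m) for m in "abc"] + [(m, "t") for m in "abc"]
    tg = make_tg(nodes, edges)
    paths, total = enumerate_pathways(tg, ["s"], ["t"], max_hops=2, sample_cap=2)
    assert total == 3 and len(paths) == 2
    with pytest.raises(ValueError):
        enumerate_pathways(tg, ["s"], ["s"], max_hops=2)


def test_axon_laterality_cutoffs():
    frac = pd.Series({"a": 0.0, "b": 0.2, "c": 0.21, "d": 0.79,
                      "e": 0.8, "f": 1.0, "g": np.nan})
    out = axon_laterality(frac)
    assert out["a"] == out["b"] == "ipsilateral"       # boundary inclusive
    assert out["c"] == out["d"] == "bilateral"
    assert out["e"] == out["f"] == "contralateral"
    assert out["g"] == "unlabeled"
    with pytest.raises(ValueError):
        axon_laterality(pd.Series({"x": 1.5}))


def test_contralateral_output_fraction():
    nodes = ["L0", "L1", "R0"]
    w = np.array([[0, 1, 3], [0, 0, 0], [0, 0, 0]], dtype=float)
    hemi = pd.Series({"L0": "left", "L1": "left", "R0": "right"})
    frac = contralateral_output_fraction(w, nodes, hemi)
    assert frac["L0"] == pytest.approx(0.75)
    assert np.isnan(frac["L1"])  # no output


def test_bilateral_partner_similarity_cosine():
    # L0 projects ipsi to pair0/pair1 targets, contra to pair0/pair2
    nodes = ["L0", "La", "Lb", "Lc", "Ra", "Rb", "Rc", "R0"]
    pm = PairMap({"L0": "R0", "La": "Ra", "Lb": "Rb", "Lc": "Rc"})
    edges = [("L0", "La"), ("L0", "Lb"), ("L0", "Ra"), ("L0", "Rc")]
    tg = make_tg(nodes, edges)
    # ipsi vector over pairs (a,b,c) = (1,1,0); contra = (1,0,1); cos = 0.5
    assert bilateral_partner_similarity(tg, pm, "L0") == pytest.approx(0.5)
    tg2 = make_tg(nodes, [("L0", "La")])
    assert np.isnan(bilateral_partner_similarity(tg2, pm, "L0"))
    with pytest.raises(ValueError):
        bilateral_partner_similarity(make_tg(["U", "La"], [("U", "La")]),
                                     pm, "U")


def test_homolog_reciprocal_loops_grouping():
    pm = PairMap({f"L{i}": f"R{i}" for i in range(4)})
    nodes = [f"{s}{i}" for i in range(4) for s in "LR"]
    base = []
    for i in range(3):  # pair loops on pairs 0, 1, 2; none on 3
        base += [(f"L{i}", f"R{i}"), (f"R{i}", f"L{i}")]
    tg = make_tg(nodes, base)
    out = homolog_reciprocal_loops(tg, pm)
    assert len(out["pair_loops"]) == 3
    assert out["double_loops"] == [] and out["super_loops"] == []
    # link loops 0-1 into a double loop
    tg2 = make_tg(nodes, base + [("L0", "L1")])
    out2 = homolog_reciprocal_loops(tg2, pm)
    assert len(out2["double_loops"]) == 1
    # link 1-2 as well -> super loop of three
    tg3 = make_tg(nodes, base + [("L0", "L1"), ("R1", "R2")])
    out3 = homolog_reciprocal_loops(tg3, pm)
    assert len(out3["super_loops"]) == 1
    assert len(out3["super_loops"][0]) == 3


def test_group_connection_probability():
    nodes = ["a1", "a2", "b1", "b2"]
    edges = [("a1", "b1"), ("a1", "b2"), ("a1", "a2")]
    tg = make_tg(nodes, edges)
    groups = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
    out = group_connection_probability(tg, groups)
    assert out.loc["A", "B"] == pytest.approx(0.5)   # 2 of 4
    assert out.loc["A", "A"] == pytest.approx(0.5)   # 1 of 2 (self-pairs excluded)
    assert out.loc["B", "A"] == 0.0


def test_zigzag_motifs_base_and_reciprocal():
    nodes = ["D1", "D2", "A1", "X"]
    edges = [("D1", "A1"), ("A1", "D2"),     # zigzag
             ("A1", "D1")]                    # makes D1<->A1 reciprocal
    tg = make_tg(nodes, edges)
    out = zigzag_motifs(tg, ["D1", "D2"], ["A1"], max_intermediate=1)
    assert [m.nodes for m in out["zigzags"]] == [("D1", "A1", "D2")]
    assert [m.nodes for m in out["reciprocal_loops"]] == [("D1", "A1")]


def test_zigzag_motifs_extended_legs():
    nodes = ["D1", "D2", "A1", "X"]
    edges = [("D1", "X"), ("X", "A1"), ("A1", "D2")]
    tg = make_tg(nodes, edges)
    short = zigzag_motifs(tg, ["D1", "D2"], ["A1"], max_intermediate=1)
    assert short["zigzags"] == []             # no budget for the intermediate
    ext = zigzag_motifs(tg, ["D1", "D2"], ["A1"], max_intermediate=2)
    assert [m.nodes for m in ext["zigzags"]] == [("D1", "X", "A1", "D2")]
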