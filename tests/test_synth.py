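"""Synthetic connectome generator: determinism, symmetry, planted truth."""

import numpy as np
import pytest

from hemiplex.core import EDGE_TYPES
from hemiplex.synth import GeneratorConfig, generate_connectome


def plain_config(**kw):
    """SBM-only config: no planted structures, no unpaired nodes."""
    base = dict(n_pairs=200, n_unpaired=0, n_blocks=4, mirror_noise=0.0,
                n_hubs=0, n_recurrent_loops=0, n_pair_loops=0, n_zigzag=0, seed=0)
    base.update(kw)
    return GeneratorConfig(**base)


def test_determinism():
    cfg = GeneratorConfig(n_pairs=40, n_unpaired=4, hub_degree=10, seed=3)
    c1, t1 = generate_connectome(cfg)
    c2, t2 = generate_connectome(GeneratorConfig(n_pairs=40, n_unpaired=4,
                                                 hub_degree=10, seed=3))
    assert c1.nodes == c2.nodes
    for t in EDGE_TYPES:
        np.testing.assert_array_equal(c1.layer(t), c2.layer(t))
    assert t1.hubs == t2.hubs and t1.zigzags == t2.zigzags


def test_seed_changes_output():
    c1, _ = generate_connectome(plain_config(seed=0))
    c2, _ = generate_connectome(plain_config(seed=1))
    assert any((c1.layer(t) != c2.layer(t)).any() for t in EDGE_TYPES)


def test_mirror_symmetry_at_zero_noise():
    """Swapping every node for its homolog is a weight-preserving automorphism."""
    cfg = GeneratorConfig(n_pairs=60, n_unpaired=0, mirror_noise=0.0,
                          hub_degree=10, seed=5)
    conn, truth = generate_connectome(cfg)
    pm = truth.pair_map
    swap = np.array([conn.index[pm.partner(v)] for v in conn.nodes])
    for t in EDGE_TYPES:
        a = conn.layer(t)
        np.testing.assert_array_equal(a, a[np.ix_(swap, swap)])


def test_mirror_noise_breaks_some_edges():
    conn, truth = generate_connectome(
        GeneratorConfig(n_pairs=100, n_unpaired=0, mirror_noise=0.3,
                        n_hubs=0, n_recurrent_loops=0, n_pair_loops=0,
                        n_zigzag=0, seed=2))
    pm = truth.pair_map
    swap = np.array([conn.index[pm.partner(v)] for v in conn.nodes])
    a = conn.layer("ad")
    assert ((a > 0) != (a[np.ix_(swap, swap)] > 0)).sum() > 0


def test_planted_hubs_have_high_in_degree():
    cfg = GeneratorConfig(n_pairs=80, n_unpaired=0, hub_degree=15, n_hubs=2, seed=1)
    conn, truth = generate_connectome(cfg)
    indeg = (conn.layer("ad") > 0).sum(axis=0)
    for h in truth.hubs:
        assert indeg[conn.index[h]] >= 15


def test_planted_loops_and_zigzags_present():
    cfg = GeneratorConfig(n_pairs=80, n_unpaired=0, hub_degree=10, seed=4)
    conn, truth = generate_connectome(cfg)
    a = conn.layer("ad")
    idx = conn.index
    for k in range(0, len(truth.recurrent_nodes), 2):
        u, v = truth.recurrent_nodes[k], truth.recurrent_nodes[k + 1]
        assert a[idx[u], idx[v]] >= cfg.planted_weight
        assert a[idx[v], idx[u]] >= cfg.planted_weight
    for l, r in truth.pair_loops:
        assert a[idx[l], idx[r]] >= cfg.planted_weight
        assert a[idx[r], idx[l]] >= cfg.planted_weight
    for d1, an, d2 in truth.zigzags:
        assert d1 != d2
        assert a[idx[d1], idx[an]] >= cfg.planted_weight
        assert a[idx[an], idx[d2]] >= cfg.planted_weight


def test_type_counts_match_layers():
    conn, truth = generate_connectome(plain_config(n_unpaired=6))
    for t in EDGE_TYPES:
        assert truth.type_counts[t] == int(conn.layer(t).sum())


def test_axon_laterality_routing():
    """Contralateral axons project only cross-hemisphere on axonal layers."""
    conn, truth = generate_connectome(plain_config(seed=6))
    hemi = conn.meta["hemisphere"]
    for t in ("ad", "aa"):
        a = conn.layer(t)
        for i, u in enumerate(conn.nodes):
            targets = [conn.nodes[j] for j in np.nonzero(a[i])[0]]
            if not targets:
                continue
            cross = [v for v in targets if hemi[v] != hemi[u]]
            if truth.laterality[u] == "contralateral":
                assert len(cross) == len(targets)
            elif truth.laterality[u] == "ipsilateral":
                assert not cross
    # dendritic layers ignore axon laterality: all edges ipsilateral
    for t in ("dd", "da"):
        a = conn.layer(t)
        for i, j in zip(*np.nonzero(a)):
            assert hemi[conn.nodes[i]] == hemi[conn.nodes[j]]


def test_density_matches_analytic_expectation():
    """Non-axonal layer density lands within 4 SD of the nominal target."""
    cfg = plain_config(n_pairs=400, seed=8)
    conn, _ = generate_connectome(cfg)
    n = cfg.n_pairs
    for t in ("dd", "da"):
        p = cfg.layer_densities[t]
        observed = int((conn.layer(t)[:n, :n][np.ix_(range(n), range(n))] > 0).sum())
        # left-left block has n^2 - n off-diagonal slots sampled at p
        trials = n * n - n
        sd = np.sqrt(trials * p * (1 - p))
        assert abs(observed - trials * p) <= 4 * sd


def test_weak_edge_fraction_calibration():
    cfg = plain_config(n_pairs=300, seed=9)
    conn, _ = generate_connectome(cfg)
    w = conn.layer("dd")[conn.layer("dd") > 0]  # dd: no rerouting collisions
    assert abs(float((w <= 2).mean()) - cfg.weak_edge_fraction) < 0.05


def test_synapse_share_ordering():
    conn, truth = generate_connectome(GeneratorConfig(seed=0))
    counts = truth.type_counts
    assert counts["ad"] > counts["aa"] > counts["dd"] > counts["da"]


def test_infeasible_configs_raise():
    with pytest.raises(ValueError):
        GeneratorConfig(n_pairs=4, n_blocks=8)
    with pytest.raises(ValueError):
        GeneratorConfig(mirror_noise=1.5)
    with pytest.raises(ValueError):
        GeneratorConfig(axon_side_probs=(0.5, 0.5, 0.5))
    with pytest.raises(ValueError):
        generate_connectome(GeneratorConfig(n_pairs=10, n_blocks=8, n_hubs=8,
                                            hub_degree=3))


def test_geometric_p_closed_form():
    cfg = GeneratorConfig(weak_edge_fraction=0.66)
    p = cfg.geometric_p
    assert abs((1 - (1 - p) ** 2) - 0.66) < 1e-12
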