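"""Joint left-right spectral embedding and recursive GMM clustering.

To cluster neurons so that left/right homologs land in the same cluster,
the connectome is split into four hemisphere subgraphs indexed by homolog
pair (LL, RR, LR, RL), each regularized by pass-to-ranks and embedded with
the adjacency spectral embedding (ASE).  The right-hemisphere embeddings
are aligned to the left with an orthogonal Procrustes transform (removing
ASE's orthogonal non-identifiability), the ipsilateral and contralateral
in/out positions are concatenated per node, reduced by a second SVD, and
the left and right rows of each pair are averaged.  The pair embedding is
then clustered by recursively splitting with 1- vs 2-component Gaussian
mixtures under BIC, down to a maximum depth with a minimum split size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import orthogonal_procrustes
from scipy.stats import rankdata
from sklearn.mixture import GaussianMixture

from .core import MultiplexConnectome, PairMap

__all__ = [
    "split_hemisphere_subgraphs", "pass_to_ranks", "adjacency_spectral_embedding",
    "align_embeddings", "joint_embedding", "JointEmbedding",
    "recursive_gmm_cluster", "ClusterTree", "cluster_morphology_score",
]


def split_hemisphere_subgraphs(
    conn: MultiplexConnectome, pairs: PairMap, layer: str | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Extract the LL, RR, LR and RL adjacencies, indexed by homolog pair.

    Row/column k of every returned matrix corresponds to the k-th pair in
    ``pairs.pairs()`` (LL and LR use the left member as source, RR and RL
    the right member).  Unpaired nodes are not represented.  Uses the
    summed graph when ``layer`` is None.
    """
    missing = [v for v in conn.nodes
               if pairs.is_paired(v) and conn.meta.loc[v, "hemisphere"] not in ("left", "right")]
    if missing:
        raise ValueError(f"paired nodes without hemisphere assignment: {missing[:10]}")
    a = conn.summed() if layer is None else conn.layer(layer)
    pr = pairs.pairs()
    li = np.array([conn.index[l] for l, _ in pr])
    ri = np.array([conn.index[r] for _, r in pr])
    ll = a[np.ix_(li, li)]
    rr = a[np.ix_(ri, ri)]
    lr = a[np.ix_(li, ri)]
    rl = a[np.ix_(ri, li)]
    return ll, rr, lr, rl


def pass_to_ranks(adjacency: np.ndarray) -> np.ndarray:
    """Replace nonzero weights by their average-tie ranks scaled into (0, 1].

    Zeros stay zero; the transformation is order-preserving, which makes
    spectral embeddings robust to heavy-tailed weight distributions.
    """
    a = np.asarray(adjacency, dtype=float)
    if (a < 0).any():
        raise ValueError("pass-to-ranks expects nonnegative weights")
    out = np.zeros_like(a)
    nz = a > 0
    if nz.any():
        ranks = rankdata(a[nz], method="average")
        out[nz] = ranks / nz.sum()
    return out


def adjacency_spectral_embedding(
    adjacency: np.ndarray, d: int, augment_diagonal: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Rank-d spectral positions (out, in) from a truncated SVD.

    Out-positions are the top-d left singular vectors and in-positions the
    right singular vectors, each scaled by the square root of the singular
    values, so that ``X_out @ X_in.T`` is the best rank-d approximation of
    the adjacency.  The diagonal is augmented with degree / n, a standard
    stabilization for sparse graphs.  ``d`` is reduced with a warning when
    it exceeds the matrix rank.
    """
    a = np.asarray(adjacency, dtype=float).copy()
    n = a.shape[0]
    if d > n:
        raise ValueError(f"embedding dimension {d} exceeds node count {n}")
    if augment_diagonal:
        deg = (a.sum(axis=1) + a.sum(axis=0)) / 2.0
        np.fill_diagonal(a, deg / max(n, 1))
    u, s, vt = np.linalg.svd(a, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if s.size and s[0] > 0 else 0
    if d > rank:
        import warnings

        warnings.warn(f"requested dimension {d} exceeds rank {rank}; reducing")
        d = max(rank, 1)
    scale = np.sqrt(s[:d])
    return u[:, :d] * scale, vt[:d].T * scale


def align_embeddings(
    x: np.ndarray, y: np.ndarray, seed_idx: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Orthogonal transform Q minimizing ||x_seeds - y_seeds Q||.

    Returns (y @ Q, Q).  ``seed_idx`` selects the rows with known
    correspondence (all rows by default).  When fewer seed rows than
    dimensions are available the Procrustes problem is underdetermined; a
    warning is issued and the available rows are used anyway.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape[1] != y.shape[1]:
        raise ValueError("embeddings must share dimension")
    if seed_idx is None:
        xs, ys = x, y
    else:
        xs, ys = x[seed_idx], y[seed_idx]
    if xs.shape[0] < x.shape[1]:
        import warnings

        warnings.warn("fewer seed rows than embedding dimensions; alignment may be loose")
    q, _ = orthogonal_procrustes(ys, xs)
    return y @ q, q


@dataclass
class JointEmbedding:
    """One latent position per homolog pair (left/right averaged)."""

    pairs: list[tuple[str, str]]
    positions: np.ndarray  # (n_pairs, d2)
    d1: int
    d2: int
    left_positions: np.ndarray | None = None
    right_positions: np.ndarray | None = None


def joint_embedding(
    conn: MultiplexConnectome,
    pairs: PairMap,
    d1: int = 24,
    d2: int = 10,
    layer: str | None = None,
) -> JointEmbedding:
    """Embed homolog pairs into a shared space across hemispheres.

    Each hemisphere subgraph (pass-to-ranks regularized) is embedded with
    ASE at dimension ``d1``; RR is Procrustes-aligned to LL and RL to LR;
    per node the ipsilateral and contralateral out/in positions are
    concatenated, reduced to ``d2`` by SVD, and the two homologs' rows are
    averaged.
    """
    ll, rr, lr, rl = split_hemisphere_subgraphs(conn, pairs, layer)
    embeds = {}
    for name, a in (("ll", ll), ("rr", rr), ("lr", lr), ("rl", rl)):
        embeds[name] = adjacency_spectral_embedding(pass_to_ranks(a), d1)
    # one transform per subgraph pairing, shared by out and in positions
    # (stacking out/in keeps the low-rank factorization consistent)
    for moving, fixed in (("rr", "ll"), ("rl", "lr")):
        yo, yi = embeds[moving]
        xo, xi = embeds[fixed]
        _, q = align_embeddings(np.vstack([xo, xi]), np.vstack([yo, yi]))
        embeds[moving] = (yo @ q, yi @ q)

    left_rep = np.hstack([embeds["ll"][0], embeds["ll"][1], embeds["lr"][0], embeds["lr"][1]])
    right_rep = np.hstack([embeds["rr"][0], embeds["rr"][1], embeds["rl"][0], embeds["rl"][1]])
    stacked = np.vstack([left_rep, right_rep])
    u, s, _ = np.linalg.svd(stacked, full_matrices=False)
    k = min(d2, s.size)
    proj = u[:, :k] * s[:k]
    n = left_rep.shape[0]
    left_pos, right_pos = proj[:n], proj[n:]
    return JointEmbedding(pairs.pairs(), (left_pos + right_pos) / 2.0, d1, k, left_pos, right_pos)


@dataclass
class ClusterTree:
    """Nested partition of homolog pairs.

    ``labels`` holds the label path of every pair at each level: the label
    at level k is a tuple of 0/1 split decisions of length <= k.  Leaves of
    the deepest level define the finest clustering.
    """

    pairs: list[tuple[str, str]]
    paths: list[tuple[int, ...]]
    max_depth: int
    min_size: int
    splits: list[dict] = field(default_factory=list)  # per internal node: size, BICs

    def labels_at(self, depth: int) -> list[tuple[int, ...]]:
        return [p[:depth] for p in self.paths]

    def flat_labels(self, depth: int | None = None) -> np.ndarray:
        """Integer leaf labels at the requested depth (deepest by default)."""
        depth = self.max_depth if depth is None else depth
        paths = self.labels_at(depth)
        uniq = {p: i for i, p in enumerate(sorted(set(paths)))}
        return np.array([uniq[p] for p in paths])

    def n_leaves(self, depth: int | None = None) -> int:
        return len(set(self.labels_at(self.max_depth if depth is None else depth)))


def recursive_gmm_cluster(
    embedding: JointEmbedding | np.ndarray,
    max_depth: int = 8,
    min_size: int = 32,
    seed: int = 0,
    n_init: int = 5,
    bic_tol: float = 1e-6,
) -> ClusterTree:
    """Recursively split with 1- vs 2-component Gaussian mixtures under BIC.

    At each node of the tree, full-covariance GMMs with one and two
    components are fit; the node is split only when BIC prefers two
    components and the node holds at least ``min_size`` points.  Recursion
    stops at ``max_depth``.  BIC ties (within ``bic_tol``) resolve to no
    split.  Deterministic for a fixed seed.
    """
    if isinstance(embedding, JointEmbedding):
        x = embedding.positions
        pairs = embedding.pairs
    else:
        x = np.asarray(embedding, float)
        pairs = [(str(i), str(i)) for i in range(x.shape[0])]
    if not np.isfinite(x).all():
        raise ValueError("embedding contains non-finite values")

    paths: list[list[int]] = [[] for _ in range(x.shape[0])]
    splits: list[dict] = []

    def recurse(idx: np.ndarray, depth: int) -> None:
        if depth >= max_depth or idx.size < min_size:
            return
        sub = x[idx]
        reg = 1e-6
        fits = {}
        for k in (1, 2):
            gm = GaussianMixture(n_components=k, covariance_type="full",
                                 n_init=n_init, reg_covar=reg, random_state=seed)
            gm.fit(sub)
            fits[k] = gm
        bic1, bic2 = fits[1].bic(sub), fits[2].bic(sub)
        splits.append({"size": int(idx.size), "depth": depth, "bic1": float(bic1),
                       "bic2": float(bic2), "split": bool(bic2 < bic1 - bic_tol)})
        if not (bic2 < bic1 - bic_tol):
            return
        lab = fits[2].predict(sub)
        # deterministic child naming: component containing the lowest index first
        first = lab[0]
        lab = np.where(lab == first, 0, 1)
        if (lab == 0).all() or (lab == 1).all():
            return
        for i, l in zip(idx, lab):
            paths[i].append(int(l))
        recurse(idx[lab == 0], depth + 1)
        recurse(idx[lab == 1], depth + 1)

    recurse(np.arange(x.shape[0]), 0)
    tree = ClusterTree(pairs, [tuple(p) for p in paths], max_depth, min_size, splits)
    return tree


def cluster_morphology_score(
    similarity: np.ndarray,
    clusters: list[list[int]],
    similarity_right: np.ndarray | None = None,
    clusters_right: list[list[int]] | None = None,
) -> list[float]:
    """Within-cluster morphological coherence from a similarity matrix.

    The (externally computed) pairwise similarity matrix of one hemisphere
    is symmetrized by the geometric mean of (i, j) and (j, i), converted to
    pairwise ranks scaled to [0, 1], and each cluster scored by the mean of
    its within-cluster values.  When the second hemisphere's matrix and
    clusters are given, the final score is the mean of the left and right
    scores.  Chance level is 0.5.
    """
    def hemisphere_scores(sim: np.ndarray, cls: list[list[int]]) -> list[float]:
        s = np.asarray(sim, float)
        if (s < 0).any():
            raise ValueError("similarities must be nonnegative for the geometric mean")
        sym = np.sqrt(s * s.T)
        iu = np.triu_indices_from(sym, k=1)
        vals = sym[iu]
        ranks = rankdata(vals, method="average")
        norm = np.zeros_like(sym)
        norm[iu] = (ranks - 1) / max(len(ranks) - 1, 1)
        norm = norm + norm.T
        out = []
        for members in cls:
            m = np.asarray(members)
            if m.size < 2:
                out.append(float("nan"))
                continue
            block = norm[np.ix_(m, m)]
            out.append(float(block[np.triu_indices(m.size, k=1)].mean()))
        return out

    left = hemisphere_scores(similarity, clusters)
    if similarity_right is None:
        return left
    right = hemisphere_scores(similarity_right, clusters_right or clusters)
    return [float(np.nanmean([l, r])) for l, r in zip(left, right)]
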