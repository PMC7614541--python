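"""Seeded FAQ graph matching between hemispheres and its evaluation.

Homolog pairs are predicted by aligning the left and right ipsilateral
adjacency matrices: find the permutation P maximizing
``trace(A_left P A_right^T P^T)`` (equivalently minimizing the norm of the
difference of the permuted adjacencies).  The Fast Approximate Quadratic
(FAQ) relaxation optimizes over doubly stochastic matrices with
Frank-Wolfe ascent, clamping any known seed pairs, and projects the final
iterate to a permutation by linear assignment.  Many randomly initialized
runs are combined into a consensus doubly stochastic matrix weighted by
each run's objective value, and assigned pairs are scored by the rank of
the true partner within each row of the consensus (*neighbor rank*).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import rankdata

__all__ = ["MatchRun", "ConsensusMatch", "seeded_graph_match", "match_consensus", "neighbor_ranks"]


@dataclass
class MatchRun:
    """Result of one FAQ run: permutation, objective and relaxed iterate."""

    permutation: np.ndarray          # perm[i] = matched right index of left node i
    objective: float                 # matched-edge agreement of the projected permutation
    doubly_stochastic: np.ndarray    # final Frank-Wolfe iterate (full n x n)


@dataclass
class ConsensusMatch:
    """Objective-weighted average of run solutions."""

    matrix: np.ndarray               # doubly stochastic consensus D
    vote_counts: np.ndarray          # (n, n) how often each assignment occurred
    runs: list[MatchRun]

    def ranked_candidates(self, left_index: int) -> np.ndarray:
        """Right-node indices sorted by descending consensus strength."""
        return np.argsort(-self.matrix[left_index], kind="stable")


def _objective(a: np.ndarray, b: np.ndarray, perm: np.ndarray) -> float:
    return float(np.sum(a * b[np.ix_(perm, perm)]))


def seeded_graph_match(
    a_left: np.ndarray,
    a_right: np.ndarray,
    seeds: list[tuple[int, int]] | None = None,
    n_init: int = 50,
    max_iter: int = 30,
    seed: int = 0,
    tol: float = 1e-6,
) -> list[MatchRun]:
    """Run seeded FAQ ``n_init`` times with random initializations.

    ``seeds`` are (left index, right index) pairs whose assignment is held
    fixed.  Unequal node counts are padded with isolated dummy nodes (the
    returned permutations cover the padded size; callers strip dummies).
    Each run starts from a random convex combination of the barycenter and
    a random permutation on the non-seed block and ascends the relaxed
    quadratic objective with exact-line-search Frank-Wolfe.
    """
    a = np.asarray(a_left, float)
    b = np.asarray(a_right, float)
    n = max(a.shape[0], b.shape[0])
    if a.shape[0] < n or b.shape[0] < n:
        a = np.pad(a, ((0, n - a.shape[0]),) * 2)
        b = np.pad(b, ((0, n - b.shape[0]),) * 2)
    seeds = list(seeds or [])
    if seeds:
        ls, rs = zip(*seeds)
        if len(set(ls)) != len(ls) or len(set(rs)) != len(rs):
            raise ValueError("seed endpoints must be distinct")

    # reorder so that seeds occupy the leading block
    ls = [l for l, _ in seeds]
    rs = [r for _, r in seeds]
    free_l = [i for i in range(n) if i not in set(ls)]
    free_r = [i for i in range(n) if i not in set(rs)]
    perm_l = np.array(ls + free_l, dtype=int)
    perm_r = np.array(rs + free_r, dtype=int)
    inv_l = np.argsort(perm_l)
    ap = a[np.ix_(perm_l, perm_l)]
    bp = b[np.ix_(perm_r, perm_r)]
    s = len(seeds)
    m = n - s
    a12, a21, a22 = ap[:s, s:], ap[s:, :s], ap[s:, s:]
    b12, b21, b22 = bp[:s, s:], bp[s:, :s], bp[s:, s:]

    const_grad = a21 @ b21.T + a12.T @ b12

    rng = np.random.default_rng(seed)
    runs: list[MatchRun] = []
    for _ in range(max(n_init, 1)):
        if m == 0:
            d = np.zeros((0, 0))
        else:
            gamma = rng.uniform(0.0, 1.0)
            p_rand = np.eye(m)[rng.permutation(m)]
            d = (1 - gamma) * np.full((m, m), 1.0 / m) + gamma * p_rand
        for _ in range(max_iter if m else 0):
            grad = const_grad + a22 @ d @ b22.T + a22.T @ d @ b22
            ri, ci = linear_sum_assignment(-grad)
            q = np.zeros((m, m))
            q[ri, ci] = 1.0
            r = q - d
            # exact line search on the quadratic f(d + alpha r)
            qa = float(np.sum((a22 @ r) * (r @ b22.T)))
            qb = float(np.sum(const_grad * r)
                       + np.sum((a22 @ d) * (r @ b22.T)) + np.sum((a22 @ r) * (d @ b22.T)))
            if qa < 0:
                alpha = float(np.clip(-qb / (2 * qa), 0.0, 1.0))
            else:
                alpha = 1.0 if qa + qb > 0 else 0.0
            step = alpha * r
            d = d + step
            if np.abs(step).max() < tol:
                break
        # project to a permutation on the free block
        if m:
            ri, ci = linear_sum_assignment(-d)
            free_perm = ci
        else:
            free_perm = np.zeros(0, dtype=int)
        full = np.empty(n, dtype=int)
        full[perm_l[:s]] = perm_r[:s]
        full[perm_l[s:]] = perm_r[s + free_perm] if m else perm_r[s:]
        ds_full = np.zeros((n, n))
        ds_full[np.ix_(perm_l[:s], perm_r[:s])] = np.eye(s)
        if m:
            ds_full[np.ix_(perm_l[s:], perm_r[s:])] = d
        runs.append(MatchRun(full, _objective(a, b, full), ds_full))
    return runs


def match_consensus(runs: list[MatchRun]) -> ConsensusMatch:
    """Objective-weighted average D = (1/S) sum_k s_k D^k of run iterates.

    Falls back to an unweighted average (with a warning) when all
    objectives are zero.  Vote counts record, per (left, right) cell, how
    many runs' projected permutations contained that assignment.
    """
    if not runs:
        raise ValueError("need at least one run")
    n = runs[0].doubly_stochastic.shape[0]
    s_total = sum(r.objective for r in runs)
    d = np.zeros((n, n))
    votes = np.zeros((n, n))
    for r in runs:
        w = r.objective / s_total if s_total > 0 else 1.0 / len(runs)
        d += w * r.doubly_stochastic
        votes[np.arange(n), r.permutation] += 1
    if s_total <= 0:
        import warnings

        warnings.warn("all run objectives are zero; using unweighted average")
    return ConsensusMatch(d, votes, runs)


def neighbor_ranks(consensus: np.ndarray | ConsensusMatch, true_pairs: list[tuple[int, int]]) -> np.ndarray:
    """Rank of each true partner within its consensus row (1 = strongest).

    Ties get the average rank, so a partner tied for first among two
    candidates ranks 1.5.
    """
    d = consensus.matrix if isinstance(consensus, ConsensusMatch) else np.asarray(consensus, float)
    out = np.empty(len(true_pairs))
    for k, (i, j) in enumerate(true_pairs):
        ranks = rankdata(-d[i], method="average")
        out[k] = ranks[j]
    return out
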