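"""Independent brute-force oracles used only by the test suite.

These deliberately share no code with the implementation: alignment scores by
exhaustive enumeration / straightforward Gotoh DP, distances by direct column
counting, and additive trees built by explicit random joins.
"""

from __future__ import annotations

import math

import numpy as np


def brute_global_score(a, b, match, mismatch, gap_open, gap_extend):
    """Optimal global affine score by exhaustive enumeration of alignments.

    Gap model: first gap character costs gap_open, each further one gap_extend.
    Intended for tiny strings only.
    """
    best = [-(10**9)]

    def rec(i, j, last, score):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            s = match if (a[i] == b[j] and a[i] in "ACGT") else mismatch
            rec(i + 1, j + 1, "M", score + s)
        if i < len(a):
            rec(i + 1, j, "X", score + (gap_extend if last == "X" else gap_open))
        if j < len(b):
            rec(i, j + 1, "Y", score + (gap_extend if last == "Y" else gap_open))

    rec(0, 0, "M", 0)
    return best[0]


def sw_affine_score(query, target, matrix, gap_open, gap_extend):
    """Smith-Waterman (Gotoh) local score with an affine gap model."""
    n, m = len(query), len(target)
    NEG = -1e9
    M = np.zeros((n + 1, m + 1))
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    best = 0.0
    for i in range(1, n + 1):
        qi = query[i - 1]
        for j in range(1, m + 1):
            s = matrix[qi, target[j - 1]]
            M[i, j] = max(0.0, M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + gap_open, X[i - 1, j] + gap_extend)
            Y[i, j] = max(M[i, j - 1] + gap_open, Y[i, j - 1] + gap_extend)
            if M[i, j] > best:
                best = M[i, j]
    return best


def k2p_by_counting(gapped_a, gapped_b):
    """(P, Q, sites, K2P, JC) by direct column counting and the closed forms."""
    ts = tv = sites = 0
    pur = set("AG")
    for x, y in zip(gapped_a, gapped_b):
        if x not in "ACGT" or y not in "ACGT":
            continue
        sites += 1
        if x == y:
            continue
        if (x in pur) == (y in pur):
            ts += 1
        else:
            tv += 1
    P, Q = ts / sites, tv / sites
    k = -0.5 * math.log((1 - 2 * P - Q) * math.sqrt(1 - 2 * Q))
    p = P + Q
    jc = -0.75 * math.log(1 - 4 * p / 3)
    return P, Q, sites, k, jc


def random_additive_tree(rng, n_leaves):
    """Random binary tree with integer branch lengths >= 1.

    Pairwise leaf distances are recorded as subtrees are joined (a pair's path
    is final the moment their subtrees merge). Returns
    (labels, distance matrix as numpy array, set of non-trivial bipartitions
    as frozensets of the two frozenset sides).
    """
    labels = [f"L{i:02d}" for i in range(n_leaves)]
    dist = {a: {} for a in labels}
    # each subtree: (leafset, {leaf: distance to subtree root})
    subtrees = [({lab}, {lab: 0.0}) for lab in labels]
    clades = []

    def join(li, lj, bi, bj):
        for a, da_ in li[1].items():
            for b, db_ in lj[1].items():
                d = da_ + bi + db_ + bj
                dist[a][b] = d
                dist[b][a] = d
        return (
            li[0] | lj[0],
            {**{k: v + bi for k, v in li[1].items()},
             **{k: v + bj for k, v in lj[1].items()}},
        )

    while len(subtrees) > 2:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        lj = subtrees.pop(int(j))
        li = subtrees.pop(int(i))
        clades.append(frozenset(li[0]))
        clades.append(frozenset(lj[0]))
        merged = join(li, lj, int(rng.integers(1, 10)), int(rng.integers(1, 10)))
        subtrees.append(merged)
    (sa, da), (sb, db) = subtrees
    edge = int(rng.integers(1, 10))
    clades.append(frozenset(sa))
    for a, da_ in da.items():
        for b, db_ in db.items():
            d = da_ + edge + db_
            dist[a][b] = d
            dist[b][a] = d

    mat = np.zeros((n_leaves, n_leaves))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i != j:
                mat[i, j] = dist[a][b]
    full = frozenset(labels)
    bps = set()
    for clade in clades:
        if 1 < len(clade) < n_leaves - 1:
            bps.add(frozenset((clade, full - clade)))
    return labels, mat, bps
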