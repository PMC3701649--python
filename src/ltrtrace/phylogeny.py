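"""RT-domain extraction and bootstrap neighbor-joining trees.

The reverse-transcriptase (RT) domain is the most conserved part of a Copia
retrotransposon's pol gene; a translated search of a conserved RT protein
query against element internal regions (six reading frames, Smith-Waterman
with BLOSUM62) locates it and back-projects the aligned span to nucleotides.
Trees are built from K2P distances by canonical Saitou-Nei neighbor joining,
with per-edge bootstrap support from column resampling of a star alignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .errors import DegenerateSequenceError, InsufficientDataError
from .seqcore import (
    AlignParams,
    DNA_BASES,
    PROTEIN_ALIGN_DEFAULTS,
    k2p_from_counts,
    local_align_protein,
    reverse_complement,
    six_frame_translate,
    star_align,
)

#: distance assigned to saturated pairs in bootstrap replicates
SATURATION_CAP = 10.0


@dataclass
class RtDomainHit:
    element_id: str
    cdna: str
    frame: int
    score: float
    span: tuple[int, int]  # 0-based half-open, original coordinates


def extract_rt_domain(
    internal_seq: str,
    rt_query: str,
    min_score: float = 55.0,
    element_id: str = "",
    params: AlignParams | None = None,
) -> Optional[RtDomainHit]:
    """Best six-frame local protein alignment of the RT query; None when no
    frame reaches ``min_score`` (the element lacks a recognizable rt gene)."""
    if len(internal_seq) < 300:
        raise DegenerateSequenceError("internal region must be >= 300 bp")
    params = params or PROTEIN_ALIGN_DEFAULTS
    frames = six_frame_translate(internal_seq)
    best = None
    for frame in (1, 2, 3, -1, -2, -3):
        aa = frames[frame]
        if not aa:
            continue
        hit = local_align_protein(rt_query, aa, params)
        if best is None or hit.score > best[1].score:
            best = (frame, hit)
    if best is None or best[1].score < min_score:
        return None
    frame, hit = best
    t0, t1 = hit.target_span
    off = abs(frame) - 1
    n = len(internal_seq)
    if frame > 0:
        span = (off + 3 * t0, off + 3 * t1)
        cdna = internal_seq[span[0] : span[1]]
    else:
        rc_span = (off + 3 * t0, off + 3 * t1)
        span = (n - rc_span[1], n - rc_span[0])
        cdna = reverse_complement(internal_seq[span[0] : span[1]])
    return RtDomainHit(element_id=element_id, cdna=cdna, frame=frame, score=hit.score, span=span)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


def build_distance_matrix(labels: list[str], matrix) -> DistanceMatrix:
    """Validated symmetric distance matrix (zero diagonal, finite entries)."""
    arr = np.asarray(matrix, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("distance matrix contains non-finite entries")
    return DistanceMatrix(arr, ids=list(labels))


def build_nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Canonical Saitou-Nei neighbor joining.

    Ties in the Q criterion break deterministically on the first pair in id
    order; negative branch-length estimates are clamped to zero. Returns an
    unrooted tree represented with a trifurcating root.
    """
    labels = list(dm.ids)
    n = len(labels)
    if n < 3:
        raise InsufficientDataError("NJ requires >= 3 taxa")
    nodes = [TreeNode(name=lab) for lab in labels]
    d = {i: {} for i in range(n)}
    arr = dm.data
    for i in range(n):
        for j in range(n):
            d[i][j] = float(arr[i, j])
    active = list(range(n))
    next_id = n

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i][j] for j in active if j != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d[i][j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        vi = 0.5 * d[i][j] + (r[i] - r[j]) / (2.0 * (m - 2))
        vj = d[i][j] - vi
        ni, nj = nodes[i], nodes[j]
        ni.length = max(0.0, vi)
        nj.length = max(0.0, vj)
        parent = TreeNode(children=[ni, nj])
        nodes.append(parent)
        u = next_id
        next_id += 1
        d[u] = {}
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (d[i][k] + d[j][k] - d[i][j])
            d[u][k] = duk
            d[k][u] = duk
        d[u][u] = 0.0
        active = [k for k in active if k not in (i, j)] + [u]

    i, j, k = active
    li = 0.5 * (d[i][j] + d[i][k] - d[j][k])
    lj = 0.5 * (d[i][j] + d[j][k] - d[i][k])
    lk = 0.5 * (d[i][k] + d[j][k] - d[i][j])
    for idx, length in ((i, li), (j, lj), (k, lk)):
        nodes[idx].length = max(0.0, length)
    root = TreeNode(children=[nodes[i], nodes[j], nodes[k]])
    return root


def bipartitions(tree: TreeNode) -> set[frozenset]:
    """Canonical set of non-trivial bipartitions of the leaf set."""
    all_leaves = frozenset(l.name for l in tree.tips())
    out = set()
    for node in tree.non_tips(include_self=False):
        under = frozenset(l.name for l in node.tips())
        if 1 < len(under) < len(all_leaves) - 1:
            out.add(frozenset((under, all_leaves - under)))
    return out


def _pairwise_k2p(rows: list[str], cols: Optional[np.ndarray] = None) -> np.ndarray:
    n = len(rows)
    arr = np.zeros((n, n))
    mats = []
    for r in rows:
        if cols is None:
            mats.append(r)
        else:
            mats.append("".join(r[c] for c in cols))
    for i in range(n):
        for j in range(i + 1, n):
            ts = tv = sites = 0
            for x, y in zip(mats[i], mats[j]):
                if x not in DNA_BASES or y not in DNA_BASES:
                    continue
                sites += 1
                if x == y:
                    continue
                if (x in "AG") == (y in "AG"):
                    ts += 1
                else:
                    tv += 1
            if sites == 0:
                k = SATURATION_CAP
            else:
                try:
                    k = k2p_from_counts(ts, tv, sites).k2p
                except Exception:
                    k = SATURATION_CAP
            arr[i, j] = arr[j, i] = k
    return arr


def bootstrap_support(
    cdnas: dict[str, str],
    n_replicates: int = 100,
    seed: int = 0,
) -> TreeNode:
    """Bootstrap NJ tree from RT cDNA sequences.

    Sequences are star-aligned to the longest member; per replicate, columns
    are resampled with replacement, pairwise K2P distances recomputed and a
    NJ tree rebuilt. Each internal edge of the full-data tree is labelled with
    the percentage of replicates containing its bipartition (``node.support``
    and the Newick internal-node label).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    labels = list(cdnas)
    if len(labels) < 3:
        raise InsufficientDataError("need >= 3 sequences")
    rows = star_align([cdnas[l] for l in labels])
    ncol = len(rows[0])
    if ncol < 10:
        raise ValueError("alignment shorter than 10 columns")

    main = build_nj_tree(build_distance_matrix(labels, _pairwise_k2p(rows)))
    counts: dict[frozenset, int] = {bp: 0 for bp in bipartitions(main)}

    rng = np.random.default_rng(seed)
    for _ in range(n_replicates):
        cols = rng.integers(0, ncol, size=ncol)
        rep = build_nj_tree(build_distance_matrix(labels, _pairwise_k2p(rows, cols)))
        for bp in bipartitions(rep):
            if bp in counts:
                counts[bp] += 1

    all_leaves = frozenset(labels)
    for node in main.non_tips(include_self=False):
        under = frozenset(l.name for l in node.tips())
        bp = frozenset((under, all_leaves - under))
        if bp in counts:
            support = 100.0 * counts[bp] / n_replicates
            node.bootstrap_percent = support
            node.name = str(int(round(support)))
    return main


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def read_newick(path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")
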