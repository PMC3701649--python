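"""Pairwise alignment, evolutionary distances, consensus building and translation.

These are the primitives every other module builds on: exact global
(Needleman-Wunsch) and local (Smith-Waterman) affine-gap alignment via
``Bio.Align.PairwiseAligner``, Kimura 2-parameter / Jukes-Cantor distances,
majority-rule consensus with the 50% cutoff, and six-frame translation for
translated protein searches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

from .errors import (
    AlignmentShapeError,
    DegenerateSequenceError,
    SaturationError,
)

DNA_BASES = "ACGT"
# IUPAC nucleotide alphabet accepted in input; ambiguity codes never score as a match.
DNA_ALPHABET = "ACGTRYSWKMBDHVN"
GAP = "-"

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN-acgtryswkmbdhvn",
    "TGCAYRSWMKVHDBN-tgcayrswmkvhdbn",
)

#: Standard genetic code; codons containing ambiguity translate to 'X'.
CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AlignParams:
    """Scoring parameters for pairwise alignment.

    Gap model: the first residue of a gap costs ``gap_open``, every further
    residue costs ``gap_extend`` (both non-positive).
    """

    match_score: int = 1
    mismatch_score: int = -1
    gap_open: int = -2
    gap_extend: int = -1
    protein_matrix: str = "BLOSUM62"

    def __post_init__(self):
        if self.match_score <= self.mismatch_score:
            raise ValueError("match_score must exceed mismatch_score")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be non-positive")


#: Protein-search defaults (BLAST-like gap costs with BLOSUM62).
PROTEIN_ALIGN_DEFAULTS = AlignParams(
    match_score=1, mismatch_score=-1, gap_open=-11, gap_extend=-1
)


@dataclass
class AlignedPair:
    """A gapped pairwise alignment.

    ``identity`` is the fraction of matching residues over columns where
    neither sequence is gapped; ``aligned_columns`` counts those columns.
    """

    gapped_a: str
    gapped_b: str
    identity: float
    aligned_columns: int
    score: float

    def __post_init__(self):
        if len(self.gapped_a) != len(self.gapped_b):
            raise AlignmentShapeError("gapped sequences differ in length")

    @property
    def gap_openings(self) -> int:
        """Number of distinct gap runs (indel events) in the alignment."""
        n = 0
        for g in (self.gapped_a, self.gapped_b):
            prev = False
            for c in g:
                cur = c == GAP
                if cur and not prev:
                    n += 1
                prev = cur
        return n


@dataclass
class DistanceEstimate:
    """Transition/transversion proportions and corrected distances.

    ``P`` and ``Q`` are the transition and transversion proportions over the
    ``sites`` ungapped, unambiguous columns of one pairwise alignment;
    ``k2p`` is K = -1/2 ln[(1-2P-Q) sqrt(1-2Q)] and ``jc`` the Jukes-Cantor
    distance -3/4 ln(1-4p/3) with p = P+Q.
    """

    P: float
    Q: float
    sites: int
    k2p: float
    jc: float


@dataclass
class ConsensusResult:
    consensus: str
    cutoff: float
    column_support: list[float] = field(default_factory=list)


def _identity_stats(gapped_a: str, gapped_b: str) -> tuple[float, int]:
    matches = 0
    cols = 0
    for x, y in zip(gapped_a, gapped_b):
        if x == GAP or y == GAP:
            continue
        cols += 1
        # ambiguity codes never count as identical
        if x == y and x in DNA_BASES:
            matches += 1
    return (matches / cols if cols else 0.0), cols


@lru_cache(maxsize=16)
def _dna_matrix(match: int, mismatch: int):
    m = substitution_matrices.Array(alphabet=DNA_ALPHABET, dims=2)
    for a in DNA_ALPHABET:
        for b in DNA_ALPHABET:
            if a == b and a in DNA_BASES:
                m[a, b] = match
            else:
                m[a, b] = mismatch
    return m


@lru_cache(maxsize=16)
def _dna_aligner(params: AlignParams, mode: str):
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = _dna_matrix(params.match_score, params.mismatch_score)
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    return aligner


@lru_cache(maxsize=4)
def _protein_aligner(matrix_name: str, gap_open: int, gap_extend: int):
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix_name)
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def _check_dna(seq: str, name: str) -> str:
    if not seq:
        raise DegenerateSequenceError(f"{name} is empty")
    seq = seq.upper()
    bad = set(seq) - set(DNA_ALPHABET)
    if bad:
        raise DegenerateSequenceError(f"{name} contains non-IUPAC characters {bad!r}")
    return seq


def global_align(a: str, b: str, params: AlignParams | None = None) -> AlignedPair:
    """Optimal global alignment of two DNA sequences with affine gap costs."""
    params = params or AlignParams()
    a = _check_dna(a, "sequence a")
    b = _check_dna(b, "sequence b")
    aligner = _dna_aligner(params, "global")
    aln = aligner.align(a, b)[0]
    ga, gb = str(aln[0]), str(aln[1])
    identity, cols = _identity_stats(ga, gb)
    return AlignedPair(ga, gb, identity, cols, float(aln.score))


@dataclass
class LocalProteinHit:
    """Best local protein alignment plus its coordinates (0-based half-open)."""

    pair: AlignedPair
    query_span: tuple[int, int]
    target_span: tuple[int, int]
    score: float


def local_align_protein(
    query_protein: str,
    target_protein: str,
    params: AlignParams | None = None,
) -> LocalProteinHit:
    """Highest-scoring Smith-Waterman alignment of two amino-acid sequences."""
    params = params or PROTEIN_ALIGN_DEFAULTS
    if not query_protein or not target_protein:
        raise DegenerateSequenceError("empty protein sequence")
    query_protein = query_protein.upper()
    target_protein = target_protein.upper()
    aligner = _protein_aligner(params.protein_matrix, params.gap_open, params.gap_extend)
    aln = aligner.align(query_protein, target_protein)[0]
    ga, gb = str(aln[0]), str(aln[1])
    qa_blocks, tb_blocks = aln.aligned
    q_span = (int(qa_blocks[0][0]), int(qa_blocks[-1][1]))
    t_span = (int(tb_blocks[0][0]), int(tb_blocks[-1][1]))
    matches = sum(
        1 for x, y in zip(ga, gb) if x == y and x != GAP
    )
    cols = sum(1 for x, y in zip(ga, gb) if x != GAP and y != GAP)
    identity = matches / cols if cols else 0.0
    return LocalProteinHit(
        AlignedPair(ga, gb, identity, cols, float(aln.score)),
        q_span,
        t_span,
        float(aln.score),
    )


def count_site_patterns(gapped_a: str, gapped_b: str) -> tuple[int, int, int]:
    """(transitions, transversions, comparable sites) over ungapped ACGT columns."""
    if len(gapped_a) != len(gapped_b):
        raise AlignmentShapeError("gapped sequences differ in length")
    ts = tv = sites = 0
    for x, y in zip(gapped_a.upper(), gapped_b.upper()):
        if x not in DNA_BASES or y not in DNA_BASES:
            continue
        sites += 1
        if x == y:
            continue
        if (x in PURINES) == (y in PURINES):
            ts += 1
        else:
            tv += 1
    return ts, tv, sites


def k2p_from_counts(ts: int, tv: int, sites: int) -> DistanceEstimate:
    if sites < 1:
        raise DegenerateSequenceError("no comparable (ungapped, unambiguous) columns")
    P = ts / sites
    Q = tv / sites
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(
            f"K2P distance undefined (P={P:.4f}, Q={Q:.4f}): sequences saturated"
        )
    k2p = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    p = P + Q
    wj = 1.0 - 4.0 * p / 3.0
    if wj <= 0.0:
        raise SaturationError(f"JC distance undefined (p={p:.4f}): sequences saturated")
    jc = -0.75 * math.log(wj)
    return DistanceEstimate(P=P, Q=Q, sites=sites, k2p=k2p, jc=jc)


def k2p_distance(pair: AlignedPair) -> DistanceEstimate:
    """Kimura 2-parameter (and Jukes-Cantor) distance from one gapped alignment.

    Columns containing a gap or an IUPAC ambiguity code are excluded from the
    comparable sites.
    """
    ts, tv, sites = count_site_patterns(pair.gapped_a, pair.gapped_b)
    return k2p_from_counts(ts, tv, sites)


def jc_distance(p: float) -> float:
    """Jukes-Cantor correction of a raw mismatch proportion ``p``."""
    w = 1.0 - 4.0 * p / 3.0
    if w <= 0.0:
        raise SaturationError(f"JC distance undefined for p={p}")
    return -0.75 * math.log(w)


def majority_consensus(aligned_set: list[str], cutoff: float = 0.5) -> ConsensusResult:
    """Column-wise majority consensus of equal-length gapped sequences.

    Per column the most frequent character wins (ties: bases before gap, then
    alphabetical). A winning gap drops the column; a winning base is emitted if
    its fraction reaches ``cutoff``, otherwise 'N'.
    """
    if len(aligned_set) < 2:
        raise ValueError("need >= 2 sequences")
    length = len(aligned_set[0])
    for s in aligned_set:
        if len(s) != length:
            raise AlignmentShapeError("aligned sequences differ in length")
    n = len(aligned_set)
    out: list[str] = []
    support: list[float] = []
    upper = [s.upper() for s in aligned_set]
    for col in range(length):
        counts: dict[str, int] = {}
        for s in upper:
            c = s[col]
            counts[c] = counts.get(c, 0) + 1
        # sort: highest count first; bases rank before gap on ties; then alphabetical
        winner = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0] == GAP, kv[0]))[0]
        char, count = winner
        frac = count / n
        if char == GAP:
            continue
        out.append(char if frac >= cutoff else "N")
        support.append(frac)
    return ConsensusResult("".join(out), cutoff, support)


def translate(dna: str) -> str:
    """Translate frame +1; codons with non-ACGT characters give 'X'."""
    dna = dna.upper()
    aa = []
    for i in range(0, len(dna) - len(dna) % 3, 3):
        codon = dna[i : i + 3]
        aa.append(CODON_TABLE.get(codon, "X"))
    return "".join(aa)


def six_frame_translate(dna: str) -> dict[int, str]:
    """All six reading frames, keyed +1,+2,+3,-1,-2,-3."""
    if not dna:
        raise DegenerateSequenceError("empty DNA sequence")
    dna = dna.upper()
    rc = reverse_complement(dna)
    frames: dict[int, str] = {}
    for off in range(3):
        frames[off + 1] = translate(dna[off:])
        frames[-(off + 1)] = translate(rc[off:])
    return frames


def star_align(seqs: list[str], params: AlignParams | None = None) -> list[str]:
    """Star alignment of ungapped sequences projected onto the longest member.

    Each sequence is globally aligned to the reference (the longest sequence,
    first on ties); columns are the reference positions, insertions relative to
    the reference are discarded. Returns gapped rows in input order, all of
    reference length.
    """
    if len(seqs) < 2:
        raise ValueError("need >= 2 sequences")
    params = params or AlignParams()
    ref_idx = max(range(len(seqs)), key=lambda i: (len(seqs[i]), -i))
    ref = seqs[ref_idx]
    rows: list[str] = []
    for i, s in enumerate(seqs):
        if i == ref_idx:
            rows.append(ref)
            continue
        aln = global_align(ref, s, params)
        row = [GAP] * len(ref)
        p = 0
        for rc_, sc in zip(aln.gapped_a, aln.gapped_b):
            if rc_ != GAP:
                if sc != GAP:
                    row[p] = sc
                p += 1
        rows.append("".join(row))
    return rows
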