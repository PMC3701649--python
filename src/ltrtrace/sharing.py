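"""Junction-marker extraction and shared/unshared insertion calls.

A transposon insertion present at the orthologous locus in two genomes
evidences insertion before their split. For each element with at least one
complete LTR, up to two 100-bp junction markers (50 bp flanking DNA + 50 bp
element terminal) are extracted and searched against the second assembly.
A hit passes when it aligns at >=90% identity over >=80 bp AND spans the
flank/element junction by >=10 bp on each side -- a TE-body-only match never
qualifies. Shared insertions also yield orthologous LTR pairs for dating the
species split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Literal, Optional

from Bio import Align

from ._kmer import KmerIndex, encode_one
from .errors import DegenerateSequenceError
from .miner import LtrElementAnnotation
from .seqcore import AlignedPair, DistanceEstimate, global_align, k2p_distance

JUNCTION_FLANK = 50
JUNCTION_LEN = 100


@dataclass
class JunctionMarker:
    element_id: str
    side: Literal["five_prime", "three_prime"]
    sequence: str
    junction_offset: int = JUNCTION_FLANK

    def __post_init__(self):
        if len(self.sequence) != JUNCTION_LEN:
            raise ValueError("junction marker must be exactly 100 bp")


@dataclass(frozen=True)
class SharingCriterion:
    min_identity: float = 0.90
    min_aligned_bp: int = 80
    min_junction_overlap: int = 10
    max_loci: int = 5  # more passing loci than this -> repetitive flank, unresolved


@dataclass
class JunctionHit:
    contig: str
    span: tuple[int, int]  # 1-based inclusive in the target
    identity: float
    junction_overlap: int
    aligned_bp: int


@dataclass
class SharedCall:
    element_id: str
    status: Literal["shared", "unshared", "unresolved"]
    supporting_hits: list[JunctionHit] = field(default_factory=list)


def _side_complete(ann: LtrElementAnnotation, side: str) -> bool:
    solo = ann.category.startswith("solo")
    if solo:
        return ann.ltr5_coverage >= 0.95 or ann.ltr3_coverage >= 0.95
    if side == "five_prime":
        return ann.ltr5 is not None and ann.ltr5_coverage >= 0.95
    return ann.ltr3 is not None and ann.ltr3_coverage >= 0.95


def extract_junctions(
    ann: LtrElementAnnotation, genome: dict[str, str]
) -> list[JunctionMarker]:
    """0-2 junction markers for one element; a side is skipped when its LTR is
    incomplete or its flank is truncated by a contig edge."""
    seq = genome[ann.chrom]
    s0, e0 = ann.span0
    if e0 - s0 < JUNCTION_FLANK:
        return []
    markers = []
    if _side_complete(ann, "five_prime") and s0 >= JUNCTION_FLANK:
        m = seq[s0 - JUNCTION_FLANK : s0 + JUNCTION_FLANK]
        markers.append(JunctionMarker(ann.element_id, "five_prime", m))
    if _side_complete(ann, "three_prime") and e0 + JUNCTION_FLANK <= len(seq):
        m = seq[e0 - JUNCTION_FLANK : e0 + JUNCTION_FLANK]
        markers.append(JunctionMarker(ann.element_id, "three_prime", m))
    return markers


class TargetIndex:
    """k-mer index over a target assembly for junction-marker lookups."""

    def __init__(self, genome: dict[str, str], k: int = 16):
        if not genome or all(len(s) == 0 for s in genome.values()):
            raise DegenerateSequenceError("empty target genome")
        self.k = k
        self.genome = genome
        self.indexes = {c: KmerIndex(s, k) for c, s in genome.items() if len(s) >= k}


@lru_cache(maxsize=1)
def _local_aligner():
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -1
    return aligner


def _candidate_windows(marker: str, index: TargetIndex):
    """Candidate target loci: diagonal clusters of exact k-mer seeds with seed
    support on both halves of the marker (so the junction can be spanned)."""
    k = index.k
    out = []
    for contig, idx in index.indexes.items():
        seeds: list[tuple[int, int]] = []
        for q in range(0, JUNCTION_LEN - k + 1):
            code = encode_one(marker[q : q + k])
            if code is None:
                continue
            for g in idx.lookup(code):
                seeds.append((int(g) - q, q))
        if not seeds:
            continue
        seeds.sort()
        group: list[tuple[int, int]] = [seeds[0]]
        for d, q in seeds[1:] + [(seeds[-1][0] + 10**9, 0)]:
            if d - group[-1][0] <= 30:
                group.append((d, q))
                continue
            qs = [x for _, x in group]
            left = min(qs)
            right = max(qs) + k
            if left < JUNCTION_FLANK - 5 and right > JUNCTION_FLANK + 5:
                diag = group[len(group) // 2][0]
                out.append((contig, diag))
            group = [(d, q)]
    return out


def _score_window(marker: str, index: TargetIndex, contig: str, diag: int, crit):
    seq = index.genome[contig]
    ws = max(0, diag - 30)
    we = min(len(seq), diag + JUNCTION_LEN + 30)
    window = seq[ws:we]
    if not window:
        return None
    aln = _local_aligner().align(marker, window)[0]
    q_blocks, t_blocks = aln.aligned
    q0, q1 = int(q_blocks[0][0]), int(q_blocks[-1][1])
    ga, gb = str(aln[0]), str(aln[1])
    # identity and aligned bp over non-gap columns of the local alignment
    matches = cols = 0
    for x, y in zip(ga, gb):
        if x == "-" or y == "-":
            continue
        cols += 1
        if x == y:
            matches += 1
    if cols == 0:
        return None
    identity = matches / cols
    j_overlap = min(JUNCTION_FLANK - q0, q1 - JUNCTION_FLANK)
    t0, t1 = int(t_blocks[0][0]), int(t_blocks[-1][1])
    return JunctionHit(
        contig=contig,
        span=(ws + t0 + 1, ws + t1),
        identity=identity,
        junction_overlap=max(0, j_overlap),
        aligned_bp=cols,
    ), q0, q1


def call_shared(
    markers: list[JunctionMarker],
    target: TargetIndex | dict[str, str],
    criterion: SharingCriterion | None = None,
) -> SharedCall:
    """Shared/unshared verdict for one element from its junction markers."""
    criterion = criterion or SharingCriterion()
    if isinstance(target, dict):
        target = TargetIndex(target)
    if not markers:
        return SharedCall(element_id="", status="unresolved")
    element_id = markers[0].element_id
    passing: list[JunctionHit] = []
    passing_loci = set()
    for m in markers:
        for contig, diag in _candidate_windows(m.sequence, target):
            scored = _score_window(m.sequence, target, contig, diag, criterion)
            if scored is None:
                continue
            hit, q0, q1 = scored
            if (
                hit.identity >= criterion.min_identity
                and hit.aligned_bp >= criterion.min_aligned_bp
                and hit.junction_overlap >= criterion.min_junction_overlap
            ):
                locus = (contig, hit.span[0] // 200)
                if locus not in passing_loci:
                    passing_loci.add(locus)
                    passing.append(hit)
    if len(passing_loci) > criterion.max_loci:
        return SharedCall(element_id, "unresolved", passing)
    if passing:
        return SharedCall(element_id, "shared", passing)
    return SharedCall(element_id, "unshared", [])


def call_shared_batch(
    annotations: list[LtrElementAnnotation],
    genome_a: dict[str, str],
    target: TargetIndex | dict[str, str],
    criterion: SharingCriterion | None = None,
    include_no_tsd: bool = False,
) -> dict[str, SharedCall]:
    """Sharing calls for all analyzable elements (by default those with TSDs,
    mirroring the exclusion of TSD-less copies from comparative analysis)."""
    if isinstance(target, dict):
        target = TargetIndex(target)
    calls = {}
    for ann in annotations:
        if not include_no_tsd and not (ann.category.endswith("with_tsd")):
            continue
        markers = extract_junctions(ann, genome_a)
        if not markers:
            calls[ann.element_id] = SharedCall(ann.element_id, "unresolved")
            continue
        call = call_shared(markers, target, criterion)
        call.element_id = ann.element_id
        calls[ann.element_id] = call
    return calls


@dataclass
class OrthologousLtrPair:
    element_id: str
    ltr_a: str
    ltr_b: str
    alignment: AlignedPair
    distance: DistanceEstimate


def _map_junction_to_target(marker: JunctionMarker, hit: JunctionHit, target: TargetIndex):
    """Target coordinate (0-based) corresponding to the marker's junction."""
    seq = target.genome[hit.contig]
    ws = max(0, hit.span[0] - 1 - 40)
    we = min(len(seq), hit.span[1] + 40)
    window = seq[ws:we]
    aln = _local_aligner().align(marker.sequence, window)[0]
    q_blocks, t_blocks = aln.aligned
    for (qa, qb), (ta, tb) in zip(q_blocks, t_blocks):
        if qa <= marker.junction_offset < qb:
            return ws + ta + (marker.junction_offset - qa)
    return None


def pair_orthologous_ltrs(
    ann: LtrElementAnnotation,
    genome_a: dict[str, str],
    target: TargetIndex | dict[str, str],
    call: SharedCall,
    criterion: SharingCriterion | None = None,
) -> Optional[OrthologousLtrPair]:
    """Recover the orthologous LTR pair at a shared insertion locus.

    The passing junction hit anchors the locus in the target; the LTR adjacent
    to that junction is extracted from both genomes and aligned. Returns None
    (with no pair) when the LTR cannot be recovered, e.g. at a scaffold edge.
    """
    if call.status != "shared":
        raise ValueError("orthologous LTR pairing requires a shared call")
    if isinstance(target, dict):
        target = TargetIndex(target)
    markers = {m.side: m for m in extract_junctions(ann, genome_a)}
    seq_a = genome_a[ann.chrom]
    for hit in call.supporting_hits:
        for side in ("five_prime", "three_prime"):
            m = markers.get(side)
            if m is None:
                continue
            if side == "five_prime":
                if ann.ltr5 is None:
                    continue
                ltr_len = ann.ltr5[1] - ann.ltr5[0] + 1
                ltr_a = seq_a[ann.ltr5[0] - 1 : ann.ltr5[1]]
            else:
                if ann.ltr3 is None:
                    if not ann.category.startswith("solo") or ann.ltr5 is None:
                        continue
                    ltr_len = ann.ltr5[1] - ann.ltr5[0] + 1
                    ltr_a = seq_a[ann.ltr5[0] - 1 : ann.ltr5[1]]
                else:
                    ltr_len = ann.ltr3[1] - ann.ltr3[0] + 1
                    ltr_a = seq_a[ann.ltr3[0] - 1 : ann.ltr3[1]]
            j = _map_junction_to_target(m, hit, target)
            if j is None:
                continue
            seq_b = target.genome[hit.contig]
            if side == "five_prime":
                b0, b1 = j, j + ltr_len
            else:
                b0, b1 = j - ltr_len, j
            if b0 < 0 or b1 > len(seq_b):
                continue
            ltr_b = seq_b[b0:b1]
            aln = global_align(ltr_a, ltr_b)
            try:
                dist = k2p_distance(aln)
            except Exception:
                continue
            return OrthologousLtrPair(ann.element_id, ltr_a, ltr_b, aln, dist)
    return None
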