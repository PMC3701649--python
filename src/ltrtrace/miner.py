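"""Structure- and homology-based mining of LTR retrotransposon family members.

Intact elements are found structurally: pairs of direct repeats are seeded by
shared k-mers, extended by X-drop comparison, and their boundaries refined by
the 5-bp target-site duplication (TSD) that flanks a genuine insertion. Solo
LTRs and truncated copies are then recovered by homology to the family's LTR
and internal consensus sequences. Every call is classified into one of seven
structural categories (intact/solo with or without TSD; 5'-, 3'- or both-end
truncations).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Literal, Optional

from ._kmer import KmerIndex, encode_one
from .errors import DegenerateSequenceError
from .seqcore import global_align, reverse_complement

CATEGORIES = (
    "intact_with_tsd",
    "intact_no_tsd",
    "solo_with_tsd",
    "solo_no_tsd",
    "trunc_5del",
    "trunc_3del",
    "trunc_bothdel",
)

LtrState = Literal["complete", "partial", "absent"]


@dataclass
class ElementModel:
    """Family exemplar: consensus sequences, internal motifs and termini.

    Defaults describe a short-LTR Copia-like family (194-bp LTRs, ~4.7-kb
    element, PBS ``TGGTATCAAGAA`` adjacent to the 5' LTR, PPT ``TGAGGGGGGA``
    adjacent to the 3' LTR, LTR termini ``TA..CA``). ``u3_end_offset`` marks
    the U3/R boundary within the LTR, used by the retrotransposition
    template rule of the simulator.
    """

    family_name: str = "FAM1"
    ltr_consensus: str = ""
    internal_consensus: str = ""
    pbs_motif: str = "TGGTATCAAGAA"
    ppt_motif: str = "TGAGGGGGGA"
    expected_termini: tuple[str, str] = ("TA", "CA")
    u3_end_offset: int = 120

    def __post_init__(self):
        if self.ltr_consensus and len(self.ltr_consensus) < 50:
            raise ValueError("ltr_consensus must be >= 50 bp")
        if not self.pbs_motif or not self.ppt_motif:
            raise ValueError("PBS/PPT motifs must be non-empty")
        for t in self.expected_termini:
            if len(t) != 2:
                raise ValueError("expected termini must be dinucleotides")


@dataclass(frozen=True)
class MinerParams:
    ltr_len_range: tuple[int, int] = (100, 1000)
    element_len_range: tuple[int, int] = (1000, 15000)
    min_ltr_pair_identity: float = 0.85
    tsd_len: int = 5
    homology_min_identity: float = 0.80
    homology_min_length: int = 50
    termini_policy: Literal["require_expected", "report_observed"] = "report_observed"
    seed_k: int = 16
    homology_seed_k: int = 12
    merge_tolerance: int = 50
    complete_ltr_coverage: float = 0.95

    def __post_init__(self):
        for lo, hi in (self.ltr_len_range, self.element_len_range):
            if not (0 < lo <= hi):
                raise ValueError("length ranges must be positive and ordered")
        for x in (self.min_ltr_pair_identity, self.homology_min_identity):
            if not (0 < x <= 1):
                raise ValueError("identity thresholds must be in (0,1]")


@dataclass
class LtrElementAnnotation:
    """One mined element. Coordinates are 1-based inclusive."""

    element_id: str
    chrom: str
    start: int
    end: int
    ltr5: Optional[tuple[int, int]] = None
    ltr3: Optional[tuple[int, int]] = None
    tsd_seq: Optional[str] = None
    termini: str = "??..??"
    category: str = "unresolved"
    strand: str = "+"
    ltr5_coverage: float = 0.0
    ltr3_coverage: float = 0.0
    internal_present: bool = False
    ltr_identity: Optional[float] = None
    pbs_ok: Optional[bool] = None
    ppt_ok: Optional[bool] = None

    @property
    def span0(self) -> tuple[int, int]:
        """0-based half-open element span."""
        return self.start - 1, self.end

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class StructureSummary:
    counts: dict[str, int]
    total: int
    solo_to_intact_ratio: Optional[float]
    unresolved: int = 0


@dataclass
class HitGeometry:
    """Structural evidence for one candidate element."""

    ltr5: LtrState
    ltr3: LtrState
    internal: bool
    tsd: bool


def classify_structure(geom: HitGeometry) -> str:
    """Deterministic mapping from hit geometry to structural category.

    A 'complete' LTR means homology covers >=95% of the LTR consensus at that
    end. Two complete LTRs without any internal region are contradictory
    (a tandem solo arrangement) and map to 'unresolved'.
    """
    l5, l3 = geom.ltr5, geom.ltr3
    if l5 == "absent" and l3 == "absent" and not geom.internal:
        raise ValueError("geometry contains no structural evidence")
    if geom.internal:
        if l5 == "complete" and l3 == "complete":
            return "intact_with_tsd" if geom.tsd else "intact_no_tsd"
        if l3 == "complete":
            return "trunc_5del"
        if l5 == "complete":
            return "trunc_3del"
        return "trunc_bothdel"
    # no internal region
    complete = (l5 == "complete") + (l3 == "complete")
    present = (l5 != "absent") + (l3 != "absent")
    if complete == 2 or (complete == 1 and present == 2):
        return "unresolved"
    if complete == 1:
        return "solo_with_tsd" if geom.tsd else "solo_no_tsd"
    return "trunc_bothdel"


# ---------------------------------------------------------------------------
# structural (direct-repeat) detection
# ---------------------------------------------------------------------------


def _xdrop_pair(seq: str, a: int, b: int, direction: int, limit: int, xdrop: int = 8):
    """Extend comparison of seq[a+t*dir] vs seq[b+t*dir]; return best extent t*.

    Scores +1 per match, -2 per mismatch; stops when score falls ``xdrop``
    below the running maximum or coordinates leave the sequence/limit.
    """
    n = len(seq)
    score = 0
    best = 0
    best_t = 0
    t = 0
    while t < limit:
        x = a + direction * (t + 1) if direction < 0 else a + t
        y = b + direction * (t + 1) if direction < 0 else b + t
        if x < 0 or y < 0 or x >= n or y >= n:
            break
        score += 1 if seq[x] == seq[y] else -2
        t += 1
        if score > best:
            best = score
            best_t = t
        if score < best - xdrop:
            break
    return best_t


def _find_motif(region: str, motif: str, max_mismatch: int = 2) -> bool:
    m = len(motif)
    for i in range(len(region) - m + 1):
        mm = sum(1 for a, b in zip(region[i : i + m], motif) if a != b)
        if mm <= max_mismatch:
            return True
    return False


def _boundary_support(seq, s, e, model, d, width: int = 6):
    """How well [s,e) agrees with the element's repeat structure at both ends.

    For a structural (direct-repeat) candidate with LTR-start offset ``d``, the
    true 5' boundary must continue the repeat (seq[s+i] == seq[s+d+i]) and the
    true 3' boundary must mirror the 5' LTR end (seq[e-1-i] == seq[e-d-1-i]).
    For homology candidates the family LTR consensus plays that role. Returns
    the number of matching positions out of 2*width, or None when no
    structural anchor is available.
    """
    cnt = 0
    n = len(seq)
    if d is not None:
        for i in range(width):
            if s + d + i < n and seq[s + i] == seq[s + d + i]:
                cnt += 1
            if e - d - 1 - i >= 0 and seq[e - 1 - i] == seq[e - d - 1 - i]:
                cnt += 1
        return cnt
    cons = model.ltr_consensus
    if not cons:
        return None
    for i in range(width):
        if s + i < n and seq[s + i] == cons[i]:
            cnt += 1
        if e - 1 - i >= 0 and seq[e - 1 - i] == cons[-1 - i]:
            cnt += 1
    return cnt


def _refine_boundaries(seq, s0, e0, model, params, d=None):
    """TSD-anchored boundary refinement around approximate element span [s0,e0).

    Returns (s, e, tsd_seq or None). Candidate boundaries must stay consistent
    with the repeat structure (see _boundary_support), so chance 5-mer pairings
    in the flanks cannot masquerade as TSDs. Preference order: a perfect 5-bp
    TSD with expected termini, then any perfect TSD, then an expected-termini
    snap, else the unrefined span.
    """
    t5, t3 = model.expected_termini
    tsd = params.tsd_len
    n = len(seq)
    win = 25  # must exceed the worst-case X-drop overshoot past the true boundary
    min_support = 9  # of 12 compared positions

    def supported(s, e):
        sup = _boundary_support(seq, s, e, model, d)
        return 24 if sup is None else sup  # no anchor available -> do not filter

    best = None
    for ds in range(-win, win + 1):
        s = s0 + ds
        if s - tsd < 0:
            continue
        up = seq[s - tsd : s]
        for de in range(-win, win + 1):
            e = e0 + de
            if e + tsd > n or e - s < 10:
                continue
            if seq[e : e + tsd] != up:
                continue
            sup = supported(s, e)
            if sup < min_support:
                continue
            term_ok = seq[s : s + 2] == t5 and seq[e - 2 : e] == t3
            key = (0 if term_ok else 1, -sup, abs(ds) + abs(de), ds, de)
            if best is None or key < best[0]:
                best = (key, s, e, up)
    if best is not None:
        return best[1], best[2], best[3]
    # no perfect TSD: snap to expected termini if possible
    best = None
    for ds in range(-win, win + 1):
        s = s0 + ds
        if s < 0 or seq[s : s + 2] != t5:
            continue
        for de in range(-win, win + 1):
            e = e0 + de
            if e > n or seq[e - 2 : e] != t3:
                continue
            sup = supported(s, e)
            if sup < min_support:
                continue
            key = (-sup, abs(ds) + abs(de), ds, de)
            if best is None or key < best[0]:
                best = (key, s, e)
    if best is not None:
        return best[1], best[2], None
    return s0, e0, None


def _orient_element(seq, s, e, ltr_len, model) -> tuple[str, bool, bool]:
    """Decide strand from PBS/PPT positions; return (strand, pbs_ok, ppt_ok)."""
    pbs, ppt = model.pbs_motif, model.ppt_motif
    down5 = seq[s + ltr_len : s + ltr_len + 20 + len(pbs)]
    up3 = seq[max(s, e - ltr_len - 20 - len(ppt)) : e - ltr_len]
    fwd = (_find_motif(down5, pbs), _find_motif(up3, ppt))
    rev = (
        _find_motif(up3, reverse_complement(pbs)),
        _find_motif(down5, reverse_complement(ppt)),
    )
    if sum(rev) > sum(fwd):
        return "-", rev[0], rev[1]
    return "+", fwd[0], fwd[1]


def _detect_on_chrom(chrom: str, seq: str, model: ElementModel, params: MinerParams):
    k = params.seed_k
    d_min = max(1, params.element_len_range[0] - params.ltr_len_range[1])
    d_max = params.element_len_range[1] - params.ltr_len_range[0]
    index = KmerIndex(seq, k)
    by_d: dict[int, list[int]] = defaultdict(list)
    for positions in index.duplicate_groups():
        pos = positions.tolist()
        for ai, i in enumerate(pos):
            for j in pos[ai + 1 :]:
                d = j - i
                if d < d_min:
                    continue
                if d > d_max:
                    break
                by_d[d].append(i)

    candidates = []
    chain_gap = 150
    for d, ilist in by_d.items():
        ilist.sort()
        run_start = ilist[0]
        last = ilist[0]
        for i in ilist[1:] + [None]:
            if i is not None and i - last <= chain_gap:
                last = i
                continue
            candidates.append((run_start, last + k, d))
            if i is not None:
                run_start = i
                last = i

    raw = []
    seen_spans = set()
    for i0, i1, d in candidates:
        left = _xdrop_pair(seq, i0, i0 + d, -1, params.ltr_len_range[1])
        right = _xdrop_pair(seq, i1, i1 + d, +1, params.ltr_len_range[1])
        s0 = i0 - left
        e0 = i1 + right + d
        s, e, tsd_seq = _refine_boundaries(seq, s0, e0, model, params, d=d)
        elem_len = e - s
        ltr_len = elem_len - d
        if not (params.ltr_len_range[0] <= ltr_len <= params.ltr_len_range[1]):
            continue
        if not (params.element_len_range[0] <= elem_len <= params.element_len_range[1]):
            continue
        if elem_len - 2 * ltr_len < 1:
            continue  # tandem solo arrangement, not an intact element
        if (s, e) in seen_spans:
            continue
        seen_spans.add((s, e))
        ltr5_seq = seq[s : s + ltr_len]
        ltr3_seq = seq[e - ltr_len : e]
        aln = global_align(ltr5_seq, ltr3_seq)
        if aln.identity < params.min_ltr_pair_identity:
            continue
        termini = f"{seq[s:s + 2]}..{seq[e - 2:e]}"
        if params.termini_policy == "require_expected" and (
            seq[s : s + 2] != model.expected_termini[0]
            or seq[e - 2 : e] != model.expected_termini[1]
        ):
            continue
        strand, pbs_ok, ppt_ok = _orient_element(seq, s, e, ltr_len, model)
        raw.append(
            LtrElementAnnotation(
                element_id="",
                chrom=chrom,
                start=s + 1,
                end=e,
                ltr5=(s + 1, s + ltr_len),
                ltr3=(e - ltr_len + 1, e),
                tsd_seq=tsd_seq,
                termini=termini,
                category="intact_with_tsd" if tsd_seq else "intact_no_tsd",
                strand=strand,
                ltr5_coverage=1.0,
                ltr3_coverage=1.0,
                internal_present=True,
                ltr_identity=aln.identity,
                pbs_ok=pbs_ok,
                ppt_ok=ppt_ok,
            )
        )
    return _resolve_overlaps(raw, params)


def _resolve_overlaps(anns, params: MinerParams):
    """Greedy non-overlapping selection preferring TSD-supported, motif-supported,
    higher-identity calls."""

    def key(a: LtrElementAnnotation):
        return (
            0 if a.tsd_seq else 1,
            -(bool(a.pbs_ok) + bool(a.ppt_ok)),
            -(a.ltr_identity or 0.0),
            a.length,
            a.start,
        )

    accepted: list[LtrElementAnnotation] = []
    for a in sorted(anns, key=key):
        ok = True
        for b in accepted:
            if a.chrom != b.chrom:
                continue
            ov = min(a.end, b.end) - max(a.start, b.start) + 1
            if ov > params.merge_tolerance:
                ok = False
                break
        if ok:
            accepted.append(a)
    accepted.sort(key=lambda a: (a.chrom, a.start))
    return accepted


def detect_intact_elements(
    genome: dict[str, str],
    model: ElementModel,
    params: MinerParams | None = None,
) -> list[LtrElementAnnotation]:
    """Structural scan for intact elements (pairs of direct repeats with TSD
    verification, termini recording and PBS/PPT flags)."""
    params = params or MinerParams()
    if not genome or all(len(s) == 0 for s in genome.values()):
        raise DegenerateSequenceError("empty genome")
    out = []
    for chrom in sorted(genome):
        out.extend(_detect_on_chrom(chrom, genome[chrom], model, params))
    for i, ann in enumerate(out):
        ann.element_id = f"{model.family_name}_i{i + 1:04d}"
    return out


# ---------------------------------------------------------------------------
# homology-based recovery of solo LTRs and truncated copies
# ---------------------------------------------------------------------------


@dataclass
class _Hit:
    kind: str  # 'ltr' | 'internal'
    strand: str
    gstart: int
    gend: int
    qstart: int
    qend: int
    identity: float
    qlen: int

    @property
    def coverage(self) -> float:
        return (self.qend - self.qstart) / self.qlen


def _scan_query(seq: str, index: KmerIndex, query: str, kind: str, strand: str, params):
    k = params.homology_seed_k
    seeds: list[tuple[int, int]] = []  # (diag, qpos)
    for q in range(len(query) - k + 1):
        code = encode_one(query[q : q + k])
        if code is None:
            continue
        for g in index.lookup(code):
            seeds.append((int(g) - q, q))
    if not seeds:
        return []
    seeds.sort()
    groups: list[list[tuple[int, int]]] = []
    cur = [seeds[0]]
    for dgq in seeds[1:]:
        # same-ish diagonal and genomic proximity
        if dgq[0] - cur[-1][0] <= 20 and abs(
            (dgq[0] + dgq[1]) - (cur[-1][0] + cur[-1][1])
        ) <= 600:
            cur.append(dgq)
            continue
        groups.append(cur)
        cur = [dgq]
    groups.append(cur)

    # split diagonal groups at large query gaps: a lone chance seed far from
    # the dense chain must not stretch the hit span
    chains: list[list[tuple[int, int]]] = []
    for grp in groups:
        grp = sorted(grp, key=lambda dq: dq[1])
        cur = [grp[0]]
        for dq in grp[1:]:
            if dq[1] - cur[-1][1] <= 120:
                cur.append(dq)
            else:
                chains.append(cur)
                cur = [dq]
        chains.append(cur)

    hits = []
    for grp in chains:
        diag = grp[0][0]
        q0 = min(q for _, q in grp)
        q1 = max(q for _, q in grp) + k
        g0 = diag + q0
        g1 = diag + q1
        # ungapped X-drop extension outwards
        ext_l = _xdrop_text(seq, query, g0 - 1, q0 - 1, -1)
        ext_r = _xdrop_text(seq, query, g1, q1, +1)
        q0 -= ext_l
        g0 -= ext_l
        q1 += ext_r
        g1 += ext_r
        length = q1 - q0
        if length < params.homology_min_length:
            continue
        mism = sum(1 for a, b in zip(seq[g0:g1], query[q0:q1]) if a != b)
        identity = 1 - mism / length
        if identity < params.homology_min_identity:
            continue
        if strand == "-":
            # report query coordinates on the forward consensus
            q0f = len(query) - q1
            q1f = len(query) - q0
            q0, q1 = q0f, q1f
        hits.append(_Hit(kind, strand, g0, g1, q0, q1, identity, len(query)))
    return hits


def _xdrop_text(seq: str, query: str, g: int, q: int, direction: int, xdrop: int = 10):
    score = best = best_t = t = 0
    while True:
        x = g + direction * t
        y = q + direction * t
        if x < 0 or y < 0 or x >= len(seq) or y >= len(query):
            break
        score += 1 if seq[x] == query[y] else -2
        t += 1
        if score > best:
            best, best_t = score, t
        if score < best - xdrop:
            break
    return best_t


def _dedupe_hits(hits: list[_Hit]) -> list[_Hit]:
    hits = sorted(hits, key=lambda h: (h.gstart, -(h.gend - h.gstart)))
    out: list[_Hit] = []
    for h in hits:
        redundant = False
        for o in out:
            if h.kind == o.kind and min(h.gend, o.gend) - max(h.gstart, o.gstart) > 0.8 * (
                h.gend - h.gstart
            ):
                redundant = True
                break
        if not redundant:
            out.append(h)
    return out


def recover_by_homology(
    genome: dict[str, str],
    model: ElementModel,
    already_found: list[LtrElementAnnotation],
    params: MinerParams | None = None,
) -> list[LtrElementAnnotation]:
    """Recover solo LTRs, truncated copies and missed intact elements by
    seeded, X-drop-extended homology to the family consensus sequences."""
    params = params or MinerParams()
    if not model.ltr_consensus:
        raise ValueError("model.ltr_consensus is required for homology recovery")
    occupied = defaultdict(list)
    for a in already_found:
        occupied[a.chrom].append(a.span0)
    out: list[LtrElementAnnotation] = []
    counter = 0
    for chrom in sorted(genome):
        seq = genome[chrom]
        if len(seq) < params.homology_seed_k:
            continue
        index = KmerIndex(seq, params.homology_seed_k)
        hits: list[_Hit] = []
        queries = [("ltr", model.ltr_consensus)]
        if model.internal_consensus:
            queries.append(("internal", model.internal_consensus))
        for kind, q in queries:
            hits += _scan_query(seq, index, q, kind, "+", params)
            hits += _scan_query(seq, index, reverse_complement(q), kind, "-", params)
        hits = _dedupe_hits(hits)
        # drop hits inside already-annotated elements
        kept = []
        for h in hits:
            clash = any(
                min(h.gend, e) - max(h.gstart, s) > params.merge_tolerance // 2
                for s, e in occupied[chrom]
            )
            if not clash:
                kept.append(h)
        # cluster into elements
        kept.sort(key=lambda h: h.gstart)
        clusters: list[list[_Hit]] = []
        for h in kept:
            if (
                clusters
                and h.gstart - clusters[-1][-1].gend <= params.merge_tolerance
                and h.strand == clusters[-1][-1].strand
            ):
                clusters[-1].append(h)
            else:
                clusters.append([h])
        for cl in clusters:
            counter += 1
            ann = _annotate_cluster(chrom, seq, cl, model, params, counter)
            if ann is not None:
                out.append(ann)
    return _resolve_overlaps(out, params)


def _annotate_cluster(chrom, seq, cluster, model, params, counter) -> Optional[LtrElementAnnotation]:
    cs = min(h.gstart for h in cluster)
    ce = max(h.gend for h in cluster)
    strand = cluster[0].strand
    ltr_hits = [h for h in cluster if h.kind == "ltr"]
    internal = any(
        h.kind == "internal" and h.gend - h.gstart >= params.homology_min_length
        for h in cluster
    )
    tol = 10

    def state(h: Optional[_Hit]) -> LtrState:
        if h is None:
            return "absent"
        return "complete" if h.coverage >= params.complete_ltr_coverage else "partial"

    left_ltr = next((h for h in ltr_hits if h.gstart <= cs + tol), None)
    right_ltr = next((h for h in reversed(ltr_hits) if h.gend >= ce - tol), None)
    if left_ltr is right_ltr and left_ltr is not None and internal:
        # single LTR hit with internal region: decide by position
        if left_ltr.gstart <= cs + tol and left_ltr.gend >= ce - tol:
            pass  # spans everything: ambiguous, keep as both
        elif left_ltr.gstart <= cs + tol:
            right_ltr = None
        else:
            left_ltr = None
    solo = left_ltr is right_ltr and left_ltr is not None and not internal

    # boundary refinement by TSD for clusters with complete termini
    tsd_seq = None
    s, e = cs, ce
    if state(left_ltr) == "complete" and (solo or state(right_ltr) == "complete"):
        s, e, tsd_seq = _refine_boundaries(seq, cs, ce, model, params)
    else:
        if seq[max(0, s - params.tsd_len) : s] == seq[e : e + params.tsd_len] and s >= params.tsd_len:
            tsd_seq = seq[s - params.tsd_len : s]

    if strand == "-":
        g5, g3 = right_ltr, left_ltr  # 5' LTR of the element sits at the right end
    else:
        g5, g3 = left_ltr, right_ltr
    if solo:
        g5, g3 = left_ltr, None

    geom = HitGeometry(ltr5=state(g5), ltr3=state(g3), internal=internal, tsd=tsd_seq is not None)
    try:
        category = classify_structure(geom)
    except ValueError:
        return None

    def interval(h: Optional[_Hit]) -> Optional[tuple[int, int]]:
        if h is None:
            return None
        hs = max(h.gstart, s)
        he = min(h.gend, e)
        # snap complete LTRs to the refined element boundaries
        if state(h) == "complete":
            if h is left_ltr:
                hs = s
                if solo:
                    he = e
            if h is right_ltr and not solo:
                he = e
        return (hs + 1, he)

    term5 = seq[s : s + 2] if state(g5) == "complete" else "??"
    term3 = seq[e - 2 : e] if (state(g3) == "complete" or solo) else "??"
    return LtrElementAnnotation(
        element_id=f"{model.family_name}_h{counter:04d}",
        chrom=chrom,
        start=s + 1,
        end=e,
        ltr5=interval(g5 if not solo else left_ltr),
        ltr3=interval(g3),
        tsd_seq=tsd_seq if category.endswith("with_tsd") else None,
        termini=f"{term5}..{term3}",
        category=category,
        strand=strand,
        ltr5_coverage=g5.coverage if g5 else 0.0,
        ltr3_coverage=g3.coverage if g3 else 0.0,
        internal_present=internal,
    )


def mine_genome(
    genome: dict[str, str],
    model: ElementModel,
    params: MinerParams | None = None,
) -> list[LtrElementAnnotation]:
    """Full mining pass: structural detection then homology recovery."""
    params = params or MinerParams()
    intact = detect_intact_elements(genome, model, params)
    extra = recover_by_homology(genome, model, intact, params)
    merged = sorted(intact + extra, key=lambda a: (a.chrom, a.start))
    return merged


def summarize_structures(
    annotations: list[LtrElementAnnotation],
    ratio_denominator: str = "intact_with_tsd",
) -> StructureSummary:
    """Category counts, total and the solo:intact ratio (2 decimals).

    ``ratio_denominator`` may be ``intact_with_tsd`` (default) or
    ``intact_all``; the numerator is always the solo-with-TSD count.
    """
    counts = {c: 0 for c in CATEGORIES}
    unresolved = 0
    for a in annotations:
        if a.category in counts:
            counts[a.category] += 1
        else:
            unresolved += 1
    total = sum(counts.values())
    if ratio_denominator == "intact_all":
        denom = counts["intact_with_tsd"] + counts["intact_no_tsd"]
    else:
        denom = counts["intact_with_tsd"]
    ratio = round(counts["solo_with_tsd"] / denom, 2) if denom else None
    return StructureSummary(counts=counts, total=total, solo_to_intact_ratio=ratio,
                            unresolved=unresolved)


def summary_from_counts(counts: dict[str, int], ratio_denominator="intact_with_tsd") -> StructureSummary:
    """Build a StructureSummary directly from per-category counts."""
    filled = {c: int(counts.get(c, 0)) for c in CATEGORIES}
    total = sum(filled.values())
    if ratio_denominator == "intact_all":
        denom = filled["intact_with_tsd"] + filled["intact_no_tsd"]
    else:
        denom = filled["intact_with_tsd"]
    ratio = round(filled["solo_with_tsd"] / denom, 2) if denom else None
    return StructureSummary(counts=filled, total=total, solo_to_intact_ratio=ratio)


def termini_census(annotations: list[LtrElementAnnotation]) -> dict[str, int]:
    """Frequencies of observed terminal dinucleotide pairs ('XX..YY')."""
    c = Counter(
        a.termini for a in annotations if "?" not in a.termini and len(a.termini) == 6
    )
    return dict(c)
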