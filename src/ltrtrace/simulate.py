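"""Synthetic genomes with planted LTR retrotransposon insertions of known truth.

The generator plants intact elements (two LTRs derived from one per-element
copy, each subsequently mutated independently at per-site probability
1-exp(-r*age)), solo LTRs and truncated copies, all flanked by perfect 5-bp
target-site duplications, in an i.i.d. background of configurable GC content.
A sister genome can be derived by retaining a fraction of the insertions,
excising the rest (leaving one TSD copy behind), and mutating both genomes
independently for the split time so orthologous divergence is ~2 r T.

It also implements the retrotransposition template rule by which a daughter
element's U3 (in both LTRs) is copied from the mother's 3' LTR while R+U5 is
copied from the mother's 5' LTR -- the mechanism by which a single 3'-LTR U3
mutation (a terminal G->A, turning TG.. into TA..) propagates to both LTRs of
every descendant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal, Optional

import numpy as np

from .miner import ElementModel, LtrElementAnnotation

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return _BASES[idx].tobytes().decode("ascii")


def mutate_sequence(seq: str, p: float, rng: np.random.Generator) -> str:
    """Apply i.i.d. substitutions (Jukes-Cantor moves: any site hit changes to
    one of the three other bases uniformly) at per-site probability ``p``."""
    if p <= 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    codes = _CODE[arr]
    hit = (rng.random(len(arr)) < p) & (codes != 255)
    n = int(hit.sum())
    if n == 0:
        return seq
    shifts = rng.integers(1, 4, size=n).astype(np.uint8)
    codes[hit] = (codes[hit] + shifts) % 4
    arr[hit] = _BASES[codes[hit]]
    return arr.tobytes().decode("ascii")


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic genome.

    Defaults mirror a short-LTR Copia-like family: 194-bp LTRs, ~4.7-kb
    elements, perfect 5-bp TSDs, TA..CA termini, LTR clock
    r = 1.3e-8 substitutions/site/year, insertion ages uniform over
    0.75-1.75 My with the family founded 1.75 My ago, a sister genome split
    0.28 My ago retaining 83% of insertions.
    """

    seed: int = 0
    genome_length: int = 2_000_000
    gc_content: float = 0.36
    n_intact: int = 30
    n_solo: int = 2
    n_truncated: int = 12
    ltr_length: int = 194
    element_length: int = 4700
    tsd_length: int = 5
    termini: Literal["TA_CA", "TG_CA"] = "TA_CA"
    age_distribution: tuple = ("uniform", 750_000.0, 1_750_000.0)
    family_birth_age: float = 1_750_000.0
    r: float = 1.3e-8
    split_time: float = 280_000.0
    shared_fraction: float = 0.83
    sister_extra_insertions: int = 0
    chrom_name: str = "chrA"
    min_site_gap: int = 300
    edge_margin: int = 1000
    #: optional (start, end, weight) background regions biasing insertion placement
    site_regions: Optional[list[tuple[int, int, float]]] = None

    def __post_init__(self):
        if min(self.n_intact, self.n_solo, self.n_truncated) < 0:
            raise ValueError("element counts must be >= 0")
        if not (0.0 <= self.shared_fraction <= 1.0):
            raise ValueError("shared_fraction must be in [0,1]")
        for name in ("genome_length", "ltr_length", "element_length", "tsd_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class TruthRecord:
    """Ground truth for one planted element (1-based inclusive coordinates)."""

    element_id: str
    chrom: str
    start: int
    end: int
    ltr5: Optional[tuple[int, int]]
    ltr3: Optional[tuple[int, int]]
    category: str
    termini: str
    tsd_seq: str
    true_age: float
    planted_seq: str
    shared: Optional[bool] = None
    b_chrom: Optional[str] = None
    b_start: Optional[int] = None
    b_end: Optional[int] = None


@dataclass
class SimulationResult:
    genome: dict[str, str]
    truth: list[TruthRecord]
    model: ElementModel
    config: SimulationConfig


def _draw_ages(rng, dist: tuple, n: int) -> np.ndarray:
    kind = dist[0]
    if kind == "point":
        return np.full(n, float(dist[1]))
    if kind == "uniform":
        return rng.uniform(float(dist[1]), float(dist[2]), size=n)
    if kind == "empirical":
        values = np.asarray(dist[1], dtype=float)
        return rng.choice(values, size=n, replace=True)
    raise ValueError(f"unknown age distribution {kind!r}")


def _draw_sites(rng, cfg: SimulationConfig, n: int) -> list[int]:
    lo = cfg.edge_margin
    hi = cfg.genome_length - cfg.edge_margin
    if hi <= lo or (hi - lo) < n * cfg.min_site_gap * 2:
        raise ValueError("genome too small to host the requested insertions")
    gap = cfg.min_site_gap
    regions = cfg.site_regions
    if regions:
        # weighted placement: draw region by weight*length, site uniform within;
        # resample any site closer than the minimum gap to an accepted one
        w = np.array([(e - s) * wt for s, e, wt in regions], dtype=float)
        w /= w.sum()
        sites: list[int] = []
        for _ in range(n):
            for _attempt in range(10_000):
                i = int(rng.choice(len(regions), p=w))
                s = int(rng.integers(max(lo, regions[i][0]), min(hi, regions[i][1])))
                if all(abs(s - t) >= gap for t in sites):
                    sites.append(s)
                    break
            else:
                raise ValueError("could not place insertions without overlap")
        return sorted(sites)
    # uniform with a minimum gap, via the order-statistics construction
    span = (hi - lo) - (n - 1) * gap
    if span <= n:
        raise ValueError("could not place insertions without overlap; genome too small")
    picks = np.sort(rng.choice(span, size=n, replace=False))
    return (picks + lo + np.arange(n) * gap).tolist()


def _build_elements(rng, cfg: SimulationConfig, model: ElementModel):
    """Construct element sequences + per-element metadata (pre-placement)."""
    n_total = cfg.n_intact + cfg.n_solo + cfg.n_truncated
    ages = _draw_ages(rng, cfg.age_distribution, n_total)
    ltr_anc = model.ltr_consensus
    int_anc = model.internal_consensus
    L = cfg.ltr_length
    elements = []
    trunc_kinds = ["trunc_5del", "trunc_3del", "trunc_bothdel"]
    for i in range(n_total):
        age = float(ages[i])
        pre = max(cfg.family_birth_age - age, 0.0)
        p_pre = 1.0 - math.exp(-cfg.r * pre)
        p_post = 1.0 - math.exp(-cfg.r * age)
        ltr_ins = mutate_sequence(ltr_anc, p_pre, rng)
        internal = mutate_sequence(
            int_anc, 1.0 - math.exp(-cfg.r * (pre + age)), rng
        )
        ltr5 = mutate_sequence(ltr_ins, p_post, rng)
        ltr3 = mutate_sequence(ltr_ins, p_post, rng)
        full = ltr5 + internal + ltr3
        if i < cfg.n_intact:
            seq = full
            cat = "intact_with_tsd"
            l5: Optional[tuple[int, int]] = (0, L)
            l3: Optional[tuple[int, int]] = (len(full) - L, len(full))
        elif i < cfg.n_intact + cfg.n_solo:
            seq = ltr5
            cat = "solo_with_tsd"
            l5 = (0, L)
            l3 = None
        else:
            kind = trunc_kinds[(i - cfg.n_intact - cfg.n_solo) % 3]
            ilen = len(internal)
            if kind == "trunc_5del":
                cut = int(rng.integers(L // 2 + 1, L + ilen // 3))
                seq = full[cut:]
                l5 = None
                l3 = (len(seq) - L, len(seq))
            elif kind == "trunc_3del":
                cut = int(rng.integers(L // 2 + 1, L + ilen // 3))
                seq = full[: len(full) - cut]
                l5 = (0, L)
                l3 = None
            else:
                c1 = int(rng.integers(10, max(11, ilen // 4)))
                c2 = int(rng.integers(10, max(11, ilen // 4)))
                seq = full[L + c1 : len(full) - L - c2]
                l5 = None
                l3 = None
            cat = kind
        tsd = _random_seq(rng, cfg.tsd_length, cfg.gc_content)
        elements.append((seq, cat, l5, l3, tsd, age))
    return elements


def simulate_genome(config: SimulationConfig) -> SimulationResult:
    """Generate a genome FASTA-ready sequence plus the per-element truth table."""
    rng = np.random.default_rng(config.seed)
    t5 = "TA" if config.termini == "TA_CA" else "TG"
    ltr = list(_random_seq(rng, config.ltr_length, config.gc_content))
    ltr[0:2] = t5
    ltr[-2:] = "CA"
    ltr_anc = "".join(ltr)
    model_defaults = ElementModel()
    internal_len = config.element_length - 2 * config.ltr_length
    if internal_len < len(model_defaults.pbs_motif) + len(model_defaults.ppt_motif) + 20:
        raise ValueError("element_length too small for the internal region")
    filler = _random_seq(
        rng,
        internal_len - len(model_defaults.pbs_motif) - len(model_defaults.ppt_motif),
        config.gc_content,
    )
    internal_anc = model_defaults.pbs_motif + filler + model_defaults.ppt_motif
    model = ElementModel(
        family_name="SIM",
        ltr_consensus=ltr_anc,
        internal_consensus=internal_anc,
        expected_termini=(t5, "CA"),
    )

    elements = _build_elements(rng, config, model)
    n_total = len(elements)
    background = _random_seq(rng, config.genome_length, config.gc_content)
    if n_total == 0:
        return SimulationResult({config.chrom_name: background}, [], model, config)

    sites = _draw_sites(rng, config, n_total)
    order = rng.permutation(n_total)
    placed = sorted(zip(sites, (elements[int(j)] for j in order)), key=lambda t: t[0])

    parts = []
    truth: list[TruthRecord] = []
    prev = 0
    offset = 0
    tsd_len = config.tsd_length
    for idx, (site, (seq, cat, l5, l3, tsd, age)) in enumerate(placed):
        parts.append(background[prev:site])
        parts.append(tsd + seq + tsd)
        start0 = site + offset + tsd_len
        end0 = start0 + len(seq)

        def glob(iv):
            return (start0 + iv[0] + 1, start0 + iv[1]) if iv else None

        termini = f"{seq[:2]}..{seq[-2:]}" if len(seq) >= 4 else "??..??"
        if cat == "trunc_5del":
            termini = f"??..{seq[-2:]}"
        elif cat in ("trunc_3del",):
            termini = f"{seq[:2]}..??"
        elif cat == "trunc_bothdel":
            termini = "??..??"
        truth.append(
            TruthRecord(
                element_id=f"SIM_t{idx + 1:04d}",
                chrom=config.chrom_name,
                start=start0 + 1,
                end=end0,
                ltr5=glob(l5),
                ltr3=glob(l3),
                category=cat,
                termini=termini,
                tsd_seq=tsd,
                true_age=age,
                planted_seq=seq,
            )
        )
        prev = site
        offset += len(seq) + 2 * tsd_len
    parts.append(background[prev:])
    genome = {config.chrom_name: "".join(parts)}
    return SimulationResult(genome, truth, model, config)


@dataclass
class SisterResult:
    genome_a: dict[str, str]
    genome_b: dict[str, str]
    truth: list[TruthRecord]


def simulate_sister(
    genome_a: dict[str, str],
    truth: list[TruthRecord],
    split_time: float,
    shared_fraction: float,
    seed: int,
    r: float = 1.3e-8,
) -> SisterResult:
    """Derive a sister genome: retain a fraction of insertions, cleanly excise
    the rest (one TSD copy stays), then mutate BOTH genomes independently at
    per-site probability 1-exp(-r*T) so orthologous loci diverge by ~2rT."""
    if not (0.0 <= shared_fraction <= 1.0):
        raise ValueError("shared_fraction must be in [0,1]")
    rng = np.random.default_rng(seed)
    flags = rng.random(len(truth)) < shared_fraction
    tsd_len = len(truth[0].tsd_seq) if truth else 5

    new_truth: list[TruthRecord] = []
    genome_b: dict[str, str] = {}
    for chrom in genome_a:
        seq = genome_a[chrom]
        recs = sorted(
            ((i, t) for i, t in enumerate(truth) if t.chrom == chrom),
            key=lambda it: it[1].start,
        )
        parts = []
        prev = 0
        removed = 0
        for i, t in recs:
            shared = bool(flags[i])
            s0, e0 = t.start - 1, t.end
            if shared:
                nt = replace(
                    t,
                    shared=True,
                    b_chrom=chrom,
                    b_start=t.start - removed,
                    b_end=t.end - removed,
                )
            else:
                # excise element plus the downstream TSD copy
                parts.append(seq[prev : s0])
                prev = e0 + tsd_len
                removed += (e0 + tsd_len) - s0
                nt = replace(t, shared=False, b_chrom=None, b_start=None, b_end=None)
            new_truth.append(nt)
        parts.append(seq[prev:])
        genome_b[chrom] = "".join(parts)

    p = 1.0 - math.exp(-r * split_time)
    genome_a_mut = {c: mutate_sequence(s, p, rng) for c, s in genome_a.items()}
    genome_b_mut = {c: mutate_sequence(s, p, rng) for c, s in genome_b.items()}
    new_truth.sort(key=lambda t: (t.chrom, t.start))
    return SisterResult(genome_a_mut, genome_b_mut, new_truth)


def annotations_from_truth(truth: list[TruthRecord]) -> list[LtrElementAnnotation]:
    """Convert truth records to annotations (e.g. to feed downstream stages
    with a perfect mining oracle)."""
    out = []
    for t in truth:
        intactish = t.category.startswith("intact")
        out.append(
            LtrElementAnnotation(
                element_id=t.element_id,
                chrom=t.chrom,
                start=t.start,
                end=t.end,
                ltr5=t.ltr5,
                ltr3=t.ltr3,
                tsd_seq=t.tsd_seq if t.category.endswith("with_tsd") else None,
                termini=t.termini,
                category=t.category,
                strand="+",
                ltr5_coverage=1.0 if t.ltr5 else 0.0,
                ltr3_coverage=1.0 if t.ltr3 else 0.0,
                internal_present=intactish or t.category.startswith("trunc"),
            )
        )
    return out


# ---------------------------------------------------------------------------
# retrotransposition template rule (mutation propagation model)
# ---------------------------------------------------------------------------


@dataclass
class RetroLineageConfig:
    """Founder mutation + amplification settings for the template-rule model.

    The ancestor carries TG..CA termini; the default founder mutation turns
    the 'G' at LTR position 2 (inside U3) into 'A' on the chosen LTR.
    """

    seed: int = 0
    ltr_length: int = 194
    internal_length: int = 300
    u3_end_offset: int = 120
    gc_content: float = 0.36
    mutated_ltr: Literal["five_prime", "three_prime"] = "three_prime"
    mutation_position: int = 1  # 0-based within the LTR
    mutation_to: str = "A"
    generations: int = 3
    copies_per_generation: int = 5

    def __post_init__(self):
        if not (0 <= self.mutation_position < self.u3_end_offset):
            raise ValueError("mutation position must lie within the U3 region")
        if self.u3_end_offset >= self.ltr_length:
            raise ValueError("u3_end_offset must be < ltr_length")


@dataclass
class LineageElement:
    element_id: str
    parent_id: Optional[str]
    generation: int
    ltr5: str
    ltr3: str
    internal: str

    @property
    def termini(self) -> str:
        return f"{self.ltr5[:2]}..{self.ltr3[-2:]}"


def simulate_retro_lineage(config: RetroLineageConfig) -> list[LineageElement]:
    """Amplify a founder element under the retrotransposition template rule.

    Daughter U3 (both LTRs) is copied from the mother's 3'-LTR U3; daughter
    R+U5 (both LTRs) from the mother's 5'-LTR R+U5. Returns the founder plus
    all descendants, with genealogy via ``parent_id``.
    """
    rng = np.random.default_rng(config.seed)
    ltr = list(_random_seq(rng, config.ltr_length, config.gc_content))
    ltr[0:2] = "TG"
    ltr[-2:] = "CA"
    anc_ltr = "".join(ltr)
    internal = _random_seq(rng, config.internal_length, config.gc_content)

    def mutated(seq: str) -> str:
        s = list(seq)
        s[config.mutation_position] = config.mutation_to
        return "".join(s)

    if config.mutated_ltr == "three_prime":
        founder = LineageElement("gen0_0", None, 0, anc_ltr, mutated(anc_ltr), internal)
    else:
        founder = LineageElement("gen0_0", None, 0, mutated(anc_ltr), anc_ltr, internal)

    u3 = config.u3_end_offset
    population = [founder]
    current = [founder]
    for g in range(1, config.generations + 1):
        nxt = []
        for mother in current:
            for c in range(config.copies_per_generation):
                daughter_ltr = mother.ltr3[:u3] + mother.ltr5[u3:]
                nxt.append(
                    LineageElement(
                        element_id=f"gen{g}_{len(nxt)}",
                        parent_id=mother.element_id,
                        generation=g,
                        ltr5=daughter_ltr,
                        ltr3=daughter_ltr,
                        internal=mother.internal,
                    )
                )
        population.extend(nxt)
        current = nxt
    return population


def descendant_termini_fraction(population: list[LineageElement], termini: str) -> float:
    """Fraction of non-founder elements carrying the given 'XX..YY' termini."""
    desc = [e for e in population if e.generation > 0]
    if not desc:
        raise ValueError("no descendants in population")
    return sum(1 for e in desc if e.termini == termini) / len(desc)
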