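"""Molecular-clock dating of insertions, families and species splits.

An element's two LTRs are identical at insertion and then diverge
independently, so its insertion age is T = K/(2r) where K is the corrected
distance between its 5' and 3' LTRs and r the LTR substitution rate
(default 1.3e-8 substitutions/site/year). A family's age is T = K/r with K
the mean distance of member LTRs to the family's 50% majority consensus
(each lineage alone spans the time back to the common ancestor). Shared
orthologous LTRs between two genomes date the species split with T = K/(2r).
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import mean, median
from typing import Literal

from .errors import InsufficientDataError
from .miner import LtrElementAnnotation
from .seqcore import (
    AlignParams,
    global_align,
    k2p_distance,
    majority_consensus,
    star_align,
)

MY = 1_000_000.0


@dataclass(frozen=True)
class RateConstants:
    """Substitution rates in substitutions/site/year: ``r_ltr`` for LTRs,
    ``r_gene`` for synonymous sites of nuclear genes."""

    r_ltr: float = 1.3e-8
    r_gene: float = 6.03e-9

    def __post_init__(self):
        if self.r_ltr <= 0 or self.r_gene <= 0:
            raise ValueError("rates must be positive")


@dataclass
class AgeEstimate:
    element_id: str
    K: float
    T: float  # years
    mode: Literal["insertion", "locus_divergence", "generic"]
    indels: int = 0

    @property
    def mya(self) -> float:
        return round(self.T / MY, 2)


@dataclass
class FamilyAgeEstimate:
    family_name: str
    mean_K_to_consensus: float
    T: float
    n_elements: int

    @property
    def mya(self) -> float:
        return round(self.T / MY, 2)


@dataclass
class AgeHistogram:
    bin_width: float
    counts: list[int]
    fractions: list[float]

    def fraction_between(self, lo_years: float, hi_years: float) -> float:
        """Fraction of dated elements with lo <= age < hi (bin-aligned)."""
        total = sum(self.counts)
        if total == 0:
            return 0.0
        out = 0
        for k, c in enumerate(self.counts):
            b0 = k * self.bin_width
            if b0 >= lo_years and b0 < hi_years:
                out += c
        return out / total


def convert_divergence_to_time(d: float, r: float) -> float:
    """Convert a nucleotide divergence (substitutions/site) accumulated along
    both lineages since a split into years: T = d/(2r)."""
    if d < 0:
        raise ValueError("divergence must be >= 0")
    if r <= 0:
        raise ValueError("rate must be positive")
    return d / (2.0 * r)


def to_mya(years: float) -> float:
    """Years -> million years, rounded to 2 decimals (reporting convention)."""
    return round(years / MY, 2)


def _element_ltr_seqs(ann: LtrElementAnnotation, genome: dict[str, str]) -> tuple[str, str]:
    if ann.ltr5 is None or ann.ltr3 is None:
        raise InsufficientDataError(
            f"{ann.element_id}: both LTRs must be present and complete for dating"
        )
    seq = genome[ann.chrom]
    l5 = seq[ann.ltr5[0] - 1 : ann.ltr5[1]]
    l3 = seq[ann.ltr3[0] - 1 : ann.ltr3[1]]
    return l5, l3


def insertion_age(
    ann: LtrElementAnnotation,
    genome: dict[str, str],
    rates: RateConstants | None = None,
    distance_choice: Literal["k2p", "jc"] = "k2p",
    params: AlignParams | None = None,
) -> AgeEstimate:
    """Insertion age of one intact element from its 5' vs 3' LTR divergence.

    Indel events (gap openings in the LTR alignment) are counted but excluded
    from K; an element with identical LTRs but an indel still dates to T=0.
    """
    rates = rates or RateConstants()
    if not ann.category.startswith("intact"):
        raise InsufficientDataError(
            f"{ann.element_id}: insertion dating requires an intact element"
        )
    l5, l3 = _element_ltr_seqs(ann, genome)
    aln = global_align(l5, l3, params)
    dist = k2p_distance(aln)
    K = dist.k2p if distance_choice == "k2p" else dist.jc
    return AgeEstimate(
        element_id=ann.element_id,
        K=K,
        T=K / (2.0 * rates.r_ltr),
        mode="insertion",
        indels=aln.gap_openings,
    )


def family_age(
    annotations: list[LtrElementAnnotation],
    genome: dict[str, str],
    rates: RateConstants | None = None,
    family_name: str = "family",
    use: Literal["ltr", "element"] = "ltr",
    consensus_cutoff: float = 0.5,
    distance_choice: Literal["k2p", "jc"] = "k2p",
) -> FamilyAgeEstimate:
    """Family age from the mean distance of members to the family consensus.

    Member sequences (5' LTRs by default, whole elements optionally) are star-
    aligned against the longest member, a 50% majority consensus is built, and
    T = mean K / r.
    """
    rates = rates or RateConstants()
    intact = [a for a in annotations if a.category.startswith("intact")]
    if len(intact) < 3:
        raise InsufficientDataError("family dating requires >= 3 intact elements")
    seqs = []
    for a in intact:
        if use == "ltr":
            l5, _ = _element_ltr_seqs(a, genome)
            seqs.append(l5)
        else:
            seqs.append(genome[a.chrom][a.start - 1 : a.end])
    rows = star_align(seqs)
    cons = majority_consensus(rows, cutoff=consensus_cutoff).consensus
    ks = []
    for s in seqs:
        aln = global_align(s, cons)
        d = k2p_distance(aln)
        ks.append(d.k2p if distance_choice == "k2p" else d.jc)
    mk = mean(ks)
    return FamilyAgeEstimate(
        family_name=family_name,
        mean_K_to_consensus=mk,
        T=mk / rates.r_ltr,
        n_elements=len(intact),
    )


def species_divergence(
    pairs,
    rates: RateConstants | None = None,
    threshold_years: float = 500_000.0,
    distance_choice: Literal["k2p", "jc"] = "k2p",
) -> tuple[list[AgeEstimate], dict]:
    """Per-locus split-time estimates from orthologous LTR pairs, plus a
    summary (mean, median, fraction below ``threshold_years``)."""
    rates = rates or RateConstants()
    if not pairs:
        raise InsufficientDataError("no orthologous LTR pairs supplied")
    ages = []
    for p in pairs:
        K = p.distance.k2p if distance_choice == "k2p" else p.distance.jc
        ages.append(
            AgeEstimate(
                element_id=p.element_id,
                K=K,
                T=K / (2.0 * rates.r_ltr),
                mode="locus_divergence",
            )
        )
    ts = [a.T for a in ages]
    summary = {
        "n": len(ts),
        "mean_T": mean(ts),
        "median_T": median(ts),
        "fraction_below_threshold": sum(1 for t in ts if t < threshold_years) / len(ts),
        "threshold_years": threshold_years,
    }
    return ages, summary


def age_histogram(ages_years, bin_width: float = 250_000.0) -> AgeHistogram:
    """Half-open bins [k*w, (k+1)*w) over per-element ages."""
    ages = [float(a) for a in ages_years]
    if any(a < 0 for a in ages):
        raise ValueError("ages must be >= 0")
    if not ages:
        return AgeHistogram(bin_width, [], [])
    nbins = int(max(ages) // bin_width) + 1
    counts = [0] * nbins
    for a in ages:
        counts[int(a // bin_width)] += 1
    n = len(ages)
    return AgeHistogram(bin_width, counts, [c / n for c in counts])
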