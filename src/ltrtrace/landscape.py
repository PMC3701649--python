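"""Element density per genomic partition and a permutation enrichment test.

Partitions (euchromatin / heterochromatin / centromere) come from a BED file;
an element belongs to the partition containing its midpoint. Enrichment
between two partitions is tested against a null in which the same number of
insertions is re-placed uniformly at random over the union of the two
partitions (statistic: density difference in elements/Mb; one-sided p-value
with the (b+1)/(n+1) correction).
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import read_bed
from .miner import LtrElementAnnotation

MB = 1_000_000.0


@dataclass
class GenomePartition:
    """Named set of non-overlapping intervals (0-based half-open internally)."""

    name: str
    intervals: dict[str, list[tuple[int, int]]]
    total_length: int = 0

    def __post_init__(self):
        total = 0
        for chrom, ivs in self.intervals.items():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping intervals in partition {self.name} on {chrom}")
            total += sum(e - s for s, e in ivs)
        self.total_length = total
        if self.total_length <= 0:
            raise ValueError(f"partition {self.name} has zero length")

    def contains(self, chrom: str, pos0: int) -> bool:
        ivs = self.intervals.get(chrom)
        if not ivs:
            return False
        starts = [s for s, _ in ivs]
        i = bisect_right(starts, pos0) - 1
        return i >= 0 and ivs[i][0] <= pos0 < ivs[i][1]


def partitions_from_bed(path) -> dict[str, GenomePartition]:
    """Load partitions from BED; the name column selects the partition."""
    df = read_bed(path)
    out: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.name), {}).setdefault(row.chrom, []).append(
            (int(row.start), int(row.end))
        )
    return {name: GenomePartition(name, ivs) for name, ivs in out.items()}


def _midpoint0(ann: LtrElementAnnotation) -> int:
    s0, e0 = ann.span0
    return (s0 + e0) // 2


def partition_density(
    annotations: list[LtrElementAnnotation],
    partitions: list[GenomePartition],
) -> pd.DataFrame:
    """Per-partition element count and density (elements/Mb); elements whose
    midpoint falls in no partition are tallied as 'unassigned'."""
    counts = {p.name: 0 for p in partitions}
    unassigned = 0
    for ann in annotations:
        mid = _midpoint0(ann)
        for p in partitions:
            if p.contains(ann.chrom, mid):
                counts[p.name] += 1
                break
        else:
            unassigned += 1
    rows = []
    for p in partitions:
        rows.append(
            {
                "partition": p.name,
                "count": counts[p.name],
                "length_mb": p.total_length / MB,
                "per_mb": counts[p.name] / (p.total_length / MB),
            }
        )
    rows.append({"partition": "unassigned", "count": unassigned,
                 "length_mb": float("nan"), "per_mb": float("nan")})
    return pd.DataFrame(rows)


@dataclass
class EnrichmentResult:
    partition_a: str
    partition_b: str
    density_a: float
    density_b: float
    observed_statistic: float
    p_value: float
    n_permutations: int
    seed: int
    n_insertions: int = 0


def enrichment_test(
    annotations: list[LtrElementAnnotation],
    partition_a: GenomePartition,
    partition_b: GenomePartition,
    n_permutations: int = 9999,
    seed: int = 0,
) -> EnrichmentResult:
    """One-sided permutation test of density enrichment in A relative to B.

    Under the null, the n insertions falling in A or B are re-placed uniformly
    over the union of the two partitions; the statistic is the density
    difference (A - B) in elements/Mb.
    """
    if n_permutations < 999:
        raise ValueError("use >= 999 permutations")
    la, lb = partition_a.total_length, partition_b.total_length
    n_a = n_b = 0
    for ann in annotations:
        mid = _midpoint0(ann)
        if partition_a.contains(ann.chrom, mid):
            n_a += 1
        elif partition_b.contains(ann.chrom, mid):
            n_b += 1
    n = n_a + n_b
    dens_a = n_a / (la / MB)
    dens_b = n_b / (lb / MB)
    observed = dens_a - dens_b

    rng = np.random.default_rng(seed)
    pa = la / (la + lb)
    ka = rng.binomial(n, pa, size=n_permutations) if n > 0 else np.zeros(n_permutations)
    null = ka / (la / MB) - (n - ka) / (lb / MB)
    b = int(np.sum(null >= observed))
    p = (b + 1) / (n_permutations + 1)
    return EnrichmentResult(
        partition_a=partition_a.name,
        partition_b=partition_b.name,
        density_a=dens_a,
        density_b=dens_b,
        observed_statistic=observed,
        p_value=p,
        n_permutations=n_permutations,
        seed=seed,
        n_insertions=n,
    )
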