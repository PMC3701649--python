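# Methods

This note documents the models, algorithms, parameter choices and numerical
conventions behind `ltrtrace`, and what the simulation-backed tests do and do
not demonstrate about real data.

## Sequence primitives (`seqcore`)

Pairwise alignment is exact dynamic programming through
`Bio.Align.PairwiseAligner`: Needleman–Wunsch with affine gaps for DNA
(defaults match +1, mismatch −1, gap open −2, extend −1; the first gap
character costs the opening penalty) and Smith–Waterman with BLOSUM62
(open −11, extend −1) for protein searches. IUPAC ambiguity codes are accepted
but never score as matches, and columns containing a gap or an ambiguity code
are excluded from distance estimation. Ties among co-optimal alignments are
resolved by the aligner's deterministic enumeration order; all score-level
behaviour is verified against brute-force enumeration and an independent
Gotoh implementation in the test suite.

Distances: the Kimura 2-parameter distance
K = −½·ln[(1−2P−Q)·√(1−2Q)] over the comparable columns of one pairwise
alignment, with P and Q the transition and transversion proportions, raises a
saturation error when either logarithm argument is non-positive. The
Jukes–Cantor distance −¾·ln(1−4p/3) is always computed alongside; every dating
function takes a `distance_choice` switch because the two corrections coincide
only when transitions are one third of all changes. K2P is the default.

Consensus building uses a 50% majority rule per column: the most frequent
character wins (bases outrank the gap on ties, remaining ties break
alphabetically A<C<G<T), winning gaps drop the column, and winners below the
cutoff emit `N`. Multiple alignments are star alignments projected onto the
longest member — insertions relative to the reference are discarded. This is
deliberate: family members here are short (~194 bp LTRs, RT-domain cDNAs) and
>85% identical, where a star alignment is essentially exact and fully
deterministic; it is not a general-purpose progressive MSA.

## Element mining (`miner`)

Intact elements are found structurally. Shared 16-mers seed candidate pairs
of direct repeats whose spacing is compatible with the configured element and
LTR length ranges (defaults 1,000–15,000 bp and 100–1,000 bp, bracketing a
~4.7-kb element with 194-bp LTRs); seed pairs chain by common spacing, the
repeat is extended by X-drop comparison (+1/−2, drop 8), and boundaries are
refined by searching ±25 bp for a perfect 5-bp TSD. Because a chance 5-mer
pairing inside that window occurs at an appreciable rate, TSD candidates must
also agree with the repeat structure itself (≥9 of 12 positions at the two
boundaries must continue the direct repeat); this anchoring is what makes
zero-age recall exact. Candidates keep observed termini, PBS/PPT motif flags
(≤2 mismatches within 20 bp of the inner LTR edges; reversed motifs flip the
strand call) and the LTR-pair identity (threshold 0.85). Overlapping
candidates resolve greedily, preferring TSD support, then motif support, then
identity — which also eliminates the LTR-to-LTR pairings between *different*
nearby copies of a young family.

Solo LTRs, truncated copies and structurally missed intact elements are then
recovered by homology: 12-mer seeds against the family LTR and internal
consensus on both strands, diagonal chaining (split at query gaps >120 bp so a
stray seed cannot stretch a hit), ungapped X-drop extension, and thresholds of
80% identity over ≥50 bp. Hits within 50 bp merge into elements and are
classified by a total, deterministic mapping from (5′-LTR state, 3′-LTR state,
internal presence, TSD) to the seven structural categories; an LTR end counts
as *complete* at ≥95% consensus coverage, and internal-free clusters with two
complete LTRs (tandem solos) are flagged `unresolved` and excluded from
summaries. The solo:intact ratio is reported against intact-with-TSD counts by
default, with the all-intact denominator available as an option.

All in-memory coordinates are 0-based half-open; every report, GFF3 and TSV is
1-based inclusive.

## Junction sharing (`sharing`)

Each element whose LTR is complete on a side, and whose flank is not cut by a
contig edge, yields a 100-bp marker there: 50 bp flank + 50 bp element
terminal. Elements without TSDs are excluded from comparative analysis by
default (they have typically been rearranged). Markers are searched in the
target assembly by exact 16-mer seeds clustered by diagonal; a cluster is only
aligned if it has seed support on both marker halves, which a TE-body-only
match cannot produce. Candidate windows are locally aligned (match +1,
mismatch −2, open −4, extend −1) and a hit passes at identity ≥0.90 over ≥80
aligned bp with ≥10 bp aligned on each side of the junction. Any passing
marker calls the insertion *shared*; more than 5 passing loci flags a
repetitive flank and demotes the call to *unresolved* (the analysis assumes
insertion sites are unique). The criterion is monotone: loosening thresholds
can only add passing hits.

For a shared insertion, the passing hit maps the junction coordinate into the
target, the adjacent LTR is sliced there, globally aligned to the source LTR,
and the K2P distance dates the locus (T = K/2r). Loci whose LTR cannot be
recovered (e.g. scaffold edge) are omitted.

## Chronology (`chronology`)

Rates: r_LTR = 1.3×10⁻⁸ and r_gene = 6.03×10⁻⁹ substitutions/site/year.
Insertion age uses only the element's own 5′ vs 3′ LTR; indel events in that
alignment are counted and reported but never contribute to K, so an element
with identical LTRs apart from an indel still dates to zero. Family age
star-aligns member 5′ LTRs (whole elements optionally), builds the 50%
consensus and divides the mean member-to-consensus K by r (one lineage alone
spans the time back to the ancestor, hence no factor 2). Divergence-to-time
conversion is T = d/(2r) with million-year values printed to 2 decimals. Age
histograms use half-open bins of 250,000 years by default (matching the
quarter-My resolution at which amplification activity is usually reported).

With 194-bp LTRs the per-element clock is noisy: at a true age of 1 My the
per-element standard deviation of T is ~0.46 My, so all recovery statements
are about means (mean of 100 elements: ~4.6% standard error). This matches the
broad spread seen in real single-family age spectra.

## Phylogeny (`phylogeny`)

The RT (reverse transcriptase) domain is located by aligning a conserved RT
protein query against all six reading frames of an element's internal region;
the best local alignment is accepted at a raw score ≥55 (BLOSUM62) — a
deterministic stand-in for an E-value threshold, playing the same
accept/reject role — and the aligned span is back-projected to an in-frame
cDNA (reverse frames report reverse-complemented cDNA and original-strand
coordinates). Elements lacking a recognizable RT are excluded, mirroring
incomplete copies missing pol genes.

Neighbor joining is the canonical Saitou–Nei algorithm, implemented directly
(Q-criterion, strict-improvement selection so ties break on the first pair in
id order, negative branch estimates clamped to zero) and returned as an
unrooted `skbio.TreeNode` with a trifurcating root. On additive matrices it
recovers topology and every branch length exactly; the test suite checks this
against randomly generated trees and cross-checks the topology against
scikit-bio's independent implementation. Bootstrap support resamples the
columns of a star alignment of the RT cDNAs (pairwise K2P per replicate;
saturated pairs are capped at distance 10), rebuilds the tree per replicate,
and labels each internal edge with its bipartition frequency ×100. All
resampling flows from a single integer seed and is bit-reproducible.

## Genomic landscape (`landscape`)

Partitions (e.g. euchromatin / heterochromatin / centromere) load from BED,
must be internally non-overlapping, and need not cover the genome; an element
belongs to the partition containing its midpoint, with a visible `unassigned`
bucket. Enrichment of partition A over B is a one-sided permutation test: the
insertions falling in A∪B are re-placed uniformly over the union's length
(equivalently, the A-count is binomial with p = |A|/|A∪B|), the statistic is
the density difference in elements/Mb, and the p-value uses the (b+1)/(n+1)
correction, so it is never zero and is valid at the resolution of the
permutation count (default 9,999). No specific parametric test is claimed —
the choice is an assumption-free match to the density framing; the null is
exact under uniform placement and calibration is verified by simulation.

## Synthetic genomes (`simulate`)

The generator is first-class code: it defines the conditions under which every
other module is measured. A background of i.i.d. bases at 36% GC (a plant
euchromatin-like value) hosts insertions placed uniformly (optionally
weighted by regions) with a minimum spacing of 300 bp via an order-statistics
construction, each flanked by a perfect 5-bp TSD. The family ancestor is a
random 194-bp LTR with fixed termini (TA..CA by default) plus an internal
region carrying the PBS/PPT motifs, ~4.7 kb in total. An element of age *a*
in a family founded *B* years ago receives substitutions in two stages —
lineage (B−a years) applied to its single pre-insertion LTR copy, then *a*
years independently on each of its two LTRs — so LTR-pair divergence is 2ra
while divergence from the ancestor is rB, exactly the quantities the two
clocks estimate. Mutations are Jukes–Cantor moves at per-site probability
1−exp(−r·t); there are no indels in this model (the one published 14-bp indel
case is covered by a hand-built fixture in the tests). Defaults mirror the
study conditions: ages uniform on 0.75–1.75 My, family born 1.75 My ago,
r = 1.3×10⁻⁸, sister split 0.28 My with 83% of insertions retained.

The sister genome keeps each insertion with the configured probability,
excises the others cleanly leaving one TSD copy, and then both genomes mutate
independently for the split time, so orthologous divergence is ≈2rT genome
wide. Because genome A itself mutates in this step, analyses downstream of a
sister simulation date from truth-derived annotations; pre-split genomes
guarantee that slicing at truth coordinates reproduces planted sequences
byte-for-byte.

`simulate_retro_lineage` implements the retrotransposition template rule: a
daughter's U3 (both LTRs) copies from the mother's 3′-LTR U3 and its R+U5 from
the mother's 5′-LTR R+U5 (U3/R boundary at LTR offset 120 by fixture
convention, not as a biological claim). A founder G→A at LTR position 2 of the
3′ LTR therefore yields 100% TA..CA descendants; the same mutation in the 5′
LTR yields none — the discriminating prediction between the two origin
hypotheses for a TA-terminal family.

What passing these simulations does **not** show: robustness to indels and
nested insertions, to assembly gaps and collapsed repeats, to GC/composition
heterogeneity, or to genuinely diverged (sub)families — the generator plants a
single family with substitution-only evolution. Mining thresholds transfer to
real assemblies as starting points, not guarantees.

## Pipeline (`cli`)

The `ltrtrace` command chains the stages over plain-text artifacts (FASTA,
BED, GFF3, TSV, Newick) in one output directory; `all` runs
mine→classify→share→date→family-age→divergence→phylo→density. Every TSV embeds
the configuration hash and seed as header comments, stages validate their
upstream inputs and name the producing subcommand when a file is missing, and
re-runs with the same inputs are byte-identical.

## Problem sizes and determinism

The test and acceptance workloads use 2–3-Mb genomes with 200–300 planted
insertions, 100-element dating cohorts repeated over ten seeds, 150-member
family cohorts, and 30-replicate tree/oracle checks — sizes at which every
Monte-Carlo bound holds with a margin of several standard errors while the
whole suite stays fast on a single CPU. All randomness everywhere descends
from explicit integer seeds; identical configurations produce byte-identical
outputs.

## Known limitations

* Substitution-only evolution: no indels, nested insertions or segmental
  events in v1; gap handling in distances is tested via hand-built fixtures.
* Star alignments discard insertions relative to the reference; with long or
  highly diverged members a true MSA would be preferable.
* The raw-score RT threshold is not an E-value; it was chosen for the fixture
  query scale and should be recalibrated for other queries.
* The enrichment null assumes insertions are exchangeable across the two
  partitions' union; recombination-rate or composition covariates are out of
  scope.
* Solo LTRs are planted, not generated by unequal recombination, so solo/intact
  ratios in simulations reflect configuration, not mechanism.
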