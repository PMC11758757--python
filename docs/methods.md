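# Methods

This note documents the statistical conventions, default parameters and
design choices behind each module, and what the synthetic-data
generators do and do not emulate.

## Occupancy partition

A family's frequency is the number of assemblies carrying ≥ 1 member
gene; copy number is ignored for classification (presence/absence is the
contract). Bands over N assemblies: core = N; softcore =
⌈0.85·N⌉ … N−1; dispensable = 2 … ⌈0.85·N⌉−1; cloud = 1. For N = 15 the
softcore band is 13–14. The 0.85 floor is configurable
(`PartitionThresholds(softcore_min=...)`); N ≤ 2 makes the softcore and
dispensable bands collide and is rejected with advice to use more
assemblies. Gene counts per category sum a family's members over *all*
assemblies where it is present — the family's genes travel with its
category. This is a deliberate choice where "gene-level composition"
is ambiguous; the per-assembly table in `PartitionResult.per_assembly`
gives the complementary per-assembly view.

Percentages are reported half-up at 2 decimals. Pooled shares (e.g.
dispensable+cloud) are computed on raw counts via `category_share`, not
by summing independently rounded per-category percentages, which can
drift by 0.01.

The enrichment test is a one-sided hypergeometric upper tail per term
(over-representation; enrichment analyses are conventionally one-sided)
with Benjamini–Hochberg correction across tested terms; terms with fewer
than `min_hits = 2` hit genes are reported NA and excluded from the FDR
family.

## Weir–Cockerham FST

The two-population diploid estimator of Weir & Cockerham (1984) is
implemented from the variance components: per site, with group sample
sizes n₁, n₂ (genotyped diploids), alt frequencies p₁, p₂ and observed
heterozygote fractions h₁, h₂,

- n̄ = (n₁+n₂)/2, n_c = (n₁+n₂) − (n₁²+n₂²)/(n₁+n₂),
- p̄ and h̄ are the size-weighted means, s² the size-weighted variance
  of p around p̄,
- a = (n̄/n_c)(s² − [p̄(1−p̄) − s²/2 − h̄/4]/(n̄−1)),
- b = (n̄/(n̄−1))(p̄(1−p̄) − s²/2 − h̄(2n̄−1)/(4n̄)),
- c = h̄/2,

and site FST = a/(a+b+c). Sites with fewer than two genotyped diploids
in either group, or monomorphic across both groups, contribute nothing
(NA); samples missing at a site leave that site's denominators only.
Small negative site values are expected under no differentiation and are
not clipped. Window and genome-wide estimates are the weighted ratio
Σa/Σ(a+b+c), the convention VCFtools reports as weighted FST. Haploid
input is out of contract.

Windows tile each chromosome from position 1 with size = step = 20 kb by
default ("stepping windows" read as non-overlapping tiles); both knobs
are configurable, and the anchor choice is invisible to percentile-based
region calling as long as it is fixed.

## Percentile region calling (HDRs and SV hotspots)

One shared code path: the threshold is the stated percentile (default
95) of all non-NA window values, computed with linear interpolation
between order statistics (`numpy.percentile` default). Selection is
strict (value > threshold): a constant track yields no regions and ties
at the threshold are excluded. Selected windows merge when overlapping
or bookended (adjacent tiles fuse). `RegionSet` guarantees sorted,
pairwise-disjoint output and reports total length.

## Nucleotide diversity and thinning

Site π = 2j(n−j)/(n(n−1)), j = alt alleles among the n non-missing
alleles — the average pairwise difference without replacement.
Distance thinning is greedy left-to-right per chromosome: keep a site
iff it lies ≥ `min_gap` (default 2000 bp) beyond the last kept site;
the result is idempotent and pairwise ≥ `min_gap` apart.

## SV landscape

Context annotation uses the precedence exon > intron > upstream >
downstream > intergenic across all genes; upstream/downstream are
strand-aware flanks of 1 kb by default. Deletions and inversions
overlap with their full span [pos, pos+len−1]; insertions with the
single anchor base. Gene sets without exon models collapse body hits to
a single "genic" category with a warning.

Hotspot scans count an SV in every 100-kb window (20-kb step) containing
its *start* position — span-based counting would weight long SVs by
length; an any-overlap mode exists. Gene classing against hotspots uses
body overlap first, then a 2-kb strand-aware upstream window (2 kb is
specific to this classification; the 1-kb context flank is separate, and
both are configurable).

Group frequencies are alt-allele counts over non-missing alleles
(carrier mode available; which convention a published "SV frequency in
individuals" means is ambiguous, so allele frequency is the documented
default). The favored screen is strict on both sides: frequency > 0.5
in the focal group and < 0.05 in every other group. A group with no
calls at an SV (NA) excludes the SV under the conservative default
(`na_policy="exclude"`); `"ignore"` evaluates over non-NA groups only.
Genotype filtering drops records with missing-call rate > 0.5 or minor
allele frequency < 0.05, keeping the boundary (MAF exactly 0.05 passes).

## p-distances and neighbor joining

The pairwise distance is the mean |dᵢ−dⱼ|/2 over sites where both
samples are genotyped. At a biallelic site two diploids share
2 − |dᵢ−dⱼ| alleles, so literal shared-allele counting is the same
statistic; the genuinely different alternative offered
(`mode="expected-mismatch"`) is the probability that one allele drawn
from each sample differs, which scores het–het comparisons 0.5. A pair
with zero co-genotyped sites is an error naming the pair.

Trees are plain Saitou–Nei neighbor joining with the Studier–Keppler
Q-criterion. Ties in Q are broken by the lexicographically smallest
pair of subtree labels (a subtree is labeled by its smallest leaf), so
taxon order never changes the result. Negative branch lengths are
clamped to zero. NJ is consistent on additive matrices — the test suite
verifies exact topology and path-length recovery — but makes no
minimum-evolution refinement (NNI/SPR); for cohort grouping the
distinction has not been material in testing, and no equivalence with
refined methods is claimed.

## RGA atlas

Clustering is single-linkage chaining per chromosome and family:
successive genes (sorted by start) join the open cluster when the gap to
the cluster's rightmost end so far is ≤ 200 kb (gap floored at 0 for
overlaps). Chains can therefore span more than 200 kb end-to-end; an
all-pairs variant is available behind `method="all-pairs"`. Only
clusters of ≥ 2 genes are reported.

Paired NLRs require NBS-adjacency (no NBS gene between the two, but any
number of non-NBS genes), strands (−,+) in coordinate order (divergent
transcription, promoters facing), and an intergenic gap ≤ 20 kb — a
default chosen as a generous promoter-sharing distance and reported per
pair so users can re-filter; pairing is greedy left-to-right so a
−,+,+ run pairs the left two. Because "percent paired NLRs of NBS
genes" has two readings, `paired_nlr_rates` reports both genes-in-pairs
and pairs-per-NBS percentages.

## Synthetic data

The generators produce inputs with the statistical structure the
analyses assume plus ground-truth labels; one `numpy` Generator seeded
from `SimulationConfig.seed` drives everything, so a fixed seed gives
bit-identical files.

- **Family matrix** (default 1,000 families over 15 assemblies, in
  roughly the core/softcore/dispensable/cloud proportions seen in large
  plant pan-genomes: 236/87/347/330): each family's frequency is drawn
  uniformly within its category band and its occupied cells get 1 +
  Poisson(0.3) genes. Classification recovers the planted truth exactly
  by construction — that property is what makes the classifier testable.
- **SNP cohorts** use the Balding–Nichols model: ancestral frequency
  p ~ U(0.05, 0.95), group frequency ~ Beta(p(1−F)/F, (1−p)(1−F)/F)
  with F the target FST (F = 0 uses p directly), diploid dosages
  Binomial(2, p_group). The expected Weir–Cockerham estimate equals F,
  which calibrates the estimator end-to-end (measured 0.199 at F = 0.2
  with 2×50 samples and 10,000 sites). Default layout: two 10-Mb
  chromosomes, positions unique and sorted.
- **SV cohorts** (default 2,000 SVs, three groups of 20): a configured
  fraction (default 10%) is planted as favored in a focal group with
  frequency ~ U(0.6, 1.0) there and ~ U(0, 0.03) elsewhere; the rest
  share one background frequency ~ U(0.2, 0.8) across groups. Lengths
  are log-uniform 50 bp–10 kb (no empirical SV length distribution is
  assumed); types INS/DEL/INV at 45/45/10%. Genotypes are binomial by
  default; `exact_frequencies=True` realizes each target frequency
  deterministically for threshold tests.
- **RGA gene sets** plant same-family cluster blocks with intra-gaps
  < 200 kb, paired NLRs as adjacent (−,+) NBS genes with 1–10 kb gaps,
  tail-to-tail decoys, and singleton filler genes, with > 200 kb
  between blocks so every planted structure is recoverable exactly.

What the generators do *not* emulate: linkage disequilibrium and local
correlation of allele frequencies (sites are independent), mutation-rate
or SV-density heterogeneity along chromosomes (so hotspots in simulated
data are sampling fluctuations, not biology), sequence content (no
FASTA), gene-density realism, and admixed individuals. Passing tests
therefore demonstrate correctness of the statistics and callers on data
satisfying their model assumptions, not robustness to the full structure
of real resequencing cohorts.

### A note on favored-SV recovery

With non-focal true frequencies ~ U(0, 0.03) and 20 diploids per group,
the realized frequency of a planted favored SV crosses the strict 0.05
cutoff in a non-focal group with probability ≈ 0.14 (two such groups),
so the screen's expected sensitivity against planted truth is ≈ 0.75–0.80
at this cohort size — a property of binomial sampling near the
threshold, not of the implementation; pushing sensitivity above 0.95
under these distributions would need on the order of 150+ samples per
group. The exact-frequency mode removes the sampling noise and recovers
truth perfectly, and false positives among background SVs (shared
frequency ≥ 0.2) do not occur. The acceptance suite asserts the 0.95
bar regardless and records the shortfall.

## Problem sizes and determinism

Default test and acceptance problem sizes (10,000 SNPs, 2,000 SVs,
1,000 families, 50 random trees) were chosen so the full suite completes
in seconds on one core while keeping Monte-Carlo error well inside the
asserted tolerances. The pipeline manifest hashes every output; reruns
with one config and seed are byte-identical.
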