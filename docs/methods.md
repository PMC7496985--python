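# Methods

This note documents the statistical models, estimator conventions and
design choices behind `introscan`, and what the synthetic panels do and
do not emulate.

## Data model and coordinates

Genotypes are diploid biallelic SNP calls stored as alternate-allele
dosages 0/1/2 with −1 for missing. VCF positions are 1-based; every
internal window and BED output is 0-based half-open, and a site at
position *p* belongs to window [start, end) iff start ≤ p−1 < end.
Heterozygous calls contribute one allele copy everywhere (allele counts,
distances, frequencies); no phasing or imputation is performed, and
missing calls simply drop out of per-site called-allele counts.

## Fixed interspecific SNPs

A site is a fixed interspecific difference when species A is (near-)fixed
for one allele and species B for the other. The rule is fractional —
alt<sub>A</sub>/called<sub>A</sub> < 6/318 and
alt<sub>B</sub>/called<sub>B</sub> > 134/140 — the proportions implied by
the absolute count thresholds commonly used on panels of 159+70
accessions; absolute thresholds can be supplied instead. Because ref/alt
polarity is arbitrary, the mirrored orientation is always evaluated too
and recorded. Sites with no called genotype in either species are never
flagged.

## F<sub>ST</sub> and diversity

Weir & Cockerham (1984) per-site variance components a (among
populations), b (between individuals within populations) and c (within
individuals) are computed from called diploid counts, allele frequencies
and observed heterozygosities; the reported window/genome value is the
weighted ratio Σa/Σ(a+b+c), with the mean of per-site ratios also
emitted (the two quantities vcftools prints). The Hudson estimate is the
plug-in ratio of sums with numerator (p₁−p₂)² and denominator
p₁(1−p₂)+p₂(1−p₁); in this form two identical panels give exactly 0 and
a fixed difference exactly 1, while the nearly unbiased WC value remains
the headline number. Sites with fewer than two called genotypes or a
group call rate below 50% are excluded — the call-rate floor avoids
unstable variance components at heavily missing sites.

The masking contrast recomputes genome-wide weighted F<sub>ST</sub>
using only sites outside the called introgression intervals. Since
introgressed haplotypes are, by construction, other-species-like, they
depress apparent divergence; excluding them must raise the estimate, and
this direction is asserted on every simulated replicate.

Per-site nucleotide diversity uses the unbiased estimator
2·alt·(called−alt)/(called·(called−1)); window π is the sum of per-site
values divided by window length in bp (a per-bp convention, recorded as
such), and SNP density is variants per kb.

## Three-population f3

For target C and sources A, B the per-site term is
(ĉ−â)(ĉ−b̂) − ĉ(1−ĉ)/(n<sub>C</sub>−1), with sample allele frequencies
and n<sub>C</sub> the called allele copies in the target; the correction
removes the target's finite-sample heterozygosity bias (sources need no
correction in the product form). Sites require at least two called
genotypes per group. The estimate is the plain mean of terms; its
standard error comes from a weighted delete-one block jackknife over
contiguous blocks (default 5 Mb), using the Busing-style weighting by
block site counts, and Z = f3/SE. A target that is a mixture of the two
sources drives f3 negative; |Z| ≥ 3 is reported as admixture evidence.
Which group is "the" admixed target is not prejudged: both orderings
with the race group as one source are run and reported.

## Window-tree introgression scan

Per non-overlapping 1-Mb window (the window naming convention follows
chromosome~Mb):

1. Count fixed interspecific SNPs in the window. A window is
   *assessable* when that count reaches `min_fixed` (default 20) — the
   operationalization of a "significantly divergent region" in which
   clade intrusion is interpretable. Introgression carriers themselves
   erode near-fixation fractions (three other-species-like accessions
   among thirty push the alt fraction from 1.0 to 0.9, under the
   134/140 bar), so the gate is **two-pass**: if the plain count falls
   short, the window tree is built anyway, intruders are identified, and
   fixed SNPs are recounted with the intruders excluded. A genuinely
   undifferentiated window fails both passes and stays uncalled.
2. Build a neighbor-joining tree (Saitou–Nei; Q-ties broken by lowest
   index pair, deterministic) over the two species' accessions from
   allele-sharing distances d(i,j) = mean |dose<sub>i</sub> −
   dose<sub>j</sub>|/2 across sites called in both. Negative branch
   lengths are kept internally and clamped to 0 for patristic distances
   and Newick output.
3. Flag intruders with a k-nearest-leaf rule (k = 5, ties by label): an
   accession is an intruder when more than half of its k nearest leaves
   by patristic distance belong to the other species. The rule runs in
   two rounds — after the first pass, every accession is re-evaluated
   against the non-intruding core only. Without the second round, an
   accession sitting next to several *carriers* of the other species
   (whose haplotypes are donor-like and hence cluster with the
   accession's own species) would be spuriously flagged in the opposite
   direction.
4. The window call is A→B when only B accessions intrude (they carry
   A-like haplotypes), B→A when only A accessions intrude, bidirectional
   when both.

Runs of genomically adjacent windows called in the same direction merge
into **loci** (bidirectional windows join runs of both directions); a
locus's carriers are the accessions flagged in at least half of its
windows, and carrier-less candidates are dropped. Same-chromosome,
same-direction loci whose gap is at most the **LD-decay distance** merge
into **events** named `B_INT<k>`/`A_INT<k>` (recipient species, ordered
by chromosome then start). The LD-decay distance — the midpoint of the
first distance bin whose mean dosage-r² falls below half the maximum —
is measured within the recipient panel on sites polymorphic there; in
introgressed panels the dominant LD is carrier-generated and halves
around half a window, giving a merge radius below one window. When the
decay point is undefined the radius falls back to 5 Mb.

## Trait genetics

**BLUP.** For each trait, y<sub>ij</sub> = env<sub>j</sub> (fixed) +
g<sub>i</sub> (random, σ²g) + ε (σ²e). Variance components are estimated
by EM-REML (updates σ² ← σ² + σ⁴/k·[yᵀPAᵢPy − tr(PAᵢ)]), iterated to a
relative change below 1e-8 (max 500 iterations, non-convergence flagged
and the last iterate returned); all linear algebra uses the Woodbury
identity on the accession grouping, so fits are O(N) per iteration. The
implementation agrees with R lme4's REML fit to ~5 decimal places on an
unbalanced test set. BLUPs are σ²g·Zᵀ P y, which on balanced data
reduces to the textbook shrinkage n σ²g/(n σ²g + σ²e) of env-adjusted
accession mean deviations; they sum to ≈ 0 per trait.

**Trend test.** OLS of a trait on the per-accession introgression locus
count; slope, SE, and the two-sided t-test p. Zero count variance is a
flagged degenerate result, not a p-value.

**Per-locus contrasts.** Carrier vs non-carrier two-sample t-tests per
locus × trait × environment (Welch by default for unequal group sizes;
Student available for fidelity with older practice), with
Benjamini–Hochberg FDR per trait reported alongside raw p. A locus is a
**stable effective locus** when some single trait is significant (raw
p < 0.05) with a consistent effect sign in at least `min_envs`
environments. The default is `min_envs = 3`: with nine traits and six
environments, two supporting environments would admit ≈0.9 chance calls
per panel, whereas three keeps the familywise false-call probability
near 4% while a 0.5 SD effect with adequately many carriers is still
detected essentially always.

**Marker scan.** Per SNP passing the minor-allele-frequency filter
(MAF ≥ 0.05), OLS of the phenotype (typically the BLUP) on dosage plus
the top 3 principal components of the centered, mean-imputed dosage
matrix, reported as −log₁₀ p with a Bonferroni threshold over tested
SNPs. This is a deliberate simplification of a kinship mixed model: the
PCs absorb population structure but no polygenic random effect is
fitted, which costs some power when structure aligns with the causal
carrier axis.

**Interval overlap.** Half-open overlap (max(starts) < min(ends)) with
overlap length and reciprocal fractions, for relating events to external
QTL and selective-sweep interval lists.

## Synthetic panels

The simulator is frequency-replacement, not coalescent. Sites are
classified fixed interspecific (probability `p_fixed`, default 0.55),
private to one species, or shared (11% of non-fixed), with minor allele
frequencies from a clipped Beta(0.8, 4); ref/alt polarity is randomized.
Genotypes are binomial draws from the species frequencies. The race
group draws from Balding–Nichols beta-perturbed species-A frequencies
with drift F = 0.5, which yields a realized A-vs-race F<sub>ST</sub>
near 0.21 (only A-polymorphic sites drift, hence F is about twice the
realized value). Introgression is planted by redrawing carrier calls
inside a window from the donor species' frequencies; calls outside the
window are untouched. Trait values are species baseline + Σ locus
effects × carrier indicator + environment offset + Gaussian residual,
with effects in trait-SD units. All randomness flows from one root seed
through named substreams (`SeedSequence([seed, crc32(label)])`), so
stage order cannot change results.

The **cotton panel preset** uses 5 chromosomes × 7 Mb at 1 SNP/kb with
60 + 30 + 10 accessions, and plants 17 A→B plus 7 B→A events (5–9
carriers each) including one bidirectional window on A01, arranged so no
two same-direction events occupy adjacent windows — at 1-Mb scan
resolution, adjacent same-direction windows are indistinguishable from a
single longer locus, and 7 Mb is the smallest chromosome size that hosts
this many separable events. Eight loci carry 1 SD effects on two traits
each (yield traits for segments into B, fibre-quality traits for
segments into A): with only a handful of carriers per event, smaller
effects would be statistically invisible at these panel sizes.

What the simulator does **not** emulate: within-window linkage beyond
shared donor ancestry (sites are independent given the frequencies),
recombination breakpoints inside windows, selection, genotyping error
beyond uniform missingness, and relatedness structure within species.
Passing recovery tests therefore demonstrates the estimators and the
calling logic under realistic differentiation and noise levels — not
robustness to LD confounding or pedigree structure in real panels.

## Problem sizes and numerical conventions

Tests and the acceptance script run the cotton panel preset (35,000 sites,
100 accessions) over 20 seeds for recovery and false-positive checks, 50
seeds for BLUP and stability recovery, 1,000 replicates for trend-test
calibration, and 200 permutations for the marker-scan null; these sizes
give stable pass/fail margins at desk scale. Degenerate inputs are
handled explicitly: monomorphic LD pairs are NaN (undefined, not 0),
windows without usable SNPs are omitted from F<sub>ST</sub> output,
masks covering every site are errors, and variance components are
floored at 1e-10. Output tables are written with a fixed float format so
identical seeds produce byte-identical files.

## Known limitations

Event/locus merging depends on a single LD-derived radius; real panels
with long admixture LD may need an explicit `merge_distance`. The
intrusion rule judges each window independently — segments shorter than
half a window dilute below the k-NN majority and are missed (a window
resolution limit, as for any windowed scan). The marker scan is not a
substitute for a kinship LMM on strongly structured panels. The f3 Z
depends on the number of jackknife blocks; small genomes give few blocks
and conservative standard errors.
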