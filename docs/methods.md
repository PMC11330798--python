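# Methods

This note records the models, algorithmic choices and their rationale,
the synthetic-data design, and the known limitations of the package.

## Pedigree model

A pedigree is stored topologically sorted (parents before offspring)
with integer parent indices, so every recursion below is a single
forward or backward array pass. Missing parents truncate all ancestor
paths through them; an id that appears only as a parent is materialised
as a founder with missing metadata and counts as a known ancestor of
depth 1. Cycles and sex conflicts (an id used as both sire and dam, a
recorded female used as a sire) are hard load-time errors.

Three pedigree-depth measures are computed per animal: maximum
generations (distance to the furthest known ancestor), complete
generations (`complete(i) = 1 + min(complete(sire), complete(dam))`,
zero when a parent is unknown), and equivalent complete generations
`t_i = Σ (1/2)^n` over all known ancestors — the expected fraction of
the genome covered by the recorded pedigree, computed by the recursion
`t_i = Σ_parents (1 + t_p)/2` and verified against explicit path
enumeration in the tests. Population summaries can average over all
animals or over non-founders only (the choice matters for ragged real
pedigrees; both are exposed).

The generation interval uses the four parent–offspring sex paths;
the overall mean is computed over all retained parent–offspring pairs,
which equals the path means weighted by their pair counts.

## Inbreeding, coancestry, average relatedness

F is computed by the Meuwissen–Luo indirect algorithm: for each animal,
the L-coefficients of its ancestors are accumulated youngest-first and
F is the corresponding diagonal of the numerator relationship matrix A
minus one, using the within-family segregation variances
D_j = 0.5 − 0.25(F_s + F_d) (0.75 − 0.25F for one known parent, 1 for
founders). Animals sharing both parents share F and are computed once.
Results match Wright's path-counting oracle and the dense tabular A
diagonal to < 1e−12 on random pedigrees up to 500 animals; the 1e−12
tolerance covers summation-order effects only, as the arithmetic is
dyadic-rational.

Coancestry for a subset is the tabular method restricted to the
subset's ancestor closure (memory O(closure²), never O(n²) for the
whole pedigree). Average relatedness — the row mean of A, i.e. twice
the mean coancestry of an animal with the whole pedigree including
itself — uses A = (I−P)⁻¹ D (I−P)⁻ᵀ, where P carries the half
contributions of parents: a backward solve accumulates each animal's
long-term contribution weight, a forward solve maps D times that weight
back through descent. This makes the whole-pedigree AR vector O(n).
The pedigree summary reports whether mean F exceeds half of mean AR,
the conventional diagnostic that matings occurred among relatives; it
is reported verbatim, without further interpretation.

ΔF per generation uses (F_t − F_{t−1})/(1 − F_{t−1}) over cohorts
(birth years, or windows of one generation interval, default 3.1 years
in the bundled config), with a linear regression of ΔF on cohort index
to test for acceleration.

## Probability of gene origin

Founder contributions propagate reference weights up the pedigree; the
fraction entering a missing-parent slot is attributed to the animal
itself as a phantom founder (pooled per animal by default; a mode with
one phantom per unknown-parent slot is provided, because reference
software differs on this point). f_e = 1/Σq_k².

Effective ancestors use the greedy marginal-contribution scheme: each
round scores every candidate by the reference genes that pass through
it as a proper ancestor — weight flow stopped at previously selected
ancestors — multiplied by the fraction of the candidate's own genome
not already traced through a selected ancestor above it, plus its own
phantom-founder fraction. The multiplier matters: crediting a
candidate's whole genome to itself would let accumulated contributions
exceed one as soon as both an animal and its parents were informative.
With it, the accumulated curve is non-decreasing and bounded by one,
and a pedigree without a bottleneck gives f_e/f_a = 1. The greedy
sequence and its marginals are verified against an exhaustive
enumeration of gene-origin paths on small pedigrees. Ties are broken by
unconditional contribution, then earlier birth year, then id, for
determinism. Selection stops below a marginal of 1e−6 or at a
configurable ancestor cap. GCI_i = 1/Σp_ik² over animal i's own founder
decomposition.

## Effective population size

The pedigree battery returns seven estimates, all Ne = 1/(2ΔF):

- individual increase in inbreeding ΔF_i = 1 − (1−F_i)^(1/(t_i−1)) with
  t as maximum, complete, or equivalent generations (animals with
  t ≤ 1 excluded), each averaged over the animals;
- the same individual increase restricted to a reference cohort, taken
  as the animals at or above the median equivalent-generation depth —
  a proxy for "the current, well-recorded generation" chosen because
  synthetic and real pedigrees lack an explicit cohort label;
- the slope of F on birth year times the generation interval;
- the log regression of ln(1−F̄) on cohort generation number
  (slope = ln(1−ΔF));
- the increase in pairwise coancestry Δc_jk = 1 − (1−f_jk)^(2/(t_j+t_k))
  over all pairs of a subset (default cap 10,000 animals, seeded
  subsample, matching common practice on large pedigrees).

When the signal is absent (ΔF ≤ 0) the estimate is +inf, never
negative. On discrete-generation random-mating simulations the seven
estimates straddle the true size; their spread on overlapping-
generation flock pedigrees is large, which is why the pipeline reports
the range rather than a single value.

The LD method uses the squared Pearson correlation of additive
genotypes between SNPs on *different* chromosomes only (the unlinked-
pair assumption of the drift formula; same-chromosome pairs are
excluded outright rather than thresholded by map distance). The no-LD
expectation for a sample of S animals is E[r²] = 1/(S−1) — the exact
null for a Pearson correlation — and is subtracted before inversion.
An earlier draft used the empirical null published for the Burrows
composite-Δ estimator of NeEstimator; that null is mis-matched to a
plain genotype correlation and produced a ~35% upward bias at S = N =
50 in Wright–Fisher calibration, so the exact null is used instead.
Inversion uses Ne = (1/3 + √(1/9 − 2.76 r²'))/(2 r²'), whose large-Ne
limit is the familiar 1/(3 r²'); the limit form is the fallback when
the discriminant is negative. The CI is a delete-one-locus jackknife on
the adjusted mean r². Loci below MAF 0.02 are screened (configurable).
Calibration on Wright–Fisher truth: median estimates 57 at N = 50 and
107 at N = 100 (S = N, 40 generations, 1,500 unlinked SNPs, 10–20
replicates).

## Flock differentiation from pedigrees

Nei's minimum distance and the coancestry F_ST use within-flock mean
coancestries including self-pairs f(i,i) = (1+F_i)/2 (the mean-
coancestry convention; excluding self-pairs is an option). In f̄ the
flock means are weighted by their pair counts by default, with equal
weighting exposed, since aggregation across very unequal flock sizes is
ambiguous in the field's descriptions.

## Genomic pipeline

QC drops animals below a 0.90 call rate (optionally those without
pedigree links), then unmapped SNPs and SNPs at or below a 0.90 call
rate, recomputing rates after the animal drop, and iterates the two
filters to a fixed point so QC is idempotent. The marker lineage is:
QC output → one SNP per 30-kb window (seeded uniform choice; the
*full* set) → MAF ≥ 0.01 (*reduced*) → random 50% (*thinned*). Full
feeds ROH and the MAF spectrum; reduced feeds H_E/H_O, LD decay, F_ST
and PCA; thinned feeds the LD-Ne. MAF exactly 0.01 is kept (the filter
removes strictly < 0.01).

Heterozygosity: per-SNP H_E = 2p(1−p) and H_O = heterozygote fraction,
population values are means over SNPs. Wright's F is emitted both as
(H̄_E − H̄_O)/H̄_E and as the mean of per-SNP F, because the two
averaging orders differ on real data and published tables rarely say
which was used. The per-animal variant for the inbreeding correlations
is F_i = 1 − H_O,i/H̄_E.

LD decay bins composite genotypic r² (squared Pearson correlation of
additive codes, missing calls deleted pairwise — the unphased
convention of standard tooling) by physical distance; adjacent-SNP mean
distance and r² are also reported.

## Runs of homozygosity

Detection follows the sliding-window scheme: 50-SNP windows sliding one
SNP at a time; a window with ≤ 1 heterozygous and ≤ 1 missing call is
homozygous; a SNP is eligible when ≥ 5% of the windows overlapping it
are homozygous, with the denominator equal to the number of windows
actually overlapping it (ends handled by truncation). Maximal runs of
consecutive eligible SNPs are split at inter-SNP gaps > 250 kb and kept
when they have ≥ 30 SNPs *and* span ≥ 1 Mb (two independent
conditions). Coordinates are 1-based inclusive, length = end − start
+ 1; size classes are (1,6], (6,12], (12,24], (24,48], (48,∞) Mb. An
exhaustive window-enumeration oracle in the test suite pins these
semantics, including the edge behaviour (the proportion rule typically
trims one SNP at each tract boundary). Versions of field tools differ
at chromosome edges; the oracle, not any one tool, defines this
package's behaviour.

F_ROH divides per-animal ROH length by the SNP-covered genome span
(Σ per chromosome of max − min retained-SNP position); the per-class
decomposition sums to the total exactly. Note that with ~100-kb marker
spacing, sliding-window F_ROH substantially underestimates true
autozygosity (short IBD segments fail the 30-SNP/1-Mb minima); rank
correlations with pedigree F remain high (≈ 0.8–0.9 on gene-dropped
truth), which is the property the cross-measure correlations rely on.

## Marker-based structure

Pairwise flock F_ST is the Weir–Cockerham two-population θ per locus,
aggregated as a ratio of sums, on flocks with more than 10 genotyped
animals (strict). CIs come from a seeded bootstrap over loci (default
100 draws, percentile interval). The PCA subsamples at most 20 animals
per flock per replicate (all animals for smaller flocks), draws
replicates independently but without replacement within one (a
duplicate animal inside a replicate would add no information and
degrade the distance matrix), computes 1 − IBS allele-sharing
distances, and eigendecomposes the double-centred squared-distance
matrix (classical MDS). Negative eigenvalues are reported, not
silently dropped. Whether published PCAs used 1 − IBS or another
distance is rarely stated; the distance function is a parameter.

## Synthetic data

`simulate_pedigree` emulates a flock-recording scheme: each flock keeps
a constant number of breeding ewes (ages 1–4, overlapping generations),
a few service sires per year drawn from males of breeding age — from
another flock with probability `ram_migration_rate` (default 0.10) —
and litters of 1–3 lambs (probabilities 0.25/0.55/0.20, a prolific
maternal breed). Defaults (6–8 flocks, 15–25 ewes each, 10–12 years)
are desk-scale stand-ins for a national scheme: small enough for exact
oracles, structured enough to exhibit drift, migration and flock
differentiation. `simulate_random_mating_pedigree` provides discrete
generations at constant size for Ne ground truth.

`gene_drop` assigns every founder gamete a unique haplotype tag per
chromosome, draws crossover counts Poisson in the map length (Haldane,
no interference, default 1 cM/Mb) and records, for each animal, the
fraction of SNPs where its two tags coincide — exact realised
autozygosity. Founder alleles are drawn site-independently at uniform
MAF (0.05–0.5), i.e. founders are in linkage equilibrium: LD in
descendants arises only from co-segregation in the pedigree. That is
sufficient for decay-monotonicity and ROH tests but does **not**
reproduce the ancestral LD of a real breed, so synthetic LD levels and
LD-decay scale are not comparable to array data.

`wright_fisher` is a constant-size random-mating population (two
distinct parents per offspring, unlinked SNPs on separate
chromosomes); heterozygosity decays as (1 − 1/2N)^t within Monte-Carlo
error, and it serves as the LD-Ne oracle.

Passing tests on these generators demonstrates algorithmic correctness
and estimator calibration under the stated models; they do not
demonstrate robustness to genotyping artefacts, pedigree errors,
selection, or ancestral LD, none of which are simulated.

## Problem sizes and numerical choices

The test-suite and acceptance problem sizes (pedigrees of 1,000–2,000
animals; 8,000–20,000 markers; 10–50 simulation replicates; Wright–
Fisher populations of 50–100) were chosen so every oracle comparison is
exhaustive and the full suite runs in well under a minute per module.
Tolerances: 1e−12 for rational-arithmetic oracle equivalences; Monte-
Carlo assertions use fixed seeds with bands (e.g. ±0.05 on full-sib
autozygosity over 50 replicates, 40% on LD-Ne medians) set from pilot
variance at these scales. Degenerate inputs (no usable parent–offspring
pairs, all-monomorphic panels, empty flocks, absent inbreeding signal)
raise errors or return +inf/NaN sentinels as documented per function;
pipeline stages skip structure analyses with a notice rather than fail
when every flock is below the size threshold.

## Known limitations

- Effective-ancestor marginals are expected contributions (exact
  recursion), not Monte-Carlo gene dropping; fine at desk scale, and
  deterministic, but O(rounds × pedigree) in time.
- The reference-cohort "individual increase" Ne uses a median-depth
  rule rather than an explicit cohort definition.
- F_ROH magnitudes depend strongly on marker density and the window
  minima (see above); only comparisons under a fixed panel are
  meaningful.
- Genomic F_ST assumes biallelic autosomal SNPs; no hierarchical
  F-statistics, no phased haplotype LD, no HMM autozygosity, no
  model-based ancestry clustering.
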