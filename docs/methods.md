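# Methods

## The scan statistic

For a focal SNP and a site x at physical distance d, the site-specific
extended haplotype homozygosity EHHS(x) is the probability that two
haplotypes drawn without replacement are identical over the closed
interval [focal, x]: haplotypes are grouped by their full allele string
over the interval, the unnormalised homozygosity is
Σ_g C(n_g, 2) / C(n, 2), and EHHS is that quantity divided by its value
at the focal site alone, so EHHS(focal) = 1 and EHHS is non-increasing
outward (groups only refine). iES is the trapezoidal integral of EHHS
against bp position on both sides, walked outward until EHHS first
drops below a truncation threshold (default 0.05; the first
sub-threshold site still contributes its trapezoid). A side that
reaches a chromosome edge, or an inter-site gap above 200 kb, before
crossing the threshold is *censored*; censored sites are dropped by
default because their iES is biased downward. Both thresholds follow
the conventions of the widely used REHH implementation and are
configurable (`ScanConfig`).

The per-site statistic is ln(iES_A / iES_B), standardised by the
unconditional genome-wide mean and sd (ddof = 1) of the retained,
uncensored sites — no derived-allele-frequency binning — and converted
to a two-sided normal p-value reported as −log10 p (computed through
the normal log-survival function, so extreme z never underflows).
Retention uses the *pooled* minor allele frequency of both samples,
strict `> 0.05`; a per-population filter is available by flag. By
construction the standardised scores have sample mean 0 and sd 1; the
scientific content of the neutral calibration check is the tail
(fraction of sites with −log10 p ≥ 3 stays below 0.005 despite linkage
between sites).

Sign convention: population A is the first argument / first configured
population; positive values mean longer haplotypes (candidate sweep)
in A. Swapping the populations negates raw and standardised values and
preserves p-values exactly — this antisymmetry is tested site by site.

The EHHS inner walk keeps an integer group label per haplotype and
refines it one site at a time with bincount-based relabelling (O(n) per
site); a numba-compiled version of the same walk is used when numba is
importable, with a pure-numpy fallback. Both paths are checked against
an independent pair-enumeration oracle (a boolean haplotype-pair
identity matrix updated outward) to 1e-12.

## Islands and gene linking

Significant SNPs (−log10 p ≥ 3, inclusive) are chained left to right:
a SNP joins the open island iff its distance to the island's *last
member* is ≤ 50 kb, matching `bedtools merge -d` semantics (chained,
not anchored at the island start). Island start/end are the min/max
member positions; merging is idempotent and the island count is
non-increasing in the merge distance (both property-tested against an
O(n²) transitive-closure oracle).

Each island is linked to the gene minimising interval distance
(0 on overlap). Ties are broken by smaller gene start, then gene id,
and the tie count is logged (a bedtools-style all-ties report is not
reproduced). Location category: `gene_body` if the island overlaps the
gene; else `promoter` if it overlaps a strand-aware window 5 kb
upstream of the TSS (the upstream extent is a package choice —
"promoter" has no universal definition — and is configurable); else
`intergenic`. Internal coordinates are 1-based inclusive throughout;
BED I/O converts to/from 0-based half-open.

## Expression divergence

Size factors are DESeq-style median of ratios: per-gene geometric mean
across samples as reference (genes containing any zero excluded), each
sample's factor the median ratio to the reference. Note that scaling
one sample's column by c moves its factor by c^(1−1/m) and every other
factor by c^(−1/m), because the reference moves too; factor *ratios*
change by exactly c.

The low-count rule "counts < 10 per sample in each species" is read in
its least aggressive form: a gene is removed only when every sample of
*both* species is below 10; `mode="either"` gives the stricter
reading. Technical replicates can be collapsed by summation before
normalisation.

The differential test is a transparent NB Wald test, not a DESeq2
re-implementation: per gene, normalised group means m1, m2 (pseudocount
0.5), effect ln(m2+0.5) − ln(m1+0.5), variance by the delta method
(1/(n·m) + α/n summed over groups) with gene-wise method-of-moments
dispersion α. With 3 replicates the raw moment estimate is so noisy
that its underestimates make the test anticonservative (~12% type-I at
nominal 5%), so each gene's α is floored at the across-gene median — a
crude but fully transparent moderation that brings the null rate to
~5% (checked on 2000-gene null simulations, band 3–8%). Two-sided
normal p-values, BH adjustment across genes within each contrast. DEG
calls are inclusive at |log2FC| ≥ 0.585 (= log2 1.5) with adjusted
p < 0.05, unioned over contrasts; the default contrast set is species
A vs B at each stage (`all_cross_stage` is available, since "any
pairwise comparison" admits both readings).

Profiles are Z-scores across each gene's vector of mean normalised
counts per (species, stage) cell, species-major column order;
zero-variance genes get an all-zero profile and are flagged out of
clustering. Clustering is agglomerative complete linkage on Euclidean
distance between Z-profiles (the common heatmap default; correlation
distance available), cut at k = 7; scipy's linkage makes the result
deterministic given the input, and it is invariant to row permutation
up to label renaming on tie-free data.

## Cluster enrichment

Gene score = median −log10 p over scan SNPs in the fixed-width (25 kb)
strand-aware window upstream of the TSS; genes with no window SNP are
dropped from observed and null pools symmetrically. Cluster statistic
= median of gene scores (mean by flag). Null: 1000 iterations, each
drawing the same number of genes uniformly *without replacement* from
the genome-wide scored pool — windows all share one width, so the null
windows are size-matched by construction; matching gene-body lengths
was rejected because the observed windows are fixed-width. The
cluster's own genes stay in the pool by default (exchangeable null;
exclusion by flag). Empirical p = (1 + #{null ≥ observed}) / (1 +
n_iter), one-sided greater, never exactly zero. Calibration (random
clusters significant at ~5%) and power (a cluster whose windows cover
a planted sweep reaches p ≤ 0.05) are both exercised on synthetic data.
Raw p-values are reported per cluster with a BH column alongside; with
seven clusters, multiplicity is left to the reader's judgement.

## The synthetic-data generators

**Haplotypes.** A haploid forward Wright–Fisher model: a founding panel
of `population_size` haplotypes (default 400) receives `n_sites`
segregating sites (default 6000 on a 1 Mb chromosome) with derived
counts from the neutral 1/i spectrum assigned independently per site
(founding LD ≈ 0); both populations copy this panel and evolve
independently for 30 generations with uniform crossover (5e-6 per bp
per generation), Poisson new singleton mutations (2e-6 per bp per
generation, infinite-sites so every site stays biallelic), and finally
an independent sample of `n_haplotypes_per_pop` (default 60)
haplotypes per population is emitted, positions unioned and aligned.

Two design points matter and were chosen on population-genetic grounds:

* *Panel ≪ population.* If the evolving population is the panel itself,
  ~t/N of haplotype pairs coalesce within the simulation and their long
  IBD segments put a plateau in EHHS that both inflates neutral iES
  noise and masks sweeps. Sampling 60 from 400 keeps the recently
  coalesced fraction near 7%, just above the truncation threshold, as
  in real panels drawn from large wild populations.
* *Single mutational origin of the sweep.* The selected allele enters
  at 5% frequency with all carriers copied from one founder haplotype;
  carriers seeded on independent backgrounds share no haplotype and
  produce no homozygosity signal at all. Selection is haploid
  multiplicative (fitness 1 + s for carriers); s = 0 reduces
  bit-exactly to the neutral model (the selection and allele-injection
  code paths are gated so the random streams coincide).

With these defaults a neutral run retains ~2550 sites after pooled MAF
filtering and censoring, and an s = 0.5 sweep fixes in ~15–20
generations leaving a footprint of roughly 1/(r·T) ≈ 10–15 kb — large
against the baseline EHHS decay (a few kb) and small against the
chromosome, so the genome-wide standardisation, which is computed from
this single simulated chromosome, is not swamped by hitchhiking. The
model is a stand-in for testing the machinery, not a demographic model
of any real system: no population structure, migration, varying
recombination, or mutation-rate calibration.

**Counts.** Gene g in cluster c has mean
2^(base + offset_g + archetype_c(species, stage)) per condition,
multiplied by lognormal replicate noise (sd 0.1 in natural log) and a
per-sample library factor drawn log-uniform in [0.5, 2] (so
median-of-ratios recovery is non-trivial); counts are negative binomial
with size r (`nb_dispersion`, default 20, i.e. α = 0.05;
var = μ + μ²/r, large r → Poisson). The seven default archetypes are
centred, equal-amplitude temporal shapes (rising/falling/transient in
both species, constitutive species shifts in either direction, and
opposite temporal trends), mutually near-orthogonal after Z-scoring so
that "recovery at default noise" is a well-posed target; the
between-species amplitude is `effect_size_log2` (default 2). No
magnitudes for real expression divergence are implied — they are free
parameters of the generator.

**Annotation.** Uniform random gene intervals (2–20 kb) fully inside
the chromosome, Bernoulli strand; overlap is allowed; TSS = start on
'+', end on '−'.

All three generators are deterministic given their seed (seed streams
are spawned per population/purpose via `SeedSequence`).

## Problem sizes and numerical choices

Test and acceptance runs use the defaults above (1 Mb chromosomes,
2×60-haplotype panels, 2100-gene count matrices, 1000-iteration
permutations; 20 replicates for power estimates, 200 datasets for
enrichment calibration, 100 random panels for the EHHS oracle sweep) —
sizes at which each check is statistically meaningful while the whole
suite runs in minutes on one CPU. Floating-point tolerances: EHHS
oracle agreement at 1e-12 (both sides compute the same rational
numbers in double precision); profile monotonicity allows 1e-12 slack;
Z-profile normalisation checks at 1e-9. Degenerate inputs are errors,
not silent results: identical panels (zero scan variance), clusters
with no scored gene, normalisation with no all-nonzero gene, fewer
genes than clusters.

## Limitations

* The Wright–Fisher stand-in has uniform rates and no demography; the
  neutral tail bound (≤ 0.5% at −log10 p ≥ 3) holds under these
  conditions and says nothing about demographic confounding in real
  data.
* The NB Wald test is not DESeq2: no dispersion trend, shrinkage,
  Cook's distance or independent filtering. It is adequate for
  producing DEG sets on synthetic data with known truth, which is what
  the downstream stages consume.
* Passing cluster-recovery tests show the clustering machinery is
  correct, not that seven clusters is the right k for any real
  dataset.
* One simulated chromosome serves as the "genome" for standardisation;
  real scans standardise across chromosomes, where sweeps occupy a far
  smaller fraction of the distribution.
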