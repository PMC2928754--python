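# Methods

This note records the statistical model behind each pipeline stage, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical choices a maintainer would otherwise
have to reverse-engineer.

## Variability measure

Within-population variability of gene *g* is the coefficient of
variation η<sub>g</sub> = s<sub>g</sub>/x̄<sub>g</sub>, computed on
normalized **linear-scale** intensities with the sample (n−1) standard
deviation. Linear scale because "standard deviation over mean" is only
scale-free there; a CV of log-intensities would depend on the log base
and offset. η is undefined for non-positive means, which the containers
rule out up front.

Preprocessing: genes are ranked by mean intensity pooled over all
samples of both populations and the lowest 10% are dropped (they are
assumed unexpressed; the pooled **mean** is used as the ranking summary
because it is monotone under the later normalization). Every sample
column is then rescaled so its median equals the pooled all-samples
median, putting both populations on one background scale; the operation
is idempotent (exactly so for odd gene counts, to rounding otherwise).
Note that rescaling a single sample changes the pooled target median, so
normalized matrices are reproducible up to one global factor — which η
ignores. Y-linked or otherwise excluded genes are handled by an
exclude-list, not annotation lookup.

## Outlier detection

The two η vectors are fit by OLS with intercept in both directions
(η_A on η_B, and the reverse). Residuals are **externally Studentized**
(leave-one-out variance estimate): under a Gaussian linear model these
are exactly t-distributed with n−3 degrees of freedom, which justifies
flagging |t<sub>i</sub>| > t<sub>n−3</sub>((1+level)/2) as "outside the
95% CI of the fitted t-distribution". Internally Studentized residuals
(df n−2) are available via `studentize="internal"`. The null flag rate
per direction is therefore 1−level (0.05 at the default level); on the
synthetic genome it measures slightly lower (~0.045) because η residuals
are mildly non-Gaussian.

The analysis set is the **intersection** of the two directions' flags
(direction-independent outliers), labeled by which population has the
higher η; exact ties are excluded and logged. The **union** is kept too:
it is the right exclusion set when later analyses must avoid any gene
that is possibly variability-deviant. "Linear model with random effects"
ambiguity is resolved as plain OLS, since the estimator is defined by
least squares. Genes whose microarray probe overlaps an annotated SNP
are removed from the outlier sets, with a two-proportion χ² comparing
the flagged fraction inside the outliers to the genome background (a
probe-artifact sanity check).

## Heterozygosity sweep

θ = 2p(1−p) for MAF p ∈ [0, 0.5]; MAFs are stored folded because θ is
symmetric in p ↔ 1−p. Δθ is directed: for the group with higher η in
population A it is θ_A − θ_B, and vice versa. The cutoff grid is
0 to 0.5 in steps of 0.04 (13 cutoffs); per cutoff the statistic is the
fraction of genes bearing at least one SNP with Δθ **strictly** greater
than k, among genes with ≥1 mapped SNP in the region — genes without
SNPs never enter either denominator. Significance is tested at
k = 0.04 (not 0, which is dominated by tiny frequency fluctuations)
with the square of the pooled two-proportion z statistic, df 1, no
continuity correction; the background group includes the focal genes
by default (configurable), matching a "group vs all mapped genes"
comparison.

## Differential expression

Pooled-variance Student t (not Welch): the design is balanced (30+30)
and the pooled form gives the textbook df = 58 correspondences
(|t| = 2 ↔ p ≈ 0.05, |t| = 4 ↔ p ≈ 2×10⁻⁴). Permutations re-split the
pooled 60 samples into groups of the original sizes; one re-split is
shared by all genes within a permutation, preserving gene–gene
correlation. Empirical p-values use +1 smoothing (minimum attainable
p = 1/(n_perm+1), never 0), and a tiny tolerance (1e−12) when comparing
|t*| ≥ |t| so exact ties are not lost to floating-point jitter. BH
step-up q-values come from statsmodels; DE calls use q ≤ 0.01.

The directional-enrichment test asks whether DE outlier genes
over-represent one direction label. Its null re-draws subsets of the
same size uniformly without replacement from the direction-labeled
outlier pool (the count is hypergeometric, which the tests use as a
closed-form oracle); p is one-sided with +1 smoothing. The t-score–η
relation is the Pearson correlation of **signed** t with η, restricted
to genes with η below 0.05 (the extreme-variability tail otherwise
dominates the correlation) after excluding the outlier union.

## Group and set analyses

* Tails: rank by η ascending after excluding the outlier union; tail
  size is floor(2.5% × n) (floor reproduces 424 from 16,975), ties
  broken by gene id so the selection is order-independent.
* Over-representation: one-sided hypergeometric upper tail per GMT set
  against a fixed universe, BH across sets. This is a transparent
  stand-in for web-service enrichment tools; it does not reproduce any
  specific curated category list.
* Group vs genome: two-sided Wilcoxon rank-sum of group η against all
  non-group η — exact enumeration when both sides have ≤10 tie-free
  values, otherwise the tie-corrected normal approximation.
* Bootstrap: seeded percentile CI of the group mean η from 5,000
  resamples with replacement.
* Matched nulls: only group genes whose most-specific category code is
  shared by ≥1 non-group gene are matchable; each of the 1,000
  replicates draws one same-code non-group gene per matchable group
  gene, without replacement within a replicate (excess demand beyond a
  code's supply is dropped and counted). A replicate "hits" when the
  group's η distribution is greater than the null set's (one-sided
  rank-sum at 0.05); the exceedance count out of 1,000 and the mean
  relative excess of the group mean are reported. For a *single* fixed
  group the replicate tests are correlated, so the 5% null rate only
  emerges after averaging over independent groups — the tests do
  exactly that.
* Keyword exclusion ("immune"): case-insensitive substring match on
  gene-set names and category codes, a flat approximation of an
  ontology keyword filter (no GO graph traversal).

## Synthetic data generator

The generator emulates a two-population, 30+30-sample, ~16k-gene
expression study. Per gene, intensities are log-normal with arithmetic
mean drawn from LogNormal(log 200, 1) and target CV drawn from
LogNormal(log 0.02, 1.0); σ² = log(1+CV²) maps the target CV onto the
log-normal exactly, and positivity is guaranteed. Defaults:

| parameter | default | rationale |
|---|---|---|
| n_genes | 16,000 | genome-scale transcript count of the emulated design |
| n_per_pop | 30 | the two-population sample size |
| CV location | 0.02 | genome-median η of lymphoblastoid arrays (~0.0197) |
| CV scale | 1.0 | calibrated so sample-η correlation at n=30, outliers included, sits in the 0.85–0.9 regime (measured 0.85) |
| outlier_fraction / inflation | 0.05 / 3× | ~5% of genes get their CV tripled in one population |
| de_fraction / de_effect | 0.20 / 1 SD | ~20% of genes shift mean by one within-population SD |
| de_cv_coupling | 0.5 | shift direction biased by CV rank so signed t correlates positively with η (measured r ≈ 0.19) |
| SNPs per gene per region | Poisson(2) | typical cis-SNP density per annotated region |
| maf_divergence_bias | 0.3 | planted extra MAF divergence on outlier genes' UTR SNPs |
| probe_flag_fraction | 0.05 | ~5% of probes overlap an annotated SNP |
| hiv_set_fraction / bias | 0.08 / 4× | host-factor-sized set sampled with 4× weight from the top CV quartile |
| immune_fraction | 0.16 | share of the set tagged "immune" |

Baseline MAFs follow 0.5·Beta(1, 2) (low-frequency skewed); population
B's MAF adds N(0, 0.05) noise, folded into [0, 0.5]. The divergence bias
pushes the focal population's UTR MAFs toward 0.5, i.e. toward maximal
heterozygosity. Every gene gets exactly one most-specific category code
(~15 genes per category); categories double as GMT sets.

All randomness derives from one master seed through named
`SeedSequence` sub-streams (expression / snp / sets / probes), so equal
seed + config means byte-identical outputs and each artifact is
reproducible independently of the others.

**What the generator does not emulate:** linkage disequilibrium, trio
or family structure, batch effects, probe sequences, multi-label
annotations, or an ontology hierarchy. Planted DE genes and planted
variability outliers are chosen independently, so their overlap is
small — unlike real data, where a quarter of variability outliers were
also differentially expressed. Passing tests therefore demonstrate that
the statistics recover the *kinds* of planted signal under the stated
noise model at the stated sizes, not that real microarray data behave
this way.

## Calibrated recovery thresholds

Recovery tests compare against floors frozen from a 100-seed
calibration of the default generator at 2,000 genes (re-run whenever the
generator defaults change): planted-outlier CV recovery 100/100 seeds;
intersection-call sensitivity mean 0.38, min 0.16 (floor 0.15) with
specificity ≥0.99; utr5 sweep significance in 99/100 and 96/100 seeds
per direction group; biased-set median above the genome median in
100/100. Sensitivity of ~0.4 at inflation 3 is expected: a tripled CV
moves many genes only partway out of a 95% band estimated from 30+30
noisy sample CVs, and the intersection rule is conservative by design.

## Problem sizes in the default test run

The suite and the acceptance script run the full pipeline at 2,000
genes, 30+30 samples and 10,000 permutations, recovery checks over 10
seeds, bootstrap coverage over 1,000 groups × 5,000 resamples, and
null-calibration sweeps over 200 resampled groups; these sizes keep the
whole suite in the minutes range on one core while leaving the
Monte-Carlo error well below every asserted tolerance.

## Known limitations

* The χ² arrangement at the sweep test cutoff treats focal and
  background gene counts as independent proportions even when the
  background includes the focal genes; for focal groups that are a tiny
  fraction of the background the difference is negligible.
* The matched-null procedure assumes single most-specific codes; genes
  with genuinely multi-modal annotation are not modeled.
* `eta` on heavy-tailed intensity distributions is an upward-biased
  estimate of the true CV at n = 30; comparisons are therefore made
  between groups computed the same way, never against the true CV.
* The pipeline is two-population by construction; multi-population
  designs are handled by running population pairs.
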