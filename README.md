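# popvar

**popvar** quantifies how much a gene's expression varies *across
individuals within a population*, and whether that variability differs
*between* populations. It was built for two-population microarray designs
of the HapMap type — e.g. 30 lymphoblastoid samples from each of two
ethnic populations — where the questions of interest are:

* Which genes have population-specific expression variability, and is
  that linked to divergent allele frequencies of their *cis*-SNPs?
* Which genes shift their mean expression between populations
  (differential expression), and how does that relate to their
  within-population variability?
* Are functionally annotated gene groups (e.g. virus-interacting host
  factors) more variable than the genome background, even after
  controlling for annotation composition?

Everything is exercisable end to end without external data through a
synthetic-data generator that emulates the two-population design with
known planted signal.

## The statistics

* **Variability.** For gene *g* in one population,
  η<sub>g</sub> = s<sub>g</sub> / x̄<sub>g</sub> — the coefficient of
  variation of its (median-normalized, linear-scale) intensities across
  individuals, with the sample (n−1) standard deviation. η is scale-free,
  so it is comparable across genes.
* **Outlier detection.** η in population A is regressed on η in
  population B by OLS and vice versa. Residuals are externally
  Studentized (leave-one-out variance); a gene is flagged when its
  Studentized residual falls outside the two-sided 95% band of a Student
  *t* distribution with n−3 degrees of freedom. Genes flagged in *both*
  regression directions form the outlier set, split into those with
  higher η in population A vs B.
* **Heterozygosity sweep.** Under Hardy–Weinberg equilibrium a SNP with
  minor-allele frequency *p* has expected heterozygosity
  θ = 2p(1−p); Δθ = θ<sub>focal</sub> − θ<sub>other</sub> ∈ [−0.5, 0.5].
  For cutoffs k = 0, 0.04, …, 0.48 (13 bins) the pipeline compares the
  fraction of outlier genes vs background genes bearing ≥1 cis-SNP with
  Δθ > k (per region: promoter, 5′UTR, 3′UTR), and tests the k = 0.04 bin
  with a two-proportion χ² (df = 1, no continuity correction).
* **Differential expression.** Pooled-variance two-sample *t* per gene
  (df = 58 under the 30+30 design), 10,000 label permutations shared
  across genes, empirical p = (1 + #{|t*| ≥ |t|}) / (n_perm + 1),
  Benjamini–Hochberg FDR, calls at q ≤ 0.01.
* **Group analyses.** 2.5% η tails after outlier exclusion,
  hypergeometric over-representation against GMT gene sets with BH
  correction, Wilcoxon rank-sum group-vs-genome comparisons, percentile
  bootstrap CIs of the group mean η (5,000 resamples), and
  annotation-matched null gene sets (1,000 replicates drawing, per group
  gene, one non-group gene with the same most-specific category code).

## Worked example

Run the whole pipeline on a simulated 2,000-gene study:

```bash
cat > config.txt <<EOF
simulate = true
simulate.n_genes = 2000
seed = 1
out_dir = results
EOF
popvar run-all --config config.txt
```

This writes one TSV per stage under `results/` (`variability.tsv`,
`outliers.tsv`, `hetsweep.tsv`, `diffexpr.tsv`, `tails.tsv`,
`group_comparisons.tsv`, a run `manifest.tsv`) and prints a JSON report.
Highlights from the run above:

```
"n_genes_retained": 1800,            # 10% low-expression genes filtered
"eta_correlation_r": 0.8605,         # eta strongly correlated between populations
"outliers": {"n_direction1": 49, "n_direction2": 53,
             "n_intersection": 39,   # direction-independent outliers
             "n_high_popA": 21, "n_high_popB": 18, ...},
"hetsweep": [..., {"region": "utr5", "group": "high_popA",
                   "chi2": 11.75, "p_value": 0.00061}, ...],
"n_de_genes": 211,                   # FDR <= 0.01 after 10,000 permutations
"tails": {"universe_size": 1737, "tail_size": 43},
```

Reading it: the per-gene η values of the two populations correlate at
r ≈ 0.86, 39 genes are direction-independent variability outliers, and
the outliers' 5′UTR SNPs are significantly enriched for elevated
heterozygosity in the population with the higher variability
(χ² p ≈ 6×10⁻⁴ at cutoff k = 0.04) — the generator plants exactly this
MAF divergence, so the sweep is expected to light up on the UTRs and not
on promoters. The `group_comparisons` block shows the planted
virus-interacting gene set is markedly more variable than the genome
(rank-sum p ≈ 4×10⁻¹², matched-null exceedance 1000/1000).

Every subcommand (`simulate`, `variability`, `outliers`, `hetsweep`,
`diffexpr`, `setanalysis`, `run-all`) takes `--config`, `--seed`,
`--out`, `--log-level`; reruns with the same config are byte-identical.
File-based inputs (expression TSV + population map, SNP table TSV, GMT
gene sets, probe-flag TSV) replace the `simulate` block for real data;
`popvar simulate` writes a full synthetic dataset in those formats.

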