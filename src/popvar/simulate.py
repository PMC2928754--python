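"""Synthetic two-population expression study with known ground truth.

The generator emulates the design this pipeline targets: two populations
of 30 individuals each, a genome of ~16k genes whose per-gene coefficient
of variation (CV) is shared between populations except for a small planted
fraction of variability outliers, a subset of genes with a mean-expression
shift (differential expression), per-gene cis-SNP tables with optionally
divergent minor-allele frequencies for outlier genes' UTR SNPs, a
category annotation with one most-specific code per gene, and a planted
"virus-interacting" gene set biased toward high-CV genes with an
immune-tagged subset.

Expression model: each gene's intensities are log-normal with a gene-level
mean drawn from a broad log-normal and a target CV drawn from a log-normal
whose median sits near the genome-median CV of lymphoblastoid microarray
data (~0.02).  The log-normal guarantees positivity, so the CV is always
well defined, and its sigma is set from the target CV via
CV^2 = exp(sigma^2) - 1.

All randomness flows from one master seed through deterministically
spawned sub-streams, one per generator, so identical seed + config gives
byte-identical outputs and regenerating one artifact never perturbs the
others.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GeneSetCollection, ProbeFlagTable, SnpTable
from .errors import ConfigError

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedDataset",
    "generate_expression",
    "generate_snp_table",
    "generate_gene_sets",
    "generate_probe_flags",
    "generate_all",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic two-population study.

    The defaults reproduce the emulated design: 30 individuals per
    population, a genome of 16,000 genes, ~5% planted variability
    outliers with 3x CV inflation in one population, ~20% of genes with a
    one-within-population-SD mean shift, Poisson(2) cis-SNPs per gene per
    region with extra MAF divergence of 0.3 on outlier genes' UTR SNPs,
    and ~5% of probes overlapping an annotated SNP.
    """

    n_genes: int = 16000
    n_per_pop: int = 30
    population_labels: tuple[str, str] = ("popA", "popB")
    #: (location, scale) of the per-gene CV: CV ~ exp(N(log(location), scale)).
    #: location is the median CV; scale spreads genes enough that sample CVs
    #: at n = 30, with the planted outlier contingent included, correlate
    #: ~0.85-0.9 between populations.
    base_cv_distribution: tuple[float, float] = (0.02, 1.0)
    #: (location, scale) of the per-gene mean intensity, log-normal.
    mean_distribution: tuple[float, float] = (200.0, 1.0)
    outlier_fraction: float = 0.05
    variance_inflation: float = 3.0
    de_fraction: float = 0.20
    #: mean shift of DE genes, in units of the within-population SD.
    de_effect: float = 1.0
    #: coupling in [0, 1] between a DE gene's CV rank and the direction of
    #: its shift: high-CV genes shift up in population A, so the signed
    #: t-score correlates positively with eta, as seen in real data.
    de_cv_coupling: float = 0.5
    #: per-region SNP count distribution: ("poisson", lam) or ("fixed", k).
    snp_per_gene_distribution: tuple[str, float] = ("poisson", 2.0)
    #: extra MAF divergence for UTR SNPs of planted outlier genes, applied
    #: toward 0.5 in the gene's high-variability population.
    maf_divergence_bias: float = 0.3
    #: SD of the random between-population MAF perturbation for all SNPs.
    maf_noise_sd: float = 0.05
    #: number of most-specific category codes the genome is split into.
    n_categories: int | None = None
    #: planted "virus_interacting" set: fraction of the genome and the
    #: sampling weight multiplier for genes in the top CV quartile.
    hiv_set_fraction: float = 0.08
    hiv_set_bias: float = 4.0
    #: fraction of the virus-interacting set tagged "immune".
    immune_fraction: float = 0.16
    probe_flag_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_per_pop <= 0:
            raise ConfigError("n_genes and n_per_pop must be positive")
        if self.n_per_pop < 2:
            raise ConfigError("n_per_pop must be >= 2")
        for name in ("outlier_fraction", "de_fraction", "hiv_set_fraction",
                     "immune_fraction", "probe_flag_fraction"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ConfigError(f"{name} must be in [0, 1), got {v}")
        if self.variance_inflation < 1:
            raise ConfigError("variance_inflation must be >= 1")
        if not 0 <= self.de_cv_coupling <= 1:
            raise ConfigError("de_cv_coupling must be in [0, 1]")
        if self.maf_divergence_bias < 0:
            raise ConfigError("maf_divergence_bias must be >= 0")
        kind = self.snp_per_gene_distribution[0]
        if kind not in ("poisson", "fixed"):
            raise ConfigError(f"unknown SNP count distribution {kind!r}")

    def spawn_streams(self) -> dict[str, np.random.Generator]:
        """One independent, deterministic RNG per generator."""
        ss = np.random.SeedSequence(self.seed)
        names = ("expression", "snp", "sets", "probes")
        return {n: np.random.default_rng(s) for n, s in zip(names, ss.spawn(4))}

    def as_dict(self) -> dict:
        return asdict(self)

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


@dataclass
class GroundTruth:
    """Planted signal labels recorded alongside the generated data."""

    #: gene_id -> "a" / "b": which population got the inflated CV.
    outlier_direction: dict
    #: gene_id -> +1 (higher mean in population A) or -1.
    de_sign: dict
    #: genes x populations DataFrame of true (target) CVs.
    true_cv: pd.DataFrame
    #: per-gene true mean in each population.
    true_mean: pd.DataFrame
    #: filled by generate_snp_table: the generated SNP MAFs.
    snp_mafs: pd.DataFrame | None = None

    @property
    def outlier_genes(self) -> list:
        return sorted(self.outlier_direction)

    @property
    def de_genes(self) -> list:
        return sorted(self.de_sign)


def _gene_ids(n: int) -> pd.Index:
    width = len(str(n))
    return pd.Index([f"g{str(i).zfill(width)}" for i in range(n)], name="gene_id")


def _lognormal_for(mean: np.ndarray, cv: np.ndarray, size, rng) -> np.ndarray:
    """Log-normal draws with the given arithmetic mean and CV per row."""
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2
    return np.exp(mu[:, None] + np.sqrt(sigma2)[:, None] * rng.standard_normal(size))


def generate_expression(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, GroundTruth]:
    """Generate the two per-population expression matrices plus truth labels."""
    rng = config.spawn_streams()["expression"]
    n = config.n_genes
    genes = _gene_ids(n)
    loc_cv, scale_cv = config.base_cv_distribution
    loc_m, scale_m = config.mean_distribution
    cv = np.exp(np.log(loc_cv) + scale_cv * rng.standard_normal(n))
    mean = np.exp(np.log(loc_m) + scale_m * rng.standard_normal(n))

    n_out = round(config.outlier_fraction * n)
    outlier_idx = rng.choice(n, size=n_out, replace=False)
    directions = rng.choice(["a", "b"], size=n_out)
    cv_a, cv_b = cv.copy(), cv.copy()
    for i, d in zip(outlier_idx, directions):
        if d == "a":
            cv_a[i] *= config.variance_inflation
        else:
            cv_b[i] *= config.variance_inflation

    n_de = round(config.de_fraction * n)
    de_idx = rng.choice(n, size=n_de, replace=False)
    # shift direction optionally coupled to the gene's CV rank
    cv_rank = np.empty(n)
    cv_rank[np.argsort(cv, kind="stable")] = np.arange(n) / max(n - 1, 1)
    p_plus = 0.5 + config.de_cv_coupling * (cv_rank[de_idx] - 0.5)
    de_signs = np.where(rng.random(n_de) < p_plus, 1, -1)
    mean_a, mean_b = mean.copy(), mean.copy()
    # shift expressed in within-population SDs of the un-inflated gene
    shift = np.zeros(n)
    shift[de_idx] = de_signs * config.de_effect * cv[de_idx]
    mean_b = mean * np.clip(1.0 - shift, 0.05, None)

    pops = config.population_labels
    shape = (n, config.n_per_pop)
    values_a = _lognormal_for(mean_a, cv_a, shape, rng)
    values_b = _lognormal_for(mean_b, cv_b, shape, rng)
    samples_a = [f"{pops[0]}_s{i:03d}" for i in range(config.n_per_pop)]
    samples_b = [f"{pops[1]}_s{i:03d}" for i in range(config.n_per_pop)]
    mat_a = ExpressionMatrix(
        pd.DataFrame(values_a, index=genes, columns=samples_a), pops[0]
    )
    mat_b = ExpressionMatrix(
        pd.DataFrame(values_b, index=genes, columns=samples_b), pops[1]
    )
    truth = GroundTruth(
        outlier_direction={genes[i]: d for i, d in zip(outlier_idx, directions)},
        de_sign={genes[i]: int(s) for i, s in zip(de_idx, de_signs)},
        true_cv=pd.DataFrame({pops[0]: cv_a, pops[1]: cv_b}, index=genes),
        true_mean=pd.DataFrame({pops[0]: mean_a, pops[1]: mean_b}, index=genes),
    )
    return mat_a, mat_b, truth


def _fold_maf(p: np.ndarray) -> np.ndarray:
    """Reflect frequencies into [0, 0.5] (theta is symmetric in p <-> 1-p)."""
    p = np.abs(p)
    p = np.where(p > 1, p % 1, p)
    return np.where(p > 0.5, 1.0 - p, p)


def generate_snp_table(truth: GroundTruth, config: SimulationConfig) -> SnpTable:
    """Per-gene cis-SNP table with correlated MAFs and planted divergence.

    Baseline MAFs follow a low-frequency-skewed Beta folded to [0, 0.5];
    population B's MAF is population A's plus Gaussian noise, folded and
    clipped.  UTR SNPs (utr5 and utr3) of planted outlier genes get
    ``maf_divergence_bias`` added toward 0.5 in the gene's high-CV
    population, raising that population's expected heterozygosity.
    """
    rng = config.spawn_streams()["snp"]
    genes = truth.true_cv.index
    kind, par = config.snp_per_gene_distribution
    regions = ("promoter", "utr5", "utr3")
    rows = []
    counter = 0
    for region in regions:
        if kind == "poisson":
            counts = rng.poisson(par, size=len(genes))
        else:
            counts = np.full(len(genes), int(par))
        for gene, c in zip(genes, counts):
            for _ in range(c):
                rows.append((f"rs{counter:07d}", gene, region))
                counter += 1
    if not rows:
        df = pd.DataFrame(
            columns=["snp_id", "gene_id", "region", "maf_a", "maf_b"]
        )
        truth.snp_mafs = df.copy()
        return SnpTable(df, config.population_labels)

    df = pd.DataFrame(rows, columns=["snp_id", "gene_id", "region"])
    m = len(df)
    maf_a = 0.5 * rng.beta(1.0, 2.0, size=m)
    maf_b = _fold_maf(maf_a + config.maf_noise_sd * rng.standard_normal(m))

    bias = config.maf_divergence_bias
    if bias > 0 and truth.outlier_direction:
        direction = df["gene_id"].map(truth.outlier_direction)
        on_utr = df["region"].isin(["utr5", "utr3"]).to_numpy()
        boost_a = (direction == "a").to_numpy() & on_utr
        boost_b = (direction == "b").to_numpy() & on_utr
        maf_a = np.where(boost_a, np.clip(maf_a + bias, 0.0, 0.5), maf_a)
        maf_b = np.where(boost_b, np.clip(maf_b + bias, 0.0, 0.5), maf_b)

    df["maf_a"] = maf_a
    df["maf_b"] = maf_b
    truth.snp_mafs = df.copy()
    return SnpTable(df, config.population_labels)


def generate_gene_sets(
    truth: GroundTruth, config: SimulationConfig
) -> GeneSetCollection:
    """Category codes, a CV-biased virus-interacting set and an immune tag.

    Every gene receives exactly one most-specific category code (categories
    double as GO-like sets in the GMT output).  The "virus_interacting"
    set samples genes with weight ``hiv_set_bias`` if their true CV lies
    in the top quartile, 1 otherwise; a fraction of that set, plus an
    equally sized draw from the rest of the genome, is tagged
    "immune_response".
    """
    rng = config.spawn_streams()["sets"]
    genes = truth.true_cv.index
    n = len(genes)
    n_cat = config.n_categories or max(5, n // 15)
    width = len(str(n_cat))
    code_names = [f"CAT:{str(i).zfill(width)}" for i in range(n_cat)]
    assignment = rng.integers(0, n_cat, size=n)
    codes = pd.Series([code_names[i] for i in assignment], index=genes,
                      name="category_code")

    mean_cv = truth.true_cv.mean(axis=1).to_numpy()
    q75 = np.quantile(mean_cv, 0.75)
    weights = np.where(mean_cv >= q75, config.hiv_set_bias, 1.0)
    weights = weights / weights.sum()
    set_size = round(config.hiv_set_fraction * n)
    hiv_members = (
        sorted(rng.choice(genes, size=set_size, replace=False, p=weights))
        if set_size
        else []
    )

    n_immune = round(config.immune_fraction * set_size)
    immune: list = []
    if n_immune:
        immune.extend(rng.choice(hiv_members, size=n_immune, replace=False))
        others = genes.difference(hiv_members)
        immune.extend(rng.choice(others, size=min(n_immune, len(others)),
                                 replace=False))
    sets: dict[str, list] = {}
    for i, name in enumerate(code_names):
        members = genes[assignment == i].tolist()
        if members:
            sets[name] = members
    sets["virus_interacting"] = list(hiv_members)
    sets["immune_response"] = sorted(immune)
    descriptions = {name: "synthetic category" for name in sets}
    descriptions["virus_interacting"] = "planted host-factor set (CV-biased)"
    descriptions["immune_response"] = "planted immune tag"
    return GeneSetCollection(sets, codes=codes, descriptions=descriptions)


def generate_probe_flags(truth: GroundTruth, config: SimulationConfig) -> ProbeFlagTable:
    """Flag a random fraction of probes as overlapping an annotated SNP."""
    rng = config.spawn_streams()["probes"]
    genes = truth.true_cv.index
    flags = rng.random(len(genes)) < config.probe_flag_fraction
    return ProbeFlagTable(pd.Series(flags, index=genes))


@dataclass
class SimulatedDataset:
    """Everything one synthetic study produces, plus its ground truth."""

    config: SimulationConfig
    matrix_a: ExpressionMatrix
    matrix_b: ExpressionMatrix
    snps: SnpTable
    gene_sets: GeneSetCollection
    probe_flags: ProbeFlagTable
    truth: GroundTruth


def generate_all(config: SimulationConfig) -> SimulatedDataset:
    """Run all four generators off one master seed."""
    mat_a, mat_b, truth = generate_expression(config)
    snps = generate_snp_table(truth, config)
    gene_sets = generate_gene_sets(truth, config)
    probe_flags = generate_probe_flags(truth, config)
    return SimulatedDataset(
        config=config,
        matrix_a=mat_a,
        matrix_b=mat_b,
        snps=snps,
        gene_sets=gene_sets,
        probe_flags=probe_flags,
        truth=truth,
    )
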