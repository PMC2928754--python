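"""Hardy-Weinberg expected heterozygosity and the cutoff-sweep enrichment.

Under Hardy-Weinberg equilibrium a bi-allelic SNP with minor-allele
frequency p has expected heterozygosity theta = 2 p (1 - p), the expected
fraction of heterozygous genotypes.  For each SNP genotyped in two
populations, the directed difference delta_theta = theta_focal -
theta_other measures how much more heterozygous the SNP is in the focal
population; its maximal value is 0.5 (MAF 0.5 against MAF 0).

The sweep statistic asks whether a focal gene group (e.g. genes with
higher variability in one population) is enriched, relative to genome
background, for genes bearing at least one cis-SNP with delta_theta above
a cutoff k.  k is swept over an arithmetic grid (default 0 to 0.5 in
steps of 0.04, 13 cutoffs) and significance is assessed at one test
cutoff (default k = 0.04, avoiding the numerically unstable k = 0 bin)
with a two-proportion chi-square test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import SNP_REGIONS, SnpTable
from .errors import AnalysisError, ConfigError
from .outliers import OutlierPartition

__all__ = [
    "HetSweepResult",
    "expected_heterozygosity",
    "delta_theta",
    "sweep_cutoffs",
    "gene_fraction_above",
    "enrichment_chisq",
    "run_hetsweep",
]


def expected_heterozygosity(maf):
    """theta = 2 p (1 - p) for a minor-allele frequency p in [0, 0.5]."""
    maf = np.asarray(maf, dtype=float)
    if np.any(maf < 0) or np.any(maf > 0.5):
        raise AnalysisError("MAF outside [0, 0.5]")
    theta = 2.0 * maf * (1.0 - maf)
    return float(theta) if theta.ndim == 0 else theta


def delta_theta(maf_focal, maf_other):
    """Directed heterozygosity difference theta_focal - theta_other."""
    return expected_heterozygosity(maf_focal) - expected_heterozygosity(maf_other)


def sweep_cutoffs(start: float = 0.0, step: float = 0.04, max_value: float = 0.5):
    """Arithmetic cutoff grid from ``start``, keeping values <= ``max_value``.

    Defaults give the 13 cutoffs 0, 0.04, ..., 0.48.
    """
    if step <= 0:
        raise ConfigError(f"sweep step must be > 0, got {step}")
    n = int(np.floor((max_value - start) / step + 1e-9)) + 1
    return np.round(start + step * np.arange(max(n, 1)), 10)


def _max_delta_per_gene(records: pd.DataFrame, focal: str) -> pd.Series:
    """Max over SNPs of delta_theta per gene; ``focal`` is 'a' or 'b'."""
    if focal == "a":
        d = delta_theta(records["maf_a"].to_numpy(), records["maf_b"].to_numpy())
    else:
        d = delta_theta(records["maf_b"].to_numpy(), records["maf_a"].to_numpy())
    return pd.Series(d, index=records["gene_id"].to_numpy()).groupby(level=0).max()


def gene_fraction_above(genes, max_delta: pd.Series, k: float) -> float:
    """Fraction of ``genes`` whose maximal SNP delta_theta strictly exceeds k.

    ``genes`` must already be restricted to genes with at least one mapped
    SNP in the region (i.e. present in ``max_delta``); genes without SNPs
    never enter the denominator.
    """
    genes = [g for g in genes if g in max_delta.index]
    if not genes:
        raise AnalysisError("no genes with mapped SNPs in this region")
    return float((max_delta.loc[genes] > k).mean())


def enrichment_chisq(
    focal_count_above: int, focal_total: int, bg_count_above: int, bg_total: int
) -> tuple[float, float]:
    """Two-proportion chi-square (df = 1, no continuity correction).

    Equals the square of the pooled two-proportion z statistic.  The
    background may include the focal genes, so the two counts are treated
    as independent samples rather than as a disjoint contingency table.
    """
    for cnt, tot in ((focal_count_above, focal_total), (bg_count_above, bg_total)):
        if cnt < 0 or tot <= 0 or cnt > tot:
            raise AnalysisError(
                f"invalid counts for chi-square: {cnt}/{tot}"
            )
    p1 = focal_count_above / focal_total
    p2 = bg_count_above / bg_total
    pooled = (focal_count_above + bg_count_above) / (focal_total + bg_total)
    if pooled in (0.0, 1.0):
        raise AnalysisError("degenerate margin: pooled proportion is 0 or 1")
    var = pooled * (1 - pooled) * (1 / focal_total + 1 / bg_total)
    chi2 = (p1 - p2) ** 2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


@dataclass
class HetSweepResult:
    """Cutoff-sweep output for one focal group in one region."""

    group: str
    region: str
    cutoffs: np.ndarray
    fraction_focal: np.ndarray
    fraction_background: np.ndarray
    n_focal: int
    n_background: int
    test_cutoff: float
    chi2: float
    p_value: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region": self.region,
                "group": self.group,
                "k": self.cutoffs,
                "fraction_focal": self.fraction_focal,
                "fraction_background": self.fraction_background,
            }
        )


def run_hetsweep(
    partition: OutlierPartition,
    snps: SnpTable,
    region: str,
    step: float = 0.04,
    test_cutoff: float = 0.04,
    include_focal_in_background: bool = True,
) -> dict[str, HetSweepResult]:
    """Sweep enrichment for both direction groups in one cis-region.

    The group with higher eta in population A is tested with delta_theta
    oriented A - B; the other group with B - A.  Background is all genes
    with at least one mapped SNP in the region (including the focal genes
    unless ``include_focal_in_background`` is False).
    """
    if region not in SNP_REGIONS:
        raise ConfigError(f"unknown region {region!r}")
    records = snps.for_region(region)
    if records.empty:
        raise AnalysisError(f"no SNPs mapped to region {region!r}")
    cutoffs = sweep_cutoffs(0.0, step, 0.5)
    pop_a, pop_b = partition.populations
    groups = {
        f"high_{pop_a}": (partition.high_a, "a"),
        f"high_{pop_b}": (partition.high_b, "b"),
    }
    results: dict[str, HetSweepResult] = {}
    for name, (genes, focal) in groups.items():
        max_delta = _max_delta_per_gene(records, focal)
        focal_genes = [g for g in genes if g in max_delta.index]
        if not focal_genes:
            raise AnalysisError(
                f"group {name} has no genes with mapped SNPs in {region!r}"
            )
        if include_focal_in_background:
            bg_genes = max_delta.index.tolist()
        else:
            bg_genes = [g for g in max_delta.index if g not in genes]
        frac_focal = np.array(
            [gene_fraction_above(focal_genes, max_delta, k) for k in cutoffs]
        )
        frac_bg = np.array(
            [gene_fraction_above(bg_genes, max_delta, k) for k in cutoffs]
        )
        focal_above = int((max_delta.loc[focal_genes] > test_cutoff).sum())
        bg_above = int((max_delta.loc[bg_genes] > test_cutoff).sum())
        chi2, p = enrichment_chisq(
            focal_above, len(focal_genes), bg_above, len(bg_genes)
        )
        results[name] = HetSweepResult(
            group=name,
            region=region,
            cutoffs=cutoffs,
            fraction_focal=frac_focal,
            fraction_background=frac_bg,
            n_focal=len(focal_genes),
            n_background=len(bg_genes),
            test_cutoff=test_cutoff,
            chi2=chi2,
            p_value=p,
        )
    return results
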