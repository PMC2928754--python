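"""Per-gene expression variability within populations.

Variability of a gene within one population is measured by its coefficient
of variation eta = sd / mean, computed across individuals on normalized
linear-scale intensities with the sample (n-1) standard deviation.  Eta is
dimensionless and invariant under multiplicative rescaling of a gene's
expression vector, which makes it comparable across genes and platforms.

Preprocessing mirrors a standard two-population microarray protocol:
remove the lowest-expressed genes (ranked by pooled mean intensity), then
median-normalize every sample against the pooled global median so the two
populations share one background scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix
from .errors import AnalysisError, ConfigError

__all__ = [
    "VariabilityProfile",
    "CorrelationSummary",
    "filter_low_expression",
    "median_normalize",
    "compute_eta",
    "build_profile",
    "correlate_eta",
]


@dataclass
class VariabilityProfile:
    """Per-gene eta for each population plus genome-background summaries.

    ``etas`` is a genes x populations DataFrame; ``n_samples`` maps
    population label -> number of individuals the etas were computed from.
    """

    etas: pd.DataFrame
    n_samples: dict[str, int]

    @property
    def populations(self) -> list[str]:
        return list(self.etas.columns)

    @property
    def gene_ids(self) -> pd.Index:
        return self.etas.index

    def eta(self, population: str) -> pd.Series:
        return self.etas[population]

    def genome_median(self, population: str) -> float:
        return float(self.etas[population].median())

    def subset(self, gene_ids) -> "VariabilityProfile":
        return VariabilityProfile(self.etas.loc[gene_ids], dict(self.n_samples))


@dataclass
class CorrelationSummary:
    r: float
    n: int
    p_value: float


def _shared_gene_index(matrices: list[ExpressionMatrix]) -> pd.Index:
    first = matrices[0].gene_ids
    for m in matrices[1:]:
        if not first.equals(m.gene_ids):
            raise AnalysisError(
                "expression matrices do not share a gene universe"
            )
    return first


def filter_low_expression(
    matrices: list[ExpressionMatrix], fraction: float = 0.10
) -> list[ExpressionMatrix]:
    """Drop the ``fraction`` of genes with the lowest pooled mean intensity.

    Genes are ranked by their mean intensity pooled over all samples of all
    populations; the lowest ``floor(fraction * n)`` genes are removed from
    every matrix.  ``fraction=0`` is the identity.
    """
    if not 0 <= fraction < 1:
        raise ConfigError(f"filter fraction must be in [0, 1), got {fraction}")
    genes = _shared_gene_index(matrices)
    if fraction == 0:
        return list(matrices)
    pooled = pd.concat([m.values for m in matrices], axis=1)
    n_drop = int(np.floor(fraction * len(genes)))
    if n_drop == 0:
        return list(matrices)
    # stable sort: ties resolved by input gene order
    order = pooled.mean(axis=1).to_numpy().argsort(kind="stable")
    keep = genes.delete(order[:n_drop])
    return [m.subset_genes(keep) for m in matrices]


def median_normalize(matrices: list[ExpressionMatrix]) -> list[ExpressionMatrix]:
    """Rescale every sample so its median equals the pooled global median.

    The global median is taken over all values of all samples pooled
    across populations, so both populations end up on one background
    scale and the operation is idempotent.
    """
    _shared_gene_index(matrices)
    pooled = np.concatenate([m.values.to_numpy().ravel() for m in matrices])
    global_median = float(np.median(pooled))
    out = []
    for m in matrices:
        medians = m.values.median(axis=0)
        if (medians <= 0).any():
            bad = medians.index[medians <= 0].tolist()
            raise AnalysisError(f"zero sample median for samples: {bad[:5]}")
        out.append(ExpressionMatrix(m.values / medians * global_median, m.population))
    return out


def compute_eta(matrix: ExpressionMatrix) -> pd.Series:
    """Coefficient of variation per gene: sample sd (n-1) over mean."""
    if matrix.n_samples < 2:
        raise AnalysisError("eta needs at least 2 samples")
    means = matrix.values.mean(axis=1)
    if (means <= 0).any():
        bad = means.index[means <= 0].tolist()
        raise AnalysisError(f"non-positive mean expression for gene {bad[0]!r}")
    sds = matrix.values.std(axis=1, ddof=1)
    eta = (sds / means).rename(matrix.population)
    return eta


def build_profile(matrices: list[ExpressionMatrix]) -> VariabilityProfile:
    """Compute eta for every population and assemble a profile."""
    _shared_gene_index(matrices)
    etas = pd.concat([compute_eta(m) for m in matrices], axis=1)
    n_samples = {m.population: m.n_samples for m in matrices}
    return VariabilityProfile(etas, n_samples)


def correlate_eta(
    profile: VariabilityProfile, pop_a: str, pop_b: str
) -> CorrelationSummary:
    """Pearson correlation of eta between two populations over shared genes."""
    x = profile.eta(pop_a).to_numpy()
    y = profile.eta(pop_b).to_numpy()
    if len(x) < 3:
        raise AnalysisError("correlation needs at least 3 shared genes")
    if np.std(x) == 0 or np.std(y) == 0:
        raise AnalysisError("zero variance in an eta vector")
    res = stats.pearsonr(x, y)
    return CorrelationSummary(r=float(res.statistic), n=len(x), p_value=float(res.pvalue))
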