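"""Between-population differential expression by permutation t-test.

The per-gene statistic is the pooled-variance two-sample Student t
(df = n_A + n_B - 2; 58 under the 30 + 30 design), i.e. the standardized
distance between population mean expression levels.  Significance comes
from label permutations: all samples are pooled and repeatedly re-split
into groups of the original sizes, with the same re-split applied to every
gene within a permutation so gene-gene correlation is preserved.  The
empirical p-value uses +1 smoothing, p = (1 + #{|t_perm| >= |t_obs|}) /
(n_perm + 1), and genes are called differentially expressed at a
Benjamini-Hochberg FDR threshold (default 0.01).

``directional_enrichment`` tests whether differentially expressed
variability outliers are biased toward one direction label, against a
null of equally-sized random subsets of the outlier pool.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix
from .errors import AnalysisError, ConfigError
from .outliers import OutlierPartition
from .variability import CorrelationSummary, VariabilityProfile

__all__ = [
    "DEResult",
    "DirectionalEnrichment",
    "t_score",
    "t_scores_matrix",
    "permutation_pvalues",
    "bh_fdr",
    "de_analysis",
    "directional_enrichment",
    "tscore_variability_relation",
]

_PERM_CHUNK = 2000


def t_score(values_a, values_b) -> float:
    """Pooled-variance two-sample t statistic, mean(A) - mean(B) numerator."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise AnalysisError("t-score needs at least 2 samples per group")
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 == 0:
        raise AnalysisError("zero pooled variance")
    return float((a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb)))


def _group_stats(sums, sumsq, n):
    mean = sums / n
    ss = sumsq - sums**2 / n
    return mean, ss


def t_scores_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise pooled-variance t for genes x samples arrays."""
    na, nb = a.shape[1], b.shape[1]
    mean_a, ss_a = _group_stats(a.sum(1), (a**2).sum(1), na)
    mean_b, ss_b = _group_stats(b.sum(1), (b**2).sum(1), nb)
    sp2 = (ss_a + ss_b) / (na + nb - 2)
    if np.any(sp2 <= 0):
        raise AnalysisError("zero pooled variance for at least one gene")
    return (mean_a - mean_b) / np.sqrt(sp2 * (1 / na + 1 / nb))


def permutation_pvalues(
    matrix_a: ExpressionMatrix,
    matrix_b: ExpressionMatrix,
    n_perm: int = 10000,
    seed: int | np.random.Generator | None = 0,
) -> tuple[pd.Series, pd.Series]:
    """Observed t per gene and its label-permutation p-value.

    Returns ``(t_obs, perm_p)`` Series indexed by gene.  The same random
    re-split of the pooled samples is used for all genes within one
    permutation.  Identical seed and inputs give identical p-values.
    """
    if n_perm < 1:
        raise ConfigError(f"n_perm must be >= 1, got {n_perm}")
    if not matrix_a.gene_ids.equals(matrix_b.gene_ids):
        raise AnalysisError("matrices do not share a gene universe")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    a = matrix_a.values.to_numpy(dtype=float)
    b = matrix_b.values.to_numpy(dtype=float)
    na, nb = a.shape[1], b.shape[1]
    n = na + nb
    x = np.hstack([a, b])
    x2 = x**2
    t_obs = t_scores_matrix(a, b)
    abs_obs = np.abs(t_obs) - 1e-12  # guard against float jitter on exact ties

    total = x.sum(1)
    total_sq = x2.sum(1)
    exceed = np.zeros(x.shape[0], dtype=np.int64)
    done = 0
    while done < n_perm:
        block = min(_PERM_CHUNK, n_perm - done)
        # one 0/1 column-selection matrix per permutation in the block
        masks = np.zeros((n, block))
        for j in range(block):
            masks[rng.permutation(n)[:na], j] = 1.0
        sum_a = x @ masks
        sumsq_a = x2 @ masks
        sum_b = total[:, None] - sum_a
        sumsq_b = total_sq[:, None] - sumsq_a
        mean_a, ss_a = _group_stats(sum_a, sumsq_a, na)
        mean_b, ss_b = _group_stats(sum_b, sumsq_b, nb)
        sp2 = (ss_a + ss_b) / (n - 2)
        sp2 = np.maximum(sp2, 1e-300)
        t_perm = (mean_a - mean_b) / np.sqrt(sp2 * (1 / na + 1 / nb))
        exceed += (np.abs(t_perm) >= abs_obs[:, None]).sum(1)
        done += block
    perm_p = (1 + exceed) / (n_perm + 1)
    index = matrix_a.gene_ids
    return (
        pd.Series(t_obs, index=index, name="t_score"),
        pd.Series(perm_p, index=index, name="perm_p"),
    )


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise AnalysisError("empty p-value vector")
    if np.any(p <= 0) or np.any(p > 1):
        raise AnalysisError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DEResult:
    """Per-gene differential-expression calls between two populations."""

    table: pd.DataFrame  # columns: t_score, perm_p, q_value, is_de
    populations: tuple[str, str]
    n_perm: int
    fdr_threshold: float

    @property
    def de_genes(self) -> list:
        return self.table.index[self.table["is_de"]].tolist()


def de_analysis(
    matrix_a: ExpressionMatrix,
    matrix_b: ExpressionMatrix,
    n_perm: int = 10000,
    seed: int | np.random.Generator | None = 0,
    fdr_threshold: float = 0.01,
) -> DEResult:
    """Permutation t-test for every gene followed by BH FDR correction."""
    if not 0 < fdr_threshold < 1:
        raise ConfigError(f"FDR threshold must be in (0, 1), got {fdr_threshold}")
    t_obs, perm_p = permutation_pvalues(matrix_a, matrix_b, n_perm=n_perm, seed=seed)
    q = bh_fdr(perm_p.to_numpy())
    table = pd.DataFrame(
        {
            "t_score": t_obs,
            "perm_p": perm_p,
            "q_value": q,
            "is_de": q <= fdr_threshold,
        }
    )
    return DEResult(
        table=table,
        populations=(matrix_a.population, matrix_b.population),
        n_perm=n_perm,
        fdr_threshold=fdr_threshold,
    )


@dataclass
class DirectionalEnrichment:
    """Bias of DE outlier genes toward one variability-direction label."""

    focal_label: str
    observed_fraction: float
    pool_fraction: float
    n_de: int
    n_pool: int
    null_fractions: np.ndarray
    p_value: float


def directional_enrichment(
    de_outliers,
    partition: OutlierPartition,
    focal: str = "b",
    n_draws: int = 10000,
    seed: int | np.random.Generator | None = 0,
) -> DirectionalEnrichment:
    """Test whether DE outliers over-represent one direction label.

    ``observed`` is the fraction of ``de_outliers`` carrying the focal
    label (higher eta in population B by default).  The null re-draws
    subsets of the same size uniformly without replacement from the full
    direction-labeled outlier pool; the one-sided empirical p uses +1
    smoothing.
    """
    if focal not in ("a", "b"):
        raise ConfigError("focal must be 'a' or 'b'")
    if n_draws < 1:
        raise ConfigError(f"n_draws must be >= 1, got {n_draws}")
    pool = sorted(partition.high_a | partition.high_b)
    focal_set = partition.high_b if focal == "b" else partition.high_a
    de_outliers = set(de_outliers)
    if not de_outliers:
        raise AnalysisError("empty DE-outlier set")
    stray = de_outliers - set(pool)
    if stray:
        raise AnalysisError(
            f"DE outliers not in the direction-labeled pool: {sorted(stray)[:5]}"
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    is_focal = np.array([g in focal_set for g in pool])
    m = len(de_outliers)
    observed = sum(1 for g in de_outliers if g in focal_set) / m
    # uniform subsets of size m: take the m smallest of iid uniform keys
    null_counts = np.empty(n_draws, dtype=np.int64)
    chunk = max(1, min(n_draws, 4_000_000 // max(len(pool), 1)))
    done = 0
    while done < n_draws:
        block = min(chunk, n_draws - done)
        keys = rng.random((block, len(pool)))
        idx = np.argpartition(keys, m - 1, axis=1)[:, :m]
        null_counts[done : done + block] = is_focal[idx].sum(1)
        done += block
    null_fractions = null_counts / m
    p = (1 + int((null_fractions >= observed - 1e-12).sum())) / (n_draws + 1)
    label = partition.populations[1] if focal == "b" else partition.populations[0]
    return DirectionalEnrichment(
        focal_label=f"high_{label}",
        observed_fraction=float(observed),
        pool_fraction=float(is_focal.mean()),
        n_de=m,
        n_pool=len(pool),
        null_fractions=null_fractions,
        p_value=float(p),
    )


def tscore_variability_relation(
    de_result: DEResult,
    profile: VariabilityProfile,
    population: str,
    eta_cap: float = 0.05,
) -> CorrelationSummary:
    """Pearson correlation of signed t-score with eta below a cap.

    Genes with eta >= ``eta_cap`` (a small high-variability tail) are
    excluded before correlating, mirroring the restriction used when
    relating evolvability of expression level to within-population
    variability.
    """
    shared = de_result.table.index.intersection(profile.gene_ids)
    if len(shared) < 3:
        raise AnalysisError("fewer than 3 shared genes")
    eta = profile.eta(population).loc[shared]
    keep = eta < eta_cap
    t = de_result.table.loc[shared, "t_score"][keep]
    eta = eta[keep]
    if len(t) < 3:
        raise AnalysisError("fewer than 3 genes below the eta cap")
    res = stats.pearsonr(t.to_numpy(), eta.to_numpy())
    return CorrelationSummary(r=float(res.statistic), n=len(t), p_value=float(res.pvalue))
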