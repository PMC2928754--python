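"""Gene-group analyses of expression variability.

Covers four related procedures:

* tail selection — after excluding every gene that was a variability
  outlier in either regression direction, rank the remaining genes by eta
  and take the extreme ``tail_fraction`` (default 2.5%) at each end;
* over-representation — one-sided hypergeometric enrichment of a study set
  against user-supplied gene sets with BH correction across sets;
* group-versus-genome comparisons — Wilcoxon rank-sum of a gene group's
  eta against all remaining genes, with percentile bootstrap confidence
  intervals for the group mean;
* annotation-matched null sets — re-draw, for every group gene, a
  non-group gene sharing its most specific category code, and count how
  often the real group is significantly more variable than such a null
  set; this controls for annotation composition when a group (e.g. virus-
  interacting host factors) looks more variable than the genome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GeneSetCollection
from .diffexpr import bh_fdr
from .errors import AnalysisError, ConfigError
from .variability import VariabilityProfile

__all__ = [
    "TailSelection",
    "GroupComparison",
    "select_tails",
    "overrepresentation",
    "group_vs_genome",
    "rank_sum_test",
    "bootstrap_ci",
    "matched_null_comparison",
    "exclude_keyword_genes",
    "fold_change",
]


@dataclass
class TailSelection:
    """Most- and least-variable gene tails after outlier exclusion."""

    population: str
    universe_size: int
    tail_size: int
    bottom: list
    top: list


def select_tails(
    profile: VariabilityProfile,
    population: str,
    exclusion=(),
    tail_fraction: float = 0.025,
) -> TailSelection:
    """Top and bottom ``tail_fraction`` of genes ranked by eta.

    ``exclusion`` (typically the union of both regression directions'
    outliers) is removed first.  Tail size is ``floor(tail_fraction * n)``
    on the remaining universe; ranking ties are broken by gene id so the
    selection is independent of input order.
    """
    if not 0 < tail_fraction < 0.5:
        raise ConfigError(f"tail fraction must be in (0, 0.5), got {tail_fraction}")
    eta = profile.eta(population).drop(index=list(exclusion), errors="ignore")
    n = len(eta)
    k = int(np.floor(tail_fraction * n))
    if k == 0:
        raise AnalysisError(
            f"tail of size 0: fraction {tail_fraction} on {n} genes"
        )
    order = eta.rename("eta").rename_axis("gene_id").reset_index()
    order = order.sort_values(["eta", "gene_id"], kind="stable")
    ranked = order["gene_id"].tolist()
    return TailSelection(
        population=population,
        universe_size=n,
        tail_size=k,
        bottom=ranked[:k],
        top=ranked[-k:],
    )


def overrepresentation(
    study, collection: GeneSetCollection, universe
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``study`` in each named set.

    One-sided upper-tail p per set (P[overlap >= observed] drawing
    ``|study|`` genes from the universe), BH-adjusted across all tested
    sets; rows sorted by q then name.
    """
    universe = set(universe)
    study = set(study)
    if not study:
        raise AnalysisError("empty study set")
    if not study <= universe:
        raise AnalysisError("study set is not contained in the universe")
    rows = []
    for name, members in collection.sets.items():
        members_in = set(members) & universe
        overlap = len(members_in & study)
        p = float(
            stats.hypergeom.sf(
                overlap - 1, len(universe), len(members_in), len(study)
            )
        )
        rows.append(
            {
                "set_name": name,
                "overlap": overlap,
                "set_size": len(members_in),
                "study_size": len(study),
                "universe_size": len(universe),
                "p_value": p,
            }
        )
    df = pd.DataFrame(rows)
    df["q_value"] = bh_fdr(df["p_value"].clip(lower=np.nextafter(0, 1)).to_numpy())
    return df.sort_values(["q_value", "set_name"], kind="stable").reset_index(drop=True)


def rank_sum_test(x, y, alternative: str = "two-sided") -> float:
    """Wilcoxon rank-sum p-value.

    Exact enumeration when both samples have <= 10 tie-free observations,
    otherwise the tie-corrected normal approximation with continuity
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise AnalysisError("rank-sum test needs non-empty samples")
    ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    method = "exact" if (x.size <= 10 and y.size <= 10 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.pvalue)


@dataclass
class GroupComparison:
    """Variability of a gene group against the genome background."""

    group: str
    population: str
    n_group: int
    group_mean_eta: float
    group_median_eta: float
    genome_median_eta: float
    ranksum_p: float
    ci_low: float | None = None
    ci_high: float | None = None
    null_exceedance: int | None = None
    n_null_sets: int | None = None
    mean_relative_excess: float | None = None
    n_unmatched: int | None = None


def group_vs_genome(
    group, profile: VariabilityProfile, population: str, name: str = "group"
) -> GroupComparison:
    """Two-sided rank-sum comparison of group eta against all other genes."""
    eta = profile.eta(population)
    group = [g for g in group if g in eta.index]
    if len(group) < 2:
        raise AnalysisError("group needs at least 2 genes present in the profile")
    complement = eta.index.difference(group)
    if complement.empty:
        raise AnalysisError("group covers the whole genome; empty complement")
    gx = eta.loc[group].to_numpy()
    cx = eta.loc[complement].to_numpy()
    return GroupComparison(
        group=name,
        population=population,
        n_group=len(group),
        group_mean_eta=float(gx.mean()),
        group_median_eta=float(np.median(gx)),
        genome_median_eta=float(eta.median()),
        ranksum_p=rank_sum_test(gx, cx, alternative="two-sided"),
    )


def bootstrap_ci(
    values,
    n_boot: int = 5000,
    level: float = 0.95,
    seed: int | np.random.Generator | None = 0,
) -> tuple[float, float]:
    """Seeded percentile bootstrap CI for the mean of ``values``."""
    if n_boot < 1:
        raise ConfigError(f"n_boot must be >= 1, got {n_boot}")
    if not 0 < level < 1:
        raise ConfigError(f"level must be in (0, 1), got {level}")
    vals = np.asarray(values, dtype=float)
    if vals.size < 2:
        raise AnalysisError("bootstrap needs at least 2 values")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    idx = rng.integers(0, vals.size, size=(n_boot, vals.size))
    means = vals[idx].mean(axis=1)
    alpha = (1 - level) / 2
    lo, hi = np.quantile(means, [alpha, 1 - alpha])
    return float(lo), float(hi)


def matched_null_comparison(
    group,
    collection: GeneSetCollection,
    profile: VariabilityProfile,
    population: str,
    n_sets: int = 1000,
    alpha: float = 0.05,
    seed: int | np.random.Generator | None = 0,
    name: str = "group",
) -> GroupComparison:
    """Compare group eta against annotation-matched null gene sets.

    For every group gene whose most specific category code is shared by at
    least one non-group gene, each null replicate draws one such non-group
    gene (without replacement within the replicate).  Group genes with no
    eligible match — or more demand than same-code supply — are dropped
    and counted.  The result records how many of the ``n_sets`` replicates
    the group's eta distribution exceeds the null's (one-sided rank-sum at
    ``alpha``) and the mean relative excess of the group mean eta.
    """
    if collection.codes is None:
        raise AnalysisError("collection carries no most-specific category codes")
    if n_sets < 1:
        raise ConfigError(f"n_sets must be >= 1, got {n_sets}")
    eta = profile.eta(population)
    group = [g for g in group if g in eta.index]
    group_set = set(group)
    codes = collection.codes
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    complement_by_code: dict = {}
    for g in eta.index:
        if g in group_set or g not in codes.index:
            continue
        complement_by_code.setdefault(codes[g], []).append(g)

    demand: dict = {}
    n_unmatched = 0
    for g in group:
        code = codes.get(g)
        if code is None or code not in complement_by_code:
            n_unmatched += 1
            continue
        demand[code] = demand.get(code, 0) + 1
    matched_total = 0
    for code in list(demand):
        supply = len(complement_by_code[code])
        if demand[code] > supply:
            n_unmatched += demand[code] - supply
            demand[code] = supply
        matched_total += demand[code]
    if matched_total == 0:
        raise AnalysisError("no group gene has a same-code non-group match")

    # assemble the null eta matrix (n_sets x matched_total) code by code
    null_cols = []
    for code, d in sorted(demand.items()):
        if d == 0:
            continue
        cand = np.array([eta[g] for g in complement_by_code[code]])
        keys = rng.random((n_sets, cand.size))
        take = np.argpartition(keys, d - 1, axis=1)[:, :d]
        null_cols.append(cand[take])
    null_eta = np.hstack(null_cols)

    group_eta = eta.loc[group].to_numpy()
    res = stats.mannwhitneyu(
        group_eta[None, :], null_eta, axis=1, alternative="greater",
        method="asymptotic",
    )
    exceed = int((res.pvalue < alpha).sum())
    rel_excess = float((group_eta.mean() / null_eta.mean(axis=1) - 1).mean())
    return GroupComparison(
        group=name,
        population=population,
        n_group=len(group),
        group_mean_eta=float(group_eta.mean()),
        group_median_eta=float(np.median(group_eta)),
        genome_median_eta=float(eta.median()),
        ranksum_p=rank_sum_test(
            group_eta, eta.drop(index=group).to_numpy(), alternative="two-sided"
        ),
        null_exceedance=exceed,
        n_null_sets=n_sets,
        mean_relative_excess=rel_excess,
        n_unmatched=n_unmatched,
    )


def exclude_keyword_genes(
    group, collection: GeneSetCollection, keyword: str = "immune"
) -> list:
    """Remove genes annotated to any category whose name contains ``keyword``.

    The match is a case-insensitive substring test on gene-set names and on
    per-gene category codes.
    """
    kw = keyword.lower()
    tagged: set = set()
    for set_name, members in collection.sets.items():
        if kw in set_name.lower():
            tagged.update(members)
    if collection.codes is not None:
        mask = collection.codes.astype(str).str.lower().str.contains(kw, regex=False)
        tagged.update(collection.codes.index[mask])
    kept = [g for g in group if g not in tagged]
    if not kept and list(group):
        import logging

        logging.getLogger(__name__).warning(
            "keyword %r excluded every gene in the group", keyword
        )
    return kept


def fold_change(gene, profile: VariabilityProfile, population: str) -> float:
    """Ratio of one gene's eta to the genome median eta of the population."""
    eta = profile.eta(population)
    if gene not in eta.index:
        raise AnalysisError(f"gene {gene!r} absent from the profile")
    median = profile.genome_median(population)
    if median <= 0:
        raise AnalysisError("non-positive genome median eta")
    return float(eta[gene] / median)
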