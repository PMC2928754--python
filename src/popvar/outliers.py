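"""Population-specific variability outliers via reciprocal regression.

A gene whose within-population variability differs between two populations
falls away from the common linear relation between the per-gene eta values.
We fit ordinary least squares of eta in one population on eta in the other,
Studentize the residuals, and flag genes whose Studentized residual lies
outside the two-sided confidence band of a Student t distribution with
n - 3 degrees of freedom.  The regression is run in both directions;
genes flagged independently of direction form the analysis set, which is
then split by which population shows the higher eta.

Externally Studentized residuals (leave-one-out variance estimate) are the
default because they are exactly t-distributed under the Gaussian model;
internally Studentized residuals are available behind a switch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .containers import ProbeFlagTable
from .errors import AnalysisError, ConfigError
from .variability import VariabilityProfile

__all__ = [
    "RegressionFit",
    "OutlierPartition",
    "fit_variability_regression",
    "flag_outliers",
    "reciprocal_outliers",
    "remove_probe_snp_genes",
]

logger = logging.getLogger(__name__)


@dataclass
class RegressionFit:
    """One direction of the eta-on-eta least-squares fit.

    ``studentized`` holds externally (default) or internally Studentized
    residuals, indexed like the input; ``df_resid_outlier`` is the degrees
    of freedom of the reference t distribution for outlier calling
    (n - 3 for the external flavor).
    """

    slope: float
    intercept: float
    fitted: pd.Series
    residuals: pd.Series
    studentized: pd.Series
    n: int
    df_resid_outlier: int
    flavor: str = "external"
    flags: pd.Series | None = field(default=None)


def fit_variability_regression(
    x: pd.Series, y: pd.Series, studentize: str = "external"
) -> RegressionFit:
    """OLS of ``y`` on ``x`` with intercept, plus residual diagnostics.

    Parameters
    ----------
    x, y
        Equal-length eta vectors sharing an index; n >= 4 so that the
        leave-one-out variance estimate has at least one degree of freedom.
    studentize
        ``"external"`` (leave-one-out, default) or ``"internal"``.
    """
    if studentize not in ("external", "internal"):
        raise ConfigError(f"unknown studentization flavor {studentize!r}")
    if len(x) != len(y):
        raise AnalysisError("eta vectors differ in length")
    n = len(x)
    if n < 4:
        raise AnalysisError(f"regression needs n >= 4, got {n}")
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if np.ptp(xv) == 0:
        raise AnalysisError("zero variance in the explanatory eta vector")
    index = x.index if isinstance(x, pd.Series) else pd.RangeIndex(n)

    design = sm.add_constant(xv)
    res = sm.OLS(yv, design).fit()
    influence = res.get_influence()
    if studentize == "external":
        student = influence.resid_studentized_external
        df = n - 3
    else:
        student = influence.resid_studentized_internal
        df = n - 2
    return RegressionFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        fitted=pd.Series(res.fittedvalues, index=index),
        residuals=pd.Series(res.resid, index=index),
        studentized=pd.Series(student, index=index),
        n=n,
        df_resid_outlier=df,
        flavor=studentize,
    )


def flag_outliers(fit: RegressionFit, level: float = 0.95) -> pd.Series:
    """Flag points whose |Studentized residual| exceeds the t band.

    A point is an outlier iff its Studentized residual falls outside the
    two-sided ``level`` confidence band of the Student t distribution with
    ``fit.df_resid_outlier`` degrees of freedom.
    """
    if not 0 < level < 1:
        raise ConfigError(f"level must be in (0, 1), got {level}")
    crit = stats.t.ppf(0.5 + level / 2, fit.df_resid_outlier)
    flags = fit.studentized.abs() > crit
    fit.flags = flags
    return flags


@dataclass
class OutlierPartition:
    """Direction-resolved outlier calls from the reciprocal regressions.

    ``intersection`` (direction-independent outliers) is split into the
    set with higher eta in population A (``high_a``) and higher eta in
    population B (``high_b``); exact ties are excluded and reported in
    ``ties``.  ``union`` is the direction-union, used when excluding all
    possibly-outlying genes from genome-wide analyses.
    """

    populations: tuple[str, str]
    direction1: set
    direction2: set
    intersection: set
    union: set
    high_a: set
    high_b: set
    ties: set
    fits: tuple[RegressionFit, RegressionFit] | None = None

    def swap(self) -> "OutlierPartition":
        """The same partition with the two populations relabeled."""
        return OutlierPartition(
            populations=(self.populations[1], self.populations[0]),
            direction1=set(self.direction2),
            direction2=set(self.direction1),
            intersection=set(self.intersection),
            union=set(self.union),
            high_a=set(self.high_b),
            high_b=set(self.high_a),
            ties=set(self.ties),
        )

    def summary(self) -> dict:
        return {
            "n_direction1": len(self.direction1),
            "n_direction2": len(self.direction2),
            "n_intersection": len(self.intersection),
            "n_union": len(self.union),
            "n_high_" + self.populations[0]: len(self.high_a),
            "n_high_" + self.populations[1]: len(self.high_b),
            "n_ties": len(self.ties),
        }


def reciprocal_outliers(
    profile: VariabilityProfile,
    pop_a: str,
    pop_b: str,
    level: float = 0.95,
    studentize: str = "external",
) -> OutlierPartition:
    """Run the regression in both directions and partition the outliers.

    Direction 1 regresses eta_A on eta_B (B explanatory), direction 2 the
    reverse.  The intersection of the two flag sets defines the
    direction-independent outliers, labeled by which population has the
    higher eta.
    """
    eta_a = profile.eta(pop_a)
    eta_b = profile.eta(pop_b)
    fit1 = fit_variability_regression(eta_b, eta_a, studentize=studentize)
    fit2 = fit_variability_regression(eta_a, eta_b, studentize=studentize)
    flags1 = flag_outliers(fit1, level)
    flags2 = flag_outliers(fit2, level)
    d1 = set(flags1.index[flags1])
    d2 = set(flags2.index[flags2])
    inter = d1 & d2
    union = d1 | d2
    diff = eta_a.loc[sorted(inter)] - eta_b.loc[sorted(inter)]
    high_a = set(diff.index[diff > 0])
    high_b = set(diff.index[diff < 0])
    ties = inter - high_a - high_b
    if ties:
        logger.warning(
            "%d outlier genes with exactly tied eta excluded from the "
            "direction split", len(ties),
        )
    return OutlierPartition(
        populations=(pop_a, pop_b),
        direction1=d1,
        direction2=d2,
        intersection=inter,
        union=union,
        high_a=high_a,
        high_b=high_b,
        ties=ties,
        fits=(fit1, fit2),
    )


def remove_probe_snp_genes(
    partition: OutlierPartition,
    flags: ProbeFlagTable,
    universe=None,
) -> tuple[OutlierPartition, dict]:
    """Drop genes whose probe overlaps an annotated SNP from every set.

    Returns the cleaned partition together with a report comparing the
    flagged fraction inside the outlier set against the background flagged
    fraction (two-proportion chi-square), which checks that probe-SNP
    artifacts do not explain the outlier calls.
    """
    from .heterozygosity import enrichment_chisq

    flagged = set(flags.flagged_genes())

    def clean(genes: set) -> set:
        return {g for g in genes if g not in flagged}

    cleaned = OutlierPartition(
        populations=partition.populations,
        direction1=clean(partition.direction1),
        direction2=clean(partition.direction2),
        intersection=clean(partition.intersection),
        union=clean(partition.union),
        high_a=clean(partition.high_a),
        high_b=clean(partition.high_b),
        ties=clean(partition.ties),
    )
    n_before = len(partition.intersection)
    n_removed = n_before - len(cleaned.intersection)
    if n_before and not cleaned.intersection:
        logger.warning("all outlier genes were probe-flagged; partition is empty")
    report = {
        "n_intersection_before": n_before,
        "n_intersection_removed": n_removed,
        "n_intersection_after": len(cleaned.intersection),
    }
    if universe is not None:
        universe = pd.Index(universe)
        bg_flagged = int(flags.is_flagged(universe).sum())
        if n_before > 0 and len(universe) > 0 and 0 < bg_flagged:
            chi2, p = enrichment_chisq(n_removed, n_before, bg_flagged, len(universe))
            report.update(
                {
                    "background_flagged": bg_flagged,
                    "background_total": len(universe),
                    "chi2": chi2,
                    "p_value": p,
                }
            )
    return cleaned, report
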