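from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from popvar.containers import ExpressionMatrix
from popvar.diffexpr import (
    bh_fdr,
    de_analysis,
    directional_enrichment,
    permutation_pvalues,
    t_score,
    t_scores_matrix,
    tscore_variability_relation,
)
from popvar.errors import AnalysisError, ConfigError
from popvar.outliers import OutlierPartition
from popvar.variability import VariabilityProfile


def _pair_from_arrays(a, b):
    a = np.atleast_2d(np.asarray(a, float))
    b = np.atleast_2d(np.asarray(b, float))
    genes = pd.Index([f"g{i}" for i in range(a.shape[0])], name="gene_id")
    ma = ExpressionMatrix(
        pd.DataFrame(a, index=genes, columns=[f"a{j}" for j in range(a.shape[1])]),
        "popA",
    )
    mb = ExpressionMatrix(
        pd.DataFrame(b, index=genes, columns=[f"b{j}" for j in range(b.shape[1])]),
        "popB",
    )
    return ma, mb


class TestTScore:
    def test_identical_groups_zero(self):
        assert t_score([1, 2, 3], [1, 2, 3]) == 0.0

    def test_hand_computed_value(self):
        assert t_score([1, 2, 3], [4, 5, 6]) == pytest.approx(-3.674, abs=5e-4)

    def test_tail_probabilities_at_df58(self):
        # the 30+30 design: |t| = 4 <-> p ~ 2e-4, |t| = 2 <-> p ~ 0.05
        p4 = 2 * stats.t.sf(4, 58)
        p2 = 2 * stats.t.sf(2, 58)
        assert float(f"{p4:.0e}") == 2e-4
        assert round(p2, 2) == 0.05

    def test_antisymmetric_under_group_swap(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=(2, 12))
        assert t_score(a, b) == pytest.approx(-t_score(b, a))

    def test_zero_pooled_variance_rejected(self):
        with pytest.raises(AnalysisError):
            t_score([2.0, 2.0], [2.0, 2.0])

    def test_matrix_version_matches_scalar(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(20, 7))
        b = rng.normal(size=(20, 9))
        ts = t_scores_matrix(a, b)
        for i in range(20):
            assert ts[i] == pytest.approx(t_score(a[i], b[i]), abs=1e-10)


def _exhaustive_pvalue(a, b):
    """Enumerate all re-splits of the pooled samples (oracle)."""
    pooled = np.concatenate([a, b])
    n = len(pooled)
    t_obs = abs(t_score(a, b))
    count = total = 0
    for idx in combinations(range(n), len(a)):
        mask = np.zeros(n, dtype=bool)
        mask[list(idx)] = True
        count += abs(t_score(pooled[mask], pooled[~mask])) >= t_obs - 1e-12
        total += 1
    return count / total


class TestPermutationPvalues:
    def test_matches_exhaustive_enumeration_3_plus_3(self):
        a = np.array([[1.0, 2.0, 3.0], [5.0, 6.0, 4.0], [1.0, 1.5, 0.5]])
        b = np.array([[7.0, 8.0, 6.0], [5.5, 6.5, 4.5], [9.0, 1.0, 2.0]])
        ma, mb = _pair_from_arrays(a, b)
        _, perm_p = permutation_pvalues(ma, mb, n_perm=10000, seed=1)
        for i in range(3):
            exact = _exhaustive_pvalue(a[i], b[i])
            # MC error of a binomial proportion at n_perm = 10000
            assert perm_p.iloc[i] == pytest.approx(exact, abs=4 * np.sqrt(exact * (1 - exact) / 10000) + 2e-4)

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(7)
        a = rng.normal(10, 1, size=(500, 30))
        b = rng.normal(10, 1, size=(500, 30))
        ma, mb = _pair_from_arrays(a, b)
        _, perm_p = permutation_pvalues(ma, mb, n_perm=2000, seed=2)
        assert stats.kstest(perm_p.to_numpy(), "uniform").pvalue > 0.01

    def test_saturated_effect_reaches_min_p(self):
        rng = np.random.default_rng(8)
        a = rng.normal(100, 1, size=(1, 30))
        b = rng.normal(110, 1, size=(1, 30))
        ma, mb = _pair_from_arrays(a, b)
        _, perm_p = permutation_pvalues(ma, mb, n_perm=999, seed=3)
        assert perm_p.iloc[0] == pytest.approx(1 / 1000)

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(9)
        a = rng.lognormal(size=(10, 6))
        b = rng.lognormal(size=(10, 6))
        ma, mb = _pair_from_arrays(a, b)
        p1 = permutation_pvalues(ma, mb, n_perm=200, seed=5)[1]
        p2 = permutation_pvalues(ma, mb, n_perm=200, seed=5)[1]
        pd.testing.assert_series_equal(p1, p2)

    def test_bad_nperm(self):
        ma, mb = _pair_from_arrays([[1.0, 2.0]], [[3.0, 4.0]])
        with pytest.raises(ConfigError):
            permutation_pvalues(ma, mb, n_perm=0)


class TestBH:
    def test_equal_pvalues_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.03] * 10), [0.03] * 10)

    def test_step_up_hand_computation(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_pvalue_identity(self):
        np.testing.assert_allclose(bh_fdr([0.2]), [0.2])

    def test_monotone_in_p(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=200)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()
        assert (q >= p).all() and (q <= 1).all()

    def test_controls_false_discovery_proportion(self):
        """Mean FDP <= alpha over 500 simulated mixture datasets."""
        rng = np.random.default_rng(4)
        alpha = 0.1
        fdps = []
        for _ in range(500):
            null_p = rng.uniform(size=80)
            alt_p = rng.beta(0.05, 8, size=20)  # stochastically small
            p = np.concatenate([null_p, alt_p])
            q = bh_fdr(p)
            rejected = q <= alpha
            if rejected.any():
                fdps.append(rejected[:80].sum() / rejected.sum())
            else:
                fdps.append(0.0)
        assert np.mean(fdps) <= alpha + 0.02


def _partition_with(high_a, high_b):
    return OutlierPartition(
        populations=("popA", "popB"),
        direction1=set(high_a) | set(high_b),
        direction2=set(high_a) | set(high_b),
        intersection=set(high_a) | set(high_b),
        union=set(high_a) | set(high_b),
        high_a=set(high_a),
        high_b=set(high_b),
        ties=set(),
    )


class TestDirectionalEnrichment:
    def test_degenerate_full_pool_draw(self):
        part = _partition_with([f"a{i}" for i in range(40)],
                               [f"b{i}" for i in range(30)])
        pool = sorted(part.high_a | part.high_b)
        res = directional_enrichment(pool, part, n_draws=500, seed=0)
        assert res.observed_fraction == pytest.approx(res.pool_fraction)
        assert res.p_value > 0.4

    def test_extreme_bias_hits_min_p(self):
        """All DE outliers from the focal label in a 44%-focal pool."""
        part = _partition_with([f"a{i}" for i in range(379)],
                               [f"b{i}" for i in range(300)])
        de = [f"b{i}" for i in range(184)]
        res = directional_enrichment(de, part, n_draws=10000, seed=1)
        assert res.p_value == pytest.approx(1 / 10001)
        # closed-form oracle confirms the tail really is < 1e-5
        exact = stats.hypergeom.sf(183, 679, 300, 184)
        assert exact < 1e-5

    def test_matches_hypergeometric_tail_on_small_pool(self):
        part = _partition_with([f"a{i}" for i in range(12)],
                               [f"b{i}" for i in range(8)])
        de = [f"b{i}" for i in range(5)] + [f"a{i}" for i in range(3)]
        res = directional_enrichment(de, part, n_draws=20000, seed=2)
        exact = stats.hypergeom.sf(4, 20, 8, 8)  # P[X >= 5]
        assert res.p_value == pytest.approx(exact, abs=0.012)

    def test_empty_de_rejected(self):
        part = _partition_with(["a0"], ["b0"])
        with pytest.raises(AnalysisError):
            directional_enrichment([], part)


class TestTscoreEtaRelation:
    def _de_result(self, t):
        genes = pd.Index([f"g{i}" for i in range(len(t))], name="gene_id")
        table = pd.DataFrame(
            {
                "t_score": t,
                "perm_p": np.full(len(t), 0.5),
                "q_value": np.ones(len(t)),
                "is_de": False,
            },
            index=genes,
        )
        from popvar.diffexpr import DEResult

        return DEResult(table, ("popA", "popB"), 10, 0.01)

    def _profile(self, eta):
        genes = pd.Index([f"g{i}" for i in range(len(eta))], name="gene_id")
        return VariabilityProfile(
            pd.DataFrame({"popA": eta}, index=genes), {"popA": 30}
        )

    def test_independent_eta_gives_near_zero_r(self):
        rng = np.random.default_rng(11)
        t = rng.normal(size=2000)
        eta = rng.uniform(0.001, 0.049, size=2000)
        res = tscore_variability_relation(
            self._de_result(t), self._profile(eta), "popA"
        )
        assert abs(res.r) < 0.08

    def test_monotone_eta_gives_high_r(self):
        t = np.linspace(-3, 3, 500)
        eta = 0.001 + 0.004 * (t - t.min())
        res = tscore_variability_relation(
            self._de_result(t), self._profile(eta), "popA"
        )
        assert res.r > 0.9

    def test_eta_cap_applied(self):
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        eta = np.array([0.01, 0.02, 0.03, 0.2, 0.3])
        res = tscore_variability_relation(
            self._de_result(t), self._profile(eta), "popA", eta_cap=0.05
        )
        assert res.n == 3


def test_positive_tscore_eta_relation_recovered_from_planted_coupling():
    """DE direction coupled to CV rank yields a positive t-eta correlation."""
    from popvar.outliers import reciprocal_outliers
    from popvar.simulate import SimulationConfig, generate_all
    from popvar.variability import (
        build_profile, filter_low_expression, median_normalize,
    )

    rs = []
    for seed in range(3):
        d = generate_all(SimulationConfig(n_genes=1500, seed=40 + seed))
        mats = median_normalize(filter_low_expression([d.matrix_a, d.matrix_b]))
        prof = build_profile(mats)
        part = reciprocal_outliers(prof, "popA", "popB")
        de = de_analysis(mats[0], mats[1], n_perm=50, seed=seed)
        res = tscore_variability_relation(
            de, prof.subset(prof.gene_ids.difference(part.union)), "popA"
        )
        rs.append(res.r)
    assert np.mean(rs) > 0.05
    assert sum(r > 0 for r in rs) >= 2


def test_de_analysis_recovers_planted_mean_shifts(dataset):
    """Planted one-SD shifts are enriched among FDR-0.01 calls."""
    de = de_analysis(dataset.matrix_a, dataset.matrix_b, n_perm=2000, seed=6)
    called = set(de.de_genes)
    planted = set(dataset.truth.de_sign)
    assert called
    precision = len(called & planted) / len(called)
    assert precision > 0.9
    # direction of the shift matches the sign of the t-score
    t = de.table["t_score"]
    correct = sum(
        np.sign(t[g]) == dataset.truth.de_sign[g]
        for g in called & planted
    )
    assert correct / len(called & planted) > 0.95
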