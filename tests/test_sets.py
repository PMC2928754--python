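from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from popvar.containers import GeneSetCollection
from popvar.errors import AnalysisError, ConfigError
from popvar.sets import (
    bootstrap_ci,
    exclude_keyword_genes,
    fold_change,
    group_vs_genome,
    matched_null_comparison,
    overrepresentation,
    rank_sum_test,
    select_tails,
)
from popvar.variability import VariabilityProfile


def _profile(eta, pop="popA", genes=None):
    eta = np.asarray(eta, dtype=float)
    genes = pd.Index(genes or [f"g{i:04d}" for i in range(len(eta))],
                     name="gene_id")
    return VariabilityProfile(pd.DataFrame({pop: eta}, index=genes), {pop: 30})


class TestSelectTails:
    def test_two_and_a_half_percent_tails_of_16975_genes(self):
        prof = _profile(np.linspace(0.001, 0.2, 16975))
        sel = select_tails(prof, "popA")
        assert sel.tail_size == 424
        assert len(sel.top) == len(sel.bottom) == 424
        assert not set(sel.top) & set(sel.bottom)

    def test_small_universe_floor(self):
        sel = select_tails(_profile(np.linspace(0.01, 0.1, 100)), "popA")
        assert sel.tail_size == 2
        assert sel.bottom == ["g0000", "g0001"]
        assert sel.top == ["g0098", "g0099"]

    def test_empty_tail_rejected(self):
        with pytest.raises(AnalysisError):
            select_tails(_profile(np.linspace(0.01, 0.1, 10)), "popA")

    def test_exclusion_applied_before_ranking(self):
        prof = _profile(np.linspace(0.01, 0.1, 100))
        sel = select_tails(prof, "popA", exclusion=["g0099", "g0000"])
        assert sel.universe_size == 98
        assert "g0099" not in sel.top and "g0000" not in sel.bottom

    def test_stable_under_input_permutation(self):
        rng = np.random.default_rng(0)
        eta = rng.uniform(0.01, 0.1, size=200)
        eta[10] = eta[20]  # force a tie
        prof = _profile(eta)
        perm = rng.permutation(200)
        prof_perm = VariabilityProfile(prof.etas.iloc[perm], {"popA": 30})
        s1 = select_tails(prof, "popA")
        s2 = select_tails(prof_perm, "popA")
        assert s1.top == s2.top and s1.bottom == s2.bottom


class TestOverrepresentation:
    def test_disjoint_set_p_one(self):
        universe = [f"g{i}" for i in range(10)]
        coll = GeneSetCollection({"s": universe[5:]})
        rows = overrepresentation(universe[:5], coll, universe)
        assert rows.loc[0, "p_value"] == pytest.approx(1.0)

    def test_perfect_overlap_closed_form(self):
        universe = [f"g{i}" for i in range(10)]
        coll = GeneSetCollection({"s": universe[:5]})
        rows = overrepresentation(universe[:5], coll, universe)
        assert rows.loc[0, "p_value"] == pytest.approx(1 / 252)

    def test_set_equal_universe_p_one(self):
        universe = [f"g{i}" for i in range(8)]
        coll = GeneSetCollection({"s": universe})
        rows = overrepresentation(universe[:3], coll, universe)
        assert rows.loc[0, "p_value"] == pytest.approx(1.0)

    def test_matches_enumeration_oracle_small_universe(self):
        # exhaustive oracle: enumerate all draws of |study| from the universe
        universe = [f"g{i}" for i in range(12)]
        members = universe[2:7]
        study = universe[4:9]
        coll = GeneSetCollection({"s": members})
        p = overrepresentation(study, coll, universe).loc[0, "p_value"]
        observed = len(set(members) & set(study))
        count = total = 0
        for draw in combinations(universe, len(study)):
            count += len(set(draw) & set(members)) >= observed
            total += 1
        assert p == pytest.approx(count / total, abs=1e-12)

    def test_empty_study_rejected(self):
        coll = GeneSetCollection({"s": ["g1"]})
        with pytest.raises(AnalysisError):
            overrepresentation([], coll, ["g1", "g2"])


class TestRankSum:
    def test_exact_enumeration_value(self):
        assert rank_sum_test([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=5)
        y = rng.normal(size=6)
        p = rank_sum_test(x, y)
        # enumerate all C(11, 5) group assignments of the pooled values
        pooled = np.concatenate([x, y])
        ranks = stats.rankdata(pooled)
        obs = ranks[:5].sum()
        n = len(pooled)
        mean = 5 * (n + 1) / 2
        count = total = 0
        for idx in combinations(range(n), 5):
            count += abs(ranks[list(idx)].sum() - mean) >= abs(obs - mean) - 1e-12
            total += 1
        assert p == pytest.approx(count / total, abs=1e-12)

    def test_group_vs_genome_null_calibration(self):
        rng = np.random.default_rng(2)
        eta = rng.lognormal(np.log(0.02), 0.6, size=800)
        prof = _profile(eta)
        ps = []
        for _ in range(200):
            group = rng.choice(prof.gene_ids, size=40, replace=False)
            ps.append(group_vs_genome(group, prof, "popA").ranksum_p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_group_covering_genome_rejected(self):
        prof = _profile(np.linspace(0.01, 0.05, 20))
        with pytest.raises(AnalysisError):
            group_vs_genome(prof.gene_ids.tolist(), prof, "popA")


class TestBootstrapCI:
    def test_constant_values_degenerate_ci(self):
        lo, hi = bootstrap_ci([3.0, 3.0, 3.0, 3.0], n_boot=100, seed=0)
        assert lo == hi == 3.0

    def test_seed_determinism(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=30)
        assert bootstrap_ci(vals, seed=42) == bootstrap_ci(vals, seed=42)

    def test_coverage_near_nominal(self):
        """Percentile CI covers the true mean ~95% of the time (n = 30)."""
        rng = np.random.default_rng(4)
        covered = 0
        n_groups = 1000
        for i in range(n_groups):
            vals = rng.normal(0.5, 0.2, size=30)
            lo, hi = bootstrap_ci(vals, n_boot=5000, seed=rng)
            covered += lo <= 0.5 <= hi
        assert covered / n_groups == pytest.approx(0.95, abs=0.02)

    def test_bad_nboot(self):
        with pytest.raises(ConfigError):
            bootstrap_ci([1.0, 2.0], n_boot=0)


def _coded_collection(codes: dict, sets=None):
    return GeneSetCollection(
        sets or {}, codes=pd.Series(codes, name="category_code")
    )


class TestMatchedNull:
    def test_unmatchable_group_rejected(self):
        prof = _profile([0.01, 0.02, 0.03, 0.04])
        coll = _coded_collection(
            {"g0000": "c1", "g0001": "c1", "g0002": "c2", "g0003": "c2"}
        )
        with pytest.raises(AnalysisError):
            # both c1 genes are in the group: no non-group gene shares c1
            matched_null_comparison(["g0000", "g0001"], coll, prof, "popA",
                                    n_sets=10)

    def test_null_calibration_exceedance(self):
        """Unbiased groups: the exceedance rate averages ~5% over groups.

        For one fixed group the per-replicate tests are correlated (they
        share the group draw), so the rate is only binomial after
        averaging over independent group draws.
        """
        rng = np.random.default_rng(5)
        n = 1500
        eta = rng.lognormal(np.log(0.02), 0.6, size=n)
        genes = [f"g{i:04d}" for i in range(n)]
        codes = {g: f"c{i % 30}" for i, g in enumerate(genes)}
        prof = _profile(eta, genes=genes)
        coll = _coded_collection(codes)
        total = hits = 0
        for _ in range(30):
            group = list(rng.choice(genes, size=200, replace=False))
            res = matched_null_comparison(group, coll, prof, "popA",
                                          n_sets=100, seed=rng)
            hits += res.null_exceedance
            total += res.n_null_sets
        assert 0.005 <= hits / total <= 0.18

    def test_planted_elevated_group_near_saturation(self, dataset, profile):
        coll = dataset.gene_sets
        group = [g for g in coll["virus_interacting"] if g in profile.gene_ids]
        res = matched_null_comparison(group, coll, profile, "popA",
                                      n_sets=200, seed=7)
        assert res.null_exceedance >= 190
        assert res.mean_relative_excess > 0

    def test_singleton_codes_drop_all(self):
        prof = _profile([0.01, 0.02])
        coll = _coded_collection({"g0000": "c1", "g0001": "c2"})
        with pytest.raises(AnalysisError):
            matched_null_comparison(["g0000"], coll, prof, "popA", n_sets=5)


class TestKeywordExclusion:
    def test_no_match_identity(self):
        coll = GeneSetCollection({"signaling": ["g1", "g2"]})
        assert exclude_keyword_genes(["g1", "g3"], coll) == ["g1", "g3"]

    def test_mixed_collection(self):
        coll = GeneSetCollection(
            {"immune response": ["g1", "g2"], "transport": ["g3"]}
        )
        assert exclude_keyword_genes(["g1", "g2", "g3", "g4", "g5"], coll) == [
            "g3", "g4", "g5",
        ]

    def test_all_tagged_empties_group(self):
        coll = GeneSetCollection({"IMMUNE": ["g1", "g2"]})
        assert exclude_keyword_genes(["g1", "g2"], coll) == []


class TestFoldChange:
    def test_median_gene_fold_one(self):
        prof = _profile([0.01, 0.02, 0.03])
        assert fold_change("g0001", prof, "popA") == pytest.approx(1.0)

    def test_reported_fold_changes(self):
        # 0.049 and 0.035 against a genome median of 0.0197
        eta = np.full(101, 0.0197)
        eta[0], eta[1] = 0.049, 0.035
        prof = _profile(eta)
        assert round(fold_change("g0000", prof, "popA"), 1) == 2.5
        assert round(fold_change("g0001", prof, "popA"), 1) == 1.8

    def test_absent_gene_rejected(self):
        prof = _profile([0.01, 0.02, 0.03])
        with pytest.raises(AnalysisError):
            fold_change("missing", prof, "popA")
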