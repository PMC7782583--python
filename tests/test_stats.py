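import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import thymotrace as tt
from thymotrace.stats import bh_adjust, fisher_exact_table, linear_by_linear_test
from oracle_utils import fisher_two_sided_p, rank_sum_exact_p


def _nm(values):
    values = np.asarray(values, dtype=float)
    n, g = values.shape
    return tt.NormalizedMatrix(
        values, [f"c{i}" for i in range(n)], [f"g{j}" for j in range(g)], 1e4
    )


class TestWilcoxonRankSum:
    def test_tiny_groups_exact_two_sided(self):
        _, p = tt.wilcoxon_rank_sum([1, 2], [3, 4])
        assert p == pytest.approx(1 / 3)

    def test_identical_distributions_give_p_one(self):
        _, p = tt.wilcoxon_rank_sum([5, 5, 5], [5, 5, 5])
        assert p == pytest.approx(1.0)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        a=st.lists(st.integers(0, 4), min_size=2, max_size=7),
        b=st.lists(st.integers(0, 4), min_size=2, max_size=7),
        alternative=st.sampled_from(["two-sided", "less", "greater"]),
    )
    def test_exact_matches_enumeration_oracle(self, a, b, alternative):
        _, p = tt.wilcoxon_rank_sum(a, b, alternative)
        assert p == pytest.approx(rank_sum_exact_p(a, b, alternative), rel=1e-9)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=30)
        b = rng.normal(loc=0.5, size=25)
        _, p1 = tt.wilcoxon_rank_sum(a, b)
        _, p2 = tt.wilcoxon_rank_sum(np.exp(a), np.exp(b))
        assert p1 == pytest.approx(p2)


def test_bh_step_up_by_hand():
    adj = bh_adjust(np.array([0.01, 0.02, 0.03]))
    np.testing.assert_allclose(adj, [0.03, 0.03, 0.03])


class TestWilcoxonDE:
    def test_identical_values_give_null_results(self):
        base = np.random.default_rng(1).normal(size=(5, 4)) ** 2
        values = np.vstack([base, base])  # two groups with identical values
        nm = _nm(values)
        de = tt.wilcoxon_de(nm, np.arange(5), np.arange(5, 10))
        assert (de["p_value"] == 1.0).all()
        np.testing.assert_allclose(de["log2_fold_change"], 0.0, atol=1e-12)

    def test_overlapping_groups_rejected(self):
        nm = _nm(np.ones((6, 2)))
        with pytest.raises(ValueError, match="overlap"):
            tt.wilcoxon_de(nm, np.arange(4), np.arange(3, 6))

    def test_adjusted_p_dominates_p(self, wt_products):
        nm = wt_products["nm"]
        inter = wt_products["intermediates"]
        states = wt_products["calls"]["state"].to_numpy()
        a = inter & (states == "CD4_state")
        b = inter & (states == "CD8_state")
        de = tt.wilcoxon_de(nm, a, b)
        assert (de["adjusted_p"] >= de["p_value"] - 1e-12).all()
        assert de["adjusted_p"].between(0, 1).all()
        # lineage program genes should differ between the subsets
        truth = wt_products["truth"]
        lin = [g for g in nm.gene_ids if truth.program_of_gene[g] == "cd4_lineage"]
        assert de.loc[lin, "adjusted_p"].min() < 0.01


class TestLineageSpecificity:
    def test_printed_contrast(self):
        # Runx3 in CD4-lineage cells (63/419) vs Zbtb7b in CD8-lineage (0/245)
        p, odds = tt.lineage_specificity_test(63, 419, 0, 245)
        assert p == pytest.approx(4.58e-14, rel=1e-2)

    def test_no_expression_anywhere(self):
        p, _ = tt.lineage_specificity_test(0, 10, 0, 10)
        assert p == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self):
        p, _ = tt.lineage_specificity_test(3, 5, 1, 5)
        assert p == pytest.approx(fisher_two_sided_p([[3, 2], [1, 4]]), rel=1e-9)

    def test_shares_fisher_core(self):
        p1, _ = tt.lineage_specificity_test(4, 9, 2, 11)
        _, p2 = fisher_exact_table(np.array([[4, 5], [2, 9]]))
        assert p1 == p2

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            tt.lineage_specificity_test(5, 3, 0, 10)


class TestPairwiseCorrelation:
    def test_gene_with_itself(self, wt_products):
        nm = wt_products["nm"]
        res = tt.pairwise_gene_correlation(nm, "Cd4", "Cd4")
        assert res.r == pytest.approx(1.0)

    def test_hand_value(self):
        nm = _nm(np.array([[0.0, 0.0], [1.0, 2.0], [2.0, 1.0]]))
        res = tt.pairwise_gene_correlation(nm, "g0", "g1")
        assert res.r == pytest.approx(0.5)

    def test_constant_gene_flagged_not_raised(self):
        nm = _nm(np.array([[1.0, 0.0], [1.0, 2.0], [1.0, 1.0]]))
        res = tt.pairwise_gene_correlation(nm, "g0", "g1")
        assert res.constant
        assert np.isnan(res.r)


class TestConditionShift:
    def test_identical_distributions_centre_near_half(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=(40, 1)) ** 2
        nm_wt = _nm(vals[:20])
        nm_ko = _nm(vals[20:])
        p = tt.condition_shift_test(
            nm_wt, nm_ko, np.arange(20), np.arange(20), "g0"
        )
        assert 0.1 < p < 0.9

    def test_fully_separated_exact_value(self):
        # only 1 of the C(20,10) assignments puts every KO value below every
        # WT value, so the exact one-sided p is 1/C(20,10)
        from math import comb

        nm_wt = _nm(np.full((10, 1), 5.0))
        nm_ko = _nm(np.zeros((10, 1)))
        p = tt.condition_shift_test(nm_wt, nm_ko, np.arange(10), np.arange(10), "g0")
        assert p == pytest.approx(1 / comb(20, 10), rel=1e-9)

    def test_activation_damping_detected_in_dp_intermediates(self):
        wt_cfg = tt.SimulationConfig(seed=9)
        ko_cfg = tt.mhcii_ko_config(wt_cfg)
        cm_w, ann_w, truth = tt.generate_dataset(wt_cfg)
        cm_k, ann_k, _ = tt.generate_dataset(ko_cfg)
        nm_w, nm_k = tt.lognormalize(cm_w), tt.lognormalize(cm_k)
        from thymotrace.coreceptor import call_states, pool_intermediates

        mask_w = pool_intermediates(ann_w) & (
            call_states(cm_w)["state"].to_numpy() == "DP_state"
        )
        mask_k = pool_intermediates(ann_k) & (
            call_states(cm_k)["state"].to_numpy() == "DP_state"
        )
        act = sorted(truth.truth_genesets["activation"].genes)
        ps = np.array(
            [tt.condition_shift_test(nm_w, nm_k, mask_w, mask_k, g) for g in act]
        )
        assert ps.min() < 0.01
        # far more small p-values than the 1% a true null would give
        assert (ps < 0.01).mean() >= 0.05


class TestCrossLevelCoherence:
    def _de(self, fc):
        import pandas as pd

        return pd.DataFrame(
            {"log2_fold_change": fc}, index=[f"g{i}" for i in range(len(fc))]
        )

    def test_identical_results_fully_coherent(self):
        rng = np.random.default_rng(3)
        fc = rng.normal(size=100)
        r, p = tt.cross_level_coherence(self._de(fc), self._de(fc))
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_independent_results_incoherent(self):
        rng = np.random.default_rng(4)
        r, p = tt.cross_level_coherence(
            self._de(rng.normal(size=1000)), self._de(rng.normal(size=1000))
        )
        assert abs(r) < 0.1
        assert p > 0.01

    def test_too_few_shared_genes(self):
        with pytest.raises(ValueError, match="shared genes"):
            tt.cross_level_coherence(self._de([1.0] * 5), self._de([1.0] * 5))

    def test_linear_by_linear_statistic_by_hand(self):
        table = np.array([[20, 5, 2], [6, 30, 7], [1, 4, 25]], dtype=float)
        m2, p = linear_by_linear_test(table)
        # direct score-test computation with integer scores
        n = table.sum()
        rows, cols = np.indices(table.shape)
        x = rows.ravel().repeat(table.ravel().astype(int))
        y = cols.ravel().repeat(table.ravel().astype(int))
        r = np.corrcoef(x, y)[0, 1]
        assert m2 == pytest.approx((n - 1) * r**2, rel=1e-9)
        from scipy.stats import chi2

        assert p == pytest.approx(chi2.sf((n - 1) * r**2, 1), rel=1e-9)
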