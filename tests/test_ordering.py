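import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import thymotrace as tt
from thymotrace.ordering import ConditionVerdict, KSResult, OrderingResult, peak_bin
from oracle_utils import ecdf_sup_diff, ks_one_sided_exact_p


class TestFrequencyCurves:
    def test_every_curve_peaks_at_one(self, wt_products):
        inter = wt_products["intermediates"]
        axis = wt_products["emb"].pc(1)[inter]
        states = wt_products["calls"]["state"].to_numpy()[inter]
        curves = tt.frequency_curves(axis, states)
        assert curves
        for centers, freq in curves.values():
            assert freq.max() == pytest.approx(1.0)

    def test_single_bin_state_is_indicator(self):
        axis = np.array([0.0, 0.01, 5.0, 6.0])
        states = np.array(["CD4_state", "CD4_state", "CD8_state", "CD8_state"])
        curves = tt.frequency_curves(axis, states, n_bins=4)
        assert curves["CD4_state"][1].tolist() == [1.0, 0.0, 0.0, 0.0]

    def test_matches_histogram_oracle(self):
        rng = np.random.default_rng(0)
        axis = rng.uniform(0, 1, 50)
        states = rng.choice(["CD4_state", "CD8_state"], size=50)
        curves = tt.frequency_curves(axis, states, n_bins=10,
                                     include=("CD4_state", "CD8_state"))
        edges = np.linspace(axis.min(), axis.max(), 11)
        for state in ("CD4_state", "CD8_state"):
            manual, _ = np.histogram(axis[states == state], bins=edges)
            np.testing.assert_allclose(
                curves[state][1], manual / manual.max()
            )

    def test_too_few_bins_is_error(self):
        with pytest.raises(ValueError):
            tt.frequency_curves(np.arange(4.0), np.array(["CD4_state"] * 4), n_bins=1)


class TestKSOrderTest:
    def test_identical_samples_have_zero_d(self):
        a = np.array([1.0, 2.0, 3.0])
        res = tt.ks_order_test(a, a)
        assert res.d == 0.0
        assert res.p == pytest.approx(1.0)

    def test_disjoint_supports(self):
        res = tt.ks_order_test([1, 2, 3], [4, 5, 6])
        assert res.d == 1.0
        # only the fully ordered split of C(6,3)=20 reaches D=1
        assert res.p == pytest.approx(1 / 20)

    def test_direction_symmetry(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=6), rng.normal(size=5)
        d_fwd = tt.ks_order_test(a, b, "A_before_B").d
        d_rev = tt.ks_order_test(b, a, "B_before_A").d
        assert d_fwd == pytest.approx(d_rev)

    def test_empty_sample_is_error(self):
        with pytest.raises(ValueError):
            tt.ks_order_test([], [1.0])

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        a=st.lists(st.integers(0, 5), min_size=2, max_size=6),
        b=st.lists(st.integers(0, 5), min_size=2, max_size=6),
    )
    def test_exact_p_matches_enumeration_oracle(self, a, b):
        res = tt.ks_order_test(a, b)
        assert res.method == "exact"
        assert res.d == pytest.approx(ecdf_sup_diff(a, b))
        assert res.p == pytest.approx(ks_one_sided_exact_p(a, b), rel=1e-9)

    def test_large_sample_uses_asymptotic_tail(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=40)
        b = rng.normal(loc=2.0, size=40)
        res = tt.ks_order_test(a, b)
        assert res.method == "asymptotic"
        assert res.p == pytest.approx(np.exp(-2 * res.d**2 * 40 * 40 / 80))


class TestCentroidDistances:
    def test_identical_groups_have_zero_distance(self, wt_products):
        emb = wt_products["emb"]
        mask = np.zeros(len(emb.cell_ids), dtype=bool)
        mask[:10] = True
        d = tt.centroid_distances(emb, {"a": mask, "b": mask.copy()})
        assert d.loc["a", "b"] == 0.0

    def test_three_four_five(self):
        emb = tt.Embedding(
            scores=np.array([[0.0, 0.0], [3.0, 4.0]]),
            loadings=np.zeros((2, 2)),
            hvg_genes=["g0", "g1"], cell_ids=["a", "b"],
            var_fraction_total=np.array([0.5, 0.5]),
            var_fraction_first5=np.array([0.5, 0.5]),
        )
        d = tt.centroid_distances(
            emb, {"a": np.array([0]), "b": np.array([1])}, pcs=(1, 2)
        )
        assert d.loc["a", "b"] == pytest.approx(5.0)

    def test_matches_mean_then_norm_oracle(self, wt_products):
        emb = wt_products["emb"]
        rng = np.random.default_rng(3)
        ga = rng.choice(len(emb.cell_ids), 30, replace=False)
        gb = rng.choice(len(emb.cell_ids), 25, replace=False)
        d = tt.centroid_distances(emb, {"a": ga, "b": gb}, pcs=(1, 3))
        ca = np.array([emb.pc(1)[ga].mean(), emb.pc(3)[ga].mean()])
        cb = np.array([emb.pc(1)[gb].mean(), emb.pc(3)[gb].mean()])
        assert d.loc["a", "b"] == pytest.approx(np.linalg.norm(ca - cb))

    def test_empty_group_is_error(self, wt_products):
        emb = wt_products["emb"]
        with pytest.raises(ValueError, match="empty"):
            tt.centroid_distances(emb, {"a": np.array([], dtype=int)})


class TestCompareConditions:
    def _result(self, axis, p):
        ks = KSResult(0.5, p, "A_before_B", 10, 10, "asymptotic")
        return OrderingResult(axis, {}, {}, {"CD4_before_CD8": ks}, {})

    def test_threshold_logic(self):
        verdicts = tt.compare_conditions(
            self._result("pc1", 1e-10), self._result("pc1", 0.8), alpha=0.01
        )
        assert verdicts["WT"].verdict == "sequential"
        assert verdicts["MHCII_KO"].verdict == "simultaneous"

    def test_both_nonsignificant_means_both_simultaneous(self):
        verdicts = tt.compare_conditions(
            self._result("pc1", 0.5), self._result("pc1", 0.5), alpha=0.01
        )
        assert all(v.verdict == "simultaneous" for v in verdicts.values())

    def test_mismatched_axes_is_error(self):
        with pytest.raises(ValueError, match="different axes"):
            tt.compare_conditions(
                self._result("pc1", 0.5), self._result("pseudotime", 0.5)
            )


def test_order_states_summary(wt_products):
    inter = wt_products["intermediates"]
    axis = wt_products["emb"].pc(1)[inter]
    states = wt_products["calls"]["state"].to_numpy()[inter]
    res = tt.order_states(axis, states, "pc1")
    assert res.axis_name == "pc1"
    assert "CD4_before_CD8" in res.ks
    assert peak_bin(res.curves["CD4_state"]) < peak_bin(res.curves["CD8_state"])
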