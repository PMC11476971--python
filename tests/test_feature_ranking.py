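"""F-ratio filter, RF importance, replicate subsampling, Borda aggregation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lipidchemo.feature_ranking import (
    borda_aggregate,
    corrected_importance_pvalues,
    fisher_ratio,
    replicate_subsample,
    rf_importance,
    segment_counts,
    significance_threshold_count,
    stability_ranking,
)


class TestFisherRatio:
    def test_hand_worked_anova(self):
        """Two classes [1,2,3] vs [7,8,9]: between-MS 54, within-MS 1 -> F = 54."""
        X = np.array([[1.0], [2.0], [3.0], [7.0], [8.0], [9.0]])
        res = fisher_ratio(X, ["a", "a", "a", "b", "b", "b"])
        assert res.f[0] == pytest.approx(54.0)
        assert (res.df_num, res.df_den) == (1, 4)

    def test_matches_scipy_oneway_oracle(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(84, 15))
        labels = np.r_[np.zeros(40), np.ones(44)]
        res = fisher_ratio(X, labels)
        oracle = np.array(
            [stats.f_oneway(X[labels == 0, j], X[labels == 1, j]).statistic
             for j in range(15)]
        )
        np.testing.assert_allclose(res.f, oracle, rtol=1e-10)
        assert (res.df_num, res.df_den) == (1, 82)
        assert res.critical_value == pytest.approx(stats.f.ppf(0.95, 1, 82))
        np.testing.assert_array_equal(res.selected, res.f > res.critical_value)

    def test_identical_classes_give_zero(self):
        X = np.tile([[5.0]], (6, 1))
        res = fisher_ratio(X, ["a"] * 3 + ["b"] * 3)
        assert res.f[0] == 0.0 and not res.selected[0]

    def test_small_class_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            fisher_ratio(np.zeros((3, 2)), ["a", "b", "b"])


class TestRfImportance:
    def test_perfect_separator_ranks_first(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 10))
        y = np.r_[np.zeros(20), np.ones(20)]
        X[:, 3] = y * 4 + rng.normal(scale=0.1, size=40)
        imp = rf_importance(X, y, n_trees=100, seed=0)
        assert imp.ranking("gini")[0] == 3
        assert imp.ranking("accuracy")[0] == 3
        assert imp.mean_decrease_gini.min() >= 0

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 6))
        y = rng.integers(0, 2, 30)
        a = rf_importance(X, y, n_trees=25, seed=7)
        b = rf_importance(X, y, n_trees=25, seed=7)
        np.testing.assert_array_equal(a.mean_decrease_gini, b.mean_decrease_gini)
        np.testing.assert_array_equal(a.mean_decrease_accuracy, b.mean_decrease_accuracy)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            rf_importance(np.zeros((10, 3)), np.zeros(10))


class TestReplicateSubsample:
    def test_one_sample_per_individual(self, replicate_metadata):
        idx = replicate_subsample(replicate_metadata, seed_or_rng=0)
        chosen = replicate_metadata.iloc[idx]
        assert len(idx) == replicate_metadata.individual_id.nunique()
        assert chosen.individual_id.is_unique

    def test_each_replicate_drawn_one_third_of_the_time(self, replicate_metadata):
        counts = np.zeros(len(replicate_metadata))
        rng = np.random.default_rng(0)
        n_draws = 3000
        for _ in range(n_draws):
            counts[replicate_subsample(replicate_metadata, rng)] += 1
        freq = counts / n_draws
        np.testing.assert_allclose(freq, 1 / 3, atol=0.03)


class TestSegmentCounts:
    def test_enumerated_example(self):
        # feature 0 ranked 2, 4, 7 across 3 lists of 8 features
        lists = np.array([
            [1, 0, 2, 3, 4, 5, 6, 7],
            [1, 2, 3, 0, 4, 5, 6, 7],
            [1, 2, 3, 4, 5, 6, 0, 7],
        ])
        counts = segment_counts(lists, segments=((1, 5), (6, 10)))
        assert counts.loc[0].tolist() == [2, 1]

    def test_single_list_gives_indicators(self):
        lists = np.array([[2, 0, 1]])
        counts = segment_counts(lists, segments=((1, 2), (3, 3)))
        assert set(counts.to_numpy().ravel()) <= {0, 1}

    def test_conservation_per_segment(self):
        rng = np.random.default_rng(3)
        lists = np.array([rng.permutation(20) for _ in range(15)])
        counts = segment_counts(lists, segments=((1, 5), (6, 10), (11, 15)))
        for col in counts:
            assert counts[col].sum() == 5 * 15

    def test_overlapping_segments_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            segment_counts(np.array([[0, 1, 2]]), segments=((1, 2), (2, 3)))


class TestBorda:
    def test_brute_force_three_lists(self):
        """Lists (f0,f1,f2),(f1,f0,f2),(f0,f2,f1): enumerating features
        ranked below each candidate gives scores 5, 3, 1 and order f0>f1>f2."""
        lists = np.array([[0, 1, 2], [1, 0, 2], [0, 2, 1]])
        borda, mean_rank, order = borda_aggregate(lists)
        # independent brute force: count lower-ranked features per list
        brute = np.zeros(3, dtype=int)
        for lst in lists:
            for pos, feat in enumerate(lst):
                brute[feat] += len(lst) - 1 - pos
        np.testing.assert_array_equal(borda, brute)
        np.testing.assert_array_equal(borda, [5, 3, 1])
        np.testing.assert_array_equal(order, [0, 1, 2])

    def test_identical_lists_reproduce_the_list(self):
        lst = np.array([3, 0, 2, 1])
        _, _, order = borda_aggregate(np.tile(lst, (5, 1)))
        np.testing.assert_array_equal(order, lst)

    def test_equivalent_to_mean_rank_ordering(self):
        rng = np.random.default_rng(4)
        lists = np.array([rng.permutation(30) for _ in range(50)])
        borda, mean_rank, order = borda_aggregate(lists)
        np.testing.assert_array_equal(order, np.lexsort((np.arange(30), mean_rank)))

    def test_invariant_to_list_order(self):
        rng = np.random.default_rng(5)
        lists = np.array([rng.permutation(10) for _ in range(9)])
        _, _, o1 = borda_aggregate(lists)
        _, _, o2 = borda_aggregate(lists[::-1])
        np.testing.assert_array_equal(o1, o2)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            borda_aggregate([np.array([0, 1, 2]), np.array([0, 1])])


class TestStabilityRanking:
    def test_single_list_trivial_case(self, replicate_metadata):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(18, 8))
        y = replicate_metadata.class_label.to_numpy()
        X[:, 5] = (y == "SCH") * 5 + rng.normal(scale=0.1, size=18)
        res = stability_ranking(X, y, replicate_metadata, B=1, n_trees=50, seed=0)
        assert res.lists[0][0] == 5
        assert res.aggregate[0] == 5

    def test_informative_features_occupy_top_segment(self, replicate_metadata):
        rng = np.random.default_rng(7)
        meta = pd.DataFrame(
            dict(
                individual_id=np.repeat([f"i{i}" for i in range(18)], 3),
                replicate_index=np.tile([1, 2, 3], 18),
                class_label=np.repeat(["C", "SCH"] * 9, 3),
                gender="M",
                batch=1,
            ),
            index=[f"i{i}_r{r}" for i in range(18) for r in (1, 2, 3)],
        )
        n = len(meta)
        X = rng.normal(size=(n, 20))
        y = meta.class_label.to_numpy()
        strong = [2, 9, 17]
        for j in strong:
            X[:, j] += (y == "SCH") * 6
        res = stability_ranking(X, y, meta, B=30, n_trees=50, seed=1)
        top = res.segment_counts["rank_1_5"]
        for j in strong:
            assert top[j] >= 0.9 * res.B

    def test_top_feature_overlap_across_seeds(self, small_cohort):
        from lipidchemo.preprocess import autoscale, impute_missing, log_transform

        ctrl = small_cohort.subset_samples(
            small_cohort.samples.index[small_cohort.class_labels == "C"]
        )
        scaled, _ = autoscale(log_transform(impute_missing(ctrl.intensities)))
        y = ctrl.samples.gender.to_numpy()
        tops = []
        for seed in (1, 2):
            res = stability_ranking(scaled.to_numpy(), y, ctrl.samples,
                                    B=40, n_trees=50, seed=seed)
            tops.append(set(res.aggregate[:10]))
        jaccard = len(tops[0] & tops[1]) / len(tops[0] | tops[1])
        assert jaccard >= 0.8


class TestCorrectedPvalues:
    def test_null_pvalues_approximately_uniform(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(60, 100))
        y = rng.permutation(np.r_[np.zeros(30), np.ones(30)])
        _, pvals = corrected_importance_pvalues(
            X, y, n_classifiers=30, n_trees=30, seed=0
        )
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_informative_feature_gets_small_p(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(40, 30))
        y = np.r_[np.zeros(20), np.ones(20)]
        X[:, 4] += y * 5
        corrected, pvals = corrected_importance_pvalues(
            X, y, n_classifiers=20, n_trees=50, seed=0
        )
        assert corrected[4] == corrected.max()
        assert pvals[4] == pvals.min()


class TestSignificanceCount:
    def test_direct_moments(self):
        pv = [np.r_[np.zeros(c), np.ones(150 - c)] for c in (100, 110, 120)]
        mean, sd, interval = significance_threshold_count(pv, alpha=0.5)
        assert mean == pytest.approx(110.0)
        assert sd == pytest.approx(10.0)
        assert interval == (100.0, 120.0)

    def test_identical_members_zero_sd(self):
        pv = [np.array([0.01, 0.2, 0.8])] * 3
        _, sd, _ = significance_threshold_count(pv)
        assert sd == 0.0

    def test_null_count_matches_binomial_expectation(self):
        rng = np.random.default_rng(10)
        pv = [rng.uniform(size=192) for _ in range(30)]
        mean, _, _ = significance_threshold_count(pv, alpha=0.05)
        expect = 0.05 * 192
        sd_binom = np.sqrt(192 * 0.05 * 0.95)
        assert abs(mean - expect) < 3 * sd_binom

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            significance_threshold_count([])


# ---------------------------------------------------------------------------
# property tests
# ---------------------------------------------------------------------------

from hypothesis import given, settings, strategies as st


@st.composite
def ranking_lists(draw):
    p = draw(st.integers(min_value=2, max_value=12))
    b = draw(st.integers(min_value=1, max_value=6))
    seed = draw(st.integers(min_value=0, max_value=2**16))
    rng = np.random.default_rng(seed)
    return np.array([rng.permutation(p) for _ in range(b)])


@settings(max_examples=50, derandomize=True)
@given(ranking_lists())
def test_borda_properties_hold_for_any_list_ensemble(lists):
    """Borda scores sum to B*p*(p-1)/2, the aggregate is a permutation,
    and aggregation is invariant to the order lists are supplied in."""
    B, p = lists.shape
    borda, mean_rank, order = borda_aggregate(lists)
    assert borda.sum() == B * p * (p - 1) // 2
    assert sorted(order) == list(range(p))
    _, _, order_rev = borda_aggregate(lists[::-1])
    np.testing.assert_array_equal(order, order_rev)


@settings(max_examples=50, derandomize=True)
@given(ranking_lists())
def test_segment_counts_conserve_mass(lists):
    """Each segment's counts over features total (segment width) * B."""
    B, p = lists.shape
    hi = min(5, p)
    counts = segment_counts(lists, segments=((1, hi),))
    assert counts.iloc[:, 0].sum() == hi * B
    assert (counts.iloc[:, 0] <= B).all()
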