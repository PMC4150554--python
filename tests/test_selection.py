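import itertools

import numpy as np
import pandas as pd
import pytest

from hrvrisk import (
    EnsembleSelector,
    SelectionParams,
    build_balanced_subsets,
    ensemble_occurrences,
    mann_whitney_p,
    rank_subset,
    select_variables,
)
from tests.conftest import make_noise_frame

FAST = SelectionParams(n_subsets=15, trees_per_forest=40, top_k=3)


class TestBalancedSubsets:
    def test_subset_composition(self):
        X, y = make_noise_frame(100, 10, 5, seed=0)
        rng = np.random.default_rng(1)
        subsets = build_balanced_subsets(X, y, 20, rng)
        pos = set(np.flatnonzero(y == 1))
        assert len(subsets) == 20
        for idx in subsets:
            assert len(idx) == 20  # all 10 positives + 10 negatives
            assert pos <= set(idx)
            assert len(set(idx)) == len(idx)  # no within-subset repeats

    def test_reproducible_given_seed(self):
        X, y = make_noise_frame(60, 6, 4, seed=0)
        a = build_balanced_subsets(X, y, 5, np.random.default_rng(3))
        b = build_balanced_subsets(X, y, 5, np.random.default_rng(3))
        for s1, s2 in zip(a, b):
            np.testing.assert_array_equal(s1, s2)

    def test_equal_class_sizes_force_whole_cohort(self):
        X, y = make_noise_frame(20, 10, 3, seed=0)
        subsets = build_balanced_subsets(X, y, 4, np.random.default_rng(0))
        for idx in subsets:
            np.testing.assert_array_equal(idx, np.arange(20))

    def test_fewer_negatives_than_positives_errors(self):
        X, y = make_noise_frame(10, 7, 3, seed=0)
        with pytest.raises(ValueError):
            build_balanced_subsets(X, y, 2, np.random.default_rng(0))


class TestRankSubset:
    def test_perfect_separator_ranked_first(self):
        params = SelectionParams(n_subsets=1, trees_per_forest=60, top_k=3)
        for seed in range(10):
            X, y = make_noise_frame(60, 30, 6, seed=seed)
            X["v0"] = np.where(y == 1, 5.0, -5.0)  # perfect separation
            assert rank_subset(X, y, params, seed)[0] == "v0"

    def test_permuted_labels_break_concentration(self):
        params = SelectionParams(n_subsets=1, trees_per_forest=60, top_k=3)
        rng = np.random.default_rng(0)
        firsts = set()
        for seed in range(12):
            X, y = make_noise_frame(60, 30, 6, seed=seed)
            X["v0"] = np.where(y == 1, 5.0, -5.0)
            y_perm = rng.permutation(y)
            firsts.add(rank_subset(X, y_perm, params, seed)[0])
        assert len(firsts) > 1  # no single variable dominates under the null

    def test_top_k_equal_to_p_returns_all(self):
        X, y = make_noise_frame(40, 20, 4, seed=1)
        params = SelectionParams(n_subsets=1, trees_per_forest=30, top_k=4)
        assert sorted(rank_subset(X, y, params, 0)) == sorted(X.columns)


class TestOccurrences:
    def test_conservation_and_bounds(self):
        X, y = make_noise_frame(80, 8, 10, seed=2, signal=["v0", "v1"])
        occ = ensemble_occurrences(X, y, FAST, seed=0)
        assert occ.sum() == FAST.top_k * FAST.n_subsets
        assert (occ <= FAST.n_subsets).all() and (occ >= 0).all()

    def test_single_subset_counts(self):
        X, y = make_noise_frame(40, 4, 6, seed=3)
        params = SelectionParams(n_subsets=1, trees_per_forest=30, top_k=3)
        occ = ensemble_occurrences(X, y, params, seed=0)
        assert sorted(occ.values, reverse=True)[:3] == [1, 1, 1]
        assert occ.sum() == 3

    def test_signal_variables_top_occurrences(self):
        # strong three-variable signal should head the occurrence ranking
        params = SelectionParams(n_subsets=25, trees_per_forest=60, top_k=4)
        wins = 0
        for seed in range(5):
            X, y = make_noise_frame(
                120, 12, 8, seed=seed, signal=["v0", "v1", "v2"], shift=1.5
            )
            occ = ensemble_occurrences(X, y, params, seed=seed)
            top3 = set(occ.sort_values(ascending=False).index[:3])
            wins += top3 == {"v0", "v1", "v2"}
        assert wins >= 4

    def test_null_occurrences_approximately_uniform(self):
        # within one cohort occurrences are correlated through the shared
        # positives, so uniformity is judged across independent cohorts:
        # no variable is systematically favoured
        params = SelectionParams(n_subsets=20, trees_per_forest=40, top_k=5)
        runs = []
        for seed in range(8):
            X, y = make_noise_frame(80, 10, 10, seed=100 + seed)
            runs.append(ensemble_occurrences(X, y, params, seed=seed))
        occ = pd.concat(runs, axis=1)
        expected = params.top_k * params.n_subsets / 10
        mean = occ.mean(axis=1)
        se = occ.std(axis=1, ddof=1) / np.sqrt(occ.shape[1])
        assert ((mean - expected).abs() <= 4 * se.clip(lower=1.0)).all()
        # the top-occurring variable changes across cohorts
        assert occ.idxmax(axis=0).nunique() > 1


class TestMannWhitney:
    def test_identical_groups(self):
        assert mann_whitney_p(np.ones(5), np.ones(8)) == 1.0

    def test_fully_separated_small_groups_exact(self):
        # 1/C(6,3) in each tail, doubled
        assert mann_whitney_p([1, 2, 3], [10, 11, 12]) == pytest.approx(0.1)

    def test_large_shift_is_significant(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 400)
        b = rng.normal(2, 1, 400)
        assert mann_whitney_p(a, b) < 1e-6

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            m, n = rng.integers(3, 7), rng.integers(3, 7)
            combined = rng.permutation(np.arange(m + n) + rng.random(m + n) * 0.1)
            a, b = combined[:m], combined[m:]
            u_obs = sum(
                1.0 if x > v else 0.5 if x == v else 0.0 for x in a for v in b
            )
            us = []
            for pick in itertools.combinations(range(m + n), m):
                grp = combined[list(pick)]
                rest = np.delete(combined, list(pick))
                us.append(
                    sum(1.0 if x > v else 0.5 if x == v else 0.0
                        for x in grp for v in rest)
                )
            us = np.asarray(us)
            p_oracle = min(
                1.0,
                2.0 * min((us <= u_obs).mean(), (us >= u_obs).mean()),
            )
            assert mann_whitney_p(a, b) == pytest.approx(p_oracle, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_p([], [1.0])


class TestSelectVariables:
    def test_all_significant_keeps_topk(self):
        X, y = make_noise_frame(
            120, 40, 3, seed=6, signal=["v0", "v1", "v2"], shift=2.0
        )
        params = SelectionParams(n_subsets=10, trees_per_forest=40, top_k=3)
        res = select_variables(X, y, params, seed=0)
        assert len(res.selected) == 3
        assert res.audit == []

    def test_null_variable_excluded_by_refinement(self):
        # one variable separates subsets by construction quirk but has
        # identical group distributions -> the p-value filter removes it
        X, y = make_noise_frame(100, 50, 4, seed=7, signal=["v0"], shift=3.0)
        params = SelectionParams(n_subsets=10, trees_per_forest=40, top_k=4)
        res = select_variables(X, y, params, seed=0)
        assert "v0" in res.selected
        assert all(res.p_values[v] < params.alpha for v in res.selected)
        assert len(res.audit) >= 1  # at least one null candidate excluded

    def test_empty_selection_warns(self):
        X, y = make_noise_frame(60, 30, 3, seed=8)
        params = SelectionParams(
            n_subsets=5, trees_per_forest=30, top_k=3, alpha=1e-12
        )
        with pytest.warns(UserWarning):
            res = select_variables(X, y, params, seed=0)
        assert res.selected == []
        assert len(res.audit) == 3

    def test_deterministic_given_seed(self):
        X, y = make_noise_frame(80, 20, 6, seed=9, signal=["v1"])
        a = select_variables(X, y, FAST, seed=5)
        b = select_variables(X, y, FAST, seed=5)
        assert a.selected == b.selected
        pd.testing.assert_series_equal(a.occurrence, b.occurrence)

    def test_summary_lists_occurrences(self):
        X, y = make_noise_frame(60, 20, 4, seed=10, signal=["v2"])
        res = select_variables(X, y, FAST, seed=1)
        text = res.summary()
        assert "occurrence" in text and "v2" in text
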