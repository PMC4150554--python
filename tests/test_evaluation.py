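import numpy as np
import pandas as pd
import pytest

from hrvrisk import (
    DistanceRiskModel,
    compare_auc_bootstrap,
    loocv_scores,
    optimal_cutoff,
    prefix_performance,
    roc_auc,
    summarize_groups,
    wald_ci,
)
from tests.conftest import make_noise_frame


def brute_force_auc(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else 0.5 if p == n else 0.0
    return total / (len(pos) * len(neg))


class TestROC:
    def test_perfect_separation(self):
        r = roc_auc([0.9, 0.8, 0.4, 0.3], [1, 1, 0, 0])
        assert r.auc == 1.0

    def test_all_ties_give_half(self):
        r = roc_auc([5.0] * 6, [1, 1, 0, 0, 0, 0])
        assert r.auc == 0.5

    def test_crossed_pairs(self):
        r = roc_auc([0.9, 0.3, 0.8, 0.4], [1, 1, 0, 0])
        assert r.auc == 0.5

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(40):
            n = rng.integers(4, 30)
            labels = np.zeros(n, dtype=int)
            labels[: rng.integers(1, n)] = 1
            rng.shuffle(labels)
            if labels.sum() in (0, n):
                continue
            scores = np.round(rng.random(n), 1)  # coarse grid forces ties
            r = roc_auc(scores, labels)
            assert r.auc == pytest.approx(brute_force_auc(scores, labels))

    def test_curve_monotone_with_unit_endpoints(self, small_cohort):
        y = small_cohort.outcome
        rng = np.random.default_rng(1)
        r = roc_auc(rng.random(len(y)), y)
        assert (np.diff(r.fpr) >= 0).all() and (np.diff(r.tpr) >= 0).all()
        assert (r.fpr[0], r.tpr[0]) == (0.0, 0.0)
        assert (r.fpr[-1], r.tpr[-1]) == (1.0, 1.0)

    def test_ci_contains_auc_and_orders(self):
        rng = np.random.default_rng(2)
        scores = np.r_[rng.normal(1, 1, 20), rng.normal(0, 1, 80)]
        labels = np.r_[np.ones(20, int), np.zeros(80, int)]
        for method in ("delong", "bootstrap"):
            r = roc_auc(scores, labels, ci_method=method, seed=0)
            assert r.ci[0] <= r.auc <= r.ci[1]
            assert 0.0 <= r.ci[0] and r.ci[1] <= 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])


class TestCutoff:
    def test_perfect_classifier_hits_corner(self):
        r = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        c = optimal_cutoff(r)
        assert c.sensitivity == 1.0 and c.specificity == 1.0
        assert c.distance == 0.0
        assert 0.2 < c.threshold < 0.8

    def test_wald_interval_arithmetic(self):
        lo, hi = wald_ci(0.828, 29)
        assert round(100 * lo, 1) == pytest.approx(69.0, abs=0.1)
        assert round(100 * hi, 1) == pytest.approx(96.5, abs=0.1)

    def test_cis_contain_point_estimates(self, small_cohort):
        y = small_cohort.outcome
        rng = np.random.default_rng(3)
        r = roc_auc(rng.random(len(y)) + y * 0.3, y)
        c = optimal_cutoff(r)
        assert c.sensitivity_ci[0] <= c.sensitivity <= c.sensitivity_ci[1]
        assert c.specificity_ci[0] <= c.specificity <= c.specificity_ci[1]

    def test_tie_breaks_toward_sensitivity(self):
        # all scores tied: (0,0) and (1,1) are equidistant from the corner;
        # the more sensitive operating point must win
        r = roc_auc([2.0, 2.0, 2.0], [1, 0, 0])
        c = optimal_cutoff(r)
        assert c.sensitivity == 1.0
        assert c.specificity == 0.0


class TestLOOCV:
    def test_score_count_and_fold_size(self):
        X, y = make_noise_frame(10, 4, 2, seed=0, signal=["v0"])
        seen = []

        def builder(Xtr, ytr, s):
            seen.append(len(Xtr))
            return DistanceRiskModel(Xtr, ytr, lam=0.0).fit(s)

        s = loocv_scores(X, y, builder=builder)
        assert len(s) == 10
        assert seen == [9] * 10

    def test_duplicate_patients_get_identical_scores(self):
        # twins with the same features and label leave identical training
        # folds when either is held out, so their scores must coincide
        X, y = make_noise_frame(12, 4, 2, seed=1, signal=["v0"])
        X.iloc[5] = X.iloc[4]
        y[5] = y[4]
        s = loocv_scores(X, y, lam=0.0)
        assert s[4] == pytest.approx(s[5], abs=1e-9)

    def test_no_leakage_of_held_out_point(self):
        # a cheating harness that trains on all n rows scores higher on
        # signal data; the honest harness must not match it
        X, y = make_noise_frame(60, 12, 3, seed=4, signal=["v0"], shift=1.0)
        honest = loocv_scores(X, y, lam=0.0)

        cheat_model = DistanceRiskModel(X, y, lam=0.0).fit(0)
        cheat = cheat_model.predict(X)
        auc_h = roc_auc(honest, y).auc
        auc_c = roc_auc(cheat, y).auc
        assert auc_c > auc_h  # optimism of refit-on-all
        assert not np.allclose(honest, cheat)

    def test_training_fold_must_keep_both_classes(self):
        X, y = make_noise_frame(10, 1, 2, seed=5)
        with pytest.raises(ValueError):
            loocv_scores(X, y)


class TestPrefix:
    def test_single_variable_prefix_equals_direct_auc(self):
        X, y = make_noise_frame(40, 10, 3, seed=6, signal=["v0"], shift=2.0)
        table = prefix_performance(X, y, ["v0"], lam=0.0)
        s = loocv_scores(X, y, variables=["v0"], lam=0.0)
        assert len(table) == 1
        assert table.loc[1, "auc"] == pytest.approx(roc_auc(s, y).auc)
        assert bool(table.loc[1, "best"])

    def test_peak_at_true_signal_size(self):
        # 2 strong signal variables ranked first, then pure noise: the best
        # prefix should stop at or before the noise in most seeds
        wins = 0
        for seed in range(5):
            X, y = make_noise_frame(
                80, 16, 4, seed=seed, signal=["v0", "v1"], shift=1.5
            )
            table = prefix_performance(X, y, ["v0", "v1", "v2", "v3"], lam=0.0)
            wins += table["auc"].idxmax() <= 2
        assert wins >= 3

    def test_empty_ranking_rejected(self):
        X, y = make_noise_frame(20, 5, 2, seed=7)
        with pytest.raises(ValueError):
            prefix_performance(X, y, [])


class TestComparison:
    def test_self_comparison_is_null(self):
        rng = np.random.default_rng(8)
        y = np.r_[np.ones(10, int), np.zeros(40, int)]
        s = rng.random(50)
        res = compare_auc_bootstrap(s, s, y, n_boot=300, seed=0)
        assert res.difference == 0.0
        assert res.p_value > 0.9

    def test_perfect_vs_random_significant(self):
        rng = np.random.default_rng(9)
        y = np.r_[np.ones(40, int), np.zeros(160, int)]
        perfect = y + rng.random(200) * 0.1
        random_s = rng.random(200)
        res = compare_auc_bootstrap(perfect, random_s, y, n_boot=500, seed=1)
        assert res.p_value < 0.01
        assert res.difference > 0.3

    def test_swap_negates_difference_with_equal_p(self):
        rng = np.random.default_rng(10)
        y = np.r_[np.ones(15, int), np.zeros(60, int)]
        a = rng.random(75) + 0.4 * y
        b = rng.random(75)
        r1 = compare_auc_bootstrap(a, b, y, n_boot=400, seed=2)
        r2 = compare_auc_bootstrap(b, a, y, n_boot=400, seed=2)
        assert r1.difference == pytest.approx(-r2.difference)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_too_few_replicates_warns(self):
        y = np.r_[np.ones(5, int), np.zeros(5, int)]
        with pytest.warns(UserWarning):
            compare_auc_bootstrap(np.arange(10), np.arange(10), y, n_boot=50, seed=0)


class TestGroupSummary:
    def test_constant_variable_null(self, small_cohort):
        f = small_cohort.frame.copy()
        f["const"] = 1.0
        rep = summarize_groups(f, variables=["const"])
        assert rep.loc["const", "p_value"] == 1.0
        assert rep.loc["const", "no_mace"] == rep.loc["const", "mace"]

    def test_median_iqr_formatting(self, small_cohort):
        rep = summarize_groups(small_cohort.frame, variables=["GCS", "SBP"])
        assert "to" in rep.loc["GCS", "no_mace"]  # "15 (15 to 15)" style
        assert "(" in rep.loc["SBP", "mace"]

    def test_group_means_near_generator_targets(self):
        from hrvrisk import default_config, generate_cohort

        cfg = default_config(n_total=4000, n_positive=2000)
        f = generate_cohort(cfg, seed=13).frame
        rep = summarize_groups(f, variables=["SBP"])
        mean = float(rep.loc["SBP", "mace"].split(" ")[0])
        se = cfg.variables["SBP"].pos[1] / np.sqrt(2000)
        assert abs(mean - cfg.variables["SBP"].pos[0]) < 3 * se
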