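"""Feature rankings, filter + wrapper selection, metrics and the
nine-classifier benchmark, with simulation-based oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import stdtr

from lvadsound import synthio
from lvadsound.errors import ParameterError
from lvadsound.modeling import (KernelNaiveBayes, benchmark_classifiers,
                                evaluate_metrics, filter_select,
                                loo_misclassification, rank_by_gini,
                                rank_by_nca, rank_by_ttest, select_features,
                                wrapper_select)


def two_sample_p(a, b):
    """Closed-form equal-variance two-sample t-test (independent oracle)."""
    na, nb = len(a), len(b)
    sp2 = (((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1))
           / (na + nb - 2))
    t = (np.mean(a) - np.mean(b)) / np.sqrt(sp2 * (1 / na + 1 / nb))
    return 2 * stdtr(na + nb - 2, -abs(t))


def planted_table(n=120, n_noise=7, n_informative=3, shift=1.0, seed=0,
                  prevalence=1 / 3):
    rng = np.random.default_rng(seed)
    y = (np.arange(n) < round(n * prevalence)).astype(int)
    rng.shuffle(y)
    X = rng.standard_normal((n, n_noise + n_informative))
    X[:, :n_informative] += shift * y[:, None]
    cols = ([f"inf{i}" for i in range(n_informative)]
            + [f"noise{i}" for i in range(n_noise)])
    df = pd.DataFrame(X, columns=cols)
    df["ar_label"] = y
    return df


class TestRankByTtest:
    def test_matches_closed_form_oracle(self):
        df = planted_table(seed=1)
        ranking = rank_by_ttest(df)
        y = df["ar_label"].to_numpy()
        oracle_p = {c: two_sample_p(df[c][y == 0], df[c][y == 1])
                    for c in df.columns if c != "ar_label"}
        assert ranking == sorted(oracle_p, key=lambda c: oracle_p[c])

    def test_separated_feature_first_constant_feature_last(self):
        rng = np.random.default_rng(2)
        y = (np.arange(60) < 20).astype(int)
        df = pd.DataFrame({
            "same": np.tile([1.0, 1.001, 0.999], 20),  # identical by class
            "huge": 10.0 * y + 0.5 * rng.standard_normal(60),
        })
        df["ar_label"] = y
        ranking = rank_by_ttest(df)
        assert ranking[0] == "huge"
        assert ranking[-1] == "same"
        p_same = two_sample_p(df["same"][y == 0], df["same"][y == 1])
        assert p_same > 0.5

    def test_single_class_rejected(self):
        df = planted_table()
        df["ar_label"] = 0
        with pytest.raises(ParameterError):
            rank_by_ttest(df)

    def test_ils_features_rank_high_under_clinical_contrasts(self):
        """Over 50 cohort replicates the ILS amplitude-variation feature
        (the strongest clinical contrast) ranks near the top; ILS speed
        competes with heart rate and the h2 frequency variation, which share
        its effect size, but stays in the upper half."""
        ranks = {"ils_amp_var_h1_au": [], "ils_rpm": []}
        for s in range(50):
            df = synthio.sample_feature_table(n=245, seed=1000 + s)
            ranking = rank_by_ttest(df)
            for k in ranks:
                ranks[k].append(ranking.index(k) + 1)
        assert np.median(ranks["ils_amp_var_h1_au"]) <= 4
        assert np.mean(np.array(ranks["ils_amp_var_h1_au"]) <= 6) >= 0.8
        assert np.median(ranks["ils_rpm"]) <= 8


class TestRankByGini:
    def test_separating_feature_beats_noise(self):
        df = planted_table(n_informative=1, shift=5.0, seed=3)
        assert rank_by_gini(df, seed=0)[0] == "inf0"

    def test_permutation_destroys_importance(self):
        """Permuting a planted feature's values drops it below the median
        rank (permutation oracle)."""
        df = planted_table(n_informative=3, shift=1.5, seed=4)
        before = rank_by_gini(df, seed=0)
        assert before.index("inf0") < 3
        rng = np.random.default_rng(5)
        df2 = df.copy()
        df2["inf0"] = rng.permutation(df2["inf0"].to_numpy())
        after = rank_by_gini(df2, seed=0)
        assert after.index("inf0") >= len(after) // 2

    def test_deterministic_given_seed(self):
        df = planted_table(seed=6)
        assert rank_by_gini(df, seed=7) == rank_by_gini(df, seed=7)


class TestRankByNca:
    def test_separating_feature_gets_top_weight(self):
        df = planted_table(n_informative=1, shift=5.0, seed=8)
        ranking, weights = rank_by_nca(df, seed=0)
        assert ranking[0] == "inf0"

    def test_noise_weights_near_uniform(self):
        df = synthio.sample_feature_table(n=150, seed=5, effect_multiplier=0.0)
        _ranking, w = rank_by_nca(df, seed=0)
        assert w.max() / w.min() < 5.0

    def test_deterministic_given_seed(self):
        df = planted_table(seed=9)
        r1, w1 = rank_by_nca(df, seed=3)
        r2, w2 = rank_by_nca(df, seed=3)
        assert r1 == r2
        np.testing.assert_array_equal(w1, w2)


class TestFilterSelect:
    def test_perfect_feature_gives_singleton_zero_error(self):
        df = planted_table(n_informative=1, shift=8.0, seed=10)
        ranking = rank_by_ttest(df)
        subset, trace = filter_select(df, ranking)
        assert subset == ["inf0"]
        assert trace[0] == 0.0

    def test_pure_noise_trace_grows_and_subset_stays_small(self):
        """With no signal the LOOCV error cannot improve as features are
        added; the earliest-prefix tie rule keeps the subset small."""
        firsts, lasts, sizes = [], [], []
        for s in range(20):
            df = planted_table(n_informative=0, n_noise=10, seed=100 + s,
                               prevalence=0.25)
            subset, trace = filter_select(df, [f"noise{i}" for i in range(10)])
            firsts.append(trace[0])
            lasts.append(trace[-1])
            sizes.append(len(subset))
        assert np.mean(lasts) >= np.mean(firsts)
        assert np.median(sizes) <= 3

    def test_planted_informative_features_recovered(self):
        """Filter selection keeps all three planted features in >= 80% of
        50 seeded replicates."""
        hits = 0
        for s in range(50):
            df = planted_table(seed=200 + s)
            subset, _ = filter_select(df, rank_by_ttest(df))
            hits += {"inf0", "inf1", "inf2"} <= set(subset)
        assert hits / 50 >= 0.8


class TestWrapperSelect:
    def test_singleton_filter_subset_returned_unchanged(self):
        df = planted_table(n_informative=1, shift=8.0, seed=11)
        subset, _ = wrapper_select(df, ["inf0"])
        assert subset == ["inf0"]

    def test_duplicate_feature_never_selected_twice(self):
        df = synthio.sample_feature_table(n=150, seed=6)
        df["dup"] = df["ils_amp_var_h1_au"]
        subset, _ = wrapper_select(df, ["ils_amp_var_h1_au", "dup", "ils_rpm"])
        assert not {"ils_amp_var_h1_au", "dup"} <= set(subset)

    def test_wrapper_never_worse_than_filter_subset(self):
        df = planted_table(seed=12, shift=0.8)
        filter_subset, trace = filter_select(df, rank_by_ttest(df))
        wrapper_subset, _ = wrapper_select(df, filter_subset)
        y = df["ar_label"].to_numpy()
        err_w = loo_misclassification(df[wrapper_subset].to_numpy(), y)
        err_f = loo_misclassification(df[filter_subset].to_numpy(), y)
        assert err_w <= err_f
        assert set(wrapper_subset) <= set(filter_subset)

    def test_selection_pipeline_deterministic(self):
        df = synthio.sample_feature_table(n=150, seed=13)
        r1 = select_features(df, seed=5)
        r2 = select_features(df, seed=5)
        assert r1 == r2
        assert set(r1.wrapper_subset) <= set(r1.filter_subset)
        assert len(r1.filter_trace) == 19


class TestKernelNaiveBayes:
    def test_separable_data_classified_perfectly(self):
        df = planted_table(n_informative=2, shift=6.0, seed=14)
        X = df[["inf0", "inf1"]].to_numpy()
        y = df["ar_label"].to_numpy()
        clf = KernelNaiveBayes().fit(X, y)
        assert (clf.predict(X) == y).all()
        proba = clf.predict_proba(X)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)


class TestEvaluateMetrics:
    def test_perfect_predictions(self):
        y = np.array([0, 0, 1, 1])
        m = evaluate_metrics(y, [0.1, 0.2, 0.8, 0.9], y)
        assert (m["accuracy"], m["auc"], m["tpr"], m["tnr"]) == (1, 1, 1, 1)

    def test_constant_scores_give_auc_half(self):
        y = np.array([0, 1, 0, 1, 1])
        m = evaluate_metrics(y, np.ones(5), y)
        assert m["auc"] == 0.5

    def test_all_negative_classifier_on_imbalanced_cohort(self):
        """Predicting all-negative on a 26/219 cohort: accuracy 219/245,
        zero sensitivity, perfect specificity (arithmetic oracle)."""
        y = np.array([1] * 26 + [0] * 219)
        pred = np.zeros(245, dtype=int)
        m = evaluate_metrics(pred, np.zeros(245), y)
        assert m["accuracy"] == pytest.approx(219 / 245)
        assert m["tpr"] == 0.0
        assert m["tnr"] == 1.0

    @settings(derandomize=True, max_examples=25)
    @given(st.sampled_from(["exp", "cube", "affine"]))
    def test_auc_invariant_to_monotone_score_transforms(self, kind):
        rng = np.random.default_rng(15)
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        s = rng.standard_normal(40)
        transform = {"exp": np.exp, "cube": lambda v: v ** 3,
                     "affine": lambda v: 3.0 * v + 7.0}[kind]
        pred = (s > 0).astype(int)
        base = evaluate_metrics(pred, s, y)["auc"]
        assert evaluate_metrics(pred, transform(s), y)["auc"] == \
            pytest.approx(base)


class TestBenchmark:
    def test_linearly_separable_cohort_is_perfect(self):
        df = planted_table(n=80, n_informative=2, n_noise=0, shift=8.0,
                           seed=16, prevalence=0.3)
        report = benchmark_classifiers(df, ["inf0", "inf1"], split_seed=0)
        assert len(report.results) == 9
        for name, m in report.results.items():
            assert m["accuracy"] == 1.0, name
            assert m["auc"] == 1.0, name

    def test_all_nine_algorithms_reported_with_valid_metrics(self):
        df = synthio.sample_feature_table(n=150, seed=17)
        report = benchmark_classifiers(df, ["ils_rpm", "ils_amp_var_h1_au"],
                                       split_seed=1, tune=False)
        assert set(report.results) == {
            "discriminant_analysis", "knn", "naive_bayes",
            "kernel_naive_bayes", "random_forest", "svm", "kernel_svm",
            "decision_tree", "ensemble"}
        for m in report.results.values():
            for v in m.values():
                assert 0.0 <= v <= 1.0

    def test_permuted_labels_give_chance_auc(self):
        """Median AUC over 20 label permutations stays in [0.35, 0.65] for
        every algorithm (permutation-null simulation)."""
        aucs = {}
        for s in range(20):
            df = synthio.sample_feature_table(n=200, ar_prevalence=0.2, seed=s)
            rng = np.random.default_rng(s)
            df["ar_label"] = rng.permutation(df["ar_label"].to_numpy())
            rep = benchmark_classifiers(
                df, ["ils_amp_var_h1_au", "ils_rpm", "amp_h1_au"],
                split_seed=s, tune=False)
            for k, m in rep.results.items():
                aucs.setdefault(k, []).append(m["auc"])
        for k, v in aucs.items():
            assert 0.35 <= np.median(v) <= 0.65, k

    def test_auc_monotone_in_planted_effect_size(self):
        """Median ensemble test AUC over 20 seeds is non-decreasing in the
        planted AR effect multiplier (0, 0.5, 1, 2)."""
        feats = list(synthio.CLASS_FEATURE_STATS)
        medians = []
        for mult in (0.0, 0.5, 1.0, 2.0):
            vals = [benchmark_classifiers(
                synthio.sample_feature_table(n=245, seed=300 + s,
                                             effect_multiplier=mult),
                feats, split_seed=s, tune=False,
                algorithms=["ensemble"]).results["ensemble"]["auc"]
                for s in range(20)]
            medians.append(np.median(vals))
        assert all(b >= a for a, b in zip(medians, medians[1:]))
        assert medians[-1] > 0.7

    def test_planted_effects_detectable_against_permutation_null(self):
        """Planted clinical contrasts: median real ensemble AUC beats the
        label-permutation null's median, and doubling the effects clears the
        null's 97.5th percentile."""
        feats = list(synthio.CLASS_FEATURE_STATS)

        def auc(df, s):
            return benchmark_classifiers(
                df, feats, split_seed=s, tune=False,
                algorithms=["ensemble"]).results["ensemble"]["auc"]

        real = [auc(synthio.sample_feature_table(n=245, seed=400 + s), s)
                for s in range(10)]
        strong = [auc(synthio.sample_feature_table(
            n=245, seed=400 + s, effect_multiplier=2.0), s)
            for s in range(10)]
        df0 = synthio.sample_feature_table(n=245, seed=400)
        null = []
        for s in range(20):
            d = df0.copy()
            d["ar_label"] = np.random.default_rng(s).permutation(
                d["ar_label"].to_numpy())
            null.append(auc(d, s))
        assert np.median(real) > np.median(null)
        assert np.median(strong) > np.percentile(null, 97.5)

    def test_anti_leakage_canary(self):
        """A feature equal to the label in would-be test rows only carries no
        training signal: its training LOOCV error stays at chance while the
        same feature is a perfect predictor on the leaked rows."""
        from sklearn.model_selection import train_test_split

        rng = np.random.default_rng(18)
        n = 160
        y = (np.arange(n) < 48).astype(int)
        rng.shuffle(y)
        idx = np.arange(n)
        tr_idx, te_idx = train_test_split(idx, test_size=0.25, stratify=y,
                                          random_state=0)
        canary = rng.standard_normal(n)
        # leak into the test rows only (small jitter keeps variances finite)
        canary[te_idx] = y[te_idx] + 0.01 * rng.standard_normal(te_idx.size)
        err_train = loo_misclassification(canary[tr_idx, None], y[tr_idx])
        err_leaked = loo_misclassification(canary[te_idx, None], y[te_idx])
        majority_err = min(np.mean(y[tr_idx]), 1 - np.mean(y[tr_idx]))
        assert err_train >= 0.5 * majority_err  # no better than chance-ish
        assert err_leaked <= 0.1                # the leak itself is real

    def test_empty_subset_rejected(self):
        df = planted_table(seed=19)
        with pytest.raises(ParameterError):
            benchmark_classifiers(df, [])
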