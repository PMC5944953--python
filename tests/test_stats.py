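import itertools
import warnings

import numpy as np
import pandas as pd
import pytest

from gaitlds import (
    CohortSimConfig,
    CohortTable,
    bonferroni_alpha,
    ks_normality,
    mann_whitney,
    reproduce_tables,
    roc_combined,
    roc_single,
    simulate_cohort,
)
from gaitlds.stats import StatsError


def _enumerated_mw_p(a, b):
    """Exact two-sided p by enumerating all group assignments (tiny n only)."""
    pooled = np.concatenate([a, b])
    n1 = len(a)
    ranks = pd.Series(pooled).rank().to_numpy()

    def u_of(idx):
        r = ranks[list(idx)].sum()
        return r - n1 * (n1 + 1) / 2

    observed = u_of(range(n1))
    mean_u = n1 * len(b) / 2
    arrangements = list(itertools.combinations(range(len(pooled)), n1))
    us = np.array([u_of(idx) for idx in arrangements])
    return np.mean(np.abs(us - mean_u) >= abs(observed - mean_u) - 1e-12)


class TestMannWhitney:
    def test_fully_separated_small_samples_exact_p(self):
        c = mann_whitney([1, 2, 3], [4, 5, 6])
        assert c.u_statistic in (0.0, 9.0)
        assert c.p_value == pytest.approx(0.1, abs=1e-12)

    @pytest.mark.parametrize("a,b", [
        ([1.2, 3.4, 2.2], [2.9, 4.1, 5.0, 0.3]),
        ([10, 12, 9, 14], [11, 13, 15]),
    ])
    def test_small_sample_p_matches_enumeration(self, a, b):
        c = mann_whitney(a, b)
        assert c.p_value == pytest.approx(_enumerated_mw_p(a, b), abs=1e-9)

    def test_identical_samples_give_p_one(self):
        with pytest.warns(UserWarning, match="identical"):
            c = mann_whitney([2.0, 2.0], [2.0, 2.0, 2.0])
        assert c.p_value == 1.0

    def test_type_one_error_calibrated(self, rng):
        hits = 0
        reps = 400
        for _ in range(reps):
            a = rng.normal(size=120)
            b = rng.normal(size=120)
            hits += mann_whitney(a, b).p_value < 0.05
        assert 0.02 <= hits / reps <= 0.08

    def test_adjusted_significance_flag(self):
        c = mann_whitney([1, 2, 3, 4], [10, 11, 12, 13], alpha=0.05, k=3)
        assert c.adjusted_alpha == pytest.approx(0.05 / 3)
        assert c.significant_adjusted == (c.p_value < 0.05 / 3)


class TestKsNormality:
    def test_normal_draws_usually_pass(self):
        ok = 0
        for seed in range(100):
            x = np.random.default_rng(seed).normal(size=1000)
            ok += ks_normality(x) > 0.05
        assert ok >= 90

    def test_exponential_draws_fail(self):
        rejected = 0
        for seed in range(100):
            x = np.random.default_rng(seed).exponential(size=1000)
            rejected += ks_normality(x) < 0.05
        assert rejected >= 99

    def test_tiny_sample_rejected(self):
        with pytest.raises(StatsError, match="n >= 5"):
            ks_normality([1.0, 2.0, 3.0, 4.0])


class TestBonferroni:
    @pytest.mark.parametrize("alpha,k,expected", [
        (0.05, 3, 0.05 / 3),
        (0.05, 1, 0.05),
        (0.10, 5, 0.02),
    ])
    def test_division(self, alpha, k, expected):
        assert bonferroni_alpha(alpha, k) == pytest.approx(expected)

    def test_invalid_inputs(self):
        with pytest.raises(StatsError):
            bonferroni_alpha(1.5, 3)
        with pytest.raises(StatsError):
            bonferroni_alpha(0.05, 0)


class TestRocSingle:
    def test_perfect_separation(self):
        r = roc_single([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert r.auc == 1.0
        assert r.youden_j == pytest.approx(1.0)
        assert r.specificity == 1.0 and r.sensitivity == 1.0

    def test_four_point_example(self):
        r = roc_single([1, 2, 3, 4], [0, 0, 1, 1])
        assert r.auc == 1.0
        assert 2 < r.cutoff <= 3

    def test_null_scores_mean_half(self, rng):
        aucs = []
        for _ in range(300):
            scores = rng.normal(size=200)
            labels = rng.integers(0, 2, size=200)
            if labels.min() == labels.max():
                continue
            # fixed orientation: auto-orientation folds null AUCs above 0.5
            aucs.append(roc_single(scores, labels, direction="higher-is-positive").auc)
        assert 0.48 <= np.mean(aucs) <= 0.52

    def test_lower_is_positive_orientation(self):
        # low clinical scores flag the positive (faller) class
        r = roc_single([28, 28, 27, 25, 24], [0, 0, 0, 1, 1])
        assert r.direction == "lower-is-positive"
        assert r.auc == 1.0

    def test_youden_maximal_over_brute_force(self, rng):
        for _ in range(20):
            scores = rng.normal(size=60).round(1)  # ties on purpose
            labels = (rng.uniform(size=60) < 0.4).astype(int)
            if labels.min() == labels.max():
                continue
            r = roc_single(scores, labels)
            s = scores if r.direction == "higher-is-positive" else -scores
            best = -np.inf
            for thr in np.unique(s):
                sens = np.mean(s[labels == 1] >= thr)
                spec = np.mean(s[labels == 0] < thr)
                best = max(best, sens + spec - 1)
            assert r.youden_j == pytest.approx(best, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(StatsError, match="both classes"):
            roc_single([1, 2, 3], [1, 1, 1])


class TestRocCombined:
    def test_duplicated_feature_adds_nothing(self, rng):
        x = rng.normal(size=100)
        labels = (x + rng.normal(size=100) > 0).astype(int)
        single = roc_single(x, labels).auc
        combined = roc_combined(np.column_stack([x, x]), labels)
        assert combined.auc == pytest.approx(single, abs=1e-12)

    def test_noise_feature_is_harmless(self, rng):
        worst = 0.0
        for _ in range(40):
            n = 500
            signal = rng.normal(size=n) + 0.8 * rng.integers(0, 2, size=n)
            labels = (signal + rng.normal(size=n) > 0.4).astype(int)
            if labels.min() == labels.max():
                continue
            noise = rng.normal(size=n)
            single = roc_single(signal, labels).auc
            combined = roc_combined(np.column_stack([signal, noise]), labels).auc
            worst = max(worst, single - combined)
        assert worst <= 0.02

    def test_two_informative_features_beat_each_alone(self, study_cohort):
        table, _ = study_cohort
        sub = table.data[table.data["group"].isin(["N", "F2+"])]
        labels = (sub["group"] == "F2+").astype(int).to_numpy()
        # independent information: stLE and gait speed carry separate signal
        rng = np.random.default_rng(4)
        f1 = sub["stle_trunk_ml"].to_numpy()
        f2 = -sub["stle_trunk_ml"].to_numpy() * 0.5 + rng.normal(size=len(sub))
        f2 += 2.0 * labels  # second, independent channel
        a1 = roc_single(f1, labels).auc
        a2 = roc_single(f2, labels).auc
        comb = roc_combined(np.column_stack([f1, f2]), labels).auc
        assert comb >= max(a1, a2) - 1e-9

    def test_converged_fit_has_small_gradient(self, study_cohort):
        import statsmodels.api as sm

        table, _ = study_cohort
        sub = table.data[table.data["group"].isin(["N", "F2+"])]
        labels = (sub["group"] == "F2+").astype(int).to_numpy()
        X = sub[["tinetti_total", "stle_trunk_ml"]].to_numpy()
        r = roc_combined(X, labels, feature_names=["tinetti_total", "stle_trunk_ml"])
        assert not r.separation_flag
        params = np.array([r.coefficients["intercept"],
                           r.coefficients["tinetti_total"],
                           r.coefficients["stle_trunk_ml"]])
        model = sm.Logit(labels, sm.add_constant(X))
        grad = model.score(params)
        assert np.abs(grad).max() < 1e-6

    def test_complete_separation_flagged_but_scored(self):
        x1 = np.concatenate([np.zeros(20), np.ones(20)])
        x2 = np.arange(40, dtype=float)
        labels = np.concatenate([np.zeros(20, int), np.ones(20, int)])
        r = roc_combined(np.column_stack([x1, x2]), labels)
        assert r.separation_flag
        assert r.auc == 1.0


class TestAucUEquivalence:
    def test_trapezoid_auc_equals_rank_u(self, rng):
        # identity AUC = U / (n1 n2) under midrank tie handling
        for _ in range(50):
            n0, n1 = rng.integers(5, 40, size=2)
            scores = np.concatenate([rng.integers(0, 8, n0), rng.integers(0, 8, n1)]).astype(float)
            labels = np.concatenate([np.zeros(n0, int), np.ones(n1, int)])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                c = mann_whitney(scores[labels == 1], scores[labels == 0])
                from sklearn.metrics import roc_auc_score

                auc = roc_auc_score(labels, scores)
            assert auc == pytest.approx(c.u_statistic / (n0 * n1), abs=1e-12)


class TestReproduceTables:
    def test_degenerate_three_subject_cohort(self):
        df = pd.DataFrame({
            "subject_id": ["a", "b", "c"],
            "prospective_falls": [0, 1, 2],
            "age": [70, 71, 72],
            "tinetti_balance": [16, 15, 14],
            "tinetti_gait": [12, 12, 11],
            "tinetti_total": [28, 27, 25],
            "stle_trunk_ml": [1.2, 1.3, 1.5],
        })
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = reproduce_tables(CohortTable(df))
        assert any("only" in w for w in rep["warnings"])
        assert rep["group_sizes"] == {"N": 1, "F1": 1, "F2+": 1}

    def test_missing_predictor_leaves_gap(self, study_cohort):
        table, _ = study_cohort
        df = table.data.drop(columns=["stle_trunk_ml"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = reproduce_tables(CohortTable(df))
        assert rep["roc"]["single"]["stle_trunk_ml"] is None
        assert any("stle_trunk_ml" in w for w in rep["warnings"])
        assert rep["roc"]["single"]["tinetti_total"] is not None

    def test_null_cohort_shows_no_signal(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table, _ = simulate_cohort(CohortSimConfig(
                seed=3, tinetti_profile="null", demographics_profile="null",
                sampling="random"))
            rep = reproduce_tables(table)
        r = rep["roc"]["single"]["stle_trunk_ml"]
        assert 0.35 <= r["auc"] <= 0.65
        comp = rep["clinical"]["tinetti_total"]["comparisons"]["N vs F2+"]
        assert comp["significant_adjusted"] is False
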