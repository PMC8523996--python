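import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from fdopakin import compare


def mann_whitney_auc(scores, labels):
    """All-pairs probability oracle: U/(n1*n0) with ties counted half."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    u = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return u / (len(pos) * len(neg))


class TestROC:
    def test_auc_equals_all_pairs_mann_whitney_probability(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            n1, n0 = rng.integers(3, 12, size=2)
            y = np.r_[np.ones(n1), np.zeros(n0)]
            s = np.round(rng.normal(size=y.size) + 0.7 * y, 1)  # rounding induces ties
            res = compare.roc_analysis(s, y)
            oracle = mann_whitney_auc(s, y)
            assert res.auc == pytest.approx(max(oracle, 1 - oracle), abs=1e-12)

    def test_perfectly_separated_scores(self):
        y = np.r_[np.zeros(5), np.ones(5)]
        s = np.r_[np.zeros(5), np.ones(5) + 1.0]
        res = compare.roc_analysis(s, y)
        assert res.auc == 1.0
        assert res.accuracy == 100.0
        assert res.sensitivity == 100.0 and res.specificity == 100.0
        assert 0.0 < res.cutoff < 2.0  # midpoint between the separated groups

    def test_uninformative_scores_give_an_auc_near_half(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, size=2000)
        y[:2] = [0, 1]
        s = rng.normal(size=2000)
        res = compare.roc_analysis(s, y)
        assert 0.5 <= res.auc < 0.55

    def test_orientation_flip_is_recorded(self):
        y = np.r_[np.zeros(5), np.ones(5)]
        s = np.r_[np.ones(5), np.zeros(5)]  # low scores indicate the positive class
        res = compare.roc_analysis(s, y)
        assert res.auc == 1.0
        assert res.direction == "less"

    def test_cutoff_is_consistent_with_reported_accuracy(self):
        rng = np.random.default_rng(3)
        y = np.r_[np.zeros(23), np.ones(14)]
        s = rng.normal(size=37) + 1.2 * y
        res = compare.roc_analysis(s, y)
        pred = s > res.cutoff if res.direction == "greater" else s < res.cutoff
        acc = 100.0 * np.mean(pred == (y == 1))
        assert acc == pytest.approx(res.accuracy, abs=1e-9)

    def test_single_class_labels_are_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            compare.roc_analysis(np.arange(5.0), np.ones(5))


def delong_enumeration_oracle(a, b, labels):
    """Textbook structural-components estimate computed by direct loops."""
    pos = [i for i, y in enumerate(labels) if y == 1]
    neg = [i for i, y in enumerate(labels) if y == 0]
    m, n = len(pos), len(neg)

    def psi(x, y):
        return 1.0 if x > y else 0.5 if x == y else 0.0

    out = {}
    for name, s in (("a", a), ("b", b)):
        v10 = [sum(psi(s[i], s[j]) for j in neg) / n for i in pos]
        v01 = [sum(psi(s[i], s[j]) for i in pos) / m for j in neg]
        out[name] = (np.mean(v10), np.array(v10), np.array(v01))
    auc_a, v10a, v01a = out["a"]
    auc_b, v10b, v01b = out["b"]

    def cov(x, y):
        return np.sum((x - x.mean()) * (y - y.mean())) / (len(x) - 1)

    var = (cov(v10a, v10a) + cov(v10b, v10b) - 2 * cov(v10a, v10b)) / m
    var += (cov(v01a, v01a) + cov(v01b, v01b) - 2 * cov(v01a, v01b)) / n
    return auc_a - auc_b, var


class TestDeLong:
    def test_identical_scores_give_a_half_p_value(self, labels_23_14):
        rng = np.random.default_rng(0)
        s = rng.normal(size=37)
        assert compare.delong_test(s, s.copy(), labels_23_14) == 0.5

    def test_variance_matches_direct_enumeration_for_small_samples(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            n1, n0 = rng.integers(4, 11, size=2)
            y = np.r_[np.ones(n1), np.zeros(n0)]
            a = rng.normal(size=y.size) + 0.5 * y
            b = 0.6 * a + rng.normal(size=y.size)
            diff, var = delong_enumeration_oracle(a, b, y)
            p = compare.delong_test(a, b, y)
            expected = sps.norm.sf(diff / np.sqrt(var)) if var > 0 else 0.5
            assert p == pytest.approx(expected, abs=1e-12)

    def test_opposite_one_sided_p_values_sum_to_one(self, labels_23_14):
        rng = np.random.default_rng(9)
        a = rng.normal(size=37) + labels_23_14
        b = rng.normal(size=37) + 0.5 * labels_23_14
        p_ab = compare.delong_test(a, b, labels_23_14)
        p_ba = compare.delong_test(b, a, labels_23_14)
        assert p_ab + p_ba == pytest.approx(1.0, abs=1e-12)

    def test_mismatched_lengths_are_rejected(self, labels_23_14):
        with pytest.raises(ValueError, match="equal length"):
            compare.delong_test(np.arange(36.0), np.arange(37.0), labels_23_14)

    def test_null_rejection_rate_is_calibrated(self):
        # two equally informative, correlated scores: the one-sided test
        # should reject at close to its nominal level
        rng = np.random.default_rng(2024)
        rejections = 0
        reps = 500
        for _ in range(reps):
            y = np.r_[np.zeros(23), np.ones(14)]
            base = rng.normal(size=37) + 0.8 * y
            a = base + 0.5 * rng.normal(size=37)
            b = base + 0.5 * rng.normal(size=37)
            rejections += compare.delong_test(a, b, y) < 0.05
        assert 0.02 <= rejections / reps <= 0.08


def bh_oracle(p):
    """Step-up definition computed directly from sorted p-values."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m - 1, -1, -1):
        i = order[rank_from_top]
        running_min = min(running_min, p[i] * m / (rank_from_top + 1))
        adjusted[i] = running_min
    return adjusted


class TestBH:
    def test_single_p_value_is_unchanged(self):
        np.testing.assert_allclose(compare.bh_adjust([0.031]), [0.031])

    def test_equal_p_values_stay_equal(self):
        np.testing.assert_allclose(compare.bh_adjust([0.2, 0.2, 0.2]), 0.2)

    @settings(derandomize=True, max_examples=60)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=10))
    def test_matches_brute_force_step_up_definition(self, p):
        np.testing.assert_allclose(compare.bh_adjust(p), bh_oracle(np.asarray(p)), atol=1e-12)

    def test_dominates_raw_p_and_preserves_order(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=8)
        adj = compare.bh_adjust(p)
        assert np.all(adj >= p - 1e-15)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)  # weakly order-preserving
        # an all-equal vector is a fixed point of the step-up adjustment
        np.testing.assert_allclose(compare.bh_adjust(compare.bh_adjust([0.3] * 5)), 0.3)

    def test_out_of_range_inputs_are_rejected(self):
        with pytest.raises(ValueError):
            compare.bh_adjust([0.5, 1.5])


class TestGroupCompare:
    def test_identical_groups_are_not_distinguishable(self):
        values = np.r_[np.arange(5.0), np.arange(5.0)]
        labels = np.r_[np.zeros(5), np.ones(5)]
        assert compare.group_compare(values, labels) >= 0.99

    def test_exact_small_sample_p_matches_permutation_enumeration(self):
        values = np.array([1.0, 2.0, 4.0, 3.0, 5.0, 6.0])
        labels = np.array([0, 0, 0, 1, 1, 1])
        p = compare.group_compare(values, labels)
        # enumerate all 20 equally likely group assignments of the ranks
        stats = []
        for pos in itertools.combinations(range(6), 3):
            u = sum(
                1.0 if values[i] > values[j] else 0.5 if values[i] == values[j] else 0.0
                for i in pos
                for j in range(6)
                if j not in pos
            )
            stats.append(u)
        u_obs = sum(
            1.0 if values[i] > values[j] else 0.0
            for i in range(3, 6)
            for j in range(0, 3)
        )
        u_hi = max(u_obs, 9 - u_obs)
        p_oracle = np.mean([s >= u_hi for s in stats]) + np.mean([s <= 9 - u_hi for s in stats])
        assert p == pytest.approx(p_oracle, abs=1e-12)

    def test_chi_squared_statistic_matches_the_hand_rule(self):
        labels = np.r_[np.zeros(20), np.ones(20)]
        values = np.array(["a"] * 14 + ["b"] * 6 + ["a"] * 8 + ["b"] * 12)
        p = compare.group_compare(values, labels, kind="chi_squared")
        table = np.array([[14, 6], [8, 12]])
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        stat = ((table - expected) ** 2 / expected).sum()
        assert p == pytest.approx(float(sps.chi2.sf(stat, df=1)), abs=1e-12)

    def test_empty_group_is_rejected(self):
        with pytest.raises(ValueError):
            compare.group_compare(np.arange(4.0), np.ones(4))


class TestSpearman:
    def test_self_correlation_and_monotone_transform_are_one(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=10)
        df = pd.DataFrame({"x": x, "exp_x": np.exp(x)})
        corr = compare.correlation_matrix(df)
        assert corr.loc["x", "x"] == 1.0
        assert corr.loc["x", "exp_x"] == pytest.approx(1.0)

    def test_matches_pearson_of_ranks(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame(rng.normal(size=(5, 4)), columns=list("abcd"))
        corr = compare.correlation_matrix(df)
        ranks = df.rank()
        oracle = np.corrcoef(ranks.T.to_numpy())
        np.testing.assert_allclose(corr.to_numpy(), oracle, atol=1e-12)

    def test_constant_column_is_reported_missing(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0], "c": 1.0})
        corr = compare.correlation_matrix(df)
        assert np.isnan(corr.loc["x", "c"]) and np.isnan(corr.loc["c", "c"])


class TestStepwise:
    def test_aic_matches_its_definition_for_the_selected_model(self, labels_23_14):
        rng = np.random.default_rng(12)
        X = pd.DataFrame({"u": rng.normal(size=37) + labels_23_14, "v": rng.normal(size=37)})
        res = compare.stepwise_glm(X, labels_23_14)
        design = sm.add_constant(X[res.selected], has_constant="add")
        glm = sm.GLM(labels_23_14, design, family=sm.families.Binomial()).fit()
        assert res.aic == pytest.approx(-2 * glm.llf + 2 * len(glm.params), rel=1e-9)

    def test_selection_never_worsens_the_intercept_only_aic(self, labels_23_14):
        rng = np.random.default_rng(13)
        for _ in range(5):
            X = pd.DataFrame(rng.normal(size=(37, 4)), columns=list("abcd"))
            res = compare.stepwise_glm(X, labels_23_14)
            null_aic = compare._fit_logit(X, np.asarray(labels_23_14, dtype=int), [])[0]
            assert res.aic <= null_aic + 1e-9

    def test_strongly_informative_predictor_is_selected(self, labels_23_14):
        rng = np.random.default_rng(14)
        hits = 0
        for _ in range(20):
            X = pd.DataFrame(rng.normal(size=(37, 5)), columns=list("vwxyz"))
            X["v"] += 2.0 * labels_23_14
            res = compare.stepwise_glm(X, labels_23_14)
            hits += "v" in res.selected
        assert hits >= 18

    def test_too_many_predictors_are_rejected(self):
        X = pd.DataFrame(np.eye(4))
        with pytest.raises(ValueError, match="more subjects"):
            compare.stepwise_glm(X, [0, 1, 0, 1])


@pytest.fixture(scope="module")
def table():
    rng = np.random.default_rng(21)
    y = np.r_[np.zeros(23), np.ones(14)]
    cols = [c for cs in compare.MODEL_PARAMS.values() for c in cs]
    df = pd.DataFrame(rng.normal(size=(37, len(cols))), columns=cols)
    df["ttp"] += 3.0 * y  # strong separation by construction
    return df, y


class TestFullComparison:
    def test_constructed_strong_parameter_is_flagged_significant(self, table):
        df, y = table
        report = compare.run_full_comparison(df, y)
        assert report.univariate.loc["ttp", "p_value_bh"] < 0.05
        assert report.univariate.loc["ttp", "auc"] > 0.9

    def test_report_has_six_model_aucs_and_a_full_pairwise_matrix(self, table):
        df, y = table
        report = compare.run_full_comparison(df, y)
        assert len(report.model_aucs) == 6
        assert report.delong_p.shape == (6, 6)
        assert report.delong_p.isna().to_numpy().sum() == 6  # diagonal only
        off = ~np.eye(6, dtype=bool)
        assert np.all((report.delong_p.to_numpy()[off] >= 0) & (report.delong_p.to_numpy()[off] <= 1))
        assert np.all(report.delong_p_adjusted.to_numpy()[off] >= report.delong_p.to_numpy()[off] - 1e-12)

    def test_report_is_deterministic(self, table):
        df, y = table
        r1 = compare.run_full_comparison(df, y)
        r2 = compare.run_full_comparison(df, y)
        pd.testing.assert_frame_equal(r1.univariate, r2.univariate)
        pd.testing.assert_frame_equal(r1.model_aucs, r2.model_aucs)
        pd.testing.assert_frame_equal(r1.delong_p, r2.delong_p)
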