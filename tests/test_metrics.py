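"""Evaluation stack: AUC/DeLong, cutoffs, calibration, decision curves, SHAP."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from oligopath.metrics import (
    calibration_curve,
    confusion_metrics,
    decision_curve,
    delong_compare,
    hosmer_lemeshow,
    kernel_shap_explain,
    net_benefit,
    roc_auc,
    youden_cutoff,
)


def auc_concordance_oracle(y, s):
    """Exact pairwise concordance with half credit for ties."""
    pos = s[y == 1]
    neg = s[y == 0]
    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    return wins / (pos.size * neg.size)


class TestRocAuc:
    def test_worked_example(self):
        """y=[0,0,1,1], s=[0.1,0.4,0.35,0.8]: 3 of 4 pairs concordant."""
        r = roc_auc([0, 0, 1, 1], [0.1, 0.4, 0.35, 0.8])
        assert r.auc == pytest.approx(0.75)

    def test_perfect_and_all_tied(self):
        assert roc_auc([0, 1, 0, 1], [0.1, 0.9, 0.2, 0.8]).auc == 1.0
        assert roc_auc([0, 1, 0, 1], [0.5] * 4).auc == 0.5

    def test_matches_concordance_oracle_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            n = int(rng.integers(10, 50))
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            s = np.round(rng.random(n), 1)  # coarse grid forces ties
            assert roc_auc(y, s).auc == pytest.approx(auc_concordance_oracle(y, s))

    def test_matches_sklearn_reference(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 80)
        y[0], y[1] = 0, 1
        s = rng.random(80)
        assert roc_auc(y, s).auc == pytest.approx(roc_auc_score(y, s))

    def test_ci_contains_auc_and_curve_monotone(self):
        rng = np.random.default_rng(2)
        y = np.repeat([0, 1], 50)
        s = y + rng.standard_normal(100)
        r = roc_auc(y, s)
        assert r.ci_low <= r.auc <= r.ci_high
        assert np.all(np.diff(r.fpr) >= 0) and np.all(np.diff(r.tpr) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 1, 1], [0.1, 0.2, 0.3])

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        y=st.lists(st.integers(0, 1), min_size=4, max_size=40),
        key=st.integers(0, 2**31 - 1),
    )
    def test_auc_concordance_property(self, y, key):
        """Property: AUC always equals the pairwise-concordance statistic,
        including heavily tied score vectors."""
        y = np.asarray(y)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        s = np.round(np.random.default_rng(key).random(y.size) * 4) / 4
        assert roc_auc(y, s).auc == pytest.approx(auc_concordance_oracle(y, s))


class TestDeLong:
    def test_identical_scores_p_one(self):
        y = np.repeat([0, 1], 20)
        s = np.random.default_rng(0).random(40)
        delta, z, p = delong_compare(y, s, s)
        assert delta == 0.0 and p == 1.0

    def test_monotone_transform_zero_delta(self):
        rng = np.random.default_rng(1)
        y = np.repeat([0, 1], 30)
        s = y + rng.standard_normal(60)
        delta, _, _ = delong_compare(y, s, np.exp(2 * s))
        assert delta == pytest.approx(0.0, abs=1e-12)

    def test_power_matches_bootstrap_oracle(self):
        """Known AUC gap 0.15 at n=500: DeLong rejection rate at alpha=0.05
        agrees with a paired-bootstrap test oracle within 5 points over
        200 simulations."""
        rng = np.random.default_rng(7)
        n, n_sims, n_boot = 500, 200, 150
        sa = 1.0 / (np.sqrt(2) * stats.norm.ppf(0.80))  # noise for AUC 0.80
        sb = 1.0 / (np.sqrt(2) * stats.norm.ppf(0.65))  # noise for AUC 0.65

        def fast_auc(y, s):
            r = stats.rankdata(s)
            m = y.sum()
            return (r[y == 1].sum() - m * (m + 1) / 2) / (m * (y.size - m))

        rej_delong = rej_boot = 0
        for _ in range(n_sims):
            y = rng.integers(0, 2, n)
            y[:2] = [0, 1]
            a = y + sa * rng.standard_normal(n)
            b = y + sb * rng.standard_normal(n)
            _, _, p = delong_compare(y, a, b)
            rej_delong += p < 0.05
            # paired bootstrap of the AUC difference
            deltas = np.empty(n_boot)
            idx = rng.integers(0, n, (n_boot, n))
            for k in range(n_boot):
                ii = idx[k]
                if y[ii].min() == y[ii].max():
                    deltas[k] = 0.0
                    continue
                deltas[k] = fast_auc(y[ii], a[ii]) - fast_auc(y[ii], b[ii])
            lo, hi = np.percentile(deltas, [2.5, 97.5])
            rej_boot += (lo > 0) or (hi < 0)
        assert abs(rej_delong - rej_boot) / n_sims <= 0.05


class TestYouden:
    def test_worked_example_midpoint(self):
        """y=[0,1,1], p=[0.2,0.6,0.9]: any cutoff in (0.2,0.6] attains J=1;
        the midpoint 0.4 is returned."""
        assert youden_cutoff([0, 1, 1], [0.2, 0.6, 0.9]) == pytest.approx(0.4)

    def test_anti_ranked_scores_best_j_is_zero(self):
        y = np.array([0, 0, 1, 1])
        p = np.array([0.9, 0.8, 0.2, 0.1])
        c = youden_cutoff(y, p)
        pred = (p >= c).astype(int)
        m = confusion_metrics(y, pred)
        assert m["sensitivity"] + m["specificity"] - 1 == pytest.approx(0.0)

    def test_returned_cutoff_maximises_j(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 50)
        y[:2] = [0, 1]
        p = rng.random(50)
        c = youden_cutoff(y, p)

        def j(cut):
            m = confusion_metrics(y, (p >= cut).astype(int))
            return m["sensitivity"] + m["specificity"] - 1

        best = j(c)
        for cut in np.linspace(0.01, 0.99, 99):
            assert best >= j(cut) - 1e-12


class TestConfusion:
    def test_worked_arithmetic(self):
        y = np.array([1] * 60 + [0] * 40)
        pred = np.array([1] * 50 + [0] * 10 + [1] * 10 + [0] * 30)
        m = confusion_metrics(y, pred)
        assert m["sensitivity"] == pytest.approx(50 / 60)
        assert m["specificity"] == pytest.approx(0.75)
        assert m["accuracy"] == pytest.approx(0.80)

    def test_undefined_ratio_is_nan_not_zero(self):
        m = confusion_metrics([1, 1, 1], [1, 0, 1])
        assert np.isnan(m["specificity"])
        assert m["sensitivity"] == pytest.approx(2 / 3)

    def test_perfect_labels(self):
        m = confusion_metrics([0, 1, 0, 1], [0, 1, 0, 1])
        assert m["accuracy"] == m["sensitivity"] == m["specificity"] == 1.0


class TestHosmerLemeshow:
    def test_exact_agreement_gives_chi2_zero(self):
        # two risk strata whose observed event rates equal the predictions
        p = np.array([0.2] * 50 + [0.8] * 50)
        y = np.array([1] * 10 + [0] * 40 + [1] * 40 + [0] * 10)
        chi2, df, pval = hosmer_lemeshow(y, p, g=2)
        assert chi2 == pytest.approx(0.0, abs=1e-9)
        assert pval == pytest.approx(1.0)

    def test_nominal_type_i_error_on_calibrated_nulls(self):
        """y ~ Bernoulli(p) at n=1000 with p re-fitted in sample (the
        situation the g-2 degrees of freedom calibrate): ~5% rejection
        over 200 simulations."""
        from sklearn.linear_model import LogisticRegression

        rng = np.random.default_rng(0)
        rejections = 0
        n_sims = 200
        for _ in range(n_sims):
            p_true = rng.uniform(0.05, 0.95, 1000)
            y = (rng.random(1000) < p_true).astype(int)
            x = np.log(p_true / (1 - p_true))[:, None]
            lr = LogisticRegression(C=1e6).fit(x, y)
            p_hat = lr.predict_proba(x)[:, 1]
            _, _, pval = hosmer_lemeshow(y, p_hat)
            rejections += pval < 0.05
        rate = rejections / n_sims
        assert abs(rate - 0.05) <= 0.05  # Monte-Carlo tolerance

    def test_overconfident_probabilities_rejected(self):
        """Predicting p^2 when the truth is p is flagged in >80% of sims,
        the miscalibrated-model situation the test is meant to catch."""
        rng = np.random.default_rng(1)
        rejections = 0
        for _ in range(50):
            p = rng.uniform(0.05, 0.95, 1000)
            y = (rng.random(1000) < p).astype(int)
            _, _, pval = hosmer_lemeshow(y, p**2)
            rejections += pval < 0.05
        assert rejections / 50 > 0.8


class TestCalibrationCurve:
    def test_calibrated_input_stays_near_diagonal(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.05, 0.95, 2000)
        y = (rng.random(2000) < p).astype(int)
        rep = calibration_curve(y, p, n_boot=30, seed=0)
        assert np.max(np.abs(rep.apparent - rep.grid)) < 0.08
        assert rep.bin_table["n"].sum() == 2000

    def test_no_bootstrap_equals_apparent(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0.1, 0.9, 300)
        y = (rng.random(300) < p).astype(int)
        rep = calibration_curve(y, p, n_boot=0)
        assert np.array_equal(rep.apparent, rep.bias_corrected)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0.1, 0.9, 300)
        y = (rng.random(300) < p).astype(int)
        a = calibration_curve(y, p, n_boot=25, seed=9)
        b = calibration_curve(y, p, n_boot=25, seed=9)
        assert np.array_equal(a.bias_corrected, b.bias_corrected)


class TestDecisionCurve:
    def test_net_benefit_worked_example(self):
        """n=100, TP=20, FP=10 at p_t=0.47: NB = 0.2 - 0.1*(0.47/0.53)."""
        nb = net_benefit(tp=20, fp=10, n=100, threshold=0.47)
        assert nb == pytest.approx(0.2 - 0.1 * 0.47 / 0.53)

    def test_treat_all_at_study_prevalence(self):
        """95/462 positives at p_t=0.1 reproduce NB = pi - (1-pi)/9."""
        y = np.array([1] * 95 + [0] * 367)
        p = np.ones_like(y, dtype=float) * 0.99  # model that flags everyone
        dc = decision_curve(y, p, thresholds=np.array([0.1]))
        row = dc.table.iloc[0]
        pi = 95 / 462
        expected = pi - (1 - pi) * 0.1 / 0.9
        assert row["nb_all"] == pytest.approx(expected)
        # a flag-everyone model coincides with treat-all
        assert row["nb_model"] == pytest.approx(expected)

    def test_nnt_from_printed_net_benefit(self):
        """NB = 0.16 corresponds to 1/0.16 = 6.25, reported as about 6."""
        y = np.array([1] * 16 + [0] * 84)
        p = np.array([0.9] * 16 + [0.1] * 84)
        # constructed so that TP=16, FP=0 at the 0.47 threshold
        dc = decision_curve(y, p)
        assert dc.net_benefit_at(0.47) == pytest.approx(0.16)
        assert dc.nnt_at(0.47) == pytest.approx(6.25)
        assert round(dc.nnt_at(0.47)) == 6

    def test_identities_on_random_inputs(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            y = rng.integers(0, 2, 80)
            y[:2] = [0, 1]
            p = rng.random(80)
            dc = decision_curve(y, p)
            assert np.all(dc.table["nb_none"] == 0.0)
            assert np.all(dc.table["nb_model"] <= y.mean() + 1e-12)

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            decision_curve([0, 1], [0.2, 0.8], thresholds=np.array([1.0]))


class LinearToy:
    """f(x) = 2 x0 + 3 x1 (+ 0 x2 when present) via decision_function."""

    def __init__(self, w):
        self.w = np.asarray(w, dtype=float)

    def decision_function(self, X):
        return np.asarray(X, dtype=float) @ self.w


class TestKernelShap:
    def test_two_feature_linear_matches_exact_shapley(self):
        """For a linear model the exact Shapley value (enumerating all 4
        coalitions) is w_j (x_j - mean background_j)."""
        rng = np.random.default_rng(0)
        bg = pd.DataFrame(rng.standard_normal((40, 2)), columns=["a", "b"])
        xs = pd.DataFrame(rng.standard_normal((5, 2)), columns=["a", "b"])
        rep = kernel_shap_explain(LinearToy([2.0, 3.0]), bg, xs)
        expected = (xs - bg.mean()) * np.array([2.0, 3.0])
        assert np.allclose(rep.values.to_numpy(), expected.to_numpy(), atol=1e-10)

    def test_additivity_per_subject(self):
        rng = np.random.default_rng(1)
        bg = pd.DataFrame(rng.standard_normal((30, 4)), columns=list("abcd"))
        xs = pd.DataFrame(rng.standard_normal((6, 4)), columns=list("abcd"))

        class Quad:
            def decision_function(self, X):
                X = np.asarray(X)
                return X[:, 0] * X[:, 1] + np.sin(X[:, 2]) - 0.5 * X[:, 3] ** 2

        rep = kernel_shap_explain(Quad(), bg, xs)
        total = rep.values.sum(axis=1).to_numpy() + rep.base_value
        assert np.allclose(total, rep.model_output, atol=1e-8)

    def test_null_player_gets_zero(self):
        rng = np.random.default_rng(2)
        bg = pd.DataFrame(rng.standard_normal((30, 3)), columns=list("abc"))
        xs = pd.DataFrame(rng.standard_normal((8, 3)), columns=list("abc"))
        rep = kernel_shap_explain(LinearToy([2.0, 3.0, 0.0]), bg, xs)
        assert np.abs(rep.values["c"].to_numpy()).max() < 1e-10
        assert rep.ranking.index[-1] == "c"

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError, match="background"):
            kernel_shap_explain(LinearToy([1.0]), pd.DataFrame(columns=["a"]), pd.DataFrame({"a": [1.0]}))
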