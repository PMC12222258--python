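"""Feature-screening cascade: per-stage oracles and the nesting invariant."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oligopath.screening import (
    ScreeningConfig,
    StageError,
    icc_2_1,
    lasso_select,
    mann_whitney_filter,
    minmax_normalize,
    mrmr_rank,
    run_screening,
    spearman_prune,
)
from oligopath.simulate import CohortSpec, generate_feature_cohort, generate_replicate_set


class TestMinMax:
    def test_basic_scaling_and_clipping(self):
        train = pd.DataFrame({"a": [2.0, 4.0, 6.0]})
        val = pd.DataFrame({"a": [1.0, 7.0, 5.0]})
        tr, va, params = minmax_normalize(train, val)
        assert list(tr["a"]) == [0.0, 0.5, 1.0]
        # out-of-range validation values clip to the unit interval
        assert list(va["a"]) == [0.0, 1.0, 0.75]

    def test_constant_column_dropped_with_record(self):
        train = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 3.0]})
        with pytest.warns(UserWarning, match="constant"):
            tr, _, params = minmax_normalize(train)
        assert list(tr.columns) == ["a"]
        assert params.dropped_constant == ["b"]


class TestIcc:
    def test_identical_replicates_icc_one(self):
        rng = np.random.default_rng(0)
        base = rng.standard_normal((30, 4))
        data = np.repeat(base[:, None, :], 3, axis=1)
        assert np.allclose(icc_2_1(data), 1.0)

    def test_pure_noise_icc_near_zero(self):
        """No subject effect: ICC ~ 0 across 50 seeded simulations."""
        vals = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            vals.append(float(icc_2_1(rng.standard_normal((60, 3, 1)))[0]))
        assert abs(np.median(vals)) < 0.05

    def test_matches_pingouin_reference(self):
        """ICC(2,1) agrees with pingouin's ICC2 on a small table."""
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        data = rng.standard_normal((12, 1)) + 0.6 * rng.standard_normal((12, 4))
        long = pd.DataFrame(
            [
                {"subject": i, "rater": j, "score": data[i, j]}
                for i in range(12)
                for j in range(4)
            ]
        )
        ref = pingouin.intraclass_corr(
            long, targets="subject", raters="rater", ratings="score"
        )
        # two-way random effects, absolute agreement, single rater
        sel = ref["Type"].isin(["ICC2", "ICC(A,1)"])
        ref_icc2 = float(ref.loc[sel, "ICC"].iloc[0])
        assert icc_2_1(data[:, :, None])[0] == pytest.approx(ref_icc2, abs=1e-9)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="2 subjects"):
            icc_2_1(np.zeros((1, 3, 2)))


class TestMannWhitney:
    def test_disjoint_small_groups_exact_p(self):
        """Class 0 {1,2,3} vs class 1 {4,5,6}: U=0 and the exact two-sided
        p is 2/20 = 0.10 (enumeration of all 20 assignments), so the
        feature is dropped at alpha=0.05."""
        X = pd.DataFrame({"f": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]})
        y = np.array([0, 0, 0, 1, 1, 1])
        kept, table = mann_whitney_filter(X, y, alpha=0.05)
        assert table.loc["f", "U"] == 0.0
        assert table.loc["f", "p"] == pytest.approx(0.10, abs=1e-12)
        assert kept == []

    def test_null_rejection_rate_near_alpha(self):
        """Permuted labels: per-feature rejection ~ 5% (100 null datasets)."""
        rng = np.random.default_rng(0)
        rejections = 0
        for _ in range(100):
            X = pd.DataFrame(rng.standard_normal((60, 5)))
            X.columns = [f"f{i}" for i in range(5)]
            y = rng.permutation(np.repeat([0, 1], 30))
            kept, _ = mann_whitney_filter(X, y, alpha=0.05)
            rejections += len(kept)
        rate = rejections / 500
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 500)

    def test_constant_feature_p_one(self):
        X = pd.DataFrame({"f": np.ones(20)})
        y = np.repeat([0, 1], 10)
        kept, table = mann_whitney_filter(X, y)
        assert table.loc["f", "p"] == 1.0
        assert kept == []

    def test_single_class_rejected(self):
        X = pd.DataFrame({"f": [1.0, 2.0]})
        with pytest.raises(ValueError, match="two classes"):
            mann_whitney_filter(X, np.array([1, 1]))


class TestSpearmanPrune:
    def test_duplicate_column_keeps_one(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(50)
        X = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.standard_normal(50)})
        priority = pd.Series({"a": 0.01, "b": 0.02, "c": 0.5})
        kept, pruned = spearman_prune(X, priority)
        assert kept == ["a", "c"]
        assert pruned == [("a", "b", pytest.approx(1.0))]

    def test_correlated_triple_keeps_smallest_p(self):
        rng = np.random.default_rng(1)
        base = rng.standard_normal(200)
        X = pd.DataFrame(
            {
                "a": base + 0.01 * rng.standard_normal(200),
                "b": base + 0.01 * rng.standard_normal(200),
                "c": base + 0.01 * rng.standard_normal(200),
            }
        )
        priority = pd.Series({"a": 0.3, "b": 0.001, "c": 0.2})
        kept, _ = spearman_prune(X, priority)
        assert kept == ["b"]

    def test_monotone_transform_is_pruned(self):
        """x vs x^3 has Spearman rho exactly 1 (rank-based), so one goes."""
        x = np.linspace(-2, 2, 40)
        X = pd.DataFrame({"a": x, "b": x**3})
        kept, pruned = spearman_prune(X, pd.Series({"a": 0.01, "b": 0.5}))
        assert kept == ["a"]
        assert pruned[0][2] == pytest.approx(1.0)


def _mi_oracle(a: np.ndarray, b: np.ndarray) -> float:
    """Plug-in mutual information from the joint contingency table."""
    joint = pd.crosstab(pd.Series(a), pd.Series(b)).to_numpy().astype(float)
    joint /= joint.sum()
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log(joint / (pa * pb))
    return float(np.nansum(terms))


def _mrmr_oracle(X: pd.DataFrame, y: np.ndarray, k: int) -> list[str]:
    """Independent greedy mRMR-MID with 3-bin equal-frequency binning."""
    def binned(col):
        edges = np.quantile(col, [1 / 3, 2 / 3])
        return np.searchsorted(edges, col, side="right")

    b = {f: binned(X[f].to_numpy()) for f in X.columns}
    rel = {f: _mi_oracle(b[f], y) for f in X.columns}
    chosen: list[str] = []
    remaining = sorted(X.columns)
    while len(chosen) < k:
        scores = {}
        for f in remaining:
            red = np.mean([_mi_oracle(b[f], b[s]) for s in chosen]) if chosen else 0.0
            scores[f] = rel[f] - red
        # deterministic alphabetical tie-break
        top = max(scores.values())
        best = sorted([f for f in remaining if abs(scores[f] - top) < 1e-15])[0]
        chosen.append(best)
        remaining.remove(best)
    return chosen


class TestMrmr:
    def test_matches_bruteforce_oracle_on_small_instances(self):
        """Full ranking equals an independent implementation of greedy
        mRMR-MID on random 4-6 feature tables."""
        rng = np.random.default_rng(0)
        for trial in range(5):
            p = int(rng.integers(4, 7))
            y = rng.integers(0, 2, 60)
            X = pd.DataFrame(
                rng.standard_normal((60, p)) + 0.8 * y[:, None] * rng.random(p),
                columns=[f"f{i}" for i in range(p)],
            )
            ours, _ = mrmr_rank(X, y, p)
            assert ours == _mrmr_oracle(X, y, p)

    def test_label_copy_ranks_first(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 90)
        X = pd.DataFrame(
            {
                "alpha": rng.standard_normal(90),
                "oracle": y + 0.001 * rng.standard_normal(90),
                "zeta": rng.standard_normal(90),
            }
        )
        ranked, _ = mrmr_rank(X, y, 3)
        assert ranked[0] == "oracle"

    def test_duplicated_feature_penalised_by_redundancy(self):
        """A clone of the top feature carries maximal redundancy and falls
        behind an independent, weaker feature."""
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 300)
        strong = y + 0.2 * rng.standard_normal(300)
        weak = y + 2.0 * rng.standard_normal(300)
        X = pd.DataFrame({"strong": strong, "clone": strong.copy(), "weak": weak})
        ranked, _ = mrmr_rank(X, y, 3)
        # relevance ties between the twins resolve alphabetically; the
        # remaining twin then scores maximal redundancy and ranks last
        assert ranked[0] in {"strong", "clone"}
        assert ranked[1] == "weak"

    def test_invalid_k(self):
        X = pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 1.0]})
        with pytest.raises(ValueError):
            mrmr_rank(X, np.array([0, 1]), 0)


class TestLasso:
    def test_orthonormal_soft_thresholding(self):
        """With X'X = I (gaussian family) the LASSO solution is the
        soft-thresholded OLS estimate sign(b)(|b| - n*lambda)+ under
        sklearn's 1/(2n) loss scaling."""
        rng = np.random.default_rng(0)
        n, p = 64, 5
        raw = rng.standard_normal((n, p))
        raw -= raw.mean(axis=0)  # zero-mean columns keep Q orthonormal
        Q, _ = np.linalg.qr(raw)  # after the intercept is centred out
        X = pd.DataFrame(Q, columns=[f"f{i}" for i in range(p)])
        beta = np.array([2.0, -1.5, 0.8, 0.0, -0.1])
        y = Q @ beta  # noiseless; OLS = X'y = beta
        lam = 0.01
        res = lasso_select(
            X, y, family="gaussian", lambda_grid=np.array([lam]), folds=3, standardize=False
        )
        expected = np.sign(beta) * np.clip(np.abs(beta) - n * lam, 0.0, None)
        fitted = np.zeros(p)
        for i, f in enumerate(X.columns):
            fitted[i] = res.coefficients.get(f, 0.0)
        assert np.allclose(fitted, expected, atol=1e-4)

    def test_huge_lambda_kills_all_coefficients(self, small_cohort):
        X, y = small_cohort
        res = lasso_select(X, y, lambda_grid=np.array([1e6, 1e5]), folds=3)
        assert res.selected == []
        assert (res.path["n_nonzero"] == 0).all()

    def test_path_nonzeros_nonincreasing_in_lambda(self, small_cohort):
        X, y = small_cohort
        res = lasso_select(X, y, folds=3, n_lambdas=25)
        nz = res.path.sort_values("lmbda")["n_nonzero"].to_numpy()
        assert np.all(np.diff(nz) <= 0)

    def test_planted_feature_recovery(self):
        """6 informative of 80 features (effect 1.0, n=400): lambda.min
        recovers >= 5 of 6, median over 20 seeded cohorts."""
        recovered = []
        for seed in range(20):
            table = generate_feature_cohort(
                CohortSpec(n_subjects=400, n_features=80, n_informative=6, effect_size=1.0, seed=seed)
            )
            y = table["label"].to_numpy()
            X = table.drop(columns=["label"])
            res = lasso_select(X, y, folds=5, seed=seed, n_lambdas=40)
            planted = set(table.attrs["informative_features"])
            recovered.append(len(planted & set(res.selected)))
        assert np.median(recovered) >= 5


class TestCascade:
    def test_nesting_invariant_and_report(self):
        table = generate_feature_cohort(
            CohortSpec(n_subjects=300, n_features=60, n_informative=5, effect_size=1.0, seed=2)
        )
        y = table["label"].to_numpy()
        X = table.drop(columns=["label"])
        reps = generate_replicate_set(X, 3, 0.03, seed=1)
        report = run_screening(X, y, reps, ScreeningConfig(mrmr_k=20, seed=0))
        chain = [
            report.normalized_features,
            report.icc_retained,
            report.mw_retained,
            report.spearman_retained,
            report.mrmr_retained,
            report.final_features,
        ]
        for outer, inner in zip(chain, chain[1:]):
            assert set(inner) <= set(outer)
        assert report.stage_sizes["lasso"] >= 1

    def test_null_cohort_runs_without_crash(self):
        """Zero-effect cohort: the cascade completes and the survivor set
        stays small (type-I control at the end of the funnel)."""
        table = generate_feature_cohort(
            CohortSpec(n_subjects=300, n_features=120, effect_size=0.0, n_informative=0, seed=4)
        )
        y = table["label"].to_numpy()
        X = table.drop(columns=["label"])
        try:
            report = run_screening(X, y, None, ScreeningConfig(mrmr_k=20, seed=0))
            assert len(report.final_features) <= 20
        except StageError as err:
            # an empty survivor set at some stage is the other legitimate
            # outcome on pure-noise data
            assert err.stage in {"mann_whitney", "spearman", "mrmr", "lasso"}

    def test_deterministic_given_seed(self):
        table = generate_feature_cohort(
            CohortSpec(n_subjects=200, n_features=40, n_informative=4, effect_size=1.0, seed=6)
        )
        y = table["label"].to_numpy()
        X = table.drop(columns=["label"])
        r1 = run_screening(X, y, None, ScreeningConfig(mrmr_k=15, seed=9))
        r2 = run_screening(X, y, None, ScreeningConfig(mrmr_k=15, seed=9))
        assert r1.final_features == r2.final_features
        assert r1.lasso.lambda_min == r2.lasso.lambda_min
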