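"""Five-stage feature-screening cascade with a full audit trail.

Order: min-max normalisation → ICC reproducibility filter → Mann-Whitney U
association filter → Spearman collinearity pruning → mRMR ranking → LASSO
(logistic, lambda.min by stratified cross-validation). Each stage's output
is a subset of its input and every intermediate statistic is kept in the
:class:`ScreeningReport`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Lasso, LogisticRegression
from sklearn.metrics import mutual_info_score
from sklearn.model_selection import KFold, StratifiedKFold

from .simulate import ReplicateSet

__all__ = [
    "ScreeningConfig",
    "ScreeningReport",
    "MinMaxParams",
    "StageError",
    "minmax_normalize",
    "icc_2_1",
    "icc_filter",
    "mann_whitney_filter",
    "spearman_prune",
    "mrmr_rank",
    "lasso_select",
    "run_screening",
]


class StageError(RuntimeError):
    """A screening stage produced an empty survivor set."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass(frozen=True)
class ScreeningConfig:
    icc_threshold: float = 0.75
    alpha: float = 0.05
    rho_max: float = 0.9
    mrmr_k: int = 30
    lasso_folds: int = 5
    lambda_rule: str = "lambda.min"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.rho_max <= 1:
            raise ValueError("rho_max must lie in (0, 1]")
        if self.mrmr_k < 1:
            raise ValueError("mrmr_k must be >= 1")
        if self.lambda_rule != "lambda.min":
            raise ValueError("only the lambda.min rule is supported")


# ---------------------------------------------------------------------------
# stage 0: min-max normalisation
# ---------------------------------------------------------------------------


@dataclass
class MinMaxParams:
    mins: pd.Series
    maxs: pd.Series
    dropped_constant: list[str]

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        cols = self.mins.index
        scaled = (table[cols] - self.mins) / (self.maxs - self.mins)
        return scaled.clip(0.0, 1.0)


def minmax_normalize(
    train: pd.DataFrame, apply_to: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame | None, MinMaxParams]:
    """Per-feature (x − min)/(max − min), fitted on the training table only.

    Out-of-range values in ``apply_to`` are clipped to [0, 1]. Zero-range
    (constant) training features are dropped with a warning and recorded.
    """
    if train.empty:
        raise ValueError("training table is empty")
    mins = train.min(axis=0)
    maxs = train.max(axis=0)
    constant = list(train.columns[(maxs - mins) <= 0])
    if constant:
        warnings.warn(
            f"dropping {len(constant)} constant feature(s): {constant[:5]}...",
            stacklevel=2,
        )
    params = MinMaxParams(mins=mins.drop(constant), maxs=maxs.drop(constant), dropped_constant=constant)
    train_out = params.transform(train)
    apply_out = params.transform(apply_to) if apply_to is not None else None
    return train_out, apply_out, params


# ---------------------------------------------------------------------------
# stage 1: ICC reproducibility filter
# ---------------------------------------------------------------------------


def icc_2_1(data: np.ndarray) -> np.ndarray:
    """Vectorised ICC(2,1) — two-way random effects, absolute agreement,
    single measurement — for ``data[subject, replicate, feature]``.

    From the two-way ANOVA decomposition:
    ICC = (MSR − MSE) / (MSR + (k−1)·MSE + k·(MSC − MSE)/n).
    """
    data = np.asarray(data, dtype=float)
    if data.ndim == 2:
        data = data[..., None]
    n, k = data.shape[0], data.shape[1]
    if n < 2:
        raise ValueError("ICC requires at least 2 subjects")
    if k < 2:
        raise ValueError("ICC requires at least 2 replicates")
    grand = data.mean(axis=(0, 1))
    row_mean = data.mean(axis=1)
    col_mean = data.mean(axis=0)
    ss_total = ((data - grand) ** 2).sum(axis=(0, 1))
    ss_rows = k * ((row_mean - grand) ** 2).sum(axis=0)
    ss_cols = n * ((col_mean - grand) ** 2).sum(axis=0)
    ss_err = np.clip(ss_total - ss_rows - ss_cols, 0.0, None)
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    with np.errstate(invalid="ignore", divide="ignore"):
        icc = np.where(denom > 0, (msr - mse) / denom, 1.0)
    return icc


def icc_filter(
    replicates: ReplicateSet, threshold: float = 0.75
) -> tuple[list[str], pd.Series]:
    """Retain features whose ICC(2,1) strictly exceeds ``threshold``."""
    icc = icc_2_1(replicates.data)
    values = pd.Series(icc, index=replicates.feature_names, name="icc")
    retained = list(values.index[values > threshold])
    return retained, values


# ---------------------------------------------------------------------------
# stage 2: Mann-Whitney U filter
# ---------------------------------------------------------------------------


def mann_whitney_filter(
    X: pd.DataFrame, y: np.ndarray, alpha: float = 0.05
) -> tuple[list[str], pd.DataFrame]:
    """Two-sided Mann-Whitney U test per feature; retain p < alpha.

    Exact p-values for small tie-free samples, tie-corrected normal
    approximation otherwise (scipy's ``method="auto"``). No multiplicity
    adjustment — raw per-feature p-values are compared with alpha.
    """
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("Mann-Whitney filter requires exactly two classes in y")
    g0 = X.loc[y == classes[0]]
    g1 = X.loc[y == classes[1]]
    records = []
    for name in X.columns:
        a, b = g0[name].to_numpy(), g1[name].to_numpy()
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            u, p = a.size * b.size / 2.0, 1.0
        else:
            res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
            u, p = float(res.statistic), float(res.pvalue)
        records.append((name, u, p))
    table = pd.DataFrame(records, columns=["feature", "U", "p"]).set_index("feature")
    retained = list(table.index[table["p"] < alpha])
    return retained, table


# ---------------------------------------------------------------------------
# stage 3: Spearman collinearity pruning
# ---------------------------------------------------------------------------


def spearman_prune(
    X: pd.DataFrame, priority: pd.Series, rho_max: float = 0.9
) -> tuple[list[str], list[tuple[str, str, float]]]:
    """Greedy rank-correlation pruning.

    Features are visited in ascending priority (Mann-Whitney p, ties broken
    lexicographically); a feature is dropped when its |Spearman ρ| with an
    already-kept feature exceeds ``rho_max``, so of any correlated pair the
    smaller-p member survives. Returns retained names and the pruned pairs
    ``(kept, dropped, rho)``.
    """
    if X.shape[1] < 2:
        return list(X.columns), []
    order = sorted(X.columns, key=lambda f: (priority.get(f, 1.0), f))
    rho = pd.DataFrame(
        stats.spearmanr(X.to_numpy())[0] if X.shape[1] > 2 else None,
        index=X.columns,
        columns=X.columns,
    )
    if X.shape[1] == 2:
        r = stats.spearmanr(X.iloc[:, 0], X.iloc[:, 1])[0]
        rho.iloc[:, :] = [[1.0, r], [r, 1.0]]
    kept: list[str] = []
    pruned: list[tuple[str, str, float]] = []
    for f in order:
        clash = None
        for g in kept:
            r = rho.loc[f, g]
            if np.isfinite(r) and abs(r) > rho_max:
                clash = (g, f, float(r))
                break
        if clash is None:
            kept.append(f)
        else:
            pruned.append(clash)
    kept_in_input_order = [f for f in X.columns if f in set(kept)]
    return kept_in_input_order, pruned


# ---------------------------------------------------------------------------
# stage 4: mRMR ranking
# ---------------------------------------------------------------------------


def _equal_frequency_bins(x: np.ndarray, n_bins: int = 3) -> np.ndarray:
    edges = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(edges, x, side="right")


def mrmr_rank(
    X: pd.DataFrame, y: np.ndarray, k: int
) -> tuple[list[str], pd.Series]:
    """Greedy mRMR-MID ranking: relevance minus mean redundancy.

    Mutual information is estimated on an equal-frequency 3-bin
    discretisation of each feature (labels used as-is). The first feature
    maximises I(f; y); each subsequent pick maximises
    ``I(f; y) − mean_{s in selected} I(f; s)``. Ties break by feature name.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > X.shape[1]:
        raise ValueError(f"k={k} exceeds the {X.shape[1]} candidate features")
    y = np.asarray(y)
    binned = {f: _equal_frequency_bins(X[f].to_numpy()) for f in X.columns}
    relevance = {f: mutual_info_score(binned[f], y) for f in X.columns}
    mi_cache: dict[tuple[str, str], float] = {}

    def redundancy(f: str, g: str) -> float:
        key = (f, g) if f < g else (g, f)
        if key not in mi_cache:
            mi_cache[key] = mutual_info_score(binned[f], binned[g])
        return mi_cache[key]

    selected: list[str] = []
    scores: list[float] = []
    candidates = set(X.columns)
    while len(selected) < k:
        best_f, best_score = None, -np.inf
        for f in sorted(candidates):
            if selected:
                red = np.mean([redundancy(f, s) for s in selected])
            else:
                red = 0.0
            score = relevance[f] - red
            if score > best_score + 1e-15:
                best_f, best_score = f, score
        selected.append(best_f)
        scores.append(best_score)
        candidates.discard(best_f)
    return selected, pd.Series(scores, index=selected, name="mrmr_score")


# ---------------------------------------------------------------------------
# stage 5: LASSO selection at lambda.min
# ---------------------------------------------------------------------------


@dataclass
class LassoResult:
    selected: list[str]
    coefficients: pd.Series  # nonzero coefficients at lambda_min
    intercept: float
    lambda_min: float
    path: pd.DataFrame  # columns: lmbda, cv_error, n_nonzero
    separation_warning: bool = False


def _fit_l1(X: np.ndarray, y: np.ndarray, lmbda: float, family: str):
    n = X.shape[0]
    if family == "binomial":
        model = LogisticRegression(
            l1_ratio=1.0,
            C=1.0 / max(n * lmbda, 1e-12),
            solver="liblinear",
            max_iter=1000,
            tol=1e-5,
            intercept_scaling=20.0,
            random_state=0,
        )
        model.fit(X, y)
        return model.coef_.ravel(), float(model.intercept_[0])
    model = Lasso(alpha=lmbda, max_iter=50000, tol=1e-8)
    model.fit(X, y)
    return model.coef_.ravel(), float(model.intercept_)


def _cv_error(X: np.ndarray, y: np.ndarray, lmbda: float, family: str, splits) -> float:
    errs = []
    for tr, te in splits:
        coef, b0 = _fit_l1(X[tr], y[tr], lmbda, family)
        eta = X[te] @ coef + b0
        if family == "binomial":
            # binomial deviance, numerically guarded
            p = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
            p = np.clip(p, 1e-10, 1 - 1e-10)
            errs.append(-2.0 * np.mean(y[te] * np.log(p) + (1 - y[te]) * np.log(1 - p)))
        else:
            errs.append(np.mean((y[te] - eta) ** 2))
    return float(np.mean(errs))


def lasso_select(
    X: pd.DataFrame,
    y: np.ndarray,
    folds: int = 5,
    seed: int = 0,
    family: str = "binomial",
    lambda_grid: np.ndarray | None = None,
    n_lambdas: int = 60,
    standardize: bool = True,
) -> LassoResult:
    """L1-penalised selection with lambda.min chosen by cross-validation.

    A glmnet-style log-spaced λ grid is searched with stratified (binomial)
    or plain (gaussian) seeded K-fold CV; λ_min minimises mean CV deviance
    (binomial) or MSE (gaussian). The model is refit at λ_min on all data
    and features with nonzero coefficients are returned. Features are
    standardised internally by default (as in glmnet); reported
    coefficients are mapped back to the input scale.
    """
    if X.shape[1] < 2:
        raise ValueError("LASSO selection requires >= 2 features")
    y = np.asarray(y, dtype=float)
    Xv = X.to_numpy(dtype=float)
    if standardize:
        mu = Xv.mean(axis=0)
        sd = Xv.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        Xv = (Xv - mu) / sd
    else:
        mu = np.zeros(Xv.shape[1])
        sd = np.ones(Xv.shape[1])
    n = Xv.shape[0]
    if family == "binomial" and np.unique(y).size != 2:
        raise ValueError("binomial LASSO requires both classes present")

    if lambda_grid is None:
        resid = y - y.mean()
        lam_max = np.abs(Xv.T @ resid).max() / n
        lam_max = max(lam_max, 1e-6)
        lambda_grid = np.logspace(np.log10(lam_max), np.log10(lam_max * 1e-3), n_lambdas)
    lambda_grid = np.sort(np.asarray(lambda_grid, dtype=float))[::-1]

    if family == "binomial":
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        splits = list(cv.split(Xv, y))
    else:
        cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
        splits = list(cv.split(Xv))

    cv_errors = np.array([_cv_error(Xv, y, l, family, splits) for l in lambda_grid])
    n_nonzero = []
    finite = np.isfinite(cv_errors)
    separation = not finite.any()
    if separation:
        warnings.warn("degenerate CV error at every lambda; returning smallest-lambda fit", stacklevel=2)
        idx = len(lambda_grid) - 1
    else:
        idx = int(np.nanargmin(np.where(finite, cv_errors, np.inf)))
    lambda_min = float(lambda_grid[idx])

    for l in lambda_grid:
        coef_l, _ = _fit_l1(Xv, y, l, family)
        n_nonzero.append(int(np.sum(np.abs(coef_l) > 1e-8)))
    coef, b0 = _fit_l1(Xv, y, lambda_min, family)
    nz = np.abs(coef) > 1e-8
    coef = coef / sd  # back to the input scale
    b0 = b0 - float(np.sum(coef * mu))
    selected = [f for f, keep in zip(X.columns, nz) if keep]
    path = pd.DataFrame({"lmbda": lambda_grid, "cv_error": cv_errors, "n_nonzero": n_nonzero})
    return LassoResult(
        selected=selected,
        coefficients=pd.Series(coef[nz], index=selected, name="coefficient"),
        intercept=b0,
        lambda_min=lambda_min,
        path=path,
        separation_warning=separation,
    )


# ---------------------------------------------------------------------------
# the cascade
# ---------------------------------------------------------------------------


@dataclass
class ScreeningReport:
    input_features: list[str]
    normalized_features: list[str]
    dropped_constant: list[str]
    icc_values: pd.Series
    icc_retained: list[str]
    mw_table: pd.DataFrame
    mw_retained: list[str]
    spearman_pruned: list[tuple[str, str, float]]
    spearman_retained: list[str]
    mrmr_scores: pd.Series
    mrmr_retained: list[str]
    lasso: LassoResult
    final_features: list[str] = field(default_factory=list)

    @property
    def stage_sizes(self) -> dict[str, int]:
        return {
            "input": len(self.input_features),
            "normalized": len(self.normalized_features),
            "icc": len(self.icc_retained),
            "mann_whitney": len(self.mw_retained),
            "spearman": len(self.spearman_retained),
            "mrmr": len(self.mrmr_retained),
            "lasso": len(self.final_features),
        }

    def to_dict(self) -> dict:
        return {
            "stage_sizes": self.stage_sizes,
            "dropped_constant": self.dropped_constant,
            "icc": self.icc_values.to_dict(),
            "mann_whitney": self.mw_table.reset_index().to_dict(orient="list"),
            "spearman_pruned": self.spearman_pruned,
            "mrmr_scores": self.mrmr_scores.to_dict(),
            "lambda_min": self.lasso.lambda_min,
            "lasso_coefficients": self.lasso.coefficients.to_dict(),
            "final_features": self.final_features,
        }


def run_screening(
    X_train: pd.DataFrame,
    y_train: np.ndarray,
    replicates: ReplicateSet | None,
    config: ScreeningConfig = ScreeningConfig(),
) -> ScreeningReport:
    """Execute the full cascade and capture every intermediate result.

    ``replicates`` feeds the ICC stage; pass ``None`` to skip it (the ICC
    values are then reported as 1 for every feature). Stage outputs are
    nested subsets in cascade order; an empty survivor set raises
    :class:`StageError` naming the stage.
    """
    y_train = np.asarray(y_train)
    X_norm, _, mm = minmax_normalize(X_train)
    feats = list(X_norm.columns)
    if not feats:
        raise StageError("normalize", "all features constant on the training data")

    if replicates is not None:
        rep_idx = [replicates.feature_names.index(f) for f in feats if f in replicates.feature_names]
        rep = ReplicateSet(
            data=replicates.data[:, :, rep_idx],
            feature_names=[replicates.feature_names[i] for i in rep_idx],
        )
        icc_kept, icc_vals = icc_filter(rep, config.icc_threshold)
        icc_kept = [f for f in feats if f in set(icc_kept)]
    else:
        icc_vals = pd.Series(1.0, index=feats, name="icc")
        icc_kept = feats
    if not icc_kept:
        raise StageError("icc", "no feature exceeded the ICC threshold")

    mw_kept, mw_table = mann_whitney_filter(X_norm[icc_kept], y_train, config.alpha)
    if not mw_kept:
        raise StageError("mann_whitney", "no feature passed the U test")

    sp_kept, sp_pruned = spearman_prune(X_norm[mw_kept], mw_table["p"], config.rho_max)
    if not sp_kept:
        raise StageError("spearman", "no feature survived correlation pruning")

    k = min(config.mrmr_k, len(sp_kept))
    mrmr_kept, mrmr_scores = mrmr_rank(X_norm[sp_kept], y_train, k)

    if len(mrmr_kept) < 2:
        raise StageError("mrmr", "LASSO needs >= 2 candidate features after mRMR")
    lasso = lasso_select(
        X_norm[mrmr_kept], y_train, folds=config.lasso_folds, seed=config.seed
    )
    if not lasso.selected:
        raise StageError("lasso", "LASSO shrank every coefficient to zero")

    return ScreeningReport(
        input_features=list(X_train.columns),
        normalized_features=feats,
        dropped_constant=mm.dropped_constant,
        icc_values=icc_vals,
        icc_retained=icc_kept,
        mw_table=mw_table,
        mw_retained=mw_kept,
        spearman_pruned=sp_pruned,
        spearman_retained=sp_kept,
        mrmr_scores=mrmr_scores,
        mrmr_retained=mrmr_kept,
        lasso=lasso,
        final_features=lasso.selected,
    )
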