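"""Discrimination, calibration, clinical-utility and interpretability metrics.

ROC/AUC uses the Mann-Whitney identity with half-credit for ties; the
confidence interval and paired curve comparisons use DeLong's structural
components. Calibration is assessed with the Hosmer-Lemeshow test on
equal-count risk deciles and a bootstrap bias-corrected calibration curve.
Clinical utility follows decision-curve analysis: net benefit
``TP/n − FP/n · p_t/(1 − p_t)`` against treat-all and treat-none.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from .shap_kernel import kernel_shap

__all__ = [
    "RocResult",
    "DecisionCurve",
    "CalibrationReport",
    "ShapReport",
    "roc_auc",
    "delong_compare",
    "youden_cutoff",
    "confusion_metrics",
    "hosmer_lemeshow",
    "calibration_curve",
    "decision_curve",
    "net_benefit",
    "kernel_shap_explain",
]


# ---------------------------------------------------------------------------
# ROC / AUC / DeLong
# ---------------------------------------------------------------------------


@dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray

    @property
    def ci(self) -> tuple[float, float]:
        return (self.ci_low, self.ci_high)


def _check_binary(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y).astype(int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if np.unique(y).size != 2:
        raise ValueError("both classes must be present")
    return y


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(y: np.ndarray, scores: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and DeLong structural components V10 (positives), V01 (negatives)."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = pos.size, neg.size
    all_ranks = _midrank(np.concatenate([pos, neg]))
    pos_ranks = _midrank(pos)
    neg_ranks = _midrank(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    return float(auc), v10, v01


def roc_auc(y, scores, alpha: float = 0.05) -> RocResult:
    """AUC with a DeLong 95% CI and the ROC curve points.

    The AUC is the tie-aware pairwise concordance probability (concordant
    pairs count 1, ties count ½).
    """
    y = _check_binary(y)
    scores = np.asarray(scores, dtype=float)
    auc, v10, v01 = _delong_components(y, scores)
    var = 0.0
    if v10.size > 1:
        var += np.var(v10, ddof=1) / v10.size
    if v01.size > 1:
        var += np.var(v01, ddof=1) / v01.size
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(max(var, 0.0))
    fpr, tpr, thr = _sk_roc_curve(y, scores)
    return RocResult(
        auc=auc,
        ci_low=float(np.clip(auc - half, 0.0, 1.0)),
        ci_high=float(np.clip(auc + half, 0.0, 1.0)),
        fpr=fpr,
        tpr=tpr,
        thresholds=thr,
    )


def delong_compare(y, scores_a, scores_b) -> tuple[float, float, float]:
    """Paired DeLong test for two correlated ROC curves on the same subjects.

    Returns ``(delta_auc, z, p_two_sided)``; identical (or rank-identical)
    score vectors give delta 0 and p = 1.
    """
    y = _check_binary(y)
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    if sa.shape != sb.shape or sa.shape[0] != y.shape[0]:
        raise ValueError("score vectors must align with y")
    auc_a, v10a, v01a = _delong_components(y, sa)
    auc_b, v10b, v01b = _delong_components(y, sb)
    delta = auc_a - auc_b
    m, n = v10a.size, v01a.size
    var = 0.0
    if m > 1:
        s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
        var += (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
    if n > 1:
        s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
        var += (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    if var <= 1e-16:
        return float(delta), 0.0, 1.0 if abs(delta) < 1e-12 else 0.0
    z = delta / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(delta), float(z), float(min(p, 1.0))


# ---------------------------------------------------------------------------
# cutoffs and confusion metrics
# ---------------------------------------------------------------------------


def youden_cutoff(y, probabilities) -> float:
    """Probability cutoff maximising the Youden index J = sens + spec − 1.

    Candidates are midpoints between consecutive sorted unique
    probabilities, plus one candidate below the minimum and one above the
    maximum (predict-all / predict-none); ties resolve to the smallest
    cutoff. Classification rule is probability ≥ cutoff.
    """
    y = _check_binary(y)
    p = np.asarray(probabilities, dtype=float)
    uniq = np.unique(p)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    below = uniq[0] / 2.0 if uniq[0] > 0 else uniq[0] - 1.0
    above = (uniq[-1] + 1.0) / 2.0 if uniq[-1] < 1 else uniq[-1] + 1.0
    candidates = np.concatenate([[below], mids, [above]])
    n_pos = (y == 1).sum()
    n_neg = (y == 0).sum()
    pred = p[None, :] >= candidates[:, None]
    tp = (pred & (y == 1)).sum(axis=1)
    tn = (~pred & (y == 0)).sum(axis=1)
    j = tp / n_pos + tn / n_neg - 1.0
    best = np.flatnonzero(j >= j.max() - 1e-12)[0]  # smallest cutoff on ties
    return float(candidates[best])


def confusion_metrics(y, labels) -> dict[str, float]:
    """Accuracy, sensitivity, specificity; undefined ratios are NaN."""
    y = np.asarray(y).astype(int)
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels)) - {0, 1} or set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    tp = int(np.sum((labels == 1) & (y == 1)))
    tn = int(np.sum((labels == 0) & (y == 0)))
    fp = int(np.sum((labels == 1) & (y == 0)))
    fn = int(np.sum((labels == 0) & (y == 1)))
    total = tp + tn + fp + fn
    return {
        "accuracy": (tp + tn) / total if total else float("nan"),
        "sensitivity": tp / (tp + fn) if (tp + fn) else float("nan"),
        "specificity": tn / (tn + fp) if (tn + fp) else float("nan"),
        "tp": tp,
        "tn": tn,
        "fp": fp,
        "fn": fn,
    }


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------


def hosmer_lemeshow(y, probabilities, g: int = 10) -> tuple[float, int, float]:
    """Hosmer-Lemeshow goodness-of-fit χ² on equal-count risk deciles.

    Subjects are grouped into ``g`` equal-count bins of predicted risk
    (ties kept in one bin); ``χ² = Σ (O − E)² / (E (1 − E/n_b))``; p from a
    χ² distribution with ``g_effective − 2`` degrees of freedom. Bins with
    a degenerate expected count are merged into their neighbour with a
    warning and the degrees of freedom adjusted.
    """
    y = _check_binary(y)
    p = np.asarray(probabilities, dtype=float)
    n = y.size
    if n < g:
        raise ValueError(f"need at least g={g} subjects")
    # equal-count bins with ties kept together: bin by average rank
    ranks = stats.rankdata(p, method="average") - 0.5
    bins = np.minimum((ranks * g / n).astype(int), g - 1)
    obs, exp, cnt = [], [], []
    for b in range(g):
        sel = bins == b
        if not sel.any():
            continue
        obs.append(y[sel].sum())
        exp.append(p[sel].sum())
        cnt.append(sel.sum())
    obs, exp, cnt = np.array(obs, float), np.array(exp, float), np.array(cnt, float)

    # merge bins whose expected events (or non-events) vanish
    def _degenerate(e, c):
        return (e <= 1e-10) | (c - e <= 1e-10)

    while obs.size > 2 and _degenerate(exp, cnt).any():
        i = int(np.flatnonzero(_degenerate(exp, cnt))[0])
        j = i - 1 if i > 0 else i + 1
        warnings.warn("merging a degenerate Hosmer-Lemeshow bin", stacklevel=2)
        obs[j] += obs[i]
        exp[j] += exp[i]
        cnt[j] += cnt[i]
        obs, exp, cnt = np.delete(obs, i), np.delete(exp, i), np.delete(cnt, i)

    denom = exp * (1.0 - exp / cnt)
    denom = np.where(denom <= 1e-12, np.nan, denom)
    chi2 = float(np.nansum((obs - exp) ** 2 / denom))
    df = max(int(obs.size) - 2, 1)
    pval = float(stats.chi2.sf(chi2, df))
    return chi2, df, pval


@dataclass
class CalibrationReport:
    bin_table: pd.DataFrame  # predicted mean, observed rate, n per bin
    hl_chi2: float
    hl_df: int
    hl_p: float
    grid: np.ndarray
    apparent: np.ndarray
    bias_corrected: np.ndarray


def _calibration_smoother(p: np.ndarray, y: np.ndarray):
    """Logistic recalibration: fit y ~ intercept + slope · logit(p)."""
    logit = np.log(np.clip(p, 1e-10, 1 - 1e-10) / np.clip(1 - p, 1e-10, 1))
    from sklearn.linear_model import LogisticRegression

    lr = LogisticRegression(C=1e6, solver="lbfgs", max_iter=1000)
    lr.fit(logit[:, None], y)

    def predict(grid: np.ndarray) -> np.ndarray:
        lg = np.log(np.clip(grid, 1e-10, 1 - 1e-10) / np.clip(1 - grid, 1e-10, 1))
        return lr.predict_proba(lg[:, None])[:, 1]

    return predict


def calibration_curve(
    y, probabilities, bins: int = 10, n_boot: int = 200, seed: int = 0
) -> CalibrationReport:
    """Binned observed-vs-predicted calibration with bootstrap bias correction.

    The apparent curve is a logistic recalibration smoother evaluated on a
    probability grid; the bias-corrected curve is the bootstrap
    bias-corrected estimate ``2·S(grid) − mean_b S_b(grid)`` over ``n_boot``
    resamples (``n_boot=0`` returns the apparent curve unchanged).
    """
    y = _check_binary(y)
    p = np.asarray(probabilities, dtype=float)
    edges = np.quantile(p, np.linspace(0, 1, bins + 1))
    idx = np.clip(np.searchsorted(edges[1:-1], p, side="right"), 0, bins - 1)
    rows = []
    for b in range(bins):
        sel = idx == b
        if sel.any():
            rows.append((p[sel].mean(), y[sel].mean(), int(sel.sum())))
    table = pd.DataFrame(rows, columns=["predicted_mean", "observed_rate", "n"])

    grid = np.linspace(max(p.min(), 1e-4), min(p.max(), 1 - 1e-4), 50)
    smoother = _calibration_smoother(p, y)
    apparent = smoother(grid)
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        acc = np.zeros_like(grid)
        done = 0
        for _ in range(n_boot):
            sel = rng.integers(0, y.size, y.size)
            if np.unique(y[sel]).size < 2:
                continue
            acc += _calibration_smoother(p[sel], y[sel])(grid)
            done += 1
        corrected = 2.0 * apparent - acc / max(done, 1)
        corrected = np.clip(corrected, 0.0, 1.0)
    else:
        corrected = apparent.copy()
    chi2, df, pval = hosmer_lemeshow(y, p, g=min(bins, max(3, y.size // 5)))
    return CalibrationReport(
        bin_table=table,
        hl_chi2=chi2,
        hl_df=df,
        hl_p=pval,
        grid=grid,
        apparent=apparent,
        bias_corrected=corrected,
    )


# ---------------------------------------------------------------------------
# decision curves
# ---------------------------------------------------------------------------


@dataclass
class DecisionCurve:
    table: pd.DataFrame  # threshold, nb_model, nb_all, nb_none

    def net_benefit_at(self, threshold: float) -> float:
        i = int(np.argmin(np.abs(self.table["threshold"].to_numpy() - threshold)))
        return float(self.table["nb_model"].iloc[i])

    def nnt_at(self, threshold: float) -> float:
        """Number needed to treat = 1 / net benefit (NaN when NB ≤ 0)."""
        nb = self.net_benefit_at(threshold)
        return 1.0 / nb if nb > 0 else float("nan")


def net_benefit(tp: float, fp: float, n: int, threshold: float) -> float:
    """NB = TP/n − FP/n · p_t/(1 − p_t) at risk threshold p_t."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    return tp / n - fp / n * threshold / (1.0 - threshold)


def decision_curve(y, probabilities, thresholds: np.ndarray | None = None) -> DecisionCurve:
    """Decision-curve analysis against treat-all and treat-none.

    High-risk rule is probability ≥ p_t. Treat-all has
    ``NB = π − (1 − π) p_t/(1 − p_t)`` at prevalence π; treat-none is 0.
    """
    y = _check_binary(y)
    p = np.asarray(probabilities, dtype=float)
    if thresholds is None:
        thresholds = np.arange(0.01, 1.0, 0.01)
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(thresholds >= 1) or np.any(thresholds <= 0):
        raise ValueError("thresholds must lie strictly inside (0, 1)")
    n = y.size
    prev = y.mean()
    rows = []
    for t in thresholds:
        pred = p >= t
        tp = float(np.sum(pred & (y == 1)))
        fp = float(np.sum(pred & (y == 0)))
        nb = net_benefit(tp, fp, n, t)
        nb_all = prev - (1 - prev) * t / (1 - t)
        rows.append((t, nb, nb_all, 0.0))
    return DecisionCurve(table=pd.DataFrame(rows, columns=["threshold", "nb_model", "nb_all", "nb_none"]))


# ---------------------------------------------------------------------------
# SHAP
# ---------------------------------------------------------------------------


@dataclass
class ShapReport:
    values: pd.DataFrame  # subjects × features
    base_value: float
    model_output: np.ndarray
    ranking: pd.Series  # mean |SHAP| per feature, descending


def kernel_shap_explain(model, X_background: pd.DataFrame, X_explain: pd.DataFrame) -> ShapReport:
    """Kernel SHAP attribution of the model's decision function.

    ``model`` may expose ``decision_function`` (used preferentially) or
    ``predict_risk``; the background table defines the reference
    distribution and the per-subject attributions satisfy
    ``base + Σ_f shap_f(x) = f(x)`` (efficiency).
    """
    if len(X_background) == 0:
        raise ValueError("background table is empty")
    if hasattr(model, "decision_function"):
        f = lambda A: np.asarray(model.decision_function(A))
    elif hasattr(model, "predict_risk"):
        f = lambda A: np.asarray(model.predict_risk(A))
    elif callable(model):
        f = lambda A: np.asarray(model(A))
    else:
        raise TypeError("model must expose decision_function/predict_risk or be callable")
    cols = list(X_explain.columns)
    if list(X_background.columns) != cols:
        raise ValueError("background and explain tables must share feature columns")
    phi, base = kernel_shap(f, X_background.to_numpy(float), X_explain.to_numpy(float))
    values = pd.DataFrame(phi, index=X_explain.index, columns=cols)
    ranking = values.abs().mean(axis=0).sort_values(ascending=False)
    return ShapReport(
        values=values,
        base_value=base,
        model_output=f(X_explain.to_numpy(float)),
        ranking=ranking,
    )
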