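"""RBF-SVM oligometastasis risk model with DMS-PSO-tuned hyperparameters.

The modelling surface follows the statsmodels convention:
:class:`OligoRiskModel` holds the data and exogenous design,
``OligoRiskModel.fit()`` tunes (C, γ) — by DMS-PSO over (log2 C, log2 γ)
against the cross-validated 1−AUC fitness by default — retrains the final
SVM, fits a Platt probability calibrator on out-of-fold decision scores and
derives a Youden-index decision cutoff; the returned
:class:`OligoRiskResults` carries the estimates, the optimizer trace and
the evaluation/interpretation methods.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize as sp_optimize
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from . import metrics
from .pso import OptimizeResult, PsoConfig, optimize

__all__ = [
    "SvmHyperparams",
    "FittedModel",
    "OligoRiskModel",
    "OligoRiskResults",
    "DEFAULT_BOUNDS",
    "cv_fitness",
    "tune",
    "fit_final",
    "predict_risk",
    "classify",
    "stratified_split",
]

#: Default DMS-PSO search box in (log2 C, log2 gamma).
DEFAULT_BOUNDS = ((-5.0, 15.0), (-15.0, 3.0))


@dataclass(frozen=True)
class SvmHyperparams:
    C: float
    gamma: float

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be positive")

    @classmethod
    def from_log2(cls, position: np.ndarray) -> "SvmHyperparams":
        return cls(C=float(2.0 ** position[0]), gamma=float(2.0 ** position[1]))

    def to_log2(self) -> np.ndarray:
        return np.array([np.log2(self.C), np.log2(self.gamma)])


def _as_matrix(X, feature_names: list[str] | None = None) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        if feature_names is not None:
            missing = [f for f in feature_names if f not in X.columns]
            extra = [f for f in X.columns if f not in feature_names]
            if missing or extra:
                raise ValueError(
                    f"feature mismatch: missing={missing}, unexpected={extra}"
                )
            X = X[feature_names]
        return X.to_numpy(dtype=float)
    return np.asarray(X, dtype=float)


def cv_fitness(
    hyperparams: SvmHyperparams | tuple[float, float],
    X,
    y,
    folds: int = 5,
    seed: int = 0,
) -> float:
    """1 − mean out-of-fold AUC of an RBF-SVM at the given (C, γ).

    Folds are stratified and seeded; AUC is computed on raw decision
    scores (rank-equivalent to calibrated probabilities and cheaper).
    """
    if not isinstance(hyperparams, SvmHyperparams):
        hyperparams = SvmHyperparams(*hyperparams)
    Xv = _as_matrix(X)
    y = np.asarray(y).astype(int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < folds:
        raise ValueError(
            f"minority class has {counts.min()} subjects, fewer than {folds} folds; "
            "use a larger sample or fewer folds"
        )
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    aucs = []
    for tr, te in cv.split(Xv, y):
        svc = SVC(C=hyperparams.C, gamma=hyperparams.gamma, kernel="rbf")
        svc.fit(Xv[tr], y[tr])
        scores = svc.decision_function(Xv[te])
        aucs.append(metrics.roc_auc(y[te], scores).auc)
    return 1.0 - float(np.mean(aucs))


def tune(
    X,
    y,
    pso_config: PsoConfig | None = None,
    bounds=DEFAULT_BOUNDS,
    folds: int = 5,
    seed: int = 0,
) -> tuple[SvmHyperparams, OptimizeResult]:
    """DMS-PSO search for (C, γ) minimising the cross-validated 1−AUC."""
    if pso_config is None:
        pso_config = PsoConfig(bounds=bounds, seed=seed)
    Xv = _as_matrix(X)
    y = np.asarray(y).astype(int)

    def fitness(position: np.ndarray) -> float:
        return cv_fitness(SvmHyperparams.from_log2(position), Xv, y, folds=folds, seed=seed)

    result = optimize(fitness, pso_config)
    return SvmHyperparams.from_log2(result.position), result


def _platt_fit(scores: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Platt sigmoid p = 1/(1+exp(A·s + B)) by regularised ML.

    Uses Platt's prior-corrected targets t+ = (N+ + 1)/(N+ + 2),
    t− = 1/(N− + 2) to avoid degenerate fits on separable data.
    """
    y = np.asarray(y).astype(int)
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    t = np.where(y == 1, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))

    def nll(ab):
        a, b = ab
        z = a * scores + b
        # log(1+exp(z)) stable
        log1pexp = np.where(z > 30, z, np.log1p(np.exp(np.clip(z, -30, 30))))
        return np.sum(t * log1pexp + (1 - t) * (log1pexp - z))

    res = sp_optimize.minimize(nll, x0=np.array([-1.0, 0.0]), method="Nelder-Mead")
    a, b = res.x
    # decision scores are oriented towards class 1, so A must be negative
    # for p to increase with the score; fall back on a degenerate fit
    if a >= 0:
        a = -1.0
    return float(a), float(b)


def _platt_apply(scores: np.ndarray, a: float, b: float) -> np.ndarray:
    z = np.clip(a * scores + b, -500, 500)
    return 1.0 / (1.0 + np.exp(z))


@dataclass
class FittedModel:
    """Trained RBF-SVM with Platt calibration and a decision cutoff."""

    hyperparams: SvmHyperparams
    feature_names: list[str] | None
    platt_a: float
    platt_b: float
    cutoff: float = 0.47
    _svc: SVC | None = field(default=None, repr=False)
    # flat state for JSON round-trips (decision function without sklearn obj)
    support_vectors: np.ndarray | None = field(default=None, repr=False)
    dual_coef: np.ndarray | None = field(default=None, repr=False)
    intercept: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.cutoff < 1:
            raise ValueError("cutoff must lie in (0, 1)")

    def decision_function(self, X) -> np.ndarray:
        Xv = _as_matrix(X, self.feature_names)
        if self._svc is not None:
            return self._svc.decision_function(Xv)
        d2 = (
            (Xv**2).sum(axis=1)[:, None]
            + (self.support_vectors**2).sum(axis=1)[None, :]
            - 2.0 * Xv @ self.support_vectors.T
        )
        k = np.exp(-self.hyperparams.gamma * d2)
        return k @ self.dual_coef + self.intercept

    def predict_risk(self, X) -> np.ndarray:
        return _platt_apply(self.decision_function(X), self.platt_a, self.platt_b)

    def classify(self, X) -> np.ndarray:
        return (self.predict_risk(X) >= self.cutoff).astype(int)

    def to_json(self) -> str:
        return json.dumps(
            {
                "C": self.hyperparams.C,
                "gamma": self.hyperparams.gamma,
                "feature_names": self.feature_names,
                "platt_a": self.platt_a,
                "platt_b": self.platt_b,
                "cutoff": self.cutoff,
                "support_vectors": self.support_vectors.tolist(),
                "dual_coef": self.dual_coef.tolist(),
                "intercept": self.intercept,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "FittedModel":
        d = json.loads(text)
        return cls(
            hyperparams=SvmHyperparams(C=d["C"], gamma=d["gamma"]),
            feature_names=d["feature_names"],
            platt_a=d["platt_a"],
            platt_b=d["platt_b"],
            cutoff=d["cutoff"],
            support_vectors=np.array(d["support_vectors"]),
            dual_coef=np.array(d["dual_coef"]),
            intercept=d["intercept"],
        )


def fit_final(
    X,
    y,
    hyperparams: SvmHyperparams,
    seed: int = 0,
    folds: int = 5,
    cutoff: float | None = None,
) -> FittedModel:
    """Retrain the RBF-SVM on the full training set and calibrate it.

    Platt sigmoid parameters are fitted on out-of-fold decision scores from
    an internal stratified ``folds``-fold CV; the decision cutoff defaults
    to the Youden-index maximiser of the calibrated training probabilities.
    """
    if cutoff is not None and not 0 < cutoff < 1:
        raise ValueError("cutoff must lie in (0, 1)")
    feature_names = list(X.columns) if isinstance(X, pd.DataFrame) else None
    Xv = _as_matrix(X)
    y = np.asarray(y).astype(int)
    if np.unique(y).size != 2:
        raise ValueError("both classes must be present to fit the model")
    svc = SVC(C=hyperparams.C, gamma=hyperparams.gamma, kernel="rbf")
    svc.fit(Xv, y)

    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    oof = np.zeros(y.size)
    for tr, te in cv.split(Xv, y):
        m = SVC(C=hyperparams.C, gamma=hyperparams.gamma, kernel="rbf")
        m.fit(Xv[tr], y[tr])
        oof[te] = m.decision_function(Xv[te])
    a, b = _platt_fit(oof, y)

    model = FittedModel(
        hyperparams=hyperparams,
        feature_names=feature_names,
        platt_a=a,
        platt_b=b,
        cutoff=0.5,
        _svc=svc,
        support_vectors=svc.support_vectors_.copy(),
        dual_coef=svc.dual_coef_.ravel().copy(),
        intercept=float(svc.intercept_[0]),
    )
    if cutoff is None:
        train_probs = model.predict_risk(Xv)
        cutoff = float(np.clip(metrics.youden_cutoff(y, train_probs), 1e-6, 1 - 1e-6))
    model.cutoff = cutoff
    return model


def predict_risk(model: FittedModel, X) -> np.ndarray:
    """Calibrated oligometastasis probabilities in (0, 1)."""
    return model.predict_risk(X)


def classify(model: FittedModel, X) -> np.ndarray:
    """High-risk labels: 1 iff predicted probability ≥ the model cutoff."""
    return model.classify(X)


def stratified_split(
    X: pd.DataFrame,
    y,
    train_fraction: float = 0.8,
    seed: int = 0,
    stratify: bool = True,
):
    """Seeded train/validation split (stratified on the label by default)."""
    from sklearn.model_selection import train_test_split

    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie in (0, 1)")
    y = np.asarray(y).astype(int)
    idx = np.arange(len(X))
    tr, te = train_test_split(
        idx,
        train_size=train_fraction,
        random_state=seed,
        stratify=y if stratify else None,
        shuffle=True,
    )
    return X.iloc[tr], X.iloc[te], y[tr], y[te]


# ---------------------------------------------------------------------------
# statsmodels-style modelling objects
# ---------------------------------------------------------------------------


class OligoRiskModel:
    """Oligometastasis risk model: RBF-SVM on screened pathomics features.

    Parameters
    ----------
    X : DataFrame (subjects × features), typically min-max normalised
    y : binary outcome (1 = oligometastasis)

    ``fit(method=...)`` supports:

    * ``"dms-pso"`` — DMS-PSO hyperparameter search (default);
    * ``"pso"`` — single-swarm local-best PSO (no regrouping);
    * ``"grid"`` — coarse log2 grid search;
    * ``"default"`` — sklearn defaults C=1, γ=1/(d·Var(X)) without tuning.
    """

    def __init__(self, X: pd.DataFrame, y, feature_names: list[str] | None = None):
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
            X.columns = feature_names or [f"x{i}" for i in range(X.shape[1])]
        self.X = X
        self.y = np.asarray(y).astype(int)
        if np.unique(self.y).size != 2:
            raise ValueError("y must contain both classes")
        self.feature_names = list(X.columns)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, label_col: str = "label") -> "OligoRiskModel":
        if label_col not in data.columns:
            raise ValueError(f"label column {label_col!r} not found")
        y = data[label_col].to_numpy()
        X = data.drop(columns=[label_col])
        return cls(X, y)

    def fit(
        self,
        method: str = "dms-pso",
        pso_config: PsoConfig | None = None,
        bounds=DEFAULT_BOUNDS,
        folds: int = 5,
        seed: int = 0,
        hyperparams: SvmHyperparams | None = None,
        grid_size: int = 5,
    ) -> "OligoRiskResults":
        history: OptimizeResult | None = None
        if hyperparams is not None:
            method = "fixed"
        elif method == "dms-pso":
            if pso_config is None:
                pso_config = PsoConfig(bounds=bounds, seed=seed)
            hyperparams, history = tune(self.X, self.y, pso_config, bounds, folds, seed)
        elif method == "pso":
            if pso_config is None:
                pso_config = PsoConfig(
                    bounds=bounds, n_subswarms=1, regroup_period=None, seed=seed
                )
            hyperparams, history = tune(self.X, self.y, pso_config, bounds, folds, seed)
        elif method == "grid":
            best, best_fit = None, np.inf
            for lc in np.linspace(bounds[0][0], bounds[0][1], grid_size):
                for lg in np.linspace(bounds[1][0], bounds[1][1], grid_size):
                    hp = SvmHyperparams(2.0**lc, 2.0**lg)
                    f = cv_fitness(hp, self.X, self.y, folds=folds, seed=seed)
                    if f < best_fit:
                        best, best_fit = hp, f
            hyperparams = best
        elif method == "default":
            gamma = 1.0 / (self.X.shape[1] * self.X.to_numpy(float).var())
            hyperparams = SvmHyperparams(C=1.0, gamma=gamma)
        else:
            raise ValueError(f"unknown method {method!r}")
        fitted = fit_final(self.X, self.y, hyperparams, seed=seed, folds=folds)
        return OligoRiskResults(model=self, fitted=fitted, method=method, history=history, seed=seed)


class OligoRiskResults:
    """Fit results: tuned hyperparameters, calibration, cutoff, diagnostics."""

    def __init__(
        self,
        model: OligoRiskModel,
        fitted: FittedModel,
        method: str,
        history: OptimizeResult | None,
        seed: int,
    ):
        self.model = model
        self.fitted = fitted
        self.method = method
        self.history = history
        self.seed = seed

    @property
    def hyperparams(self) -> SvmHyperparams:
        return self.fitted.hyperparams

    @property
    def cutoff(self) -> float:
        return self.fitted.cutoff

    def predict_risk(self, X=None) -> np.ndarray:
        return self.fitted.predict_risk(self.model.X if X is None else X)

    def classify(self, X=None) -> np.ndarray:
        return self.fitted.classify(self.model.X if X is None else X)

    def evaluate(self, X=None, y=None, n_boot: int = 200) -> dict:
        """Full evaluation stack on (X, y); defaults to the training data."""
        if X is None:
            X, y = self.model.X, self.model.y
        y = np.asarray(y).astype(int)
        probs = self.fitted.predict_risk(X)
        roc = metrics.roc_auc(y, probs)
        conf = metrics.confusion_metrics(y, (probs >= self.cutoff).astype(int))
        hl = metrics.hosmer_lemeshow(y, probs) if y.size >= 10 else (np.nan, 0, np.nan)
        dca = metrics.decision_curve(y, probs)
        cal = metrics.calibration_curve(y, probs, n_boot=n_boot, seed=self.seed)
        return {
            "roc": roc,
            "confusion": conf,
            "hosmer_lemeshow": {"chi2": hl[0], "df": hl[1], "p": hl[2]},
            "decision_curve": dca,
            "calibration": cal,
            "probabilities": probs,
        }

    def shap_values(self, X_explain, X_background=None):
        bg = self.model.X if X_background is None else X_background
        return metrics.kernel_shap_explain(self.fitted, bg, X_explain)

    def summary(self) -> str:
        ev = self.evaluate(n_boot=0)
        roc, conf = ev["roc"], ev["confusion"]
        lines = [
            "        Oligometastasis risk model (RBF-SVM)",
            "=" * 56,
            f"Tuning method:        {self.method}",
            f"No. subjects:         {self.model.y.size}",
            f"No. features:         {len(self.model.feature_names)}",
            f"Event prevalence:     {self.model.y.mean():.3f}",
            "-" * 56,
            f"C (penalty):          {self.hyperparams.C:.6g}",
            f"gamma (RBF width):    {self.hyperparams.gamma:.6g}",
            f"Decision cutoff:      {self.cutoff:.3f} (Youden)",
            f"Platt A, B:           {self.fitted.platt_a:.4f}, {self.fitted.platt_b:.4f}",
            "-" * 56,
            f"Training AUC:         {roc.auc:.3f} (95% CI {roc.ci_low:.3f}-{roc.ci_high:.3f})",
            f"Accuracy at cutoff:   {conf['accuracy']:.3f}",
            f"Sensitivity:          {conf['sensitivity']:.3f}",
            f"Specificity:          {conf['specificity']:.3f}",
        ]
        if self.history is not None:
            lines.append(f"Optimizer iterations: {self.history.n_iter}")
            lines.append(f"Best CV fitness:      {self.history.fitness:.4f} (1-AUC)")
        lines.append("=" * 56)
        return "\n".join(lines)
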