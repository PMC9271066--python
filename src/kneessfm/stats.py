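"""Demographic statistics on SSFM mode scores.

Two analyses mirror common morphometric practice: (1) per-mode multiple
linear regression of scores on sex, height, body mass and age with
standardized coefficients (betas), and (2) a forward-stepwise multivariable
logistic regression classifying sex from mode scores, evaluated by
stratified ten-fold cross-validation with an exact (Clopper-Pearson)
binomial confidence interval on the pooled accuracy and the pooled AUC.

Sex is coded female = 0, male = 1 throughout.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from scipy.special import expit, logit
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

__all__ = [
    "PREDICTORS",
    "RegressionResult",
    "ClassifierResult",
    "StandardizedLinearModel",
    "StepwiseSexClassifier",
    "standardized_mlr",
    "regression_table",
    "forward_stepwise_logistic",
    "stratified_cv",
    "binomial_ci_exact",
    "decision_geometry",
]

PREDICTORS = ["sex", "height", "mass", "age"]


def _zscore(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant predictor or response cannot be standardized")
    return (x - x.mean()) / sd


@dataclass
class RegressionResult:
    """Standardized betas, two-sided p-values and R^2 for one mode's scores."""

    betas: pd.Series
    pvalues: pd.Series
    r_squared: float

    def significance(self, predictor: str) -> str:
        """Stars at the 95% (*) and 99% (**) levels."""
        p = self.pvalues[predictor]
        return "**" if p < 0.01 else ("*" if p < 0.05 else "")


class StandardizedLinearModel(BaseEstimator):
    """OLS of a z-scored response on z-scored predictors (standardized betas).

    ``fit(X, y)`` takes an n x p predictor array (or DataFrame with named
    columns) and an n-vector response; both are z-scored internally so the
    coefficients are directly comparable across predictors.
    """

    def __init__(self, max_condition: float = 1e8):
        self.max_condition = max_condition

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            names = [f"x{j}" for j in range(X.shape[1])]
        y = np.asarray(y, dtype=float)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y disagree on sample count")
        if X.shape[0] < X.shape[1] + 2:
            raise ValueError("need more subjects than parameters")
        Xz = np.column_stack([_zscore(X[:, j]) for j in range(X.shape[1])])
        if np.linalg.cond(Xz) > self.max_condition:
            raise ValueError("predictors are collinear (condition number too large)")
        yz = _zscore(y)
        ols = sm.OLS(yz, sm.add_constant(Xz)).fit()
        self.feature_names_in_ = names
        self.coef_ = ols.params[1:]
        self.pvalues_ = ols.pvalues[1:]
        self.r_squared_ = float(ols.rsquared)
        self.result_ = RegressionResult(
            pd.Series(self.coef_, index=names),
            pd.Series(self.pvalues_, index=names),
            self.r_squared_,
        )
        return self


def standardized_mlr(scores: np.ndarray, demographics: pd.DataFrame) -> RegressionResult:
    """Standardized multiple linear regression of one mode's scores.

    `demographics` must carry columns sex (0/1), height (cm), mass (kg),
    age (years); all five variables are z-scored before the OLS fit.
    """
    X = demographics[PREDICTORS]
    return StandardizedLinearModel().fit(X, np.asarray(scores, float)).result_


def regression_table(scores: np.ndarray, demographics: pd.DataFrame) -> pd.DataFrame:
    """Mode-by-predictor table of standardized betas, p-values and R^2."""
    scores = np.atleast_2d(np.asarray(scores, float))
    rows = {}
    for k in range(scores.shape[1]):
        res = standardized_mlr(scores[:, k], demographics)
        col = {p: res.betas[p] for p in PREDICTORS}
        col.update({f"p_{p}": res.pvalues[p] for p in PREDICTORS})
        col["R2"] = res.r_squared
        rows[f"mode{k + 1}"] = col
    return pd.DataFrame(rows)


# -- logistic sex classifier -------------------------------------------------


def _fit_logit(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, float, bool]:
    """MLE logistic fit; penalised (L2) fallback when separation breaks MLE.

    Returns (coefficients, intercept, log-likelihood, penalized_flag).
    """
    design = sm.add_constant(np.atleast_2d(X), has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
        params = np.asarray(fit.params)
        if np.all(np.isfinite(params)) and np.abs(params).max() < 1e6:
            return params[1:], float(params[0]), float(fit.llf), False
    except Exception:  # separation / singular hessian
        pass
    logger.warning("logistic MLE failed (likely perfect separation); using L2 penalty")
    clf = LogisticRegression(C=1.0, max_iter=1000)
    clf.fit(np.atleast_2d(X), y)
    prob = np.clip(clf.predict_proba(np.atleast_2d(X))[:, 1], 1e-12, 1 - 1e-12)
    llf = float(np.sum(y * np.log(prob) + (1 - y) * np.log(1 - prob)))
    return clf.coef_[0], float(clf.intercept_[0]), llf, True


def _null_llf(y: np.ndarray) -> float:
    p = y.mean()
    if p in (0.0, 1.0):
        return 0.0
    n1 = y.sum()
    n0 = len(y) - n1
    return float(n1 * np.log(p) + n0 * np.log(1 - p))


class StepwiseSexClassifier(BaseEstimator, ClassifierMixin):
    """Forward-stepwise logistic regression over mode scores.

    Greedy selection: at each step the candidate mode giving the smallest
    likelihood-ratio-test p-value against the current model is added,
    stopping when the best candidate's p >= ``alpha``. The final model is
    refit on all data over the selected modes.

    Fitted attributes: ``selected_`` (0-based column indices in selection
    order), ``coef_``, ``intercept_``, ``penalized_``.
    """

    def __init__(self, alpha: float = 0.05, candidates: list[int] | None = None):
        self.alpha = alpha
        self.candidates = candidates

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if set(np.unique(y)) - {0.0, 1.0}:
            raise ValueError("sex labels must be coded 0/1")
        if len(np.unique(y)) < 2:
            raise ValueError("both classes must be present")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        pool = list(self.candidates) if self.candidates is not None else list(
            range(X.shape[1])
        )
        selected: list[int] = []
        current_llf = _null_llf(y)
        while pool:
            best: tuple[float, int, float] | None = None
            for j in pool:
                cols = selected + [j]
                _, _, llf, _ = _fit_logit(X[:, cols], y)
                lr = max(0.0, 2.0 * (llf - current_llf))
                p = float(sps.chi2.sf(lr, df=1))
                if best is None or p < best[0]:
                    best = (p, j, llf)
            if best is None or best[0] >= self.alpha:
                break
            selected.append(best[1])
            pool.remove(best[1])
            current_llf = best[2]
        self.selected_ = selected
        if selected:
            coef, intercept, llf, pen = _fit_logit(X[:, selected], y)
        else:
            coef, intercept, llf, pen = (
                np.zeros(0),
                float(logit(np.clip(y.mean(), 1e-12, 1 - 1e-12))),
                _null_llf(y),
                False,
            )
        self.coef_ = np.asarray(coef, float)
        self.intercept_ = float(intercept)
        self.llf_ = float(llf)
        self.penalized_ = bool(pen)
        self.classes_ = np.array([0.0, 1.0])
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if not self.selected_:
            return np.full(X.shape[0], self.intercept_)
        return X[:, self.selected_] @ self.coef_ + self.intercept_

    def predict_proba(self, X) -> np.ndarray:
        p = expit(self.decision_function(X))
        return np.column_stack([1 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) > 0).astype(float)


def forward_stepwise_logistic(
    scores: np.ndarray, sex: np.ndarray, alpha: float = 0.05
) -> tuple[list[int], StepwiseSexClassifier]:
    """Selected mode indices (0-based) and the refit stepwise classifier."""
    clf = StepwiseSexClassifier(alpha=alpha).fit(scores, sex)
    return clf.selected_, clf


def stratified_cv(
    scores: np.ndarray,
    sex: np.ndarray,
    folds: int = 10,
    seed: int = 0,
) -> dict:
    """Stratified k-fold CV of a logistic model on the given score columns.

    The model is refit per fold; held-out predictions are pooled over all
    subjects, giving one accuracy (correct / n), one AUC from the pooled
    predicted probabilities, and per-fold assignments.
    """
    X = np.atleast_2d(np.asarray(scores, dtype=float))
    y = np.asarray(sex, dtype=float).ravel()
    counts = np.bincount(y.astype(int), minlength=2)
    if counts.min() < folds:
        raise ValueError(
            f"smallest class ({counts.min()}) is below the fold count ({folds})"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    prob = np.zeros(len(y))
    fold_of = np.zeros(len(y), dtype=int)
    for f, (train, test) in enumerate(skf.split(X, y)):
        coef, intercept, _, _ = _fit_logit(X[train], y[train])
        prob[test] = expit(X[test] @ coef + intercept)
        fold_of[test] = f
    pred = (prob > 0.5).astype(float)
    correct = int(np.sum(pred == y))
    accuracy = correct / len(y)
    auc = float(roc_auc_score(y, prob))
    lower, upper = binomial_ci_exact(correct, len(y))
    detail = pd.DataFrame(
        {"fold": fold_of, "sex": y, "probability": prob, "predicted": pred}
    )
    return {
        "accuracy": accuracy,
        "correct": correct,
        "n": len(y),
        "ci95": (lower, upper),
        "auc": auc,
        "folds": detail,
    }


def binomial_ci_exact(
    successes: int, n: int, level: float = 0.95
) -> tuple[float, float]:
    """Clopper-Pearson exact binomial confidence interval (proportions in [0,1])."""
    if not 0 <= successes <= n:
        raise ValueError("successes must be between 0 and n")
    alpha = 1.0 - level
    lower = 0.0 if successes == 0 else float(
        sps.beta.ppf(alpha / 2, successes, n - successes + 1)
    )
    upper = 1.0 if successes == n else float(
        sps.beta.ppf(1 - alpha / 2, successes + 1, n - successes)
    )
    return lower, upper


def decision_geometry(
    classifier: StepwiseSexClassifier, scores: np.ndarray, sex: np.ndarray
) -> dict:
    """Decision-boundary hyperplane and male-female axis in mode-score space.

    The boundary is the locus of predicted probability 0.5: unit normal along
    the coefficient vector with signed offset -intercept/||coef||. The axis
    is the mean male score vector minus the mean female score vector over the
    selected modes.
    """
    coef = np.asarray(classifier.coef_, float)
    if coef.size == 0 or np.allclose(coef, 0):
        raise ValueError("classifier has no non-zero coefficients")
    X = np.atleast_2d(np.asarray(scores, float))[:, classifier.selected_]
    y = np.asarray(sex, float).ravel()
    norm = np.linalg.norm(coef)
    return {
        "normal": coef / norm,
        "offset": -classifier.intercept_ / norm,
        "male_female_axis": X[y == 1].mean(axis=0) - X[y == 0].mean(axis=0),
        "modes": list(classifier.selected_),
    }
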