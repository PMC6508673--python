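"""Ghost-forest classification from vegetation-structure metrics.

Ghost forest — standing dead stands left by saltwater exposure — shows up
in vegetation structure as reduced return density in the midstory
(4.5-10 m) and canopy (20-30 m) layers.  This module classifies cells or
points as ghost vs unaffected forest from the seven structure metrics via
logistic regression, selecting predictors with a constrained stepwise AIC
procedure:

1.  fit each metric alone and keep the one with the lowest AIC;
2.  at each later step consider only remaining metrics whose Pearson
    correlation with *every* already-selected metric is below the
    threshold (0.5 by default), and accept the best candidate only if it
    strictly lowers AIC;
3.  stop when no eligible candidate remains or none improves.

The gate handles the strong collinearity among height and density
metrics, which otherwise makes manual variable removal subjective.  The
final model is validated by sensitivity/specificity on a class-stratified
holdout split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import train_test_split

from .rasters import METRIC_NAMES

__all__ = [
    "LogisticFit",
    "StepwiseResult",
    "PerfectSeparationWarning",
    "pearson_correlation",
    "fit_logistic",
    "stepwise_select",
    "split_train_validation",
    "evaluate_sensitivity_specificity",
    "classify_ghost_report",
]


class PerfectSeparationWarning(UserWarning):
    """The labels are perfectly separated; a tiny ridge keeps the fit finite."""


def pearson_correlation(x, y) -> float:
    """Product-moment correlation of two equal-length vectors.

    Raises on length < 3, unequal lengths, or zero variance in either
    argument (degenerate input).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need two equal-length 1-D vectors of length >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(stats.pearsonr(x, y).statistic)


@dataclass
class LogisticFit:
    """A fitted logistic regression (intercept first in ``coef``)."""

    coef: np.ndarray
    feature_names: list[str]
    loglik: float
    aic: float
    converged: bool
    separated: bool = False

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        eta = self.coef[0] + X @ self.coef[1:]
        return 1.0 / (1.0 + np.exp(-eta))


def _irls(X1: np.ndarray, y: np.ndarray, ridge: float,
          max_iter: int = 60, tol: float = 1e-10) -> tuple[np.ndarray, bool]:
    """Newton / iteratively reweighted least squares for logistic MLE."""
    n, p = X1.shape
    beta = np.zeros(p)
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X1 @ beta, -35, 35)
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = mu * (1.0 - mu)
        H = X1.T @ (X1 * W[:, None]) + ridge * np.eye(p)
        g = X1.T @ (y - mu) - ridge * beta
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    return beta, converged


def _bernoulli_loglik(X1: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = X1 @ beta
    # log p = -log(1+e^-eta); log(1-p) = -log(1+e^eta)
    return float(-(np.logaddexp(0.0, -eta) * y
                   + np.logaddexp(0.0, eta) * (1.0 - y)).sum())


def fit_logistic(X, y, feature_names: list[str] | None = None) -> LogisticFit:
    """Maximum-likelihood logistic regression with an intercept.

    ``AIC = 2k - 2 logLik`` with ``k`` the number of coefficients
    including the intercept.  Perfect separation (diverging coefficients)
    is flagged with :class:`PerfectSeparationWarning` and the fit is
    redone with a tiny ridge penalty (1e-6) so parameters stay finite.
    Rank-deficient designs raise.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and len(np.asarray(y)) == X.shape[1]:
        X = X.T
    y = np.asarray(y, dtype=float)
    if not np.isin(y, [0.0, 1.0]).all():
        raise ValueError("labels must be binary")
    X1 = np.column_stack([np.ones(len(y)), X])
    if np.linalg.matrix_rank(X1) < X1.shape[1]:
        raise ValueError("design matrix is rank deficient after adding "
                         "an intercept")
    beta, converged = _irls(X1, y, ridge=0.0)
    separated = (not converged) or np.max(np.abs(beta)) > 30.0
    if separated:
        warnings.warn("perfect or quasi-perfect separation detected; "
                      "refitting with ridge 1e-6",
                      PerfectSeparationWarning, stacklevel=2)
        beta, converged = _irls(X1, y, ridge=1e-6)
    ll = _bernoulli_loglik(X1, y, beta)
    k = X1.shape[1]
    names = list(feature_names) if feature_names is not None else \
        [f"x{i}" for i in range(X.shape[1])]
    return LogisticFit(coef=beta, feature_names=names, loglik=ll,
                       aic=2 * k - 2 * ll, converged=converged,
                       separated=separated)


@dataclass
class StepwiseResult:
    """Outcome of the constrained stepwise selection."""

    selected: list[str]
    steps: pd.DataFrame
    fit: LogisticFit
    corr_threshold: float = 0.5

    @property
    def aic_path(self) -> list[float]:
        """AIC of the accepted model after each accepted step."""
        acc = self.steps[self.steps["accepted"]]
        return list(acc.groupby("step")["aic"].min())


def stepwise_select(table: pd.DataFrame, corr_threshold: float = 0.5,
                    metrics: tuple[str, ...] = METRIC_NAMES,
                    label_column: str = "ghost") -> StepwiseResult:
    """Forward stepwise logistic selection under a collinearity gate.

    See the module docstring for the procedure.  The returned
    ``steps`` table records every candidate model evaluated (step,
    model terms, log-likelihood, AIC, delta-AIC within step, accepted).
    """
    metrics = [m for m in metrics if m in table.columns]
    if len(metrics) < 2:
        raise ValueError("need at least two candidate metrics")
    y = table[label_column].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class; cannot select")
    corr = table[metrics].corr().abs()
    selected: list[str] = []
    current_aic = np.inf
    rows = []
    step = 0
    while True:
        step += 1
        eligible = [m for m in metrics if m not in selected and
                    all(corr.loc[m, s] < corr_threshold for s in selected)]
        if not eligible:
            break
        fits = {}
        for m in eligible:
            cand = selected + [m]
            fits[m] = fit_logistic(table[cand].to_numpy(), y,
                                   feature_names=cand)
        best = min(fits, key=lambda m: fits[m].aic)
        best_aic = fits[best].aic
        improves = best_aic < current_aic
        for m in eligible:
            rows.append({
                "step": step,
                "model": " + ".join(selected + [m]),
                "loglik": fits[m].loglik,
                "aic": fits[m].aic,
                "delta_aic": fits[m].aic - best_aic,
                "accepted": improves and (m == best),
            })
        if not improves:
            break
        selected.append(best)
        current_aic = best_aic
        final_fit = fits[best]
    steps = pd.DataFrame(rows)
    return StepwiseResult(selected=selected, steps=steps, fit=final_fit,
                          corr_threshold=corr_threshold)


def split_train_validation(labels, train_fraction: float = 0.6,
                           seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Class-stratified disjoint split into train / validation index sets."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 members to stratify")
    idx = np.arange(len(labels))
    train, val = train_test_split(idx, train_size=train_fraction,
                                  stratify=labels, random_state=seed)
    return np.sort(train), np.sort(val)


def evaluate_sensitivity_specificity(fit: LogisticFit,
                                     validation: pd.DataFrame,
                                     prob_threshold: float = 0.5,
                                     label_column: str = "ghost",
                                     ) -> tuple[float, float]:
    """Holdout sensitivity and specificity of a fitted classifier.

    Sensitivity = TP / (TP + FN) on the ghost class; specificity =
    TN / (TN + FP).  A class absent from the validation set makes the
    corresponding metric NaN (undefined).  Classification is by predicted
    probability >= ``prob_threshold``.
    """
    y = validation[label_column].to_numpy(dtype=float)
    X = validation[fit.feature_names].to_numpy(dtype=float)
    pred = fit.predict_proba(X) >= prob_threshold
    pos, neg = y == 1, y == 0
    sens = float(pred[pos].mean()) if pos.any() else float("nan")
    spec = float((~pred[neg]).mean()) if neg.any() else float("nan")
    return sens, spec


def classify_ghost_report(table: pd.DataFrame, corr_threshold: float = 0.5,
                          train_fraction: float = 0.6,
                          prob_threshold: float = 0.5,
                          seed: int = 0) -> dict:
    """Run selection + holdout validation and return a JSON-able report.

    Variable selection uses the full table (the selection question is
    which metrics carry the signal); the selected model is then refit on
    the stratified training split and scored on the validation split.
    """
    result = stepwise_select(table, corr_threshold=corr_threshold)
    train, val = split_train_validation(table["ghost"].to_numpy(),
                                        train_fraction=train_fraction,
                                        seed=seed)
    train_tab = table.iloc[train]
    fit = fit_logistic(train_tab[result.selected].to_numpy(),
                       train_tab["ghost"].to_numpy(),
                       feature_names=result.selected)
    sens, spec = evaluate_sensitivity_specificity(
        fit, table.iloc[val], prob_threshold=prob_threshold)
    return {
        "selected_metrics": result.selected,
        "aic_table": result.steps.to_dict(orient="records"),
        "coefficients": dict(zip(["intercept"] + result.selected,
                                 map(float, fit.coef))),
        "sensitivity": sens,
        "specificity": spec,
        "n_train": int(len(train)),
        "n_validation": int(len(val)),
    }
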