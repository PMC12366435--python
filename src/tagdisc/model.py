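"""Ridge-penalized logistic regression and classifier evaluation.

The classifier over normalized tag frequencies is an ordinary logistic
regression. With ~135 features and ~135 speakers the unpenalized MLE is
usually non-identified (perfect separation), so the fit maximizes the
Bernoulli log-likelihood minus a ridge term ``(lam/2) * sum(beta_j^2)``
on the tag coefficients; the intercept is never penalized. Optimization
is damped Newton (IRLS with step-halving), which is deterministic and
monotone in the penalized objective.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .corpus import FeatureMatrix


class ConvergenceWarning(UserWarning):
    """Fit stopped before reaching gradient tolerance."""


@dataclass(frozen=True)
class LogisticModel:
    """Fitted logistic model: ``logit P(y=1|x) = intercept + x @ coef``."""

    intercept: float
    coef: np.ndarray  # (m,) log-odds per unit normalized frequency
    converged: bool
    n_iter: int
    penalty: float
    grad_norm: float = np.nan

    def __post_init__(self) -> None:
        object.__setattr__(self, "coef", np.asarray(self.coef, dtype=np.float64))


def penalized_loglik(
    beta0: float, beta: np.ndarray, x: np.ndarray, y: np.ndarray, penalty: float
) -> float:
    """Bernoulli log-likelihood minus ``(penalty/2)*||beta||^2`` (intercept free)."""
    eta = beta0 + x @ beta
    # log(1+e^eta) computed stably for large |eta|
    ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
    return ll - 0.5 * penalty * float(beta @ beta)


def fit_logistic(
    features: FeatureMatrix,
    penalty: float = 1.0,
    *,
    standardize: bool = False,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> LogisticModel:
    """Fit by damped Newton iteration on the penalized log-likelihood.

    Parameters
    ----------
    features
        Normalized frequency matrix with binary labels; both classes must
        be present.
    penalty
        Ridge weight ``lam >= 0`` on the tag coefficients. ``lam = 0`` is
        allowed but typically non-convergent when classes are separable;
        a warning then suggests setting ``lam > 0``.
    standardize
        If True, columns are z-scored before fitting (so the ridge acts on
        unit-variance features — the usual choice when the model is used as
        a classifier) and the coefficients are mapped back to the raw
        frequency scale afterwards. Default False: per-word frequencies
        enter unscaled and coefficients stay directly on that scale.
    tol
        Convergence when the gradient sup-norm falls below ``tol``.
    """
    x, y = features.x, features.y.astype(np.float64)
    n, m = x.shape
    if n < 2 or len(np.unique(y)) < 2:
        raise ValueError("need at least two speakers with both classes present")
    if penalty < 0:
        raise ValueError(f"penalty must be >= 0, got {penalty}")

    col_loc = np.zeros(m)
    col_scale = np.ones(m)
    if standardize:
        col_loc = x.mean(axis=0)
        sd = x.std(axis=0)
        col_scale = np.where(sd > 0, sd, 1.0)  # constant columns left alone
        x = (x - col_loc) / col_scale

    theta = np.zeros(m + 1)  # [intercept, coef]
    xa = np.hstack([np.ones((n, 1)), x])
    pen = np.full(m + 1, penalty)
    pen[0] = 0.0  # intercept unpenalized

    def objective(t: np.ndarray) -> float:
        return penalized_loglik(t[0], t[1:], x, y, penalty)

    obj = objective(theta)
    grad_norm = np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        eta = xa @ theta
        p = 1.0 / (1.0 + np.exp(-eta))
        grad = xa.T @ (y - p) - pen * theta
        grad_norm = float(np.abs(grad).max())
        if grad_norm < tol:
            break
        w = p * (1.0 - p)
        hess = (xa * w[:, None]).T @ xa + np.diag(pen)
        # small ridge jitter keeps the solve well-posed when w underflows
        hess[np.diag_indices_from(hess)] += 1e-12
        step = np.linalg.solve(hess, grad)
        # step-halving keeps the objective monotone
        scale = 1.0
        for _ in range(50):
            cand = theta + scale * step
            if objective(cand) >= obj:
                break
            scale *= 0.5
        theta = theta + scale * step
        obj = objective(theta)

    converged = grad_norm < tol
    # with separable classes at penalty=0 the likelihood has no maximum: the
    # coefficients drift to infinity while the gradient vanishes, so a small
    # gradient alone is not convergence there
    diverged = penalty == 0 and float(np.abs(theta).max()) > 30.0
    if diverged:
        converged = False
    if not converged:
        msg = (
            f"logistic fit did not reach tol={tol:g} in {max_iter} iterations "
            f"(gradient sup-norm {grad_norm:.3g})"
        )
        if diverged:
            msg = (
                "logistic MLE appears unbounded (separable classes at "
                "penalty=0); set penalty > 0 to stabilize the fit"
            )
        warnings.warn(msg, ConvergenceWarning, stacklevel=2)
    coef = theta[1:] / col_scale  # identity unless standardize=True
    intercept = float(theta[0] - (col_loc / col_scale) @ theta[1:])
    return LogisticModel(
        intercept=intercept,
        coef=coef,
        converged=converged,
        n_iter=n_iter,
        penalty=penalty,
        grad_norm=grad_norm,
    )


def predict(
    model: LogisticModel, features: FeatureMatrix, threshold: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Return ``(labels, probabilities)``; label 1 iff ``p >= threshold``."""
    if features.n_tags != model.coef.shape[0]:
        raise ValueError(
            f"feature count {features.n_tags} does not match model "
            f"({model.coef.shape[0]})"
        )
    eta = model.intercept + features.x @ model.coef
    prob = 1.0 / (1.0 + np.exp(-eta))
    labels = (prob >= threshold).astype(np.int8)
    return labels, prob


# ---------------------------------------------------------------------------
# evaluation


@dataclass(frozen=True)
class ClassifierMetrics:
    """Confusion counts and the four derived proportions.

    Ratios with a zero denominator are NaN (with a warning at computation
    time), never silently zero.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    precision: float
    sensitivity: float
    specificity: float

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def to_dict(self) -> dict:
        return {
            "TP": self.tp, "FP": self.fp, "TN": self.tn, "FN": self.fn,
            "accuracy": self.accuracy, "precision": self.precision,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
        }


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN",
                      stacklevel=3)
        return float("nan")
    return num / den


def evaluate_classifier(y_true, y_pred) -> ClassifierMetrics:
    """Confusion-matrix metrics with the positive class coded 1."""
    yt = np.asarray(y_true).astype(int)
    yp = np.asarray(y_pred).astype(int)
    if yt.shape != yp.shape:
        raise ValueError(f"length mismatch: {yt.shape} vs {yp.shape}")
    if yt.size < 1:
        raise ValueError("need at least one sample")
    tp = int(((yt == 1) & (yp == 1)).sum())
    fp = int(((yt == 0) & (yp == 1)).sum())
    tn = int(((yt == 0) & (yp == 0)).sum())
    fn = int(((yt == 1) & (yp == 0)).sum())
    return ClassifierMetrics(
        tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=_ratio(tp + tn, tp + fp + tn + fn, "accuracy"),
        precision=_ratio(tp, tp + fp, "precision"),
        sensitivity=_ratio(tp, tp + fn, "sensitivity"),
        specificity=_ratio(tn, tn + fp, "specificity"),
    )


def cross_validate(
    features: FeatureMatrix,
    k: int = 5,
    penalty: float = 1.0,
    seed: int = 0,
    *,
    standardize: bool = False,
    threshold: float = 0.5,
) -> ClassifierMetrics:
    """Stratified k-fold CV; metrics pooled over held-out predictions.

    Fold assignment is a deterministic function of ``seed``. With
    ``standardize=True`` the z-scoring is computed inside each training
    fold (no leakage into the held-out speakers).
    """
    y = features.y
    counts = np.bincount(y, minlength=2)
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} members, fewer than k={k} folds"
        )
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    pooled_pred = np.empty_like(y)
    for train_idx, test_idx in splitter.split(features.x, y):
        train = FeatureMatrix(
            x=features.x[train_idx],
            y=y[train_idx],
            tag_names=features.tag_names,
            speaker_ids=tuple(features.speaker_ids[i] for i in train_idx),
        )
        test = FeatureMatrix(
            x=features.x[test_idx],
            y=y[test_idx],
            tag_names=features.tag_names,
            speaker_ids=tuple(features.speaker_ids[i] for i in test_idx),
        )
        model = fit_logistic(train, penalty, standardize=standardize)
        labels, _ = predict(model, test, threshold)
        pooled_pred[test_idx] = labels
    return evaluate_classifier(y, pooled_pred)
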