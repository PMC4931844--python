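"""Orthogonal-signal-correction PLS discriminant analysis (O-PLS-DA)
with permutation validation.

The predictor matrix is autoscaled (mean 0, unit variance per gene) and
class labels one-hot encoded.  Orthogonal signal correction removes
``n_ortho`` components of X-variation orthogonal to the class structure
(Trygg & Wold style), after which a standard NIPALS PLS2 with
``n_components`` predictive components is fitted.  Model quality is
summarized as Xvar, the percentage of (scaled) predictor variance
captured by the predictive components, and validated by permuting the
class labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cross_decomposition import PLSRegression

from .datatypes import ValidationError


@dataclass
class OplsdaResult:
    scores: np.ndarray          # samples x n_components predictive scores
    n_ortho: int
    n_components: int
    xvar: float                 # percent of scaled-X variance, in [0, 100]
    classes: list
    y_labels: np.ndarray
    pvalue: float | None = None
    n_permutations: int | None = None
    seed: int | None = None
    cv_sd: float | None = None


def _autoscale(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def _one_hot(y: np.ndarray) -> tuple[np.ndarray, list]:
    classes = sorted(set(y))
    Y = np.zeros((len(y), len(classes)))
    for j, c in enumerate(classes):
        Y[np.asarray(y) == c, j] = 1.0
    return Y - Y.mean(axis=0), classes


def _osc_filter(X: np.ndarray, Y: np.ndarray, n_ortho: int) -> np.ndarray:
    """Remove n_ortho orthogonal components from X (O-PLS filtering)."""
    Xf = X.copy()
    for _ in range(n_ortho):
        # first PLS2 weight vector of the current X against Y
        w = Xf.T @ Y @ np.linalg.pinv(Y.T @ Y)
        u, _, _ = np.linalg.svd(w, full_matrices=False)
        w1 = u[:, 0]
        t = Xf @ w1
        p = Xf.T @ t / (t @ t)
        w_ortho = p - (w1 @ p) * w1
        norm = np.linalg.norm(w_ortho)
        if norm < 1e-12:
            break  # nothing orthogonal left to remove
        w_ortho /= norm
        t_ortho = Xf @ w_ortho
        p_ortho = Xf.T @ t_ortho / (t_ortho @ t_ortho)
        Xf = Xf - np.outer(t_ortho, p_ortho)
    return Xf


def _xvar_percent(X_scaled: np.ndarray, X_filtered: np.ndarray,
                  pls: PLSRegression) -> float:
    T = pls.x_scores_
    P = pls.x_loadings_
    resid = X_filtered - T @ P.T
    captured = (X_filtered ** 2).sum() - (resid ** 2).sum()
    total = (X_scaled ** 2).sum()
    return float(100.0 * captured / total)


def fit_oplsda(X, y, n_ortho: int = 1, n_components: int = 2,
               seed: int | None = None) -> OplsdaResult:
    """Fit O-PLS-DA on a samples x genes matrix with class labels.

    With ``n_ortho=0`` this reduces exactly to PLS-DA.  Xvar is reported
    relative to the total variance of the autoscaled X, so removing
    orthogonal variation cannot inflate it.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValidationError("X must be samples x genes aligned with y")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValidationError("need at least 2 classes")
    if (counts < 2).any():
        raise ValidationError("every class needs at least 2 samples")
    rank = min(X.shape[0] - 1, X.shape[1])
    if n_ortho >= rank:
        raise ValidationError(f"n_ortho={n_ortho} >= rank(X)={rank}")
    Xs = _autoscale(X)
    Y, class_list = _one_hot(y)
    Xf = _osc_filter(Xs, Y, n_ortho)
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(Xf, Y)
    xvar = _xvar_percent(Xs, Xf, pls)
    return OplsdaResult(
        scores=pls.x_scores_.copy(),
        n_ortho=n_ortho,
        n_components=n_components,
        xvar=xvar,
        classes=list(class_list),
        y_labels=y,
        seed=seed,
    )


def permutation_pvalue(X, y, n_permutations: int = 999, n_ortho: int = 1,
                       n_components: int = 2, seed: int = 0) -> tuple[float, float]:
    """Permutation p-value for the O-PLS-DA Xvar statistic.

    p = (1 + #{permuted Xvar >= observed}) / (n_permutations + 1), so the
    smallest attainable value is 1 / (n_permutations + 1).
    Returns (pvalue, observed Xvar).
    """
    if n_permutations < 99:
        raise ValidationError("need at least 99 permutations")
    observed = fit_oplsda(X, y, n_ortho, n_components).xvar
    rng = np.random.default_rng(seed)
    y = np.asarray(y)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(y)
        try:
            stat = fit_oplsda(X, perm, n_ortho, n_components).xvar
        except ValidationError:
            continue  # degenerate permutation (class lost); counts as non-exceeding
        if stat >= observed:
            exceed += 1
    p = (1 + exceed) / (n_permutations + 1)
    return float(p), float(observed)


def cross_validated_xvar_sd(X, y, n_ortho: int = 1, n_components: int = 2,
                            n_splits: int = 5, seed: int = 0) -> float:
    """Standard deviation of Xvar over K leave-fold-out refits."""
    from sklearn.model_selection import StratifiedKFold

    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    n_splits = min(n_splits, counts.min() // 2) or 2
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    xvars = []
    for train, _ in skf.split(X, y):
        try:
            xvars.append(fit_oplsda(X[train], y[train], n_ortho, n_components).xvar)
        except ValidationError:
            continue
    return float(np.std(xvars, ddof=1)) if len(xvars) > 1 else float("nan")
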