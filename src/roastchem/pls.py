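"""Latent-variable core: PCA, NIPALS partial least squares, PLS-DA,
Venetian-blinds cross-validation, latent-variable selection, and
classification metrics.

PLS is implemented as classical NIPALS with X- and Y-deflation.  For each
component a weight vector ``w`` (unit norm), scores ``t = X w``, X-loadings
``p = X't / t't`` and Y-loadings ``q = Y't / t't`` are extracted and X is
deflated by ``t p'``.  The regression coefficient matrix is

    B = W (P' W)^{-1} Q',

so predictions for preprocessed data are ``X B``.  Scores are mutually
orthogonal and, at full rank, predictions coincide with ordinary least
squares.  Models capture their preprocessing state (column means, and
standard deviations when autoscaling) at fit time, so ``predict`` accepts
raw-scale inputs and returns raw-scale responses.

Cross-validation uses Venetian blinds: fold ``s`` holds the samples whose
position in the stored sample order is congruent to ``s`` modulo the number
of splits.  Preprocessing states are re-estimated on each fold's training
part only.  The number of latent variables is chosen by a parsimony rule:
the smallest count whose cross-validation error is within a relative
tolerance (default 2%) of the global minimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

NIPALS_MAX_ITER = 500
NIPALS_TOL = 1e-10


# ---------------------------------------------------------------------------
# PCA

def pca(X: np.ndarray, n_pc: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Principal component analysis of the centered matrix via SVD.

    Returns ``(scores, loadings, explained_variance_fraction)`` with
    ``scores = U S`` and ``loadings`` the right singular vectors (columns).
    """
    X = np.asarray(X, dtype=float)
    if n_pc < 1 or n_pc > min(X.shape):
        raise ValueError("n_pc must be between 1 and min(n_samples, n_features)")
    Xc = X - X.mean(axis=0)
    total = float(np.sum(Xc**2))
    if total <= 0:
        raise ValueError("matrix has no variance; PCA is degenerate")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    scores = U[:, :n_pc] * s[:n_pc]
    loadings = Vt[:n_pc].T
    explained = (s[:n_pc] ** 2) / total
    return scores, loadings, explained


# ---------------------------------------------------------------------------
# preprocessing helpers

def _fit_scale(X: np.ndarray, mode: str) -> tuple[np.ndarray, np.ndarray]:
    """Column means and divisors for mode in {'none', 'center', 'autoscale'}."""
    n_col = X.shape[1]
    if mode == "none":
        return np.zeros(n_col), np.ones(n_col)
    if mode == "center":
        return X.mean(axis=0), np.ones(n_col)
    if mode == "autoscale":
        std = X.std(axis=0, ddof=1)
        if np.any(std <= 0):
            bad = np.flatnonzero(std <= 0)
            raise ValueError(f"zero-variance columns cannot be autoscaled: {bad.tolist()}")
        return X.mean(axis=0), std
    raise ValueError(f"unknown scaling mode {mode!r}")


def _as_matrix(data) -> tuple[np.ndarray, Optional[list]]:
    if isinstance(data, pd.DataFrame):
        return data.to_numpy(dtype=float), list(data.columns)
    arr = np.asarray(data, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, None


# ---------------------------------------------------------------------------
# the fitted model

@dataclass
class PLSModel:
    """Fitted NIPALS PLS state (see module docstring for the algebra)."""

    n_lv: int
    weights: np.ndarray  # W: features x LV
    x_loadings: np.ndarray  # P: features x LV
    y_loadings: np.ndarray  # Q: responses x LV
    scores: np.ndarray  # T: training samples x LV
    x_mean: np.ndarray
    x_div: np.ndarray
    y_mean: np.ndarray
    y_div: np.ndarray
    response_kind: str = "continuous"  # or "class-dummy"
    classes: Optional[list] = None
    feature_names: Optional[list] = None
    response_names: Optional[list] = None

    def coefficients(self, n_lv: Optional[int] = None) -> np.ndarray:
        """Regression coefficients B using the first ``n_lv`` components."""
        a = self.n_lv if n_lv is None else n_lv
        if not 1 <= a <= self.n_lv:
            raise ValueError(f"n_lv must be in [1, {self.n_lv}]")
        W, P, Q = self.weights[:, :a], self.x_loadings[:, :a], self.y_loadings[:, :a]
        return W @ np.linalg.solve(P.T @ W, Q.T)

    @property
    def B(self) -> np.ndarray:
        return self.coefficients()

    def preprocess_x(self, X_new) -> np.ndarray:
        X, names = _as_matrix(X_new)
        if X.shape[1] != self.x_mean.size:
            raise ValueError(
                f"feature grid mismatch: model has {self.x_mean.size} features, "
                f"input has {X.shape[1]}"
            )
        if names is not None and self.feature_names is not None and names != self.feature_names:
            raise ValueError("feature names do not match the model's feature grid")
        return (X - self.x_mean) / self.x_div


def fit_pls(
    X,
    Y,
    n_lv: int,
    x_scale: str = "center",
    y_scale: str = "center",
) -> PLSModel:
    """Fit a PLS regression with ``n_lv`` components by NIPALS.

    ``x_scale`` / ``y_scale`` select the preprocessing captured in the model
    ('none', 'center' or 'autoscale'); the decomposition itself runs on the
    preprocessed blocks.
    """
    Xr, feature_names = _as_matrix(X)
    Yr, response_names = _as_matrix(Y)
    if Xr.shape[0] != Yr.shape[0]:
        raise ValueError("X and Y have different numbers of samples")
    if n_lv < 1:
        raise ValueError("n_lv must be >= 1")

    x_mean, x_div = _fit_scale(Xr, x_scale)
    y_mean, y_div = _fit_scale(Yr, y_scale)
    Xk = (Xr - x_mean) / x_div
    Yk = (Yr - y_mean) / y_div

    n, p = Xk.shape
    m = Yk.shape[1]
    x_scale_floor = max(float(np.sum(Xk**2)), 1e-300)

    W = np.empty((p, n_lv))
    P = np.empty((p, n_lv))
    Q = np.empty((m, n_lv))
    T = np.empty((n, n_lv))

    for a in range(n_lv):
        if np.sum(Xk**2) < 1e-13 * x_scale_floor:
            raise ValueError(
                f"n_lv={n_lv} exceeds the effective rank of X (failed at component {a + 1})"
            )
        # start from the Y column with the largest variance
        u = Yk[:, int(np.argmax(Yk.var(axis=0)))].copy()
        if not np.any(u):
            u = Yk[:, 0].copy()
        w = np.zeros(p)
        for iteration in range(NIPALS_MAX_ITER):
            w_new = Xk.T @ u
            norm = np.linalg.norm(w_new)
            if norm <= 0:
                raise ValueError(f"NIPALS degenerate weight vector at component {a + 1}")
            w_new /= norm
            t = Xk @ w_new
            tt = float(t @ t)
            if tt <= 1e-13 * x_scale_floor:
                raise ValueError(
                    f"n_lv={n_lv} exceeds the effective rank of X (failed at component {a + 1})"
                )
            q = Yk.T @ t / tt
            qq = float(q @ q)
            u_new = Yk @ q / qq if qq > 0 else t.copy()
            if np.linalg.norm(w_new - w) < NIPALS_TOL:
                w = w_new
                break
            w, u = w_new, u_new
        else:
            raise ValueError(
                f"NIPALS did not converge for component {a + 1} "
                f"after {NIPALS_MAX_ITER} iterations"
            )
        t = Xk @ w
        tt = float(t @ t)
        p_vec = Xk.T @ t / tt
        q_vec = Yk.T @ t / tt
        Xk = Xk - np.outer(t, p_vec)
        Yk = Yk - np.outer(t, q_vec)
        W[:, a], P[:, a], Q[:, a], T[:, a] = w, p_vec, q_vec, t

    return PLSModel(
        n_lv=n_lv,
        weights=W,
        x_loadings=P,
        y_loadings=Q,
        scores=T,
        x_mean=x_mean,
        x_div=x_div,
        y_mean=y_mean,
        y_div=y_div,
        feature_names=feature_names,
        response_names=response_names,
    )


def predict(model: PLSModel, X_new, n_lv: Optional[int] = None) -> np.ndarray:
    """Response-scale predictions for raw-scale inputs."""
    Xp = model.preprocess_x(X_new)
    Yp = Xp @ model.coefficients(n_lv)
    return Yp * model.y_div + model.y_mean


# ---------------------------------------------------------------------------
# cross-validation and LV selection

@dataclass
class CVResult:
    """Venetian-blinds cross-validation summary across candidate LV counts."""

    rmsecv: np.ndarray  # per LV count 1..max_lv
    explained_x: np.ndarray  # cumulative fraction per LV (full-data fit)
    explained_y: np.ndarray
    n_lv: int
    split: str
    misclassification: Optional[np.ndarray] = None  # class responses only
    warnings: list[str] = field(default_factory=list)
    cv_predictions: Optional[np.ndarray] = None  # max_lv x n x m held-out predictions

    @property
    def criterion(self) -> np.ndarray:
        return self.rmsecv if self.misclassification is None else self.misclassification


def _fit_saturating(
    X: np.ndarray, Y: np.ndarray, n_lv: int, x_scale: str, y_scale: str,
    notes: list[str], context: str,
) -> PLSModel:
    """Fit with as many components as the data supports, up to ``n_lv``.

    Cross-validation deliberately probes LV counts past what a training
    subset can sustain; when a deep component fails (rank exhaustion, or a
    NIPALS eigen-tie on noise), the count is reduced and the event recorded
    instead of aborting the whole CV.
    """
    for a in range(n_lv, 0, -1):
        try:
            model = fit_pls(X, Y, a, x_scale=x_scale, y_scale=y_scale)
        except ValueError:
            continue
        if a < n_lv:
            notes.append(f"{context}: saturated at {a} of {n_lv} LVs")
        return model
    raise ValueError(f"{context}: no PLS component could be extracted")


def venetian_blinds_folds(n_samples: int, n_splits: int) -> list[np.ndarray]:
    """Interleaved folds: fold s holds samples with index % n_splits == s."""
    idx = np.arange(n_samples)
    return [idx[idx % n_splits == s] for s in range(n_splits)]


def select_n_lv(cv: CVResult, rel_tol: float = 0.02) -> int:
    """Parsimonious LV count: smallest within ``rel_tol`` of the minimum
    cross-validation error."""
    curve = np.asarray(cv.criterion, dtype=float)
    best = float(np.min(curve))
    cutoff = best * (1.0 + rel_tol)
    return int(np.flatnonzero(curve <= cutoff)[0]) + 1


def venetian_blinds_cv(
    X,
    Y,
    max_lv: int,
    n_splits: int = 5,
    x_scale: str = "center",
    y_scale: str = "center",
    class_labels: Optional[Sequence] = None,
    classes: Optional[list] = None,
    rel_tol: float = 0.02,
) -> CVResult:
    """Cross-validate PLS over 1..max_lv components with interleaved folds.

    Each fold is predicted by a model fitted — preprocessing states included
    — on the remaining folds only.  RMSECV pools squared errors over folds
    and response columns; for class responses (``class_labels`` given) the
    per-LV misclassification rate is recorded as well and used as the
    selection criterion.
    """
    Xr, _ = _as_matrix(X)
    Yr, _ = _as_matrix(Y)
    n = Xr.shape[0]
    if n_splits < 2:
        raise ValueError("n_splits must be >= 2")
    if n_splits > n:
        raise ValueError("n_splits exceeds the number of samples")

    folds = venetian_blinds_folds(n, n_splits)
    predictions = np.full((max_lv, n, Yr.shape[1]), np.nan)
    notes: list[str] = []

    for s, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        if class_labels is not None:
            held = set(np.asarray(class_labels)[train_idx])
            lost = set(np.asarray(class_labels)) - held
            if lost:
                notes.append(f"fold {s} training set lost classes {sorted(lost)}")
        Xt = Xr[train_idx]
        if np.allclose(Yr[train_idx].std(axis=0), 0.0):
            # degenerate fold (e.g. a single surviving class): intercept only
            notes.append(f"fold {s} has a constant response; intercept-only predictions")
            predictions[:, test_idx] = Yr[train_idx].mean(axis=0)
            continue
        fold_max = min(max_lv, int(np.linalg.matrix_rank(Xt - Xt.mean(axis=0))))
        if fold_max < max_lv:
            notes.append(f"fold {s} rank-limited to {fold_max} LVs")
        model = _fit_saturating(Xt, Yr[train_idx], fold_max, x_scale, y_scale, notes, f"fold {s}")
        fold_max = model.n_lv
        for a in range(1, max_lv + 1):
            # LV counts beyond the fold's rank saturate at its capacity
            predictions[a - 1, test_idx] = predict(model, Xr[test_idx], n_lv=min(a, fold_max))

    rmsecv = np.sqrt(np.mean((predictions - Yr[None]) ** 2, axis=(1, 2)))

    misclass = None
    if class_labels is not None:
        if classes is None:
            classes = sorted(set(class_labels))
        true = np.asarray(class_labels)
        misclass = np.empty(max_lv)
        for a in range(max_lv):
            assigned, _ = plsda_assign(predictions[a], classes)
            misclass[a] = float(np.mean(assigned != true))

    full_max = min(max_lv, int(np.linalg.matrix_rank(Xr - Xr.mean(axis=0))))
    if full_max < max_lv:
        notes.append(f"full data rank-limited to {full_max} LVs")
    full = _fit_saturating(Xr, Yr, full_max, x_scale, y_scale, notes, "full data")
    Xp = full.preprocess_x(Xr)
    Yp = (Yr - full.y_mean) / full.y_div
    ssx, ssy = float(np.sum(Xp**2)), float(np.sum(Yp**2))
    tt = np.sum(full.scores**2, axis=0)
    explained_x = np.cumsum(tt * np.sum(full.x_loadings**2, axis=0)) / ssx
    explained_y = np.cumsum(tt * np.sum(full.y_loadings**2, axis=0)) / max(ssy, 1e-300)

    cv = CVResult(
        rmsecv=rmsecv,
        explained_x=explained_x,
        explained_y=explained_y,
        n_lv=1,
        split=f"venetian blinds, {n_splits} splits, {n} samples",
        misclassification=misclass,
        warnings=notes,
        cv_predictions=predictions,
    )
    cv.n_lv = select_n_lv(cv, rel_tol=rel_tol)
    return cv


# ---------------------------------------------------------------------------
# discriminant analysis

def one_hot(labels: Sequence, classes: list) -> np.ndarray:
    lookup = {c: i for i, c in enumerate(classes)}
    Y = np.zeros((len(labels), len(classes)))
    for i, lab in enumerate(labels):
        Y[i, lookup[lab]] = 1.0
    return Y


def plsda_fit(
    X,
    class_labels: Sequence,
    max_lv: int = 10,
    n_splits: int = 5,
    x_scale: str = "center",
    rel_tol: float = 0.02,
) -> tuple[PLSModel, CVResult]:
    """PLS-DA: one-hot class response, Venetian-blinds CV, parsimonious LV
    count selected on the cross-validated misclassification rate."""
    classes = list(dict.fromkeys(class_labels))  # stable first-appearance order
    if len(classes) < 2:
        raise ValueError("PLS-DA needs at least two classes")
    counts = pd.Series(list(class_labels)).value_counts()
    small = counts[counts < 2]
    if len(small):
        raise ValueError(f"classes with fewer than 2 samples: {list(small.index)}")
    Y = one_hot(class_labels, classes)
    Xr, _ = _as_matrix(X)
    max_lv = min(max_lv, np.linalg.matrix_rank(Xr - Xr.mean(axis=0)))
    cv = venetian_blinds_cv(
        Xr, Y, max_lv=max_lv, n_splits=n_splits, x_scale=x_scale,
        y_scale="center", class_labels=class_labels, classes=classes, rel_tol=rel_tol,
    )
    model = fit_pls(Xr, Y, cv.n_lv, x_scale=x_scale, y_scale="center")
    model.response_kind = "class-dummy"
    model.classes = classes
    model.response_names = classes
    return model, cv


def plsda_assign(
    dummy_predictions: np.ndarray, classes: list
) -> tuple[np.ndarray, np.ndarray]:
    """Hard class assignment: arg-max over class columns.

    Exact ties go to the earliest class in ``classes`` and are flagged.
    """
    pred = np.asarray(dummy_predictions, dtype=float)
    if pred.ndim != 2 or pred.shape[1] != len(classes):
        raise ValueError("dummy_predictions must have one column per class")
    winners = np.argmax(pred, axis=1)
    ties = (pred == pred.max(axis=1, keepdims=True)).sum(axis=1) > 1
    labels = np.asarray([classes[i] for i in winners], dtype=object)
    return labels, ties


@dataclass
class ClassMetrics:
    """Per-class and overall classification performance."""

    classes: list
    confusion: pd.DataFrame  # rows true, columns assigned
    sensitivity: pd.Series
    specificity: pd.Series
    per_class_accuracy: pd.Series
    accuracy: float
    classification_error: float
    r2: float

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
                "accuracy": self.per_class_accuracy,
            }
        )
        df.index.name = "class"
        return df


def classification_metrics(
    true_labels: Sequence,
    assigned_labels: Sequence,
    dummy_predictions: Optional[np.ndarray] = None,
    classes: Optional[list] = None,
) -> ClassMetrics:
    """One-vs-rest sensitivity/specificity per class, overall accuracy,
    mean balanced classification error, and R-squared on the dummy response."""
    true = np.asarray(true_labels, dtype=object)
    assigned = np.asarray(assigned_labels, dtype=object)
    if true.shape != assigned.shape:
        raise ValueError("label vectors are not aligned")
    if not set(true) & set(assigned):
        raise ValueError("true and assigned label sets are disjoint")
    if classes is None:
        classes = sorted(set(true) | set(assigned))

    n = len(true)
    confusion = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for t, a in zip(true, assigned):
        confusion.loc[t, a] += 1

    sens, spec, pc_acc = {}, {}, {}
    for c in classes:
        tp = int(np.sum((true == c) & (assigned == c)))
        fn = int(np.sum((true == c) & (assigned != c)))
        fp = int(np.sum((true != c) & (assigned == c)))
        tn = n - tp - fn - fp
        sens[c] = tp / (tp + fn) if tp + fn else np.nan
        spec[c] = tn / (tn + fp) if tn + fp else np.nan
        pc_acc[c] = (tp + tn) / n
    sens_s = pd.Series(sens)
    spec_s = pd.Series(spec)
    error = float(np.nanmean([(1 - sens_s[c]) / 2 + (1 - spec_s[c]) / 2 for c in classes]))

    r2 = np.nan
    if dummy_predictions is not None:
        Yd = one_hot(true, classes)
        pred = np.asarray(dummy_predictions, dtype=float)
        sse = float(np.sum((Yd - pred) ** 2))
        sst = float(np.sum((Yd - Yd.mean(axis=0)) ** 2))
        r2 = 1.0 - sse / sst if sst > 0 else np.nan

    return ClassMetrics(
        classes=classes,
        confusion=confusion,
        sensitivity=sens_s,
        specificity=spec_s,
        per_class_accuracy=pd.Series(pc_acc),
        accuracy=float(np.mean(true == assigned)),
        classification_error=error,
        r2=r2,
    )
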