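"""From-scratch PLS regression and sparse PLS-DA with validation.

Partial least squares is implemented with NIPALS deflation: per
component a unit-norm weight vector is extracted from the X-response
covariance, scores are the projections of (deflated) X onto it, and X
is deflated by the score's loading, which makes successive score
vectors mutually orthogonal. The discriminant variant regresses on a
class-indicator matrix; its sparse form hard-truncates each weight
vector to the ``keep`` largest absolute entries before computing
scores, and classifies held-out samples by the nearest training-class
centroid in score space.

Validation machinery mirrors standard practice for p >> n omics
classifiers: the classification error rate (CER) is minimised over a
keep grid by stratified ten-fold cross-validation, and both CER and
held-out R^2 are compared against permutation nulls in which the full
selection + fitting pipeline is re-run on shuffled responses, so no
information leaks from test labels into feature selection, centring or
scaling.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold

from .containers import ConfigurationError

DEFAULT_KEEP_GRID = (1, 2, 3, 4, 5, 10, 25, 50)


def _center_scale(X: np.ndarray, scale: bool) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd = np.where(sd > 0, sd, 1.0)
    else:
        sd = np.ones(X.shape[1])
    return (X - mean) / sd, mean, sd


def _check_components(Xc: np.ndarray, n_components: int) -> None:
    if n_components < 1:
        raise ConfigurationError("n_components must be >= 1")
    rank = np.linalg.matrix_rank(Xc)
    if n_components > rank:
        raise ConfigurationError(
            f"n_components={n_components} exceeds rank(X)={rank}"
        )


@dataclasses.dataclass
class PLSRegressionModel:
    """NIPALS PLS1 fit: weights W, loadings P, per-component y-loadings q."""

    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    W: np.ndarray  # p x A, unit-norm columns
    P: np.ndarray  # p x A
    q: np.ndarray  # A
    T: np.ndarray  # n x A training scores

    @property
    def n_components(self) -> int:
        return self.W.shape[1]

    def coefficients(self, n_components: int | None = None) -> np.ndarray:
        a = n_components or self.n_components
        W, P, q = self.W[:, :a], self.P[:, :a], self.q[:a]
        return W @ np.linalg.solve(P.T @ W, q)

    def predict(self, X: np.ndarray, n_components: int | None = None) -> np.ndarray:
        Xc = (np.asarray(X, dtype=float) - self.x_mean) / self.x_scale
        return Xc @ self.coefficients(n_components) + self.y_mean


def pls_fit(
    X: np.ndarray, y: np.ndarray, n_components: int, scale: bool = False
) -> PLSRegressionModel:
    """Fit PLS1 regression by NIPALS deflation.

    Weights are unit-norm; at ``n_components = rank(X)`` the prediction
    equals the ordinary least-squares fit.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != len(y):
        raise ValueError("X and y disagree on sample count")
    Xc, mean, sd = _center_scale(X, scale)
    _check_components(Xc, n_components)
    y_mean = y.mean()
    yc = y - y_mean

    n, p = Xc.shape
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    q = np.zeros(n_components)
    T = np.zeros((n, n_components))
    Xd, yd = Xc.copy(), yc.copy()
    for a in range(n_components):
        w = Xd.T @ yd
        norm = np.linalg.norm(w)
        if norm < 1e-14:
            # response fully explained; remaining components are null
            W, P, q, T = W[:, : a], P[:, : a], q[: a], T[:, : a]
            break
        w /= norm
        t = Xd @ w
        tt = t @ t
        p_load = Xd.T @ t / tt
        q_a = yd @ t / tt
        Xd -= np.outer(t, p_load)
        yd -= t * q_a
        W[:, a], P[:, a], q[a], T[:, a] = w, p_load, q_a, t
    return PLSRegressionModel(mean, sd, y_mean, W, P, q, T)


def _indicator(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    classes, codes = np.unique(labels, return_inverse=True)
    return np.eye(len(classes))[codes], classes


@dataclasses.dataclass
class PLSDAModel:
    """(Sparse) PLS-DA fit with nearest-centroid prediction in score space."""

    x_mean: np.ndarray
    x_scale: np.ndarray
    W: np.ndarray
    P: np.ndarray
    R: np.ndarray  # W (P'W)^-1: projection X -> scores
    classes: np.ndarray
    centroids: np.ndarray  # k x A
    keep: int

    @property
    def n_components(self) -> int:
        return self.W.shape[1]

    @property
    def selected_features(self) -> np.ndarray:
        """Indices of features with a nonzero weight in any component."""
        return np.where(np.any(self.W != 0, axis=1))[0]

    def transform(self, X: np.ndarray) -> np.ndarray:
        Xc = (np.asarray(X, dtype=float) - self.x_mean) / self.x_scale
        return Xc @ self.R

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = self.transform(X)
        d2 = ((scores[:, None, :] - self.centroids[None, :, :]) ** 2).sum(axis=2)
        return self.classes[np.argmin(d2, axis=1)]


def spls_fit(
    X: np.ndarray,
    labels: np.ndarray,
    n_components: int | None = None,
    keep: int | None = None,
    scale: bool = True,
) -> PLSDAModel:
    """Sparse PLS-DA on a class-indicator response.

    Per component the weight vector (dominant left singular vector of
    the deflated X'Y) is truncated to its ``keep`` largest absolute
    entries and renormalised before the score is computed; ``keep =
    None`` (or the full feature count) gives dense PLS-DA.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    Y, classes = _indicator(labels)
    if len(classes) < 2:
        raise ConfigurationError("need >= 2 classes")
    A = n_components if n_components is not None else len(classes) - 1
    p = X.shape[1]
    if keep is None:
        keep = p
    if keep < 1:
        raise ConfigurationError("keep must be >= 1")
    if keep > p:
        raise ConfigurationError(f"keep={keep} exceeds feature count {p}")
    Xc, mean, sd = _center_scale(X, scale)
    _check_components(Xc, A)
    Yc = Y - Y.mean(axis=0)

    n = Xc.shape[0]
    W = np.zeros((p, A))
    P = np.zeros((p, A))
    Xd, Yd = Xc.copy(), Yc.copy()
    for a in range(A):
        M = Xd.T @ Yd
        u, s, vt = np.linalg.svd(M, full_matrices=False)
        w = u[:, 0]
        # deterministic sign: largest-magnitude entry positive
        j = np.argmax(np.abs(w))
        if w[j] < 0:
            w = -w
        if keep < p:
            cutoff = np.partition(np.abs(w), p - keep)[p - keep]
            w = np.where(np.abs(w) >= cutoff, w, 0.0)
        norm = np.linalg.norm(w)
        if norm < 1e-14:
            raise ConfigurationError("degenerate component: zero weight vector")
        w /= norm
        t = Xd @ w
        tt = t @ t
        if tt < 1e-14:
            W, P = W[:, : a], P[:, : a]
            break
        p_load = Xd.T @ t / tt
        c = Yd.T @ t / tt
        Xd -= np.outer(t, p_load)
        Yd -= np.outer(t, c)
        W[:, a], P[:, a] = w, p_load

    R = W @ np.linalg.solve(P.T @ W, np.eye(W.shape[1]))
    T = Xc @ R
    centroids = np.vstack([T[labels == cls].mean(axis=0) for cls in classes])
    return PLSDAModel(mean, sd, W, P, R, classes, centroids, keep)


def cer(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Classification error rate: misclassified fraction."""
    y_true = np.asarray(y_true)
    return float(np.mean(y_true != np.asarray(y_pred)))


def _stratified_folds(labels: np.ndarray, n_folds: int, seed: int):
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < n_folds:
        raise ConfigurationError(
            f"stratified {n_folds}-fold CV impossible: smallest class has "
            f"{counts.min()} samples"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return skf.split(np.zeros(len(labels)), labels)


def cv_cer(
    X: np.ndarray,
    labels: np.ndarray,
    keep: int,
    n_components: int | None = None,
    n_folds: int = 10,
    seed: int = 0,
    scale: bool = True,
) -> float:
    """Mean stratified k-fold CER of sPLS-DA at a given sparsity.

    Centring, scaling and the sparse selection are re-estimated inside
    every training fold.
    """
    labels = np.asarray(labels)
    errs = []
    for train, test in _stratified_folds(labels, n_folds, seed):
        model = spls_fit(X[train], labels[train], n_components, keep, scale)
        errs.append(cer(labels[test], model.predict(X[test])))
    return float(np.mean(errs))


def select_keep_by_cv(
    X: np.ndarray,
    labels: np.ndarray,
    grid=DEFAULT_KEEP_GRID,
    n_components: int | None = None,
    n_folds: int = 10,
    seed: int = 0,
    scale: bool = True,
) -> tuple[int, float, dict[int, float]]:
    """Pick the sparsity minimising cross-validated CER (ties -> smallest keep)."""
    grid = sorted(set(int(g) for g in grid))
    if not grid:
        raise ConfigurationError("keep grid must be nonempty")
    p = X.shape[1]
    grid = [g for g in grid if g <= p] or [p]
    curve = {
        g: cv_cer(X, labels, g, n_components, n_folds, seed, scale) for g in grid
    }
    best = min(grid, key=lambda g: (curve[g], g))
    return best, curve[best], curve


def nested_cv_cer(
    X: np.ndarray,
    labels: np.ndarray,
    grid=DEFAULT_KEEP_GRID,
    n_components: int | None = None,
    n_folds: int = 10,
    seed: int = 0,
    scale: bool = True,
) -> float:
    """Unbiased CER of the select-then-fit pipeline via nested CV.

    The sparsity grid search runs inside each outer training fold, so
    the outer error estimate carries no selection optimism: on pure
    noise it sits at chance, unlike the minimised CV curve, which dips
    below chance by construction (minimum of noisy fold means).
    """
    labels = np.asarray(labels)
    errs = []
    for i, (train, test) in enumerate(_stratified_folds(labels, n_folds, seed)):
        keep, _, _ = select_keep_by_cv(
            X[train], labels[train], grid, n_components,
            min(n_folds, np.unique(labels[train], return_counts=True)[1].min()),
            seed + i + 1, scale,
        )
        model = spls_fit(X[train], labels[train], n_components, keep, scale)
        errs.append(cer(labels[test], model.predict(X[test])))
    return float(np.mean(errs))


@dataclasses.dataclass
class PermutationNull:
    mean: float
    se: float
    values: np.ndarray
    metric: str


def permutation_null(
    X: np.ndarray,
    y: np.ndarray,
    n_perm: int = 10,
    metric: str = "cer",
    seed: int = 0,
    grid=DEFAULT_KEEP_GRID,
    n_components: int | None = None,
    n_folds: int = 10,
    repeats: int = 5,
    fraction: float = 2 / 3,
    max_components: int = 10,
    scale: bool | None = None,
) -> PermutationNull:
    """Null distribution of CER or held-out R^2 under label permutation.

    Responses are shuffled without replacement and the complete
    pipeline is re-run per permutation with no leakage: for CER the
    nested-CV error (sparsity chosen inside each outer training fold),
    for R^2 the train/test splits with CV-chosen component count. With
    balanced classes the CER null is therefore centred at chance.
    """
    if n_perm < 2:
        raise ConfigurationError("n_perm must be >= 2 for a standard error")
    if metric not in ("cer", "r2"):
        raise ConfigurationError("metric must be 'cer' or 'r2'")
    rng = np.random.default_rng(seed)
    y = np.asarray(y)
    values = []
    for b in range(n_perm):
        y_perm = rng.permutation(y)
        sub_seed = int(rng.integers(2**31 - 1))
        if metric == "cer":
            values.append(
                nested_cv_cer(
                    X, y_perm, grid, n_components, n_folds, sub_seed,
                    scale if scale is not None else True,
                )
            )
        else:
            summary = train_test_r2(
                X, y_perm.astype(float), fraction=fraction, repeats=repeats,
                max_components=max_components, n_folds=n_folds, seed=sub_seed,
                scale=bool(scale) if scale is not None else False,
            )
            values.append(summary.mean_r2)
    values = np.asarray(values, dtype=float)
    se = float(values.std(ddof=1) / np.sqrt(len(values)))
    return PermutationNull(float(values.mean()), se, values, metric)


@dataclasses.dataclass
class ValidationSummary:
    metric: str
    mean_r2: float
    se: float
    r2_values: np.ndarray
    n_components: list[int]
    predictions: pd.DataFrame  # observed, predicted, repeat


def _choose_components_cv(
    X: np.ndarray, y: np.ndarray, max_components: int, n_folds: int, seed: int,
    scale: bool,
) -> int:
    """Component count minimising k-fold prediction MSE on the training set."""
    n, p = X.shape
    a_max = min(max_components, p, n - max(2, n // n_folds) - 1)
    a_max = max(a_max, 1)
    kf = KFold(n_splits=min(n_folds, n), shuffle=True, random_state=seed)
    sse = np.zeros(a_max)
    counts = np.zeros(a_max)
    for train, test in kf.split(X):
        a_fit = min(a_max, np.linalg.matrix_rank(X[train] - X[train].mean(axis=0)))
        model = pls_fit(X[train], y[train], a_fit, scale=scale)
        for a in range(1, model.n_components + 1):
            pred = model.predict(X[test], a)
            sse[a - 1] += np.sum((pred - y[test]) ** 2)
            counts[a - 1] += len(test)
    mse = np.where(counts > 0, sse / np.maximum(counts, 1), np.inf)
    return int(np.argmin(mse)) + 1


def train_test_r2(
    X: np.ndarray,
    age: np.ndarray,
    fraction: float = 2 / 3,
    repeats: int = 20,
    max_components: int = 10,
    n_folds: int = 10,
    seed: int = 0,
    scale: bool = False,
    sample_ids=None,
) -> ValidationSummary:
    """Repeated random train/test PLS prediction of a numeric response.

    Per repeat: a random ``fraction`` of samples trains the model (with
    the component count chosen by k-fold CV inside the training set),
    the rest are predicted, and R^2 is the squared Pearson correlation
    of predicted vs observed on the held-out third.
    """
    X = np.asarray(X, dtype=float)
    age = np.asarray(age, dtype=float)
    n = X.shape[0]
    n_train = int(round(fraction * n))
    if n - n_train < 2:
        raise ConfigurationError("test set smaller than 2 samples")
    rng = np.random.default_rng(seed)
    ids = np.asarray(sample_ids) if sample_ids is not None else np.arange(n)

    r2s, comps, pred_rows = [], [], []
    for rep in range(repeats):
        perm = rng.permutation(n)
        train, test = perm[:n_train], perm[n_train:]
        sub_seed = int(rng.integers(2**31 - 1))
        a = _choose_components_cv(
            X[train], age[train], max_components, n_folds, sub_seed, scale
        )
        model = pls_fit(X[train], age[train], a, scale=scale)
        pred = model.predict(X[test], a)
        obs = age[test]
        if np.std(pred) == 0 or np.std(obs) == 0:
            r2 = 0.0
        else:
            r2 = float(np.corrcoef(pred, obs)[0, 1] ** 2)
        r2s.append(r2)
        comps.append(a)
        pred_rows.append(
            pd.DataFrame(
                {"sample_id": ids[test], "observed_age": obs,
                 "predicted_age": pred, "repeat": rep + 1}
            )
        )
    r2s = np.asarray(r2s)
    se = float(r2s.std(ddof=1) / np.sqrt(len(r2s))) if len(r2s) > 1 else 0.0
    return ValidationSummary(
        metric="r2",
        mean_r2=float(r2s.mean()),
        se=se,
        r2_values=r2s,
        n_components=comps,
        predictions=pd.concat(pred_rows, ignore_index=True),
    )
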