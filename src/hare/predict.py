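"""Ridge-regression genomic prediction and its evaluation protocols.

The prediction model is plain ridge on standardised features: features are
centred and scaled to unit variance (training statistics only), the
intercept is unpenalised, and

    beta_hat = argmin_beta ||y - X beta||^2 + lambda ||beta||^2

is solved in closed form through the primal normal equations or the dual
(n < p) form, whichever is smaller. The penalty is chosen by minimum mean
squared error in k-fold cross-validation over a log-spaced grid, with ties
broken toward heavier shrinkage; the grid search is evaluated through a
per-fold SVD so the whole path costs one decomposition per fold.

Two evaluation protocols mirror a within-panel / cross-panel study design:
repeated 80/20 Monte Carlo splits within one panel, and training on
family-stratified subsets of one panel with testing in another. Accuracy is
the Pearson correlation between observed and predicted trait values.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold

from ._errors import InputError
from ._rng import rng_from, spawn_seeds


def _as_matrix(X) -> tuple[np.ndarray, pd.Index, pd.Index]:
    if isinstance(X, pd.DataFrame):
        if X.index.duplicated().any():
            raise InputError("duplicated line ids in feature matrix")
        return X.to_numpy(dtype=float), X.index, X.columns
    X = np.asarray(X, dtype=float)
    return X, pd.RangeIndex(X.shape[0]), pd.RangeIndex(X.shape[1])


def _as_vector(y, index=None) -> np.ndarray:
    if isinstance(y, pd.Series) and index is not None:
        y = y.loc[index]
    return np.asarray(y, dtype=float).ravel()


@dataclass
class RidgeModel:
    """Fitted ridge model on the standardised feature scale."""

    beta: np.ndarray  # on the standardised scale
    intercept: float  # mean of training y
    lam: float
    centers: np.ndarray
    scales: np.ndarray
    feature_ids: pd.Index
    dropped: pd.Index = field(default_factory=lambda: pd.Index([]))

    def predict(self, X) -> np.ndarray:
        Xm, _, cols = _as_matrix(X)
        if isinstance(X, pd.DataFrame):
            Xm = X.loc[:, self.feature_ids].to_numpy(dtype=float)
        Xs = (Xm - self.centers) / self.scales
        return self.intercept + Xs @ self.beta


def fit_ridge(X, y, lam: float) -> RidgeModel:
    """Closed-form ridge fit with standardised features and unpenalised
    intercept. Zero-variance features are dropped with a warning."""
    if lam < 0:
        raise InputError("lambda must be >= 0")
    Xm, lines, cols = _as_matrix(X)
    yv = _as_vector(y, lines)
    n, p = Xm.shape
    if n < 3:
        raise InputError("ridge fit needs at least 3 observations")
    if len(yv) != n:
        raise InputError("X and y have different numbers of lines")
    centers = Xm.mean(axis=0)
    scales = Xm.std(axis=0)
    keep = scales > 0
    dropped = cols[~keep]
    if len(dropped) > 0:
        warnings.warn(f"dropping zero-variance features: {list(dropped[:5])}", stacklevel=2)
    Xs = (Xm[:, keep] - centers[keep]) / scales[keep]
    ybar = float(yv.mean())
    yc = yv - ybar
    q = int(keep.sum())
    if lam == 0.0:
        beta, *_ = np.linalg.lstsq(Xs, yc, rcond=None)
    elif q <= n:
        A = Xs.T @ Xs + lam * np.eye(q)
        beta = np.linalg.solve(A, Xs.T @ yc)
    else:  # dual form, exact for lam > 0
        K = Xs @ Xs.T + lam * np.eye(n)
        beta = Xs.T @ np.linalg.solve(K, yc)
    return RidgeModel(
        beta=beta,
        intercept=ybar,
        lam=float(lam),
        centers=centers[keep],
        scales=scales[keep],
        feature_ids=cols[keep],
        dropped=dropped,
    )


def default_lambda_grid(X, num: int = 100) -> np.ndarray:
    """Log-spaced grid spanning ``[1e-4, 1e4] * ||X'X|| / n`` on the
    standardised feature scale (spectral norm)."""
    Xm, _, _ = _as_matrix(X)
    sd = Xm.std(axis=0)
    Xs = (Xm - Xm.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    s = np.linalg.svd(Xs, compute_uv=False)
    scale = float(s[0] ** 2) / Xm.shape[0] if len(s) else 1.0
    scale = scale if scale > 0 else 1.0
    return np.geomspace(1e-4, 1e4, num) * scale


def select_lambda_cv(
    X, y, grid: Sequence[float] | None = None, k_folds: int = 10, seed: int = 0
) -> float:
    """Penalty minimising mean held-out squared error over k folds.

    Ties are broken toward the larger lambda. The per-fold ridge path is
    computed from one SVD of the standardised training block.
    """
    Xm, lines, _ = _as_matrix(X)
    yv = _as_vector(y, lines)
    n = Xm.shape[0]
    if n < k_folds:
        raise InputError(f"n ({n}) < k_folds ({k_folds})")
    grid = np.asarray(grid if grid is not None else default_lambda_grid(Xm), dtype=float)
    if grid.size == 0:
        raise InputError("empty lambda grid")
    order = np.argsort(grid)
    grid = grid[order]
    kf = KFold(n_splits=k_folds, shuffle=True, random_state=int(seed) % 2**31)
    sse = np.zeros(len(grid))
    cnt = 0
    for tr, va in kf.split(Xm):
        Xtr, Xva = Xm[tr], Xm[va]
        ytr, yva = yv[tr], yv[va]
        m = Xtr.mean(axis=0)
        sd = Xtr.std(axis=0)
        ok = sd > 0
        Xtr_s = (Xtr[:, ok] - m[ok]) / sd[ok]
        Xva_s = (Xva[:, ok] - m[ok]) / sd[ok]
        ybar = ytr.mean()
        U, s, Vt = np.linalg.svd(Xtr_s, full_matrices=False)
        uty = U.T @ (ytr - ybar)
        proj = Xva_s @ Vt.T  # n_va x r
        for i, lam in enumerate(grid):
            shrink = s / (s**2 + lam) if lam > 0 else np.where(s > 0, 1.0 / s, 0.0)
            pred = ybar + proj @ (shrink * uty)
            sse[i] += float(((yva - pred) ** 2).sum())
        cnt += len(va)
    mse = sse / cnt
    best = len(grid) - 1 - int(np.argmin(mse[::-1]))  # ties -> larger lambda
    return float(grid[best])


def accuracy(observed, predicted) -> float:
    """Pearson correlation between observed and predicted values."""
    obs = np.asarray(observed, dtype=float).ravel()
    pred = np.asarray(predicted, dtype=float).ravel()
    if len(obs) != len(pred) or len(obs) < 3:
        raise InputError("accuracy needs equal-length vectors of length >= 3")
    if obs.std() == 0 or pred.std() == 0:
        raise InputError("accuracy undefined for a constant vector")
    return float(stats.pearsonr(obs, pred).statistic)


@dataclass
class PredictionResult:
    """Accuracies of a prediction protocol over its repeats."""

    accuracies: list[float]
    protocol: str  # "within" or "cross"
    trait: str | None = None
    feature_kind: str | None = None
    manifest: dict = field(default_factory=dict)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))


def _split_hash(indices: Sequence[np.ndarray]) -> str:
    h = hashlib.sha256()
    for idx in indices:
        h.update(np.sort(np.asarray(idx)).astype(np.int64).tobytes())
        h.update(b"|")
    return h.hexdigest()


def evaluate_within_panel(
    X,
    y,
    n_repeats: int = 20,
    train_frac: float = 0.8,
    seed: int = 0,
    grid: Sequence[float] | None = None,
    k_folds: int = 10,
    trait: str | None = None,
    feature_kind: str | None = None,
) -> PredictionResult:
    """Repeated Monte Carlo 80/20 splits with per-split penalty selection.

    The penalty is re-selected by cross-validation inside every training
    split (test data never touch the selection). Splits with a constant test
    trait are excluded and logged in the manifest.
    """
    Xm, lines, cols = _as_matrix(X)
    yv = _as_vector(y, lines)
    n = Xm.shape[0]
    if n < 10:
        raise InputError("within-panel evaluation needs at least 10 lines")
    seeds = spawn_seeds(seed, n_repeats * 2)
    accs: list[float] = []
    excluded = 0
    test_sets = []
    for r in range(n_repeats):
        rng = rng_from(seeds[2 * r])
        perm = rng.permutation(n)
        n_train = int(round(train_frac * n))
        tr, te = perm[:n_train], perm[n_train:]
        test_sets.append(te)
        if np.std(yv[te]) == 0:
            excluded += 1
            continue
        lam = select_lambda_cv(Xm[tr], yv[tr], grid=grid, k_folds=k_folds,
                               seed=seeds[2 * r + 1])
        model = fit_ridge(Xm[tr], yv[tr], lam)
        pred = model.predict(Xm[te])
        if np.std(pred) == 0:
            excluded += 1
            continue
        accs.append(accuracy(yv[te], pred))
    return PredictionResult(
        accuracies=accs,
        protocol="within",
        trait=trait,
        feature_kind=feature_kind,
        manifest={
            "n_repeats": n_repeats,
            "train_frac": train_frac,
            "seed": seed,
            "excluded_splits": excluded,
            "split_hash": _split_hash(test_sets),
        },
    )


def evaluate_cross_panel(
    X_train,
    y_train,
    X_test,
    y_test,
    family_map: Mapping[str, str] | pd.Series | None = None,
    per_family: int = 10,
    n_subsets: int = 20,
    seed: int = 0,
    grid: Sequence[float] | None = None,
    k_folds: int = 10,
    trait: str | None = None,
    feature_kind: str | None = None,
) -> PredictionResult:
    """Train in one panel, test in another sharing the feature space.

    With a ``family_map`` (training line -> family), training uses
    ``n_subsets`` stratified subsets of ``per_family`` lines per family (a
    family smaller than ``per_family`` is taken whole, with a warning) and
    the test accuracy is averaged over subsets; without one, a single
    train/test run is performed. Lines present in both panels are removed
    from the test set first.
    """
    n_removed = 0
    if isinstance(X_train, pd.DataFrame) and isinstance(X_test, pd.DataFrame):
        if not X_train.columns.equals(X_test.columns):
            raise InputError("feature columns differ between train and test panels")
        overlap = X_train.index.intersection(X_test.index)
        n_removed = len(overlap)
        if n_removed > 0:
            X_test = X_test.drop(index=overlap)
            if isinstance(y_test, pd.Series):
                y_test = y_test.drop(index=overlap, errors="ignore")
    Xtr, tr_lines, _ = _as_matrix(X_train)
    Xte, te_lines, _ = _as_matrix(X_test)
    if Xtr.shape[1] != Xte.shape[1]:
        raise InputError("feature columns differ between train and test panels")
    ytr = _as_vector(y_train, tr_lines)
    yte = _as_vector(y_test, te_lines)

    subsets: list[np.ndarray]
    if family_map is not None:
        fam = pd.Series(family_map)
        fam = fam.loc[tr_lines]
        groups = {f: np.flatnonzero((fam == f).to_numpy()) for f in fam.unique()}
        short = [f for f, idx in groups.items() if len(idx) < per_family]
        if short:
            warnings.warn(
                f"families smaller than per_family={per_family}: {short[:5]}; "
                "sampled without replacement at their size",
                stacklevel=2,
            )
        seeds = spawn_seeds(seed, n_subsets * 2)
        subsets = []
        for srep in range(n_subsets):
            rng = rng_from(seeds[2 * srep])
            chosen = [
                rng.choice(idx, size=min(per_family, len(idx)), replace=False)
                for f, idx in groups.items()
            ]
            subsets.append(np.sort(np.concatenate(chosen)))
        cv_seeds = [seeds[2 * s + 1] for s in range(n_subsets)]
    else:
        subsets = [np.arange(Xtr.shape[0])]
        cv_seeds = spawn_seeds(seed, 1)

    accs = []
    for sub, cs in zip(subsets, cv_seeds):
        lam = select_lambda_cv(Xtr[sub], ytr[sub], grid=grid, k_folds=k_folds, seed=cs)
        model = fit_ridge(Xtr[sub], ytr[sub], lam)
        pred = model.predict(Xte)
        accs.append(accuracy(yte, pred))
    return PredictionResult(
        accuracies=accs,
        protocol="cross",
        trait=trait,
        feature_kind=feature_kind,
        manifest={
            "n_subsets": len(subsets),
            "per_family": per_family if family_map is not None else None,
            "seed": seed,
            "overlapping_lines_removed": n_removed,
            "split_hash": _split_hash(subsets),
        },
    )
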