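"""Wavelength/feature selection under one fit/apply contract.

Nine reduction methods in three families, as used in spectroscopic
calibration work:

* projections — PCA, SVD, kernel PCA (RBF): transform spectra onto a small
  set of basis vectors;
* rankers — univariate F statistic, absolute Pearson correlation (PPMCC),
  k-NN mutual information: score every wavelength against the response and
  keep the top n;
* iterative searchers — recursive feature elimination (RFE), the successive
  projections algorithm (SPA), and competitive adaptive reweighted sampling
  (CARS): search the wavelength space directly.

A fitted :class:`Selector` stores either column indices or projection
parameters and can be applied, without refitting, to new spectra.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import KernelPCA
from sklearn.feature_selection import mutual_info_regression
from sklearn.model_selection import KFold

__all__ = [
    "Selector",
    "SELECT_METHODS",
    "PROJECTION_METHODS",
    "RANKER_METHODS",
    "fit_projection",
    "rank_features",
    "top_n_indices",
    "rfe_select",
    "rfe_elimination_order",
    "spa_select",
    "spa_chain",
    "cars_select",
    "edf_ratios",
    "apply_selector",
    "fit_selector",
]

# canonical order, also used for deterministic tie-breaking in reports
SELECT_METHODS = ("none", "pca", "kpca", "svd", "f_test", "ppmcc", "mi", "rfe", "spa", "cars")
PROJECTION_METHODS = ("pca", "kpca", "svd")
RANKER_METHODS = ("f_test", "ppmcc", "mi")
INDEX_METHODS = ("f_test", "ppmcc", "mi", "rfe", "spa", "cars")


@dataclass
class Selector:
    """Fitted feature-reduction state applicable to new spectra.

    ``n_features`` is the number of retained components (projections) or
    wavelengths (index methods).  ``state`` holds projection parameters or
    the sorted, unique selected column indices.
    """

    method: str
    n_features: int
    n_inputs: int
    state: dict = field(repr=False)
    fit_seed: int = 0

    @property
    def indices(self) -> np.ndarray:
        if "indices" not in self.state:
            raise AttributeError(f"{self.method} selector has no column indices")
        return self.state["indices"]


def apply_selector(selector: Selector, X: np.ndarray) -> np.ndarray:
    """Apply a fitted selector to an m x p matrix; no refitting."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != selector.n_inputs:
        raise ValueError(
            f"expected {selector.n_inputs} columns, got {X.shape[1] if X.ndim == 2 else X.shape}"
        )
    m = selector.method
    st = selector.state
    if m == "none":
        return X
    if m == "pca":
        return (X - st["mean"]) @ st["components"].T
    if m == "svd":
        return X @ st["components"].T
    if m == "kpca":
        return st["model"].transform(X)
    return X[:, st["indices"]]


def fit_projection(
    method: str,
    X: np.ndarray,
    n: int,
    *,
    kernel: str = "rbf",
    gamma: float | None = None,
) -> Selector:
    """Fit a PCA / SVD / kernel-PCA projection onto the top n components.

    PCA centers the columns and projects onto the leading eigenvectors of
    the covariance; SVD projects onto the top right singular vectors of the
    uncentered matrix; kernel PCA uses a centered RBF kernel (default
    inverse length-scale 1/p) with the usual kernel-against-training
    out-of-sample extension.  A ``kernel='linear'`` option exists so kernel
    PCA can be checked against plain PCA.
    """
    X = np.asarray(X, dtype=float)
    ns, p = X.shape
    if method == "kpca":
        if not 1 <= n < ns:
            raise ValueError("kpca needs 1 <= n < n_samples")
        model = KernelPCA(n_components=n, kernel=kernel, gamma=gamma if gamma is not None else 1.0 / p)
        model.fit(X)
        return Selector("kpca", n, p, {"model": model})
    if not 1 <= n <= min(ns, p):
        raise ValueError("n out of range for projection")
    if method == "pca":
        mean = X.mean(axis=0)
        _, _, Vt = np.linalg.svd(X - mean, full_matrices=False)
        return Selector("pca", n, p, {"mean": mean, "components": Vt[:n]})
    if method == "svd":
        _, _, Vt = np.linalg.svd(X, full_matrices=False)
        return Selector("svd", n, p, {"components": Vt[:n]})
    raise ValueError(f"unknown projection method {method!r}")


def _pearson_r(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    n = X.shape[0]
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = X.std(axis=0, ddof=1)
    sy = y.std(ddof=1)
    const = np.ptp(X, axis=0) == 0  # exact constancy; std may carry fp dust
    if np.any(const):
        warnings.warn(
            f"{int(const.sum())} constant column(s) scored 0", RuntimeWarning, stacklevel=3
        )
        sx = np.where(const, 1.0, sx)
    r = (xc * yc[:, None]).sum(axis=0) / ((n - 1) * sx * sy)
    r[const] = 0.0
    return np.clip(r, -1.0, 1.0)


def rank_features(method: str, X: np.ndarray, y: np.ndarray, *, seed: int = 0) -> np.ndarray:
    """Score every column's relevance to y; higher is more relevant.

    ``f_test``: univariate regression F = (n-2) r^2 / (1 - r^2);
    ``ppmcc``: |Pearson r|; ``mi``: k-nearest-neighbour mutual information
    (k = 3, seeded jitter on duplicates), non-negative.  Constant columns
    score 0 with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples to rank features")
    if np.ptp(y) == 0:
        raise ValueError("constant response")
    if method == "mi":
        return mutual_info_regression(X, y, n_neighbors=3, random_state=seed)
    r = _pearson_r(X, y)
    if method == "ppmcc":
        return np.abs(r)
    if method == "f_test":
        r2 = r**2
        with np.errstate(divide="ignore"):
            return np.where(r2 < 1.0, (n - 2) * r2 / (1.0 - r2), np.inf)
    raise ValueError(f"unknown ranker {method!r}")


def top_n_indices(scores: np.ndarray, n: int) -> np.ndarray:
    """Indices of the n largest scores, ties broken by lower index; sorted."""
    order = np.argsort(-np.asarray(scores), kind="stable")
    return np.sort(order[:n])


def rfe_elimination_order(X: np.ndarray, y: np.ndarray) -> list[int]:
    """Full backward-elimination order (first eliminated first).

    Columns are standardized to unit sample variance once, then OLS is
    refitted after each removal of the smallest-|coefficient| column, so
    the surviving sets are nested across all target sizes.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    sd = X.std(axis=0, ddof=1)
    sd = np.where(sd == 0, 1.0, sd)  # constant columns get coefficient 0
    Xs = X / sd
    active = list(range(p))
    eliminated: list[int] = []
    ones = np.ones((n, 1))
    while len(active) > 1:
        A = np.hstack([ones, Xs[:, active]])
        beta = np.linalg.lstsq(A, y, rcond=None)[0][1:]
        j = int(np.argmin(np.abs(beta)))  # argmin takes the lowest index on ties
        eliminated.append(active.pop(j))
    eliminated.append(active[0])
    return eliminated


def rfe_select(X: np.ndarray, y: np.ndarray, n: int) -> Selector:
    """Recursive feature elimination down to n wavelengths (deterministic)."""
    p = X.shape[1]
    if not 1 <= n < p:
        raise ValueError("need 1 <= n < p for RFE")
    order = rfe_elimination_order(X, y)
    idx = np.sort(np.asarray(order[p - n :], dtype=int))
    return Selector("rfe", n, p, {"indices": idx})


def spa_chain(X: np.ndarray, start: int, n_max: int) -> list[int]:
    """SPA forward chain from a start column.

    Repeatedly picks the column with the largest residual norm after
    orthogonal projection onto the span of the columns already chosen,
    which keeps the selected wavelengths maximally non-collinear.  Stops
    early if every remaining residual is numerically zero (duplicated
    columns are therefore never chosen twice).
    """
    X = np.asarray(X, dtype=float)
    R = X.copy()
    chain = [start]
    nv = np.linalg.norm(R[:, start])
    if nv == 0:
        raise ValueError("start column is all zeros")
    v = R[:, start] / nv
    R = R - np.outer(v, v @ R)
    for _ in range(n_max - 1):
        norms = np.linalg.norm(R, axis=0)
        norms[chain] = -1.0
        j = int(np.argmax(norms))
        if norms[j] <= 1e-10 * nv:
            break
        chain.append(j)
        v = R[:, j] / norms[j]
        R = R - np.outer(v, v @ R)
    return chain


def _cv_splits(n: int, folds: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    return list(kf.split(np.arange(n)))


def _ols_cv_rmse(F: np.ndarray, y: np.ndarray, splits) -> float:
    """Pooled RMSE of intercept-OLS over precomputed CV splits."""
    sse = 0.0
    for tr, va in splits:
        A = np.hstack([np.ones((tr.size, 1)), F[tr]])
        beta = np.linalg.lstsq(A, y[tr], rcond=None)[0]
        pred = beta[0] + F[va] @ beta[1:]
        sse += float(np.sum((y[va] - pred) ** 2))
    return math.sqrt(sse / y.size)


def spa_select(
    X: np.ndarray,
    y: np.ndarray,
    n_min: int = 2,
    n_max: int | None = None,
    *,
    seed: int = 0,
    folds: int = 5,
) -> Selector:
    """Successive projections algorithm with CV-scored subset size.

    Builds a projection chain from every start column, then scores each
    (start, chain-length) candidate with ``n_min <= length <= n_max`` by
    pooled 5-fold OLS RMSE and returns the candidate with the minimum
    (ties broken by smaller length, then lower start index).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n_max is None:
        n_max = min(25, p, n - 2)
    if not 1 <= n_min <= n_max <= min(p, n - 2):
        raise ValueError("need 1 <= n_min <= n_max <= min(p, n - 2)")
    col_norms = np.linalg.norm(X, axis=0)
    if np.all(col_norms == 0):
        raise ValueError("degenerate design: all columns are zero")
    splits = _cv_splits(n, folds, seed)
    best: tuple[float, int, int] | None = None
    best_idx: np.ndarray | None = None
    for start in range(p):
        if col_norms[start] == 0:
            continue
        chain = spa_chain(X, start, n_max)
        for length in range(n_min, len(chain) + 1):
            idx = np.sort(np.asarray(chain[:length], dtype=int))
            rmse = _ols_cv_rmse(X[:, idx], y, splits)
            key = (rmse, length, start)
            if best is None or key < best:
                best = key
                best_idx = idx
    assert best_idx is not None
    return Selector("spa", best_idx.size, p, {"indices": best_idx, "cv_rmse": best[0]}, seed)


def edf_ratios(p: int, runs: int) -> np.ndarray:
    """CARS exponentially decaying keep-ratios r_i = a e^(-k i), i = 1..runs.

    With a = (p/2)^(1/(runs-1)) and k = ln(p/2)/(runs-1) the schedule starts
    at r_1 = 1 (all wavelengths) and ends at r_runs = 2/p (two wavelengths).
    """
    if runs < 2:
        raise ValueError("runs must be at least 2")
    a = (p / 2.0) ** (1.0 / (runs - 1))
    k = math.log(p / 2.0) / (runs - 1)
    i = np.arange(1, runs + 1)
    return a * np.exp(-k * i)


def _pls_coef_path(X: np.ndarray, y: np.ndarray, max_k: int):
    """One PLS fit; regression coefficients for every component count 1..K.

    Returns (x_mean, y_mean, B) with B of shape (p, K): predictions with k
    components are ``(Xnew - x_mean) @ B[:, k-1] + y_mean``.
    """
    K = int(min(max_k, X.shape[0] - 1, X.shape[1]))
    K = max(K, 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # PLS warns when y residuals vanish early
        m = PLSRegression(n_components=K, scale=False).fit(X, y)
    contrib = m.x_rotations_ * m.y_loadings_.ravel()[None, :]
    B = np.cumsum(contrib, axis=1)
    return X.mean(axis=0), float(y.mean()), B


def _pls_cv_rmse(X: np.ndarray, y: np.ndarray, max_k: int, seed: int, folds: int = 5):
    """(best component count, RMSECV at it) by seeded k-fold CV."""
    n, p = X.shape
    splits = _cv_splits(n, folds, seed)
    K = int(min(max_k, p, min(tr.size for tr, _ in splits) - 1))
    K = max(K, 1)
    sse = np.zeros(K)
    for tr, va in splits:
        xm, ym, B = _pls_coef_path(X[tr], y[tr], K)
        pred = (X[va] - xm) @ B[:, :K] + ym
        sse += np.sum((pred - y[va][:, None]) ** 2, axis=0)
    rmse = np.sqrt(sse / n)
    best = int(np.argmin(rmse))
    return best + 1, float(rmse[best])


def cars_select(
    X: np.ndarray,
    y: np.ndarray,
    runs: int = 50,
    mc_ratio: float = 0.8,
    max_pls_components: int = 10,
    seed: int = 0,
) -> Selector:
    """Competitive adaptive reweighted sampling over wavelengths.

    Each Monte-Carlo run fits PLS (component count by internal 5-fold CV,
    capped) on a random calibration subset of the currently retained
    wavelengths, weights wavelengths by normalized |regression coefficient|,
    enforces the exponential decay schedule of :func:`edf_ratios` by keeping
    the top wavelengths, then resamples that many wavelengths with
    replacement proportionally to weight (adaptive reweighted sampling) and
    retains the unique draws.  The retained set with the lowest 5-fold PLS
    RMSECV across runs wins.  Fully seeded.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if runs < 2:
        raise ValueError("runs must be at least 2")
    if not 0.0 < mc_ratio < 1.0:
        raise ValueError("mc_ratio must be in (0, 1)")
    if n < 10:
        raise ValueError("too few samples for the internal cross-validation")
    rng = np.random.default_rng(seed)
    cv_seed = int(rng.integers(2**31))
    ratios = edf_ratios(p, runs)
    retained = np.arange(p)
    best_rmse = math.inf
    best_set = retained.copy()
    n_cal = math.ceil(mc_ratio * n)
    for i in range(runs):
        if retained.size == 0:
            continue  # collapsed set: recorded as infinite RMSECV, cannot win
        cal = rng.choice(n, size=n_cal, replace=False)
        Xr = X[np.ix_(cal, retained)]
        k, _ = _pls_cv_rmse(Xr, y[cal], max_pls_components, cv_seed)
        _, _, B = _pls_coef_path(Xr, y[cal], k)
        w = np.abs(B[:, k - 1])
        total = w.sum()
        w = w / total if total > 0 else np.full(w.size, 1.0 / w.size)
        n_keep = min(math.ceil(ratios[i] * p), retained.size)
        order = np.argsort(-w, kind="stable")  # ties -> lower wavelength index
        kept = order[:n_keep]
        probs = w[kept] / w[kept].sum() if w[kept].sum() > 0 else None
        draws = rng.choice(kept, size=n_keep, replace=True, p=probs)
        retained = np.sort(retained[np.unique(draws)])
        if retained.size == 0:
            continue
        _, rmse = _pls_cv_rmse(X[:, retained], y, max_pls_components, cv_seed)
        if rmse < best_rmse:
            best_rmse = rmse
            best_set = retained.copy()
    return Selector("cars", best_set.size, p, {"indices": best_set, "cv_rmse": best_rmse}, seed)


def fit_selector(
    method: str,
    X: np.ndarray,
    y: np.ndarray | None = None,
    n: int | None = None,
    *,
    seed: int = 0,
    **params,
) -> Selector:
    """Dispatch to the nine methods (plus ``none``) by tag."""
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    if method == "none":
        return Selector("none", p, p, {})
    if method in PROJECTION_METHODS:
        if n is None:
            raise ValueError(f"{method} requires n")
        return fit_projection(method, X, n, **params)
    if y is None:
        raise ValueError(f"{method} requires the response")
    if method in RANKER_METHODS:
        if n is None:
            raise ValueError(f"{method} requires n")
        scores = rank_features(method, X, y, seed=seed)
        idx = top_n_indices(scores, n)
        return Selector(method, n, p, {"indices": idx, "scores": scores}, seed)
    if method == "rfe":
        if n is None:
            raise ValueError("rfe requires n")
        return rfe_select(X, y, n)
    if method == "spa":
        return spa_select(
            X, y,
            n_min=int(params.get("n_min", 2)),
            n_max=params.get("n_max"),
            seed=seed,
        )
    if method == "cars":
        return cars_select(
            X, y,
            runs=int(params.get("runs", 50)),
            mc_ratio=float(params.get("mc_ratio", 0.8)),
            max_pls_components=int(params.get("max_components", 10)),
            seed=seed,
        )
    raise ValueError(f"unknown selection method {method!r}")
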