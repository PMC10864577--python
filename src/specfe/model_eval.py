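"""Sample partitioning, OLS regression, metrics and the CV protocol.

The evaluation protocol mirrors standard chemometric practice: one SPXY
(joint X-Y distance Kennard-Stone) split into calibration and prediction
sets; on the calibration set, seeded 5-fold cross-validation both selects
the number of retained features and yields the calibration metric triple
(fold means); the prediction triple comes from a single fit on the full
calibration set applied once to the held-out prediction set.  Response-
dependent steps (DOSC, all selectors) are refitted inside every fold so no
held-out information leaks into them.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.model_selection import KFold

from .preprocessing import Preprocessor
from .selection import (
    PROJECTION_METHODS,
    RANKER_METHODS,
    Selector,
    apply_selector,
    fit_projection,
    fit_selector,
    rank_features,
    rfe_elimination_order,
    top_n_indices,
)
from .synthetic import SpectralDataset

__all__ = [
    "SplitResult",
    "OlsModel",
    "MetricSet",
    "PipelineSpec",
    "ResultRow",
    "FittedPipeline",
    "spxy_selection_order",
    "spxy_split",
    "ols_fit",
    "ols_predict",
    "compute_metrics",
    "cv_evaluate",
    "fit_pipeline",
    "evaluate_pipeline",
]

#: selection methods whose feature count is chosen by the CV search
N_SEARCHED_METHODS = PROJECTION_METHODS + RANKER_METHODS + ("rfe",)
#: upper bound of the searched feature-count grid
N_SEARCH_CAP = 30


@dataclass(frozen=True)
class SplitResult:
    """Disjoint sorted calibration / prediction index lists covering 0..n-1."""

    cal_idx: np.ndarray
    pred_idx: np.ndarray


@dataclass(frozen=True)
class OlsModel:
    """Ordinary least squares fit (intercept + coefficients, minimum norm)."""

    intercept: float
    coefficients: np.ndarray


@dataclass(frozen=True)
class MetricSet:
    """RMSE (% Brix), MAPE (fraction) and RPD (= SD of measured / RMSE)."""

    rmse: float
    mape: float
    rpd: float


@dataclass(frozen=True)
class PipelineSpec:
    """One grid-cell recipe: pre-processor + selector + feature-count policy.

    ``n`` is either a fixed feature count or ``"cv"`` (chosen by 5-fold CV
    for projections/rankers/RFE; SPA and CARS size their subset internally).
    """

    preprocess: str = "none"
    select: str = "none"
    n: int | str = "cv"
    preprocess_params: dict = field(default_factory=dict)
    select_params: dict = field(default_factory=dict)
    seed: int = 0

    def name(self) -> str:
        return f"{self.preprocess}-{self.select}"


@dataclass
class ResultRow:
    """Six-metric outcome of one pipeline on one split (NA when failed)."""

    preprocess: str
    select: str
    n: int | None
    rmse_c: float = math.nan
    mape_c: float = math.nan
    rpd_c: float = math.nan
    rmse_p: float = math.nan
    mape_p: float = math.nan
    rpd_p: float = math.nan
    failed: bool = False
    reason: str = ""


def _parse_ratio(ratio: str) -> float:
    try:
        a, b = (float(t) for t in ratio.split(":"))
    except Exception as exc:
        raise ValueError(f"cannot parse split ratio {ratio!r}") from exc
    if a <= 0 or b <= 0:
        raise ValueError("ratio parts must be positive")
    return a / (a + b)


def spxy_selection_order(X: np.ndarray, y: np.ndarray, k: int) -> list[int]:
    """Kennard-Stone max-min sequence under the joint X-Y distance.

    d(i,j) = d_x(i,j)/max d_x + |y_i - y_j|/max |y_i - y_j|; the first two
    picks are the pair at maximal joint distance, then each step adds the
    sample whose minimum distance to the selected set is largest.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    Dx = squareform(pdist(X))
    Dy = np.abs(y[:, None] - y[None, :])
    mx, my = Dx.max(), Dy.max()
    if mx == 0 or my == 0:
        raise ValueError("all-identical spectra or responses: SPXY distances degenerate")
    D = Dx / mx + Dy / my
    i, j = np.unravel_index(np.argmax(D), D.shape)
    selected = [int(min(i, j)), int(max(i, j))]
    while len(selected) < k:
        mind = D[:, selected].min(axis=1)
        mind[selected] = -1.0
        selected.append(int(np.argmax(mind)))
    return selected


def spxy_split(X: np.ndarray, y: np.ndarray, ratio: str = "3:1") -> SplitResult:
    """Deterministic SPXY partition into calibration and prediction sets.

    The calibration size is round(n * ratio fraction); for 116 samples at
    3:1 this is 87 calibration and 29 prediction samples.
    """
    n = np.asarray(y).size
    if n < 4:
        raise ValueError("need at least 4 samples to split")
    k = int(math.floor(_parse_ratio(ratio) * n + 0.5))
    k = min(max(k, 2), n - 1)
    order = spxy_selection_order(X, y, k)
    cal = np.sort(np.asarray(order, dtype=int))
    pred = np.setdiff1d(np.arange(n), cal)
    return SplitResult(cal, pred)


def ols_fit(F: np.ndarray, y: np.ndarray) -> OlsModel:
    """Least squares with intercept; minimum-norm solution when rank-deficient."""
    F = np.asarray(F, dtype=float)
    y = np.asarray(y, dtype=float)
    if F.ndim != 2:
        raise ValueError("features must be 2-D")
    if F.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if not (np.all(np.isfinite(F)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in the regression inputs")
    A = np.hstack([np.ones((F.shape[0], 1)), F])
    beta = np.linalg.lstsq(A, y, rcond=None)[0]
    return OlsModel(float(beta[0]), beta[1:])


def ols_predict(model: OlsModel, F: np.ndarray) -> np.ndarray:
    F = np.asarray(F, dtype=float)
    if F.shape[1] != model.coefficients.size:
        raise ValueError("feature count does not match the fitted model")
    return model.intercept + F @ model.coefficients


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> MetricSet:
    """RMSE, MAPE (as a fraction) and RPD of predictions.

    RPD is the sample standard deviation (denominator N-1) of the measured
    values divided by the RMSE; a zero RMSE yields +inf with a warning.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size < 2:
        raise ValueError("need two equal-length vectors of at least 2 values")
    if np.any(y_true <= 0):
        raise ValueError("MAPE undefined: measured values must be strictly positive")
    err = y_true - y_pred
    rmse = float(np.sqrt(np.mean(err**2)))
    mape = float(np.mean(np.abs(err) / y_true))
    sd = float(np.std(y_true, ddof=1))
    if rmse == 0.0:
        warnings.warn("zero RMSE: RPD reported as +inf", RuntimeWarning, stacklevel=2)
        return MetricSet(0.0, mape, math.inf)
    return MetricSet(rmse, mape, sd / rmse)


def _mean_metrics(metrics: list[MetricSet]) -> MetricSet:
    return MetricSet(
        float(np.mean([m.rmse for m in metrics])),
        float(np.mean([m.mape for m in metrics])),
        float(np.mean([m.rpd for m in metrics])),
    )


def _fold_nested_features(spec: PipelineSpec, Ftr, ytr, Fva, n_max):
    """Per-fold nested feature sets for the n-searched methods.

    Returns a callable n -> (train features, val features) built so the
    top-n sets are nested and only one fit of the underlying method is done
    per fold.
    """
    method = spec.select
    if method in RANKER_METHODS:
        scores = rank_features(method, Ftr, ytr, seed=spec.seed)
        order = np.argsort(-scores, kind="stable")

        def take(n):
            idx = np.sort(order[:n])
            return Ftr[:, idx], Fva[:, idx]

    elif method in PROJECTION_METHODS:
        sel = fit_projection(method, Ftr, n_max, **spec.select_params)
        Str, Sva = apply_selector(sel, Ftr), apply_selector(sel, Fva)

        def take(n):
            return Str[:, :n], Sva[:, :n]

    else:  # rfe
        order = rfe_elimination_order(Ftr, ytr)
        p = Ftr.shape[1]

        def take(n):
            idx = np.sort(np.asarray(order[p - n :], dtype=int))
            return Ftr[:, idx], Fva[:, idx]

    return take


def cv_evaluate(
    spec: PipelineSpec,
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    wavelengths: np.ndarray,
    folds: int = 5,
    seed: int = 0,
    leaky: bool = False,
) -> tuple[MetricSet, int | None]:
    """Seeded k-fold CV of a pipeline on the calibration set.

    Response-dependent pre-processing (DOSC) and the selector are fitted on
    the training folds only (unless ``leaky``, kept for comparison studies).
    For projections/rankers/RFE the feature count n minimizing the mean fold
    RMSE over 1..min(30, fold size - 2) is chosen and returned; SPA and CARS
    size their subsets internally per fold and return None (the final count
    comes from the full-calibration fit).  Reported metrics are fold means;
    each fold's RPD uses that fold's measured-value SD.
    """
    X_cal = np.asarray(X_cal, dtype=float)
    y_cal = np.asarray(y_cal, dtype=float)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(kf.split(X_cal))
    method = spec.select

    leaky_pre = leaky_sel = None
    if leaky:
        leaky_pre = Preprocessor(spec.preprocess, **spec.preprocess_params).fit(
            X_cal, y_cal, wavelengths
        )
        F_all = leaky_pre.transform(X_cal)
        if method not in N_SEARCHED_METHODS:
            leaky_sel = fit_selector(
                method, F_all, y_cal, seed=spec.seed, **spec.select_params
            )

    if method in N_SEARCHED_METHODS:
        if isinstance(spec.n, int):
            n_grid = [spec.n]
        else:
            n_max = min(N_SEARCH_CAP, min(tr.size for tr, _ in splits) - 2, X_cal.shape[1])
            n_grid = list(range(1, n_max + 1))
        fold_metrics: list[list[MetricSet]] = [[] for _ in n_grid]
        for tr, va in splits:
            if leaky:
                Ftr, Fva = F_all[tr], F_all[va]
            else:
                pre = Preprocessor(spec.preprocess, **spec.preprocess_params).fit(
                    X_cal[tr], y_cal[tr], wavelengths
                )
                Ftr, Fva = pre.transform(X_cal[tr]), pre.transform(X_cal[va])
            take = _fold_nested_features(spec, Ftr, y_cal[tr], Fva, max(n_grid))
            for gi, n in enumerate(n_grid):
                Gtr, Gva = take(n)
                model = ols_fit(Gtr, y_cal[tr])
                fold_metrics[gi].append(compute_metrics(y_cal[va], ols_predict(model, Gva)))
        means = [_mean_metrics(ms) for ms in fold_metrics]
        gi = int(np.argmin([m.rmse for m in means]))  # ties -> smaller n
        return means[gi], n_grid[gi]

    per_fold: list[MetricSet] = []
    for tr, va in splits:
        if leaky:
            Ftr, Fva = F_all[tr], F_all[va]
            sel = leaky_sel
        else:
            pre = Preprocessor(spec.preprocess, **spec.preprocess_params).fit(
                X_cal[tr], y_cal[tr], wavelengths
            )
            Ftr, Fva = pre.transform(X_cal[tr]), pre.transform(X_cal[va])
            sel = fit_selector(method, Ftr, y_cal[tr], seed=spec.seed, **spec.select_params)
        Gtr, Gva = apply_selector(sel, Ftr), apply_selector(sel, Fva)
        model = ols_fit(Gtr, y_cal[tr])
        per_fold.append(compute_metrics(y_cal[va], ols_predict(model, Gva)))
    return _mean_metrics(per_fold), None


@dataclass
class FittedPipeline:
    """A pre-processor, selector and OLS model fitted on calibration rows."""

    spec: PipelineSpec
    preprocessor: Preprocessor
    selector: Selector
    ols: OlsModel

    def predict(self, X: np.ndarray) -> np.ndarray:
        F = self.preprocessor.transform(np.asarray(X, dtype=float))
        return ols_predict(self.ols, apply_selector(self.selector, F))


def fit_pipeline(
    spec: PipelineSpec,
    X: np.ndarray,
    y: np.ndarray,
    wavelengths: np.ndarray,
    n: int | None = None,
    cv_folds: int = 5,
    cv_seed: int = 0,
) -> FittedPipeline:
    """Fit the full pipeline on the given rows.

    For n-searched methods the feature count is (in order of precedence)
    the ``n`` argument, a fixed integer in the spec, or the count chosen by
    an internal CV run on these rows.
    """
    pre = Preprocessor(spec.preprocess, **spec.preprocess_params).fit(X, y, wavelengths)
    F = pre.transform(X)
    method = spec.select
    if method in N_SEARCHED_METHODS:
        if n is None:
            if isinstance(spec.n, int):
                n = spec.n
            else:
                _, n = cv_evaluate(spec, X, y, wavelengths, folds=cv_folds, seed=cv_seed)
        sel = fit_selector(method, F, y, n=n, seed=spec.seed, **spec.select_params)
    else:
        sel = fit_selector(method, F, y, seed=spec.seed, **spec.select_params)
    model = ols_fit(apply_selector(sel, F), y)
    return FittedPipeline(spec, pre, sel, model)


def evaluate_pipeline(
    spec: PipelineSpec,
    dataset: SpectralDataset,
    split: SplitResult,
    folds: int = 5,
    seed: int = 0,
) -> ResultRow:
    """Six-metric evaluation of one recipe against one SPXY split.

    The calibration triple is the CV fold mean; the prediction triple comes
    from a full-calibration fit applied once to the prediction rows.  Any
    numerical failure is captured in the row (failed + reason) rather than
    raised, mirroring how degenerate grid cells are reported.
    """
    X, y, wl = dataset.reflectance, dataset.ssc, dataset.wavelengths
    Xc, yc = X[split.cal_idx], y[split.cal_idx]
    Xp, yp = X[split.pred_idx], y[split.pred_idx]
    try:
        cal_metrics, chosen_n = cv_evaluate(spec, Xc, yc, wl, folds=folds, seed=seed)
        if not all(np.isfinite([cal_metrics.rmse, cal_metrics.mape])):
            raise ArithmeticError("non-finite cross-validation metrics")
        pipe = fit_pipeline(spec, Xc, yc, wl, n=chosen_n, cv_folds=folds, cv_seed=seed)
        y_hat = pipe.predict(Xp)
        if not np.all(np.isfinite(y_hat)):
            raise ArithmeticError("non-finite predictions on the prediction set")
        pred_metrics = compute_metrics(yp, y_hat)
    except (ValueError, ArithmeticError, np.linalg.LinAlgError) as exc:
        return ResultRow(spec.preprocess, spec.select, None, failed=True, reason=str(exc))
    n_report = chosen_n
    if n_report is None and spec.select != "none":
        n_report = pipe.selector.n_features
    return ResultRow(
        spec.preprocess,
        spec.select,
        n_report,
        cal_metrics.rmse,
        cal_metrics.mape,
        cal_metrics.rpd,
        pred_metrics.rmse,
        pred_metrics.mape,
        pred_metrics.rpd,
    )
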