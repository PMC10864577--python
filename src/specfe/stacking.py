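"""Two-base stacked generalization with an OLS meta-model.

Two pipelines (by default detrend+CARS and Savitzky-Golay+CARS, the usual
"best in calibration" / "best in prediction" pair) are combined by a linear
meta-model.  To avoid the refitting bias that stacking is meant to cure,
the meta-model is trained on *out-of-fold* base predictions: a shared
seeded 5-fold partition of the calibration set produces, for every
calibration row, a base prediction from a fit that never saw that row.
The base pipelines are then refitted on the full calibration set for use
at prediction time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import KFold

from .model_eval import FittedPipeline, OlsModel, PipelineSpec, fit_pipeline, ols_fit, ols_predict

__all__ = ["StackModel", "StackingBaseError", "DEFAULT_BASE_SPECS", "stack_fit", "stack_predict"]

DEFAULT_BASE_SPECS = (
    PipelineSpec(preprocess="dc", select="cars"),
    PipelineSpec(preprocess="sg", select="cars"),
)


class StackingBaseError(RuntimeError):
    """A base pipeline failed while building out-of-fold predictions."""


@dataclass
class StackModel:
    """Fitted stack: base pipelines (full-calibration fits) + OLS meta-model."""

    base_specs: tuple[PipelineSpec, ...]
    base_fits: tuple[FittedPipeline, ...]
    meta: OlsModel


def stack_fit(
    base_specs,
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    wavelengths: np.ndarray,
    folds: int = 5,
    seed: int = 0,
) -> StackModel:
    """Fit the stack on calibration rows only.

    The same seeded fold partition is shared across bases; the meta OLS is
    fitted on the n_cal x n_bases out-of-fold prediction matrix (minimum-
    norm, so identical bases are handled).  Deterministic for a fixed seed.
    """
    base_specs = tuple(base_specs)
    if len(base_specs) < 2:
        raise ValueError("need at least 2 base specs")
    X_cal = np.asarray(X_cal, dtype=float)
    y_cal = np.asarray(y_cal, dtype=float)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(kf.split(X_cal))
    Z = np.empty((y_cal.size, len(base_specs)))
    for b, spec in enumerate(base_specs):
        for tr, va in splits:
            try:
                pipe = fit_pipeline(spec, X_cal[tr], y_cal[tr], wavelengths, cv_seed=seed)
                Z[va, b] = pipe.predict(X_cal[va])
            except Exception as exc:
                raise StackingBaseError(f"base {spec.name()!r} failed on a fold: {exc}") from exc
        if not np.all(np.isfinite(Z[:, b])):
            raise StackingBaseError(f"base {spec.name()!r} produced non-finite predictions")
    meta = ols_fit(Z, y_cal)
    fits = []
    for spec in base_specs:
        try:
            fits.append(fit_pipeline(spec, X_cal, y_cal, wavelengths, cv_seed=seed))
        except Exception as exc:
            raise StackingBaseError(f"base {spec.name()!r} failed on the full set: {exc}") from exc
    return StackModel(base_specs, tuple(fits), meta)


def stack_predict(model: StackModel, X_new: np.ndarray) -> np.ndarray:
    """Combine base predictions on new spectra through the meta-model."""
    X_new = np.asarray(X_new, dtype=float)
    Z = np.column_stack([fit.predict(X_new) for fit in model.base_fits])
    return ols_predict(model.meta, Z)
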