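"""Spectral pre-processing: SNV, polynomial detrend, Savitzky-Golay, DOSC.

All four transforms preserve the matrix shape (n spectra x p wavelengths).
SNV, detrend and SG are per-spectrum operations with no fitted state; DOSC
(direct orthogonal signal correction) learns from a calibration set the
spectral subspace uncorrelated with the response and must be applied to new
spectra with the calibration-fitted parameters, so it exposes a fit/apply
pair.  :class:`Preprocessor` wraps the five options (including ``none``)
behind one fit/transform surface for pipeline code.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

__all__ = [
    "DegenerateSpectrumError",
    "DoscModel",
    "snv",
    "detrend",
    "sg_smooth",
    "dosc_fit",
    "dosc_apply",
    "Preprocessor",
    "PREPROCESS_METHODS",
]

PREPROCESS_METHODS = ("none", "snv", "dosc", "dc", "sg")


class DegenerateSpectrumError(ValueError):
    """Raised when a spectrum cannot be transformed (e.g. constant row)."""


def snv(X: np.ndarray) -> np.ndarray:
    """Standard normal variate: standardize each spectrum to mean 0, SD 1.

    Removes per-sample multiplicative scatter and additive offset.  Uses
    the sample standard deviation (denominator p-1).  Idempotent, and
    invariant to the row-wise affine map ``a*x + b`` for a > 0.
    """
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=1, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise DegenerateSpectrumError(
            f"constant spectrum (zero variance) at row(s) {bad.tolist()}"
        )
    return (X - X.mean(axis=1, keepdims=True)) / sd[:, None]


def detrend(X: np.ndarray, wavelengths: np.ndarray, degree: int = 1) -> np.ndarray:
    """Subtract a per-spectrum least-squares polynomial trend in wavelength.

    The residual of each row is orthogonal to the polynomial basis, so the
    transform exactly annihilates planted baselines of the given degree and
    is idempotent.
    """
    X = np.asarray(X, dtype=float)
    wavelengths = np.asarray(wavelengths, dtype=float)
    if degree < 0:
        raise ValueError("degree must be non-negative")
    p = X.shape[1]
    if degree >= p:
        raise ValueError("degree must be smaller than the number of wavelengths")
    # shared basis across rows: scale wavelength to [-1, 1] for conditioning
    u = 2.0 * (wavelengths - wavelengths[0]) / (wavelengths[-1] - wavelengths[0]) - 1.0
    V = np.polynomial.polynomial.polyvander(u, degree)
    Q, _ = np.linalg.qr(V)
    return X - (X @ Q) @ Q.T


def sg_smooth(X: np.ndarray, window: int = 11, polyorder: int = 2) -> np.ndarray:
    """Savitzky-Golay smoothing of each spectrum.

    Weighted polynomial regression in a moving window; edges are handled by
    evaluating the boundary polynomial fits (``mode='interp'``).
    """
    X = np.asarray(X, dtype=float)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if polyorder >= window:
        raise ValueError("polyorder must be smaller than window")
    if window > X.shape[1]:
        raise ValueError("window exceeds the number of wavelengths")
    return savgol_filter(X, window_length=window, polyorder=polyorder, axis=1, mode="interp")


@dataclass
class DoscModel:
    """Fitted direct orthogonal signal correction.

    ``weights`` maps a centered spectrum to the scores of the removed
    components; ``loadings`` reconstructs the removed spectral structure
    from those scores.  Training scores are orthogonal to the centered
    response by construction.
    """

    n_osc: int
    column_means: np.ndarray
    y_mean: float
    weights: np.ndarray  # (p, n_osc)
    loadings: np.ndarray  # (p, n_osc)


def dosc_fit(X: np.ndarray, y: np.ndarray, n_osc: int = 1) -> DoscModel:
    """Fit DOSC: remove the leading spectral variation orthogonal to y.

    Algorithm (direct orthogonal signal correction): center X and y;
    anti-project X off y to obtain the part of X with zero covariance with
    the response; take the leading principal-component score vector of that
    part; compute its loading against X and a minimum-norm weight vector so
    the score can be reproduced from new spectra; deflate and repeat for
    ``n_osc`` components.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if n_osc < 1:
        raise ValueError("n_osc must be at least 1")
    n = X.shape[0]
    if n <= n_osc + 1:
        raise ValueError("need more than n_osc + 1 samples")
    if np.ptp(y) == 0:
        raise ValueError("y is constant; DOSC requires a varying response")
    col_means = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc0 = X - col_means
    yc = y - y_mean
    Xd = Xc0.copy()
    weights = np.zeros((X.shape[1], n_osc))
    loadings = np.zeros((X.shape[1], n_osc))
    for k in range(n_osc):
        # part of the (deflated) spectra with zero covariance with y
        Z = Xd - np.outer(yc, yc @ Xd) / (yc @ yc)
        U, s, Vt = np.linalg.svd(Z, full_matrices=False)
        t = U[:, 0] * s[0]  # leading PC score vector of Z
        tt = t @ t
        # nothing orthogonal to remove (up to floating-point dust)
        if s[0] <= 1e-10 * np.linalg.norm(Xc0):
            break
        loadings[:, k] = (Xd.T @ t) / tt
        # minimum-norm weights reproduce t from the *original* centered X,
        # so one joint application corrects new spectra for all components
        weights[:, k] = np.linalg.lstsq(Xc0, t, rcond=None)[0]
        Xd = Xd - np.outer(t, loadings[:, k])
    return DoscModel(n_osc, col_means, y_mean, weights, loadings)


def dosc_apply(model: DoscModel, X: np.ndarray) -> np.ndarray:
    """Remove the fitted orthogonal components from (possibly new) spectra."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.column_means.size:
        raise ValueError("column count does not match the fitted model")
    Xc = X - model.column_means
    scores = Xc @ model.weights
    return Xc - scores @ model.loadings.T + model.column_means


class Preprocessor:
    """Uniform fit/transform wrapper over the five pre-processing options.

    ``none``, ``snv``, ``dc`` (detrend) and ``sg`` are stateless per-spectrum
    transforms; ``dosc`` fits on calibration spectra and their response.
    """

    def __init__(self, method: str = "none", **params):
        if method not in PREPROCESS_METHODS:
            raise ValueError(f"unknown pre-processing method {method!r}")
        self.method = method
        self.params = params
        self._dosc: DoscModel | None = None
        self._wavelengths: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray | None, wavelengths: np.ndarray) -> "Preprocessor":
        self._wavelengths = np.asarray(wavelengths, dtype=float)
        if self.method == "dosc":
            if y is None:
                raise ValueError("DOSC requires the response at fit time")
            self._dosc = dosc_fit(X, y, n_osc=int(self.params.get("n_osc", 1)))
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.method == "none":
            return np.asarray(X, dtype=float)
        if self.method == "snv":
            return snv(X)
        if self.method == "dc":
            if self._wavelengths is None:
                raise ValueError("detrend requires fit() to record wavelengths")
            return detrend(X, self._wavelengths, degree=int(self.params.get("degree", 1)))
        if self.method == "sg":
            return sg_smooth(
                X,
                window=int(self.params.get("window", 11)),
                polyorder=int(self.params.get("polyorder", 2)),
            )
        if self._dosc is None:
            raise ValueError("DOSC preprocessor is not fitted")
        return dosc_apply(self._dosc, X)
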