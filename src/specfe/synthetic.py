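"""Synthetic Vis-NIR spectra with a known soluble-solids signal.

Real fruit spectra in the 450-1000 nm range are a smooth continuum with
Gaussian-shaped absorption dips whose depths track chemistry (sugar, water),
corrupted by multiplicative scatter, additive baseline drift and sensor
noise.  This module generates datasets with exactly that structure, with
the informative wavelengths planted at known positions so that feature
selectors can be validated against ground truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SpectralDataset",
    "GeneratorConfig",
    "generate_dataset",
    "apply_disturbances",
    "write_spectra_csv",
    "write_truth_json",
]


@dataclass
class SpectralDataset:
    """A set of per-sample reflectance spectra with matched SSC values.

    Attributes
    ----------
    sample_ids : list of str
        Opaque identifiers, one per sample.
    wavelengths : ndarray, shape (p,)
        Strictly ascending wavelength grid in nm, within [450, 1000].
    reflectance : ndarray, shape (n, p)
        Unitless reflectance factors; all values finite.
    ssc : ndarray, shape (n,)
        Soluble solids content in % Brix; strictly positive (the relative
        error metric divides by each measured value).
    """

    sample_ids: list[str]
    wavelengths: np.ndarray
    reflectance: np.ndarray
    ssc: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        self.ssc = np.asarray(self.ssc, dtype=float)
        self.validate()

    def validate(self) -> None:
        n, p = self.reflectance.shape
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match reflectance rows")
        if self.wavelengths.shape != (p,):
            raise ValueError("wavelength count does not match reflectance columns")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly ascending")
        if self.wavelengths[0] < 450.0 or self.wavelengths[-1] > 1000.0:
            raise ValueError("wavelengths must lie within [450, 1000] nm")
        if not np.all(np.isfinite(self.reflectance)):
            raise ValueError("reflectance contains non-finite values")
        if self.ssc.shape != (n,):
            raise ValueError("ssc length does not match sample count")
        if not np.all(np.isfinite(self.ssc)) or np.any(self.ssc <= 0):
            raise ValueError("ssc values must be finite and strictly positive")

    @property
    def n_samples(self) -> int:
        return self.reflectance.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.reflectance.shape[1]


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic spectra generator.

    The defaults emulate the study conditions this package targets: 116
    fruit, SSC ~ N(13.148, 1.025^2) % Brix truncated to positive values, a
    450-1000 nm grid at 2.5 nm spacing (221 bands), low reflectance
    variance below 500 nm and high variance above 750 nm, and three
    SSC-informative absorption bands (680, 840, 960 nm) plus one
    uninformative band at 600 nm.

    ``band_couplings`` are the linear coefficients of each band's absorption
    depth on the standardized SSC; a zero coupling makes the band pure
    structure with no signal.  ``chem_noise_sd`` is the SD (in standardized
    SSC units) of a per-sample latent deviation between refractometric SSC
    and the chemistry the spectrum actually expresses: band depths couple to
    ``z + eta`` rather than to ``z`` exactly, which caps the attainable
    prediction R^2 at 1/(1 + chem_noise_sd^2) no matter how good the model
    is (= 0.5, i.e. RPD ~ 1.4, at the default 1.0).  Disturbances are
    per-sample multiplicative gain (lognormal, so reflectance stays
    positive), a per-sample linear baseline drift in normalized wavelength,
    and i.i.d. additive noise.
    """

    n_samples: int = 116
    wavelength_start: float = 450.0
    wavelength_stop: float = 1000.0
    wavelength_step: float = 2.5
    ssc_mean: float = 13.148
    ssc_sd: float = 1.025
    band_centers: tuple[float, ...] = (600.0, 680.0, 840.0, 960.0)
    band_widths: tuple[float, ...] = (18.0, 15.0, 25.0, 20.0)
    band_depths: tuple[float, ...] = (0.05, 0.06, 0.09, 0.07)
    band_couplings: tuple[float, ...] = (0.0, 0.010, 0.010, 0.010)
    informative_bands: tuple[float, ...] | None = None
    chem_noise_sd: float = 1.0
    gain_sd: float = 0.08
    drift_slope_sd: float = 0.04
    drift_offset_sd: float = 0.02
    noise_sd: float = 0.01
    low_wavelength_damping: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        if self.wavelength_step <= 0:
            raise ValueError("wavelength_step must be positive")
        lens = {
            len(self.band_centers),
            len(self.band_widths),
            len(self.band_depths),
            len(self.band_couplings),
        }
        if len(lens) != 1:
            raise ValueError("band parameter tuples must have equal lengths")
        for name in (
            "ssc_sd",
            "chem_noise_sd",
            "gain_sd",
            "drift_slope_sd",
            "drift_offset_sd",
            "noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.low_wavelength_damping < 1.0:
            raise ValueError("low_wavelength_damping must be in [0, 1)")
        inf = self.informative()
        if any(c not in self.band_centers for c in inf):
            raise ValueError("informative_bands must be a subset of band_centers")

    def informative(self) -> tuple[float, ...]:
        """Band centers flagged as carrying true SSC signal."""
        if self.informative_bands is not None:
            return tuple(self.informative_bands)
        return tuple(
            c for c, k in zip(self.band_centers, self.band_couplings) if k != 0.0
        )

    def grid(self) -> np.ndarray:
        """The wavelength grid in nm implied by start/stop/step."""
        n = int(np.floor((self.wavelength_stop - self.wavelength_start) / self.wavelength_step)) + 1
        return self.wavelength_start + self.wavelength_step * np.arange(n)


def _continuum(wavelengths: np.ndarray, damping: float) -> np.ndarray:
    # Logistic ramp: dim below 500 nm, rising through the red edge to a
    # plateau near 780 nm.  The damping factor rolls off smoothly at 500 nm
    # so the spectrum has no step discontinuity.
    base = 0.08 + 0.55 / (1.0 + np.exp(-(wavelengths - 640.0) / 60.0))
    roll = 1.0 - damping / (1.0 + np.exp((wavelengths - 500.0) / 8.0))
    return base * roll


def _clean_spectra(latent: np.ndarray, config: GeneratorConfig) -> np.ndarray:
    wl = config.grid()
    cont = _continuum(wl, config.low_wavelength_damping)
    spectra = np.tile(cont, (latent.size, 1))
    for c, w, d, k in zip(
        config.band_centers, config.band_widths, config.band_depths, config.band_couplings
    ):
        shape = np.exp(-0.5 * ((wl - c) / w) ** 2)
        depth = d + k * latent  # per-sample absorption depth, linear in z + eta
        spectra -= np.outer(depth, shape)
    return spectra


def apply_disturbances(
    clean: np.ndarray,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Apply per-sample scatter gain, linear baseline drift and noise.

    Each row i becomes ``gain_i * clean_i + offset_i + slope_i * u + noise``
    where ``u`` is the wavelength normalized to [0, 1], ``gain_i`` is
    lognormal(0, gain_sd) and offset/slope/noise are normal.  Deterministic
    for a fixed seed (``config.seed`` when no generator is passed).
    """
    clean = np.asarray(clean, dtype=float)
    if not np.all(np.isfinite(clean)):
        raise ValueError("clean spectra must be finite")
    n, p = clean.shape
    wl = config.grid()
    if p != wl.size:
        raise ValueError("column count does not match the configured wavelength grid")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    u = (wl - wl[0]) / (wl[-1] - wl[0])
    gain = rng.lognormal(mean=0.0, sigma=config.gain_sd, size=n) if config.gain_sd > 0 else np.ones(n)
    offset = rng.normal(0.0, config.drift_offset_sd, size=n) if config.drift_offset_sd > 0 else np.zeros(n)
    slope = rng.normal(0.0, config.drift_slope_sd, size=n) if config.drift_slope_sd > 0 else np.zeros(n)
    noise = rng.normal(0.0, config.noise_sd, size=(n, p)) if config.noise_sd > 0 else 0.0
    return gain[:, None] * clean + offset[:, None] + np.outer(slope, u) + noise


def generate_dataset(config: GeneratorConfig) -> SpectralDataset:
    """Draw a synthetic dataset from the configured generative model.

    SSC is normal(ssc_mean, ssc_sd) truncated to (0, inf) by redrawing;
    clean spectra are a smooth continuum minus Gaussian absorption bands
    whose depths are linear in standardized SSC plus the latent chemistry
    deviation; disturbances are then applied via
    :func:`apply_disturbances`.  Byte-identical output for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    ssc = rng.normal(config.ssc_mean, config.ssc_sd, size=n)
    while np.any(ssc <= 0):  # truncation to positive Brix by redrawing
        bad = ssc <= 0
        ssc[bad] = rng.normal(config.ssc_mean, config.ssc_sd, size=int(bad.sum()))
    z = (ssc - config.ssc_mean) / config.ssc_sd
    eta = rng.normal(0.0, config.chem_noise_sd, size=n) if config.chem_noise_sd > 0 else 0.0
    clean = _clean_spectra(z + eta, config)
    reflectance = apply_disturbances(clean, config, rng=rng)
    ids = [f"S{i + 1:03d}" for i in range(n)]
    return SpectralDataset(ids, config.grid(), reflectance, ssc)


def write_spectra_csv(dataset: SpectralDataset, path) -> None:
    """Write the wide CSV layout: ``sample_id,ssc,<nm>,<nm>,...``."""
    df = pd.DataFrame(
        dataset.reflectance,
        columns=[format(w, "g") for w in dataset.wavelengths],
    )
    df.insert(0, "ssc", dataset.ssc)
    df.insert(0, "sample_id", dataset.sample_ids)
    df.to_csv(path, index=False)


def write_truth_json(config: GeneratorConfig, path) -> None:
    """Write the ground-truth sidecar: informative centers, grid indices, config echo."""
    wl = config.grid()
    centers = list(config.informative())
    idx = [int(np.argmin(np.abs(wl - c))) for c in centers]
    payload = {
        "informative_band_centers_nm": centers,
        "informative_grid_indices": idx,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
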