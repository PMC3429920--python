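"""Spectral preprocessing: region restriction, Savitzky–Golay derivative, centering.

The preprocessing chain applied before any calibration is fixed:

    absorbance -> restrict_region -> sg_filter (optional) -> mean centering

Region restriction discards the noisy grid edges (by default everything
outside 500–2200 nm, where instrument noise rises sharply).  The
Savitzky–Golay (SG) first derivative removes additive baseline offsets by
fitting a local polynomial in a sliding window and taking its analytic
first derivative; it is the standard scatter correction in NIR chemometrics.
Derivatives are expressed per nm so results do not depend on grid spacing.
The half-window of points at each grid edge, where the SG window is not
fully supported, is dropped rather than extrapolated.

Each classification task uses a named preset: a 45-point window for species
separation, a 35-point window for age grading and Wolbachia detection, and
no derivative at all for sex classification (where it was found to hurt).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .errors import ConfigError, ValidationError
from .spectra_io import SpectrumSet


@dataclass(frozen=True)
class PreprocessConfig:
    """Preprocessing settings for one calibration task.

    Parameters
    ----------
    region_lo_nm, region_hi_nm : float
        Closed wavelength interval retained before analysis.
    sg_window : int or None
        Odd SG window length in points; ``None`` disables the derivative.
    sg_polyorder : int
        Degree of the local polynomial (2 by default).
    sg_deriv : int
        Derivative order (1; higher orders are out of scope).
    center : bool
        Mean-center using the calibration mean (always on in the standard
        chain; exposed for experiments).
    """

    region_lo_nm: float = 500.0
    region_hi_nm: float = 2200.0
    sg_window: int | None = None
    sg_polyorder: int = 2
    sg_deriv: int = 1
    center: bool = True

    def __post_init__(self) -> None:
        if self.region_lo_nm >= self.region_hi_nm:
            raise ConfigError("region_lo_nm must be below region_hi_nm")
        if self.sg_window is not None:
            w = int(self.sg_window)
            if w % 2 == 0 or w < self.sg_polyorder + 2:
                raise ConfigError(
                    f"sg_window must be odd and >= polyorder + 2, got {w}"
                )
        if self.sg_deriv != 1:
            raise ConfigError("only first-derivative SG filtering is supported")

    @property
    def sg_enabled(self) -> bool:
        return self.sg_window is not None

    @property
    def fingerprint(self) -> str:
        """Stable short hash identifying this configuration."""
        key = (
            f"{self.region_lo_nm:.6g}|{self.region_hi_nm:.6g}|{self.sg_window}"
            f"|{self.sg_polyorder}|{self.sg_deriv}|{self.center}"
        )
        return hashlib.sha256(key.encode()).hexdigest()[:16]


#: Per-task presets.  Sex classification deliberately skips the derivative.
PRESETS: dict[str, PreprocessConfig] = {
    "species": PreprocessConfig(sg_window=45),
    "gender": PreprocessConfig(sg_window=None),
    "age": PreprocessConfig(sg_window=35),
    "wolbachia": PreprocessConfig(sg_window=35),
}


def restrict_region(s: SpectrumSet, cfg: PreprocessConfig) -> SpectrumSet:
    """Keep wavelengths in the closed interval [region_lo_nm, region_hi_nm]."""
    mask = (s.wavelengths >= cfg.region_lo_nm) & (s.wavelengths <= cfg.region_hi_nm)
    if not mask.any():
        raise ValidationError(
            f"region [{cfg.region_lo_nm}, {cfg.region_hi_nm}] nm does not "
            "overlap the wavelength grid"
        )
    return s.with_values(s.values[:, mask], wavelengths=s.wavelengths[mask])


def sg_filter(s: SpectrumSet, cfg: PreprocessConfig) -> SpectrumSet:
    """Savitzky–Golay first derivative, per nm, with edge points dropped.

    Every retained output point equals the analytic first derivative of the
    least-squares polynomial of degree ``sg_polyorder`` fitted to the
    ``sg_window`` points centred on it.
    """
    if not cfg.sg_enabled:
        raise ConfigError("sg_filter called with sg_window=None")
    w = int(cfg.sg_window)
    if s.n_wavelengths < w:
        raise ConfigError(
            f"SG window of {w} points exceeds grid length {s.n_wavelengths}"
        )
    deriv = savgol_filter(
        s.values, window_length=w, polyorder=cfg.sg_polyorder,
        deriv=cfg.sg_deriv, delta=s.spacing, axis=1, mode="interp",
    )
    h = (w - 1) // 2
    return s.with_values(deriv[:, h:-h], wavelengths=s.wavelengths[h:-h])


def fit_center(s: SpectrumSet) -> tuple[SpectrumSet, np.ndarray]:
    """Center a calibration set on its own mean spectrum; returns both."""
    if s.n_samples < 2:
        raise ValidationError("centering needs at least 2 samples")
    mean = s.values.mean(axis=0)
    return s.with_values(s.values - mean), mean


def apply_center(s: SpectrumSet, mean_spectrum: np.ndarray) -> SpectrumSet:
    """Center a test set on a previously fitted calibration mean."""
    mean_spectrum = np.asarray(mean_spectrum, dtype=float)
    if mean_spectrum.shape != (s.n_wavelengths,):
        raise ValidationError(
            f"mean spectrum length {mean_spectrum.size} does not match "
            f"grid length {s.n_wavelengths}"
        )
    return s.with_values(s.values - mean_spectrum)


def preprocess(s: SpectrumSet, cfg: PreprocessConfig) -> SpectrumSet:
    """Apply region restriction then (optionally) the SG derivative.

    Centering is not applied here: the calibration mean is owned by the
    fitted model so that independent spectra are always centered by the
    calibration statistics, never their own.
    """
    if s.units != "absorbance":
        raise ValidationError(
            "preprocessing expects absorbance (log 1/R); convert reflectance first"
        )
    out = restrict_region(s, cfg)
    if cfg.sg_enabled:
        out = sg_filter(out, cfg)
    return out
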