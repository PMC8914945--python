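"""Spectral processing chain for L/S-ratio calibration spectra.

The chain mirrors standard ATR-FTIR practice for lipid spectra in
dichloromethane: truncate to the informative window (830-3500 cm^-1),
single-point baseline offset correction at 2500 cm^-1, "zapping" of the CO2
(2150-2430 cm^-1) and strong-solvent (1190-1310 cm^-1) regions by replacing
them with Gaussian noise at the instrument noise floor, and optionally a
combined Savitzky-Golay smoothing / second-derivative transform (window 15,
polynomial order 3) that removes additive and linear baseline effects while
preserving Beer-Lambert linearity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import savgol_filter

from .errors import (
    EmptyRangeError,
    InvalidGridError,
    InvalidParameterError,
    ConfigurationError,
)
from .synthetic import Spectrum

__all__ = [
    "PreprocessConfig",
    "truncate",
    "baseline_offset",
    "estimate_noise_sd",
    "zap_regions",
    "second_derivative",
    "preprocess_pipeline",
    "preprocess_dataset",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the processing chain.

    ``derivative_order`` 0 produces the "original" dataset (baselined
    absorbance), 2 the "second derivative" dataset.
    """

    truncate_lo: float = 830.0
    truncate_hi: float = 3500.0
    baseline_anchor: float = 2500.0
    zap_regions: tuple[tuple[float, float], ...] = ((2150.0, 2430.0), (1190.0, 1310.0))
    noise_estimation_region: tuple[float, float] = (2450.0, 2640.0)
    zap_noise_sd: float = 4.0e-5
    zap_seed: int = 0
    sg_window: int = 15
    sg_polyorder: int = 3
    derivative_order: int = 0

    def __post_init__(self) -> None:
        if self.truncate_lo >= self.truncate_hi:
            raise ConfigurationError("truncate_lo must be < truncate_hi")
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_polyorder:
            raise ConfigurationError("sg_window must be odd and > sg_polyorder")
        if self.derivative_order not in (0, 2):
            raise ConfigurationError("derivative_order must be 0 or 2")
        for lo, hi in self.zap_regions:
            if not (self.truncate_lo <= lo < hi <= self.truncate_hi):
                raise ConfigurationError(
                    f"zap region ({lo}, {hi}) outside truncation bounds"
                )


def truncate(spectrum: Spectrum, lo: float, hi: float) -> Spectrum:
    """Keep only grid points with lo <= nu <= hi (closed interval)."""
    mask = (spectrum.wavenumbers >= lo) & (spectrum.wavenumbers <= hi)
    if not mask.any():
        raise EmptyRangeError(f"no grid points in [{lo}, {hi}]")
    out = spectrum.copy()
    out.wavenumbers = spectrum.wavenumbers[mask]
    out.absorbances = spectrum.absorbances[mask]
    return out


def baseline_offset(spectrum: Spectrum, anchor: float) -> Spectrum:
    """Subtract the absorbance at the grid point nearest the anchor wavenumber."""
    nu = spectrum.wavenumbers
    if anchor < nu[0] or anchor > nu[-1]:
        raise InvalidParameterError(
            f"anchor {anchor} outside grid range [{nu[0]}, {nu[-1]}]"
        )
    idx = int(np.argmin(np.abs(nu - anchor)))
    return spectrum.with_absorbances(spectrum.absorbances - spectrum.absorbances[idx])


def estimate_noise_sd(
    spectrum: Spectrum, region: tuple[float, float] = (2450.0, 2640.0)
) -> float:
    """Noise standard deviation from a signal-free window.

    The window is detrended with a best-fit straight line first, so a slowly
    varying baseline does not inflate the estimate; the result is the sample
    standard deviation of the residual.
    """
    lo, hi = region
    mask = (spectrum.wavenumbers >= lo) & (spectrum.wavenumbers <= hi)
    if mask.sum() < 10:
        raise InvalidParameterError(
            f"noise estimation region [{lo}, {hi}] has {int(mask.sum())} points (< 10)"
        )
    nu = spectrum.wavenumbers[mask]
    a = spectrum.absorbances[mask]
    coeffs = np.polyfit(nu, a, 1)
    resid = a - np.polyval(coeffs, nu)
    return float(np.std(resid, ddof=1))


def zap_regions(
    spectrum: Spectrum,
    regions: Sequence[tuple[float, float]],
    noise_sd: float,
    seed: int | np.random.Generator = 0,
) -> Spectrum:
    """Replace uninformative regions with N(0, noise_sd^2) draws.

    Points outside the regions are untouched (bitwise).  Reproducible for a
    fixed seed; a Generator may be passed to share a stream across spectra.
    """
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = spectrum.with_absorbances(spectrum.absorbances.copy())
    for lo, hi in regions:
        mask = (out.wavenumbers >= lo) & (out.wavenumbers <= hi)
        out.absorbances[mask] = rng.normal(0.0, noise_sd, int(mask.sum())) if noise_sd else 0.0
    return out


def second_derivative(spectrum: Spectrum, window: int = 15, polyorder: int = 3) -> Spectrum:
    """Savitzky-Golay second derivative (smoothing and differentiation in one pass).

    Output is in A.U. per (cm^-1)^2 on the same grid; edge points come from
    the polynomial fitted to the one-sided edge window, so the point count is
    preserved.
    """
    if window % 2 == 0 or window <= polyorder:
        raise InvalidParameterError("window must be odd and > polyorder")
    nu = spectrum.wavenumbers
    if nu.size < window:
        raise InvalidParameterError(f"spectrum length {nu.size} < window {window}")
    steps = np.diff(nu)
    if not np.allclose(steps, steps[0], rtol=1e-8, atol=1e-10):
        raise InvalidGridError("second derivative requires a uniform wavenumber grid")
    deriv = savgol_filter(
        spectrum.absorbances,
        window_length=window,
        polyorder=polyorder,
        deriv=2,
        delta=float(steps[0]),
        mode="interp",
    )
    return spectrum.with_absorbances(deriv)


def preprocess_pipeline(
    spectrum: Spectrum,
    config: PreprocessConfig,
    rng: np.random.Generator | None = None,
) -> Spectrum:
    """Apply truncate -> baseline offset -> zap -> (optional) second derivative.

    Passing an explicit ``rng`` shares one zap-noise stream across calls;
    otherwise the stream is seeded from ``config.zap_seed`` per call.
    """
    out = truncate(spectrum, config.truncate_lo, config.truncate_hi)
    out = baseline_offset(out, config.baseline_anchor)
    if config.zap_regions:
        out = zap_regions(
            out,
            config.zap_regions,
            config.zap_noise_sd,
            rng if rng is not None else config.zap_seed,
        )
    if config.derivative_order == 2:
        out = second_derivative(out, config.sg_window, config.sg_polyorder)
    return out


def preprocess_dataset(
    spectra: Sequence[Spectrum], config: PreprocessConfig
) -> list[Spectrum]:
    """Process a dataset with a single zap-noise stream seeded by the config."""
    rng = np.random.default_rng(config.zap_seed)
    return [preprocess_pipeline(sp, config, rng=rng) for sp in spectra]
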