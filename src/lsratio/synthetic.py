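"""Seeded synthetic ATR-FTIR spectra of DPPC/sphingomyelin mixtures in dichloromethane.

Real L/S-ratio calibration data are recorded as mid-IR absorbance spectra of
DPPC (the dominant lecithin species) and sphingomyelin (SM) dissolved in
dichloromethane (DCM). This module emulates the statistical structure of such
measurements so the calibration pipeline can be exercised without instrument
data: Beer-Lambert-linear component mixing, per-session detector gain and
background variation, negative DCM-vapor difference bands, rotational-
vibrational water-vapor interference in a subset of replicates, and white
instrument noise at the detector noise floor.

Concentrations are in mM, wavenumbers in cm^-1, absorbances in absorbance
units (A.U.).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .errors import ConfigurationError, InvalidParameterError

__all__ = [
    "PeakDef",
    "ComponentLibrary",
    "GeneratorConfig",
    "Spectrum",
    "default_library",
    "build_reference_spectrum",
    "simulate_measurement",
    "generate_dataset",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PeakDef:
    """One absorption band rendered as an analytic line shape.

    ``height_per_mM`` is the peak absorbance contributed per mM of the parent
    component (A.U./mM); for artifact peaks it is a unit-amplitude height
    (scaled by a per-measurement amplitude draw) and may be negative.
    """

    center: float
    fwhm: float
    height_per_mM: float
    shape: Literal["lorentzian", "gaussian"] = "lorentzian"

    def __post_init__(self) -> None:
        if self.center <= 0:
            raise InvalidParameterError(f"peak center must be > 0, got {self.center}")
        if self.fwhm <= 0:
            raise InvalidParameterError(f"peak fwhm must be > 0, got {self.fwhm}")
        if self.shape not in ("lorentzian", "gaussian"):
            raise InvalidParameterError(f"unknown peak shape {self.shape!r}")

    def profile(self, wavenumbers: np.ndarray) -> np.ndarray:
        """Line shape evaluated on a grid, including the height factor."""
        nu = np.asarray(wavenumbers, dtype=float)
        half = self.fwhm / 2.0
        if self.shape == "lorentzian":
            unit = 1.0 / (1.0 + ((nu - self.center) / half) ** 2)
        else:
            unit = np.exp(-4.0 * np.log(2.0) * ((nu - self.center) / self.fwhm) ** 2)
        return self.height_per_mM * unit


@dataclass(frozen=True)
class WaterVaporBand:
    """Dense narrow ro-vibrational lines within a spectral window.

    Line positions and signed relative strengths are fixed properties of the
    band (drawn once from ``line_seed``), mimicking the fixed positions of
    real water lines; only the overall amplitude varies between measurements.
    """

    lo: float = 1400.0
    hi: float = 1900.0
    line_density: float = 0.12  # lines per cm^-1
    fwhm: float = 4.0
    line_seed: int = 20220223

    def peaks(self) -> tuple[PeakDef, ...]:
        rng = np.random.default_rng(self.line_seed)
        n_lines = int(round(self.line_density * (self.hi - self.lo)))
        centers = np.sort(rng.uniform(self.lo, self.hi, n_lines))
        strengths = rng.uniform(0.3, 1.0, n_lines) * rng.choice([-1.0, 1.0], n_lines)
        return tuple(
            PeakDef(center=c, fwhm=self.fwhm, height_per_mM=s)
            for c, s in zip(centers, strengths)
        )


@dataclass(frozen=True)
class ComponentLibrary:
    """Peak parameterization of the two analytes and the solvent artifacts."""

    dppc_peaks: tuple[PeakDef, ...]
    sm_peaks: tuple[PeakDef, ...]
    dcm_vapor_peaks: tuple[PeakDef, ...]
    water_vapor_band: WaterVaporBand = field(default_factory=WaterVaporBand)

    def __post_init__(self) -> None:
        def has_peak(peaks: Sequence[PeakDef], center: float) -> bool:
            return any(abs(p.center - center) < 1.0 for p in peaks)

        def none_in(peaks: Sequence[PeakDef], lo: float, hi: float) -> bool:
            return not any(lo <= p.center <= hi for p in peaks)

        if not has_peak(self.dppc_peaks, 1734.0):
            raise ConfigurationError("DPPC library must include the 1734 cm^-1 carbonyl band")
        if not none_in(self.dppc_peaks, 1630.0, 1660.0):
            raise ConfigurationError("DPPC library must have no band in 1630-1660 cm^-1")
        if not has_peak(self.sm_peaks, 1646.0):
            raise ConfigurationError("SM library must include the 1646 cm^-1 amide I band")
        if not none_in(self.sm_peaks, 1720.0, 1745.0):
            raise ConfigurationError("SM library must have no band in 1720-1745 cm^-1")


def _band_fwhm(center: float) -> float:
    """Default linewidth by spectral region (typical condensed-phase values)."""
    if center >= 2800.0 or 1700.0 <= center <= 1760.0:
        return 20.0  # C-H stretch region and ester carbonyl
    if 1600.0 <= center <= 1700.0:
        return 30.0  # amide I
    return 25.0  # fingerprint region


def default_library() -> ComponentLibrary:
    """Component library with the tabulated DPPC and SM band positions.

    Peak heights are not published for these measurements; the strongest band
    of each analyte is set to 4e-3 A.U./mM so that a single spectrum at ~1 mM
    has SNR near 100:1 against the 4e-5 A.U. noise floor, with the remaining
    bands scaled 0.3-0.9 relative.
    """
    strongest = 4.0e-3

    def peak(center: float, rel: float, fwhm: float | None = None) -> PeakDef:
        return PeakDef(
            center=center,
            fwhm=_band_fwhm(center) if fwhm is None else fwhm,
            height_per_mM=rel * strongest,
        )

    dppc = (
        peak(2957.0, 0.50),   # CH3 asymmetric stretch
        peak(2926.0, 1.00),   # CH2 asymmetric stretch (strongest)
        peak(2854.0, 0.80),   # CH2 symmetric stretch
        peak(1734.0, 0.85),   # ester C=O stretch (discriminating band)
        peak(1467.0, 0.45),   # C-H bend
        peak(1172.0, 0.55),   # C-O stretch
        peak(1092.0, 0.60),   # PO2 stretch
        peak(1065.0, 0.50),   # phosphodiester C-O
        peak(966.0, 0.35),    # choline stretch
    )
    sm = (
        peak(2919.0, 1.00),   # CH2 asymmetric stretch (strongest)
        peak(2851.0, 0.80),   # CH2 symmetric stretch
        peak(1646.0, 0.55),   # amide I (discriminating band)
        peak(1468.0, 0.45),   # C-H bend
        peak(1090.0, 0.60),   # PO2 stretch
        peak(1060.0, 0.50),   # COH stretch
        peak(967.0, 0.35),    # choline stretch
    )
    # Negative difference bands from DCM vapor imbalance between background
    # and sample scans; unit heights, scaled by a per-measurement amplitude.
    dcm = tuple(
        PeakDef(center=c, fwhm=15.0, height_per_mM=-h)
        for c, h in ((3000.0, 0.7), (1600.0, 0.8), (1420.0, 1.0), (900.0, 0.9))
    )
    return ComponentLibrary(dppc_peaks=dppc, sm_peaks=sm, dcm_vapor_peaks=dcm)


@dataclass(frozen=True)
class GeneratorConfig:
    """Full parameterization of one synthetic measurement campaign.

    Defaults reproduce the study design: 10 measurement sessions totalling
    259 spectra, nine L/S ratios on a 1 mM SM basis, 6-18 successive scans
    per dispensed sample, and a 4e-5 A.U. instrument noise floor.
    """

    n_sessions: int = 10
    session_group_sizes: tuple[int, ...] = (31, 31, 31, 31, 31, 21, 21, 21, 21, 20)
    ls_ratios: tuple[float, ...] = (1.0, 1.7, 2.0, 2.1, 2.2, 2.3, 2.4, 2.7, 3.4)
    sm_concentration: float = 1.0
    replicates_per_sample: tuple[int, int] = (6, 18)
    noise_sd: float = 4.0e-5
    session_gain_sd: float = 0.001
    peak_jitter_sd: float = 0.3
    dcm_vapor_max: float = 2.0e-4
    water_vapor_max: float = 3.0e-4
    water_vapor_fraction: float = 0.3
    baseline_offset_sd: float = 5.0e-4
    baseline_slope_sd: float = 1.0e-7
    baseline_drift_sd: float = 6.0e-3
    baseline_drift_scale: float = 800.0
    baseline_texture_sd: float = 8.0e-4
    baseline_texture_scale: float = 300.0
    grid: tuple[float, float, float] = (600.0, 4000.0, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.session_group_sizes) != self.n_sessions:
            raise ConfigurationError(
                f"session_group_sizes has {len(self.session_group_sizes)} entries "
                f"for {self.n_sessions} sessions"
            )
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if any(r <= 0 for r in self.ls_ratios):
            raise ConfigurationError("all L/S ratios must be > 0")
        lo, hi = self.replicates_per_sample
        if not (1 <= lo <= hi):
            raise ConfigurationError(f"invalid replicate range ({lo}, {hi})")
        if any(size < lo for size in self.session_group_sizes):
            raise ConfigurationError(
                "each session group size must admit at least one full replicate run"
            )
        if not (0.0 <= self.water_vapor_fraction <= 1.0):
            raise ConfigurationError("water_vapor_fraction must be a probability")
        gmin, gmax, gstep = self.grid
        if not (gmin < gmax and gstep > 0):
            raise ConfigurationError(f"invalid grid specification {self.grid}")

    def wavenumbers(self) -> np.ndarray:
        gmin, gmax, gstep = self.grid
        n = int(round((gmax - gmin) / gstep)) + 1
        return gmin + gstep * np.arange(n)


@dataclass
class Spectrum:
    """One absorbance measurement with its acquisition metadata."""

    wavenumbers: np.ndarray
    absorbances: np.ndarray
    session_id: str = ""
    sample_id: str = ""
    replicate: int = 0
    true_dppc: float | None = None
    true_sm: float | None = None
    water_vapor: bool = False

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbances = np.asarray(self.absorbances, dtype=float)
        if self.wavenumbers.shape != self.absorbances.shape:
            raise InvalidParameterError(
                f"grid and absorbance lengths differ: "
                f"{self.wavenumbers.size} vs {self.absorbances.size}"
            )
        if self.wavenumbers.size > 1 and not np.all(np.diff(self.wavenumbers) > 0):
            raise InvalidParameterError("wavenumber grid must be strictly increasing")
        if not np.all(np.isfinite(self.absorbances)):
            raise InvalidParameterError("absorbances contain non-finite values")

    def with_absorbances(self, absorbances: np.ndarray) -> "Spectrum":
        """Copy with new absorbances, metadata preserved."""
        return replace(self, absorbances=np.asarray(absorbances, dtype=float))

    def copy(self) -> "Spectrum":
        return replace(
            self,
            wavenumbers=self.wavenumbers.copy(),
            absorbances=self.absorbances.copy(),
        )


# ---------------------------------------------------------------------------
# Spectrum synthesis
# ---------------------------------------------------------------------------

def build_reference_spectrum(
    peaks: Sequence[PeakDef], grid: np.ndarray, **metadata
) -> Spectrum:
    """Render a peak list as a unit-concentration absorbance spectrum.

    The absorbance at each grid point is the sum over peaks of
    ``height_per_mM * L(nu; center, fwhm)`` with ``L`` the unit-height line
    shape.  An empty peak list yields the zero spectrum.
    """
    nu = np.asarray(grid, dtype=float)
    total = np.zeros_like(nu)
    for p in peaks:
        total += p.profile(nu)
    return Spectrum(wavenumbers=nu, absorbances=total, **metadata)


@dataclass(frozen=True)
class SessionEffects:
    """Per-session instrument state: multiplicative detector gain."""

    gain: float = 1.0


@dataclass(frozen=True)
class ArtifactDraws:
    """Per-measurement background state drawn when the background is retaken."""

    baseline_offset: float = 0.0
    baseline_slope: float = 0.0  # A.U. per cm^-1, about the grid midpoint
    dcm_vapor_amplitude: float = 0.0
    water_vapor_amplitude: float = 0.0
    baseline_drift: np.ndarray | None = None  # smooth A.U. offset on the grid


def draw_baseline_drift(
    rng: np.random.Generator,
    grid: np.ndarray,
    sd: float,
    scale: float,
) -> np.ndarray:
    """Smooth random baseline on the grid (ATR background shape variation).

    A natural cubic spline through independent N(0, sd^2) control points
    spaced ``scale`` cm^-1 apart, modulated by a linear low-wavenumber
    envelope (ATR backgrounds grow toward longer wavelengths): smooth on the
    scale of hundreds of cm^-1, so it confounds absorbance-domain models but
    carries almost no second derivative relative to the sharp analyte bands.
    """
    if sd <= 0:
        return np.zeros_like(grid)
    from scipy.interpolate import CubicSpline

    knots = np.arange(grid[0] - scale, grid[-1] + 2 * scale, scale)
    values = rng.normal(0.0, sd, knots.size)
    envelope = ((grid[-1] - grid) / (grid[-1] - grid[0])) ** 3
    return envelope * CubicSpline(knots, values)(grid)


def draw_baseline_texture(
    rng: np.random.Generator,
    grid: np.ndarray,
    sd: float,
    scale: float,
) -> np.ndarray:
    """Finer-scale background texture, weighted toward low wavenumbers.

    ATR backgrounds are larger and less reproducible at longer wavelengths
    (lower wavenumber) because those wavelengths traverse a longer optical
    path in the sample medium; the texture amplitude is therefore modulated
    by ``((nu_max - nu)/(nu_max - nu_min))^3``, which keeps the high-
    wavenumber noise-estimation window essentially clean.
    """
    if sd <= 0:
        return np.zeros_like(grid)
    from scipy.interpolate import CubicSpline

    knots = np.arange(grid[0] - scale, grid[-1] + 2 * scale, scale)
    values = rng.normal(0.0, sd, knots.size)
    envelope = ((grid[-1] - grid) / (grid[-1] - grid[0])) ** 3
    return envelope * CubicSpline(knots, values)(grid)


def simulate_measurement(
    dppc: float,
    sm: float,
    library: ComponentLibrary,
    grid: np.ndarray,
    session_effects: SessionEffects | None = None,
    artifacts: ArtifactDraws | None = None,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    **metadata,
) -> Spectrum:
    """Synthesize one ATR-FTIR measurement.

    The absorbance model is Beer-Lambert mixing of the component reference
    spectra, scaled by the session gain, plus additive background terms::

        A(nu) = gain * (dppc * ref_DPPC(nu) + sm * ref_SM(nu))
              + dcm_amp * vapor(nu) + water_amp * water_lines(nu)
              + offset + slope * (nu - nu_mid) + N(0, noise_sd^2)
    """
    if dppc < 0 or sm < 0:
        raise InvalidParameterError(f"concentrations must be >= 0, got ({dppc}, {sm})")
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be >= 0")
    session_effects = session_effects or SessionEffects()
    artifacts = artifacts or ArtifactDraws()
    nu = np.asarray(grid, dtype=float)

    signal = np.zeros_like(nu)
    if dppc > 0:
        signal += dppc * build_reference_spectrum(library.dppc_peaks, nu).absorbances
    if sm > 0:
        signal += sm * build_reference_spectrum(library.sm_peaks, nu).absorbances
    total = session_effects.gain * signal

    if artifacts.dcm_vapor_amplitude != 0.0:
        total += artifacts.dcm_vapor_amplitude * build_reference_spectrum(
            library.dcm_vapor_peaks, nu
        ).absorbances
    if artifacts.water_vapor_amplitude != 0.0:
        total += artifacts.water_vapor_amplitude * build_reference_spectrum(
            library.water_vapor_band.peaks(), nu
        ).absorbances
    total += artifacts.baseline_offset
    total += artifacts.baseline_slope * (nu - 0.5 * (nu[0] + nu[-1]))
    if artifacts.baseline_drift is not None:
        total = total + artifacts.baseline_drift
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        total = total + rng.normal(0.0, noise_sd, nu.size)

    metadata.setdefault("true_dppc", dppc)
    metadata.setdefault("true_sm", sm)
    metadata.setdefault("water_vapor", artifacts.water_vapor_amplitude != 0.0)
    return Spectrum(wavenumbers=nu, absorbances=total, **metadata)


def _partition_session(
    total: int, rep_lo: int, rep_hi: int, rng: np.random.Generator
) -> list[int]:
    """Split a session's measurement count into successive-scan runs.

    Run lengths are drawn uniformly from the configured replicate range; the
    final run is truncated to fit the session total (and is therefore allowed
    to be shorter than the range minimum, but never empty).
    """
    runs: list[int] = []
    remaining = total
    while remaining > 0:
        r = int(rng.integers(rep_lo, rep_hi + 1))
        r = min(r, remaining)
        runs.append(r)
        remaining -= r
    return runs


def generate_dataset(
    config: GeneratorConfig, library: ComponentLibrary | None = None
) -> list[Spectrum]:
    """Generate a full seeded measurement campaign.

    Each session dispenses a sequence of L/S-ratio samples (ratios cycled in
    a session-specific random order) and records a run of successive scans
    per sample.  The water-vapor flag marks replicates whose background
    differed in humidity; each sample retains at least one clean replicate.
    Identical configs (including seed) produce bitwise-identical datasets.
    """
    library = library or default_library()
    rng = np.random.default_rng(config.seed)
    nu = config.wavenumbers()
    rep_lo, rep_hi = config.replicates_per_sample

    # Precompute reference and artifact shapes once for speed.  Band-position
    # jitter is applied by re-evaluating the analytic line shapes on a
    # shifted grid, so the first-order effect is exact rather than
    # interpolated.
    ref_dppc = build_reference_spectrum(library.dppc_peaks, nu).absorbances
    ref_sm = build_reference_spectrum(library.sm_peaks, nu).absorbances
    ref_dcm = build_reference_spectrum(library.dcm_vapor_peaks, nu).absorbances
    ref_water = build_reference_spectrum(library.water_vapor_band.peaks(), nu).absorbances
    nu_mid = 0.5 * (nu[0] + nu[-1])

    spectra: list[Spectrum] = []
    for s_idx, group_size in enumerate(config.session_group_sizes):
        session_id = f"session{s_idx:02d}"
        gain = float(rng.normal(1.0, config.session_gain_sd))
        runs = _partition_session(group_size, rep_lo, rep_hi, rng)

        # Cycle ratios in a session-specific random order so every session
        # covers a spread of ratios without exact repetition structure.
        order = rng.permutation(len(config.ls_ratios))
        for k, n_reps in enumerate(runs):
            ratio = float(config.ls_ratios[order[k % len(order)]])
            sm_conc = config.sm_concentration
            dppc_conc = ratio * sm_conc
            sample_id = f"{session_id}_sample{k:02d}"

            vapor_flags = rng.random(n_reps) < config.water_vapor_fraction
            if vapor_flags.all():
                vapor_flags[int(rng.integers(n_reps))] = False  # keep one clean scan

            for rep in range(n_reps):
                # A fresh background precedes each set of scans; residual
                # background drift accumulates scan to scan, so background
                # terms are redrawn per measurement.
                offset = float(rng.normal(0.0, config.baseline_offset_sd))
                slope = float(rng.normal(0.0, config.baseline_slope_sd))
                dcm_amp = float(rng.uniform(0.0, config.dcm_vapor_max))
                water_amp = (
                    float(rng.uniform(0.2, 1.0) * config.water_vapor_max)
                    if vapor_flags[rep]
                    else 0.0
                )
                if config.peak_jitter_sd > 0:
                    shift = rng.normal(0.0, config.peak_jitter_sd)
                    nu_s = nu - shift
                    rd = build_reference_spectrum(library.dppc_peaks, nu_s).absorbances
                    rs = build_reference_spectrum(library.sm_peaks, nu_s).absorbances
                else:
                    rd, rs = ref_dppc, ref_sm
                total = gain * (dppc_conc * rd + sm_conc * rs)
                total += dcm_amp * ref_dcm
                if water_amp:
                    total += water_amp * ref_water
                total += offset + slope * (nu - nu_mid)
                if config.baseline_drift_sd > 0:
                    total += draw_baseline_drift(
                        rng, nu, config.baseline_drift_sd, config.baseline_drift_scale
                    )
                if config.baseline_texture_sd > 0:
                    total += draw_baseline_texture(
                        rng, nu, config.baseline_texture_sd, config.baseline_texture_scale
                    )
                if config.noise_sd > 0:
                    total = total + rng.normal(0.0, config.noise_sd, nu.size)
                spectra.append(
                    Spectrum(
                        wavenumbers=nu.copy(),
                        absorbances=total,
                        session_id=session_id,
                        sample_id=sample_id,
                        replicate=rep,
                        true_dppc=dppc_conc,
                        true_sm=sm_conc,
                        water_vapor=bool(vapor_flags[rep]),
                    )
                )
    return spectra
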