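"""Ratiometric Boltzmann nanothermometry.

Nd3+-doped nanothermometers emit from two thermally coupled levels, giving
two NIR peaks (near 820 and 870 nm) whose intensity ratio follows a
Boltzmann law::

    ln(FIR) = a + b / T

with ``FIR`` the band-integrated fluorescence intensity ratio, ``T`` the
absolute temperature, ``a`` a dimensionless intercept and ``b`` a slope in
kelvin (negative: the dimmer 820 nm band grows with temperature).  This
module holds the spectrum/calibration containers, the FIR computation, the
least-squares calibration fit and its inversion, and a synthetic
temperature-spectrum database mimicking a measured one.

All internal temperatures are kelvin; helpers convert from/to Celsius at the
user-facing surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .errors import (
    CalibrationRangeWarning,
    ConfigurationError,
    ExtrapolationError,
    InversionError,
    ParameterError,
    SpectrumCoverageError,
    UndefinedRatioError,
)

__all__ = [
    "EmissionSpectrum",
    "SpectralBands",
    "CalibrationModel",
    "EmissionDatabase",
    "PeakConfig",
    "DEFAULT_BANDS",
    "DEFAULT_CALIBRATION",
    "celsius_to_kelvin",
    "kelvin_to_celsius",
    "compute_fir",
    "fit_calibration",
    "fir_from_temperature",
    "temperature_from_fir",
    "interpolate_spectrum",
    "synthesize_emission_database",
]


def celsius_to_kelvin(t_c):
    return np.asarray(t_c, dtype=float) + 273.15 if np.ndim(t_c) else float(t_c) + 273.15


def kelvin_to_celsius(t_k):
    return np.asarray(t_k, dtype=float) - 273.15 if np.ndim(t_k) else float(t_k) - 273.15


@dataclass(frozen=True)
class EmissionSpectrum:
    """Sampled fluorescence emission spectrum on a uniform wavelength grid.

    Parameters
    ----------
    wavelengths_nm : array
        Strictly increasing, uniformly spaced wavelengths in nm.
    intensities : array
        Non-negative counts, same length as ``wavelengths_nm``.
    acquisition_time_ms : float
        Integration time of the acquisition, > 0.
    """

    wavelengths_nm: np.ndarray
    intensities: np.ndarray
    acquisition_time_ms: float = 500.0

    def __post_init__(self):
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        it = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "intensities", it)
        if wl.ndim != 1 or it.ndim != 1 or wl.size != it.size:
            raise ParameterError("wavelengths and intensities must be equal-length 1D arrays")
        if wl.size < 2:
            raise ParameterError("spectrum needs at least two samples")
        steps = np.diff(wl)
        if np.any(steps <= 0):
            raise ParameterError("wavelengths must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            raise ParameterError("wavelength grid must be uniform")
        if not np.all(np.isfinite(it)) or np.any(it < 0):
            raise ParameterError("intensities must be finite and non-negative")
        if not self.acquisition_time_ms > 0:
            raise ParameterError("acquisition_time_ms must be > 0")

    @property
    def step_nm(self) -> float:
        return float(self.wavelengths_nm[1] - self.wavelengths_nm[0])

    def covers(self, lo_nm: float, hi_nm: float) -> bool:
        return self.wavelengths_nm[0] <= lo_nm and self.wavelengths_nm[-1] >= hi_nm

    def with_intensities(self, intensities) -> "EmissionSpectrum":
        return replace(self, intensities=np.asarray(intensities, dtype=float))


@dataclass(frozen=True)
class SpectralBands:
    """The two integration bands of the thermally coupled emission peaks.

    ``band1`` is half-open [lo, hi) and ``band2`` closed [lo, hi]; the shared
    boundary (840 nm by default) is assigned to band2 — a deterministic
    tie-break for samples landing exactly on the boundary.
    """

    band1: tuple[float, float] = (790.0, 840.0)
    band2: tuple[float, float] = (840.0, 945.0)

    def __post_init__(self):
        (a0, a1), (b0, b1) = self.band1, self.band2
        if not (a0 < a1 and b0 < b1):
            raise ConfigurationError("band bounds must be increasing")
        if a1 != b0:
            raise ConfigurationError("band1 upper bound must equal band2 lower bound")

    @property
    def lo_nm(self) -> float:
        return self.band1[0]

    @property
    def hi_nm(self) -> float:
        return self.band2[1]

    def masks(self, wavelengths_nm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        wl = np.asarray(wavelengths_nm)
        m1 = (wl >= self.band1[0]) & (wl < self.band1[1])
        m2 = (wl >= self.band2[0]) & (wl <= self.band2[1])
        return m1, m2


DEFAULT_BANDS = SpectralBands()


@dataclass(frozen=True)
class CalibrationModel:
    """Boltzmann calibration ln(FIR) = a + b/T.

    ``b_K`` carries units of kelvin (slope of ln FIR against 1/T);
    ``valid_range_K`` is the temperature interval the fit was derived on.
    """

    a: float
    b_K: float
    valid_range_K: tuple[float, float] = (303.15, 353.15)

    def __post_init__(self):
        if self.b_K == 0:
            raise ParameterError("slope b_K must be nonzero")
        lo, hi = self.valid_range_K
        if not lo < hi:
            raise ParameterError("valid_range_K must be an increasing interval")


#: Shipped default constants: intercept a = 1.33, slope b = -1.32e3 K,
#: validated over the 30-80 degC calibration protocol.
DEFAULT_CALIBRATION = CalibrationModel(a=1.33, b_K=-1320.0)


def compute_fir(spectrum: EmissionSpectrum, bands: SpectralBands = DEFAULT_BANDS) -> float:
    """Fluorescence intensity ratio: band1 sample-sum over band2 sample-sum.

    Band integration is a plain sum of samples on the uniform grid (counts
    semantics of a spectrometer); the ratio is invariant to the grid step.
    """
    if not spectrum.covers(bands.lo_nm, bands.hi_nm):
        raise SpectrumCoverageError(
            f"spectrum [{spectrum.wavelengths_nm[0]:.1f}, {spectrum.wavelengths_nm[-1]:.1f}] nm "
            f"does not cover bands [{bands.lo_nm:.1f}, {bands.hi_nm:.1f}] nm"
        )
    m1, m2 = bands.masks(spectrum.wavelengths_nm)
    s1 = float(spectrum.intensities[m1].sum())
    s2 = float(spectrum.intensities[m2].sum())
    if s2 <= 0:
        raise UndefinedRatioError(f"band2 integrated intensity is {s2}; FIR undefined")
    return s1 / s2


def fit_calibration(points) -> CalibrationModel:
    """Ordinary least squares of ln(FIR) on 1/T.

    Parameters
    ----------
    points : sequence of (temperature_K, fir) pairs
        At least two distinct temperatures; all FIR values > 0.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ParameterError("need >= 2 (temperature_K, fir) pairs")
    temps, firs = pts[:, 0], pts[:, 1]
    if np.any(temps <= 0):
        raise ParameterError("temperatures must be positive kelvin")
    if np.any(firs <= 0):
        raise ParameterError("FIR values must be positive for the log fit")
    if np.unique(temps).size < 2:
        raise ParameterError("rank-deficient fit: need at least two distinct temperatures")
    x = 1.0 / temps
    y = np.log(firs)
    b, a = np.polyfit(x, y, 1)
    return CalibrationModel(a=float(a), b_K=float(b), valid_range_K=(float(temps.min()), float(temps.max())))


def fir_from_temperature(t_k: float, model: CalibrationModel = DEFAULT_CALIBRATION):
    """Forward Boltzmann law: FIR = exp(a + b/T)."""
    t = np.asarray(t_k, dtype=float)
    if np.any(t <= 0):
        raise ParameterError("temperature must be > 0 K")
    out = np.exp(model.a + model.b_K / t)
    return float(out) if out.ndim == 0 else out


def temperature_from_fir(fir: float, model: CalibrationModel = DEFAULT_CALIBRATION) -> float:
    """Invert the Boltzmann law: T = b / (ln FIR - a).

    Emits :class:`CalibrationRangeWarning` (never raises) when the result
    falls outside the model's validated temperature range.
    """
    if not fir > 0:
        raise InversionError(f"fir must be > 0, got {fir}")
    denom = np.log(fir) - model.a
    if denom == 0:
        raise InversionError("ln(fir) equals the intercept a; inversion pole")
    t = model.b_K / denom
    lo, hi = model.valid_range_K
    if not lo <= t <= hi:
        warnings.warn(
            f"inverted temperature {t:.2f} K outside validated range [{lo:.2f}, {hi:.2f}] K",
            CalibrationRangeWarning,
            stacklevel=2,
        )
    return float(t)


@dataclass(frozen=True)
class EmissionDatabase:
    """Temperature-spectrum database: one spectrum per temperature node.

    All node spectra share one wavelength grid; node temperatures are
    strictly increasing. Spectra at intermediate temperatures come from
    per-wavelength linear interpolation between the bracketing nodes.
    """

    temperatures_K: np.ndarray
    wavelengths_nm: np.ndarray
    intensities: np.ndarray  # (n_nodes, n_wavelengths)

    def __post_init__(self):
        t = np.asarray(self.temperatures_K, dtype=float)
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        it = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "temperatures_K", t)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "intensities", it)
        if t.size < 2:
            raise ParameterError("database needs >= 2 temperature nodes")
        if np.any(np.diff(t) <= 0):
            raise ParameterError("node temperatures must be strictly increasing")
        if it.shape != (t.size, wl.size):
            raise ParameterError("intensities must be (n_nodes, n_wavelengths)")

    @property
    def temperature_range_K(self) -> tuple[float, float]:
        return float(self.temperatures_K[0]), float(self.temperatures_K[-1])

    def node_spectrum(self, index: int) -> EmissionSpectrum:
        return EmissionSpectrum(self.wavelengths_nm, self.intensities[index])

    def band_sums(self, bands: SpectralBands = DEFAULT_BANDS) -> tuple[np.ndarray, np.ndarray]:
        """Per-node band-integrated intensities (band1, band2)."""
        m1, m2 = bands.masks(self.wavelengths_nm)
        return self.intensities[:, m1].sum(axis=1), self.intensities[:, m2].sum(axis=1)

    def fir_at_nodes(self, bands: SpectralBands = DEFAULT_BANDS) -> np.ndarray:
        s1, s2 = self.band_sums(bands)
        return s1 / s2


def interpolate_spectrum(db: EmissionDatabase, t_k: float) -> EmissionSpectrum:
    """Spectrum at temperature ``t_k`` by linear interpolation between nodes."""
    lo, hi = db.temperature_range_K
    if not lo <= t_k <= hi:
        raise ExtrapolationError(f"T = {t_k:.2f} K outside database range [{lo:.2f}, {hi:.2f}] K")
    temps = db.temperatures_K
    k = int(np.searchsorted(temps, t_k, side="right")) - 1
    k = min(max(k, 0), temps.size - 2)
    t0, t1 = temps[k], temps[k + 1]
    w = (t_k - t0) / (t1 - t0)
    inten = (1.0 - w) * db.intensities[k] + w * db.intensities[k + 1]
    return EmissionSpectrum(db.wavelengths_nm, inten)


@dataclass(frozen=True)
class PeakConfig:
    """Two-Gaussian synthetic lineshape for the coupled emission peaks.

    Centers default to 820 and 870 nm (50 nm apart, comfortably beyond the
    >40 nm separation dichroic filters need), widths 8 nm (Gaussian sigma).
    An optional third peak near 1064 nm can be added; it lies outside both
    integration bands by construction.
    """

    center1_nm: float = 820.0
    center2_nm: float = 870.0
    sigma_nm: float = 8.0
    include_1064_peak: bool = False
    peak1064_center_nm: float = 1064.0
    peak1064_amplitude: float = 0.3

    def __post_init__(self):
        if not (790.0 <= self.center1_nm <= 945.0 and 790.0 <= self.center2_nm <= 945.0):
            raise ConfigurationError("peak centers must lie within [790, 945] nm")
        if self.sigma_nm <= 0:
            raise ConfigurationError("sigma_nm must be > 0")


def _gaussian(wl, center, sigma):
    return np.exp(-0.5 * ((wl - center) / sigma) ** 2)


def synthesize_emission_database(
    model: CalibrationModel = DEFAULT_CALIBRATION,
    peak_config: PeakConfig = PeakConfig(),
    bands: SpectralBands = DEFAULT_BANDS,
    temperatures_K: np.ndarray | None = None,
    wavelength_step_nm: float = 0.5,
) -> EmissionDatabase:
    """Synthetic temperature-spectrum database consistent with a Boltzmann model.

    Stands in for a measured nanothermometer database: each node spectrum is a
    pair of Gaussian peaks whose band-integrated ratio equals
    ``fir_from_temperature(T, model)`` exactly (the 820-peak amplitude is
    solved per node, accounting for cross-band tails). Default nodes follow
    the 30-80 degC, step-10 calibration protocol.
    """
    cfg = peak_config
    b1lo, b1hi = bands.band1
    if not (b1lo <= cfg.center1_nm < b1hi):
        raise ConfigurationError("center1_nm must lie inside band1 (peak straddles the boundary)")
    if not (bands.band2[0] <= cfg.center2_nm <= bands.band2[1]):
        raise ConfigurationError("center2_nm must lie inside band2 (peak straddles the boundary)")

    if temperatures_K is None:
        temperatures_K = celsius_to_kelvin(np.arange(30.0, 80.0 + 1e-9, 10.0))
    temperatures_K = np.asarray(temperatures_K, dtype=float)

    wl_hi = 1100.0 if cfg.include_1064_peak else 960.0
    n = int(round((wl_hi - 780.0) / wavelength_step_nm)) + 1
    wl = 780.0 + wavelength_step_nm * np.arange(n)

    m1, m2 = bands.masks(wl)
    g1 = _gaussian(wl, cfg.center1_nm, cfg.sigma_nm)
    g2 = _gaussian(wl, cfg.center2_nm, cfg.sigma_nm)
    g1b1, g1b2 = g1[m1].sum(), g1[m2].sum()
    g2b1, g2b2 = g2[m1].sum(), g2[m2].sum()

    spectra = np.empty((temperatures_K.size, wl.size))
    for i, t in enumerate(temperatures_K):
        fir = fir_from_temperature(float(t), model)
        denom = g1b1 - fir * g1b2
        if denom <= 0:
            raise ConfigurationError("peak geometry cannot realize the requested FIR")
        a1 = (fir * g2b2 - g2b1) / denom  # amplitude of the 820 nm peak, 870 peak = 1
        if a1 < 0:
            raise ConfigurationError("peak geometry cannot realize the requested FIR")
        s = a1 * g1 + g2
        if cfg.include_1064_peak:
            s = s + cfg.peak1064_amplitude * _gaussian(wl, cfg.peak1064_center_nm, cfg.sigma_nm)
        spectra[i] = s / s.max()  # peak-normalized; FIR is scale-invariant
    return EmissionDatabase(temperatures_K=temperatures_K, wavelengths_nm=wl, intensities=spectra)
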