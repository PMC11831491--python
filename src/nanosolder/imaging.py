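"""Dual-channel ratiometric thermal imaging.

Two NIR cameras behind a dichroic splitter record the two emission peaks
(810-830 nm band and >850 nm band) of the nanothermometers relayed through
an image-guiding fiber. The processing chain: background subtraction,
integer-pixel alignment of the second channel, conversion of counts to
gain- and exposure-corrected rates, Gaussian blur of each channel (applied
before the ratio so fiber-bundle honeycomb artifacts do not amplify
division noise), the system-calibrated intensity ratio k * r820 / r870,
count thresholding, FIR -> temperature inversion with a display range, and
averaging of positioned frames into a composite soldering-path map.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ParameterError
from .fields import TemperatureField
from .spectra import (
    DEFAULT_BANDS,
    CalibrationModel,
    EmissionDatabase,
    SpectralBands,
    celsius_to_kelvin,
)

__all__ = [
    "ChannelFrame",
    "AlignmentOffset",
    "TemperatureMap",
    "subtract_background",
    "compute_fir_image",
    "temperature_map_from_fir",
    "composite_path_map",
    "render_channel_frames",
]

INVALID_TEMP_C = 0.0  # sentinel carried by invalid pixels ("appearing dark")


@dataclass(frozen=True)
class ChannelFrame:
    """One camera frame of a single emission-peak channel.

    ``gain_db`` is the camera gain in dB (linear factor 10^(dB/20));
    both frames of a pair share the acquisition time (default 500 ms) but
    use different gains, the 820 nm peak being the dimmer one.
    """

    counts: np.ndarray
    channel: str  # "peak1-820nm" | "peak2-870nm"
    gain_db: float = 0.0
    acquisition_time_ms: float = 500.0
    position_mm: tuple[float, float] | None = None

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", c)
        if c.ndim != 2:
            raise ParameterError("frame counts must be a 2D array")
        if not np.all(np.isfinite(c)) or np.any(c < 0):
            raise ParameterError("frame counts must be finite and non-negative")
        if self.channel not in ("peak1-820nm", "peak2-870nm"):
            raise ParameterError("channel must be 'peak1-820nm' or 'peak2-870nm'")
        if self.acquisition_time_ms <= 0:
            raise ParameterError("acquisition_time_ms must be > 0")

    @property
    def linear_gain(self) -> float:
        return 10.0 ** (self.gain_db / 20.0)

    def rate(self) -> np.ndarray:
        """Counts per (linear gain x ms): comparable across gain settings."""
        return self.counts / (self.linear_gain * self.acquisition_time_ms)


@dataclass(frozen=True)
class AlignmentOffset:
    """Manual integer-pixel shift applied to the second channel."""

    dx: int = 0
    dy: int = 0


@dataclass(frozen=True)
class TemperatureMap:
    """Per-pixel temperature with validity mask; invalid pixels carry 0 degC."""

    temp_c: np.ndarray
    valid: np.ndarray
    pixel_pitch_um: float | None = None
    position_mm: tuple[float, float] | None = None

    def __post_init__(self):
        t = np.asarray(self.temp_c, dtype=float)
        v = np.asarray(self.valid, dtype=bool)
        object.__setattr__(self, "temp_c", t)
        object.__setattr__(self, "valid", v)
        if t.shape != v.shape:
            raise ParameterError("temp and mask shapes differ")
        if not np.all(np.isfinite(t[v])):
            raise ParameterError("valid temperatures must be finite")


def subtract_background(frame: ChannelFrame, background) -> ChannelFrame:
    """Subtract a scalar background or the mean over a region, clipping at 0.

    ``background`` may be a scalar, a boolean mask, or an index tuple
    selecting a signal-free region of the frame.
    """
    if np.isscalar(background):
        level = float(background)
    else:
        region = frame.counts[background]
        if region.size == 0:
            raise ParameterError("background region is empty")
        level = float(region.mean())
    return replace(frame, counts=np.clip(frame.counts - level, 0.0, None))


def _shift_with_zeros(a: np.ndarray, dx: int, dy: int) -> np.ndarray:
    out = np.zeros_like(a)
    h, w = a.shape
    ys = slice(max(dy, 0), h + min(dy, 0))
    xs = slice(max(dx, 0), w + min(dx, 0))
    ys_src = slice(max(-dy, 0), h + min(-dy, 0))
    xs_src = slice(max(-dx, 0), w + min(-dx, 0))
    out[ys, xs] = a[ys_src, xs_src]
    return out


def compute_fir_image(
    frame820: ChannelFrame,
    frame870: ChannelFrame,
    offset: AlignmentOffset = AlignmentOffset(),
    system_factor_k: float = 1.0,
    blur_sigma_px: float = 7.0,
    min_counts: float = 15.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Gain-corrected, blurred FIR map with a validity mask.

    Frames must already be background-subtracted. The 870-channel is shifted
    by the manual alignment offset; each channel's rate image is Gaussian
    blurred (sigma 7 px by default); pixels whose blurred 820-channel counts
    are <= ``min_counts`` (or with no 870 signal) are masked and set to 0.
    """
    if frame820.counts.shape != frame870.counts.shape:
        raise ParameterError("frame shapes differ")
    if abs(offset.dx) >= frame820.counts.shape[1] or abs(offset.dy) >= frame820.counts.shape[0]:
        raise ParameterError("alignment offset exceeds the frame size")
    if system_factor_k <= 0:
        raise ParameterError("system_factor_k must be > 0")
    f870 = replace(frame870, counts=_shift_with_zeros(frame870.counts, offset.dx, offset.dy))
    r820 = gaussian_filter(frame820.rate(), blur_sigma_px)
    r870 = gaussian_filter(f870.rate(), blur_sigma_px)
    counts820_blur = gaussian_filter(frame820.counts, blur_sigma_px)
    mask = (counts820_blur > min_counts) & (r870 > 0)
    fir = np.zeros_like(r820)
    np.divide(system_factor_k * r820, r870, out=fir, where=mask)
    fir[~mask] = 0.0
    return fir, mask


def temperature_map_from_fir(
    fir_map: np.ndarray,
    mask: np.ndarray,
    model: CalibrationModel,
    display_range_c: tuple[float, float] = (20.0, 80.0),
    pixel_pitch_um: float | None = None,
    position_mm: tuple[float, float] | None = None,
) -> TemperatureMap:
    """Invert the FIR map pixel-wise; per-pixel failures invalidate, never raise."""
    fir = np.asarray(fir_map, dtype=float)
    valid = np.asarray(mask, dtype=bool) & (fir > 0)
    temp = np.zeros_like(fir)
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = np.where(valid, np.log(fir, where=valid, out=np.zeros_like(fir)) - model.a, np.inf)
        t_k = np.where(np.abs(denom) > 1e-12, model.b_K / denom, np.nan)
    t_c = t_k - 273.15
    lo, hi = display_range_c
    valid &= np.isfinite(t_c) & (t_c >= lo) & (t_c <= hi)
    temp[valid] = t_c[valid]
    temp[~valid] = INVALID_TEMP_C
    return TemperatureMap(temp, valid, pixel_pitch_um=pixel_pitch_um, position_mm=position_mm)


def composite_path_map(
    maps: list[TemperatureMap], valid_range_c: tuple[float, float] = (20.0, 80.0)
) -> TemperatureMap:
    """Average positioned frames on a common physical grid.

    Each location's value is the mean of all valid in-range measurements of
    it across frames; locations never validly measured stay invalid. Frame
    positions (mm) are converted to integer pixel offsets via the shared
    pixel pitch.
    """
    if not maps:
        raise ParameterError("need at least one frame")
    pitches = {m.pixel_pitch_um for m in maps}
    if len(pitches) != 1:
        raise ParameterError("frames have inconsistent pixel pitch")
    pitch_um = pitches.pop()
    shape = maps[0].temp_c.shape
    offsets = []
    for m in maps:
        if m.temp_c.shape != shape:
            raise ParameterError("frames have inconsistent shapes")
        if m.position_mm is None or pitch_um is None:
            offsets.append((0, 0))
        else:
            offsets.append(
                (
                    int(round(m.position_mm[0] * 1e3 / pitch_um)),
                    int(round(m.position_mm[1] * 1e3 / pitch_um)),
                )
            )
    xs = [o[0] for o in offsets]
    ys = [o[1] for o in offsets]
    x0, y0 = min(xs), min(ys)
    w = shape[1] + max(xs) - x0
    h = shape[0] + max(ys) - y0
    acc = np.zeros((h, w))
    cnt = np.zeros((h, w))
    lo, hi = valid_range_c
    for m, (ox, oy) in zip(maps, offsets):
        use = m.valid & (m.temp_c >= lo) & (m.temp_c <= hi)
        sy = slice(oy - y0, oy - y0 + shape[0])
        sx = slice(ox - x0, ox - x0 + shape[1])
        acc[sy, sx][use] += m.temp_c[use]
        cnt[sy, sx][use] += 1
    valid = cnt > 0
    temp = np.zeros_like(acc)
    temp[valid] = acc[valid] / cnt[valid]
    return TemperatureMap(temp, valid, pixel_pitch_um=pitch_um)


def _band_sum_tables(db: EmissionDatabase, bands: SpectralBands) -> tuple[np.ndarray, np.ndarray]:
    return db.band_sums(bands)


def render_channel_frames(
    field: TemperatureField,
    db: EmissionDatabase,
    gain820_db: float = 20.0,
    gain870_db: float = 0.0,
    acquisition_time_ms: float = 500.0,
    peak_counts_870: float = 3000.0,
    noise: bool = False,
    rng: np.random.Generator | None = None,
    bands: SpectralBands = DEFAULT_BANDS,
) -> tuple[ChannelFrame, ChannelFrame]:
    """Render the two camera frames a dual-channel system would record.

    Fixture for round-trip tests: per pixel, the band-integrated intensities
    of the database spectrum at the local temperature, scaled by channel
    gain and acquisition time so the 870-channel peaks at
    ``peak_counts_870``; optional Poisson noise. Inverse-consistent with
    :func:`compute_fir_image` at system factor k = 1.
    """
    if noise and rng is None:
        raise ParameterError("rng required when noise is enabled")
    s1_nodes, s2_nodes = _band_sum_tables(db, bands)
    t_k = celsius_to_kelvin(field.values_c)
    temps = db.temperatures_K
    lo, hi = db.temperature_range_K
    if t_k.min() < lo or t_k.max() > hi:
        raise ParameterError("field temperatures outside the database range")
    # band sums are linear in the node interpolation, so interpolate them directly
    s1 = np.interp(t_k.ravel(), temps, s1_nodes).reshape(t_k.shape)
    s2 = np.interp(t_k.ravel(), temps, s2_nodes).reshape(t_k.shape)
    g820 = 10.0 ** (gain820_db / 20.0)
    g870 = 10.0 ** (gain870_db / 20.0)
    scale = peak_counts_870 / (s2.max() * g870 * acquisition_time_ms)
    c820 = s1 * g820 * acquisition_time_ms * scale
    c870 = s2 * g870 * acquisition_time_ms * scale
    if noise:
        c820 = rng.poisson(c820).astype(float)
        c870 = rng.poisson(c870).astype(float)
    return (
        ChannelFrame(c820, "peak1-820nm", gain_db=gain820_db, acquisition_time_ms=acquisition_time_ms),
        ChannelFrame(c870, "peak2-870nm", gain_db=gain870_db, acquisition_time_ms=acquisition_time_ms),
    )
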