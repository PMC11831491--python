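"""Physical temperature fields for the forward simulator.

Laser-heated solder paste develops smooth, roughly bell-shaped temperature
profiles; the simulator emulates them with rotated, separable skew-normal
("skewed Gaussian") surfaces on a regular grid, peak-normalized so the
hottest grid pixel equals ``T_max`` and the far field relaxes to ``T_min``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

from .errors import ParameterError

__all__ = [
    "GridSpec",
    "TemperatureField",
    "SkewedGaussianParams",
    "DEFAULT_GRID",
    "make_skewed_gaussian_field",
    "sample_tmin",
]


@dataclass(frozen=True)
class GridSpec:
    """Regular pixel grid over a centered physical extent.

    ``shape`` is (ny, nx); ``extent_mm`` is (width_x, height_y). The default
    128 x 96 grid over 4.0 mm x 3.0 mm gives a square 31.25 um pixel pitch
    (a desk-scale stand-in for a 640 x 480 camera grid, which remains
    available by configuration).
    """

    shape: tuple[int, int] = (96, 128)
    extent_mm: tuple[float, float] = (4.0, 3.0)

    def __post_init__(self):
        ny, nx = self.shape
        if ny < 8 or nx < 8:
            raise ParameterError("grid dimensions must be >= 8x8")
        px = self.extent_mm[0] / nx
        py = self.extent_mm[1] / ny
        if not np.isclose(px, py, rtol=1e-9):
            raise ParameterError("pixel pitch must be equal on both axes")

    @property
    def pixel_pitch_mm(self) -> float:
        return self.extent_mm[0] / self.shape[1]

    @property
    def pixel_pitch_um(self) -> float:
        return 1e3 * self.pixel_pitch_mm

    def coordinates_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """Pixel-center coordinates (x 1D of len nx, y 1D of len ny), origin at grid center."""
        ny, nx = self.shape
        p = self.pixel_pitch_mm
        x = (np.arange(nx) - (nx - 1) / 2.0) * p
        y = (np.arange(ny) - (ny - 1) / 2.0) * p
        return x, y


DEFAULT_GRID = GridSpec()


@dataclass(frozen=True)
class TemperatureField:
    """2D physical temperature map in degC on a :class:`GridSpec`.

    Array layout is ``values_c[iy, ix]`` with x and y increasing with the
    index (origin at the grid center).
    """

    values_c: np.ndarray
    grid: GridSpec = DEFAULT_GRID

    def __post_init__(self):
        v = np.asarray(self.values_c, dtype=float)
        object.__setattr__(self, "values_c", v)
        if v.shape != self.grid.shape:
            raise ParameterError(f"field shape {v.shape} does not match grid {self.grid.shape}")
        if not np.all(np.isfinite(v)):
            raise ParameterError("field values must be finite")

    @property
    def pixel_pitch_um(self) -> float:
        return self.grid.pixel_pitch_um

    def value_at_mm(self, x_mm: float, y_mm: float) -> float:
        """Temperature of the pixel whose center is nearest (x, y)."""
        xs, ys = self.grid.coordinates_mm()
        ix = int(np.argmin(np.abs(xs - x_mm)))
        iy = int(np.argmin(np.abs(ys - y_mm)))
        return float(self.values_c[iy, ix])


@dataclass(frozen=True)
class SkewedGaussianParams:
    """Parameters of one skewed-Gaussian temperature profile.

    ``mu`` is the profile center (mm), ``sigma`` the per-axis widths (mm),
    ``a`` the per-axis skewness (dimensionless, sign selects the heavy
    side), ``phi_deg`` the rotation of the principal axes, and ``t_max_c`` /
    ``t_min_c`` the peak and baseline temperatures in degC.
    """

    mu_x_mm: float = 0.0
    mu_y_mm: float = 0.0
    sigma_x_mm: float = 0.7
    sigma_y_mm: float = 0.7
    a_x: float = 0.0
    a_y: float = 0.0
    phi_deg: float = 0.0
    t_max_c: float = 70.0
    t_min_c: float = 30.0

    def __post_init__(self):
        if self.sigma_x_mm <= 0 or self.sigma_y_mm <= 0:
            raise ParameterError("sigma must be > 0")
        if not self.t_min_c < self.t_max_c:
            raise ParameterError("t_min_c must be < t_max_c")


def _skew_shape(u: np.ndarray, sigma: float, a: float) -> np.ndarray:
    """Unnormalized 1D skew-normal density phi(u/sigma) * Phi(a u/sigma)."""
    z = u / sigma
    return np.exp(-0.5 * z * z) * ndtr(a * z)


def make_skewed_gaussian_field(
    params: SkewedGaussianParams, grid_spec: GridSpec = DEFAULT_GRID
) -> TemperatureField:
    """Render a rotated separable skew-normal temperature profile.

    T(x, y) = T_min + (T_max - T_min) * S(x', y') / max(S), with (x', y') the
    coordinates rotated by ``phi`` about the profile center and S the product
    of per-axis skew-normal shapes. The maximum is taken over the grid, so
    the hottest pixel is exactly T_max.
    """
    x, y = grid_spec.coordinates_mm()
    xx, yy = np.meshgrid(x, y)  # (ny, nx)
    dx = xx - params.mu_x_mm
    dy = yy - params.mu_y_mm
    phi = np.deg2rad(params.phi_deg)
    u = np.cos(phi) * dx + np.sin(phi) * dy
    v = -np.sin(phi) * dx + np.cos(phi) * dy
    s = _skew_shape(u, params.sigma_x_mm, params.a_x) * _skew_shape(v, params.sigma_y_mm, params.a_y)
    peak = s.max()
    if peak <= 0:
        raise ParameterError("degenerate profile: shape vanishes on the whole grid")
    t = params.t_min_c + (params.t_max_c - params.t_min_c) * (s / peak)
    return TemperatureField(values_c=t, grid=grid_spec)


def sample_tmin(t_max_c: float, rng: np.random.Generator) -> float:
    """Uniform draw of the baseline temperature in [20, T_max - 1] degC."""
    if not t_max_c > 21.0:
        raise ParameterError("t_max_c must exceed 21 degC so that [20, T_max-1] is nonempty")
    return float(rng.uniform(20.0, t_max_c - 1.0))
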