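"""Synthetic training-set generation for the thermal upscaler.

Pipeline: enumerate a grid of skewed-Gaussian field parameters, render each
field through the fiber-fluorescence forward model into a paired sample
(5x5 measured thermal image, 20x20 ground-truth thermal image over a shared
2.5 mm field of view), discard pairs whose low-resolution observation
carries too little information about the target (SSIM cutoff), and persist
the result to HDF5.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
from dataclasses import dataclass, field, replace

import h5py
import numpy as np
from skimage.metrics import structural_similarity

from .errors import ConfigurationError, ParameterError, SchemaError
from .fields import (
    DEFAULT_GRID,
    GridSpec,
    SkewedGaussianParams,
    make_skewed_gaussian_field,
    sample_tmin,
)
from .optics import BeamModel, FiberModel, NoiseConfig, sample_fiber_grid
from .spectra import (
    DEFAULT_CALIBRATION,
    CalibrationModel,
    EmissionDatabase,
    celsius_to_kelvin,
    synthesize_emission_database,
)

__all__ = [
    "ParamGrid",
    "SimConfig",
    "DatasetSample",
    "DatasetManifest",
    "TEMP_NORM_RANGE_C",
    "enumerate_param_grid",
    "render_sample",
    "normalize_temperature",
    "upsample_nearest",
    "sample_ssim",
    "ssim_filter",
    "build_dataset",
    "save_dataset",
    "load_dataset",
]

SCHEMA_VERSION = 1

#: Fixed temperature normalization range (degC) shared by the SSIM filter,
#: the training loss and the evaluation metrics.
TEMP_NORM_RANGE_C = (20.0, 90.0)


@dataclass(frozen=True)
class ParamGrid:
    """Value lists of the skewed-Gaussian parameter grid.

    Defaults follow the simulation protocol: centers +-1 mm step 0.5, widths
    0.5-1.1 mm step 0.2, x-skewness {-2, 2}, y-skewness 0, peak temperature
    40-90 degC step 5, rotation 0-90 deg step 15; the baseline temperature
    is drawn uniformly from [20, T_max - 1] per combination.
    """

    mu_x_mm: tuple = (-1.0, -0.5, 0.0, 0.5, 1.0)
    mu_y_mm: tuple = (-1.0, -0.5, 0.0, 0.5, 1.0)
    sigma_x_mm: tuple = (0.5, 0.7, 0.9, 1.1)
    sigma_y_mm: tuple = (0.5, 0.7, 0.9, 1.1)
    a_x: tuple = (-2.0, 2.0)
    a_y: tuple = (0.0,)
    t_max_c: tuple = (40.0, 45.0, 50.0, 55.0, 60.0, 65.0, 70.0, 75.0, 80.0, 85.0, 90.0)
    phi_deg: tuple = (0.0, 15.0, 30.0, 45.0, 60.0, 75.0, 90.0)

    def __post_init__(self):
        for name in ("mu_x_mm", "mu_y_mm", "sigma_x_mm", "sigma_y_mm", "a_x", "a_y", "t_max_c", "phi_deg"):
            vals = getattr(self, name)
            if len(vals) == 0:
                raise ConfigurationError(f"parameter {name} has no values")
        if min(self.t_max_c) <= 21.0:
            raise ConfigurationError("t_max values must exceed 21 degC for T_min sampling")

    @property
    def n_combinations(self) -> int:
        n = 1
        for name in ("mu_x_mm", "mu_y_mm", "sigma_x_mm", "sigma_y_mm", "a_x", "a_y", "t_max_c", "phi_deg"):
            n *= len(getattr(self, name))
        return n


def enumerate_param_grid(grid: ParamGrid, rng: np.random.Generator) -> list[SkewedGaussianParams]:
    """Cartesian product of the grid with a uniform T_min draw per combination."""
    out = []
    for mx, my, sx, sy, ax, ay, tmax, phi in itertools.product(
        grid.mu_x_mm, grid.mu_y_mm, grid.sigma_x_mm, grid.sigma_y_mm,
        grid.a_x, grid.a_y, grid.t_max_c, grid.phi_deg,
    ):
        out.append(
            SkewedGaussianParams(
                mu_x_mm=mx, mu_y_mm=my, sigma_x_mm=sx, sigma_y_mm=sy,
                a_x=ax, a_y=ay, phi_deg=phi, t_max_c=tmax,
                t_min_c=sample_tmin(tmax, rng),
            )
        )
    return out


def _default_render_db() -> EmissionDatabase:
    # Node span exceeds the 20-90 degC field range so every pixel's emission
    # is interpolable (same Boltzmann law as the shipped calibration).
    return synthesize_emission_database(
        temperatures_K=celsius_to_kelvin(np.arange(20.0, 95.0 + 1e-9, 5.0))
    )


@dataclass(frozen=True)
class SimConfig:
    """Forward-model configuration shared by all samples of a dataset.

    The 20x20 target and the 5x5 fiber grid share a centered 2.5 mm x 2.5 mm
    field of view (fiber centers at +-1 mm; each fiber maps onto a 4x4
    target block).
    """

    grid: GridSpec = DEFAULT_GRID
    beam: BeamModel = BeamModel()
    fiber: FiberModel = FiberModel()
    noise: NoiseConfig = NoiseConfig()
    calibration: CalibrationModel = replace(
        DEFAULT_CALIBRATION, valid_range_K=(celsius_to_kelvin(10.0), celsius_to_kelvin(120.0))
    )
    fov_mm: float = 2.5
    target_shape: tuple[int, int] = (20, 20)
    input_shape: tuple[int, int] = (5, 5)
    fiber_spacing_mm: float = 0.5

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class DatasetSample:
    """One paired training sample: low-res observation and high-res target (degC)."""

    input_c: np.ndarray  # (5, 5)
    target_c: np.ndarray  # (20, 20)
    params: SkewedGaussianParams
    seed: int


@dataclass
class DatasetManifest:
    n_total: int
    n_kept: int
    n_discarded: int
    ssim_cutoff: float
    seed: int
    grid_definition: dict
    config_hash: str
    schema_version: int = SCHEMA_VERSION

    def __post_init__(self):
        if self.n_total != self.n_kept + self.n_discarded:
            raise ParameterError("manifest counts must satisfy n_total = n_kept + n_discarded")


def _block_mean(a: np.ndarray, factor: int) -> np.ndarray:
    ny, nx = a.shape
    return a.reshape(ny // factor, factor, nx // factor, factor).mean(axis=(1, 3))


def _target_from_field(field_c: np.ndarray, sim: SimConfig) -> np.ndarray:
    """Block-mean downsample of the field over the central FOV to the target shape."""
    ny, nx = field_c.shape
    fov_px = int(round(sim.fov_mm / sim.grid.pixel_pitch_mm))
    ty, tx = sim.target_shape
    if fov_px % ty or fov_px % tx:
        raise ConfigurationError("FOV pixel count must be divisible by the target shape")
    y0 = (ny - fov_px) // 2
    x0 = (nx - fov_px) // 2
    crop = field_c[y0 : y0 + fov_px, x0 : x0 + fov_px]
    return _block_mean(crop, fov_px // ty)


def render_sample(
    params: SkewedGaussianParams, sim: SimConfig, rng: np.random.Generator, seed: int = 0
) -> DatasetSample:
    """Render one paired sample through the forward model.

    input: simulated 5x5 fiber-grid measurement (with detector noise);
    target: block-mean of the true field over the shared FOV.
    """
    field = make_skewed_gaussian_field(params, sim.grid)
    db = _render_db_cache(sim)
    image, _ = sample_fiber_grid(
        field,
        sim.beam,
        sim.fiber,
        db,
        sim.calibration,
        noise=sim.noise,
        rng=rng,
        n=sim.input_shape[0],
        spacing_mm=sim.fiber_spacing_mm,
    )
    target = _target_from_field(field.values_c, sim)
    return DatasetSample(input_c=image, target_c=target, params=params, seed=seed)


_DB_CACHE: dict[str, EmissionDatabase] = {}


def _render_db_cache(sim: SimConfig) -> EmissionDatabase:
    key = f"{sim.calibration.a}:{sim.calibration.b_K}"
    if key not in _DB_CACHE:
        _DB_CACHE[key] = synthesize_emission_database(
            model=sim.calibration,
            temperatures_K=celsius_to_kelvin(np.arange(15.0, 120.0 + 1e-9, 5.0)),
        )
    return _DB_CACHE[key]


def normalize_temperature(img_c: np.ndarray) -> np.ndarray:
    """Affine map of degC onto [0, 1] over the fixed range (20, 90) degC."""
    lo, hi = TEMP_NORM_RANGE_C
    return (np.asarray(img_c, dtype=float) - lo) / (hi - lo)


def upsample_nearest(img: np.ndarray, factor: int = 4) -> np.ndarray:
    return np.repeat(np.repeat(img, factor, axis=-2), factor, axis=-1)


def sample_ssim(sample: DatasetSample) -> float:
    """SSIM between the nearest-upsampled input and the target.

    Both images are normalized over the fixed 20-90 degC range; window 7
    (the 20x20 images are too small for the default window 11).
    """
    up = normalize_temperature(upsample_nearest(sample.input_c, 4))
    tgt = normalize_temperature(sample.target_c)
    return float(structural_similarity(up, tgt, win_size=7, data_range=1.0))


def ssim_filter(
    samples: list[DatasetSample], cutoff: float = 0.7
) -> tuple[list[DatasetSample], list[DatasetSample]]:
    """Split samples into (kept, discarded) by the SSIM >= cutoff rule."""
    kept, discarded = [], []
    for s in samples:
        (kept if sample_ssim(s) >= cutoff else discarded).append(s)
    return kept, discarded


def _stratified_order(params: list[SkewedGaussianParams], rng: np.random.Generator) -> np.ndarray:
    """Visit order that cycles through T_max strata (round-robin, shuffled within)."""
    tmax = np.array([p.t_max_c for p in params])
    order_within = {}
    for v in np.unique(tmax):
        idx = np.flatnonzero(tmax == v)
        rng.shuffle(idx)
        order_within[v] = list(idx)
    out = []
    keys = list(order_within)
    i = 0
    while any(order_within[k] for k in keys):
        k = keys[i % len(keys)]
        if order_within[k]:
            out.append(order_within[k].pop())
        i += 1
    return np.array(out, dtype=int)


def build_dataset(
    n: int = 5000,
    seed: int = 0,
    grid: ParamGrid = ParamGrid(),
    sim: SimConfig = SimConfig(),
    ssim_cutoff: float = 0.7,
    full_grid: bool = False,
) -> tuple[list[DatasetSample], DatasetManifest]:
    """Render and filter a dataset of paired samples.

    Walks a T_max-stratified random ordering of the parameter grid, rendering
    until ``n`` samples survive the SSIM filter (or the grid is exhausted);
    ``full_grid=True`` renders every combination instead.
    """
    rng = np.random.default_rng(seed)
    params = enumerate_param_grid(grid, rng)
    order = _stratified_order(params, rng)
    kept: list[DatasetSample] = []
    n_total = 0
    n_discarded = 0
    target_n = len(order) if full_grid else n
    for j in order:
        if not full_grid and len(kept) >= target_n:
            break
        sample = render_sample(params[j], sim, rng, seed=seed)
        n_total += 1
        if sample_ssim(sample) >= ssim_cutoff:
            kept.append(sample)
        else:
            n_discarded += 1
    manifest = DatasetManifest(
        n_total=n_total,
        n_kept=len(kept),
        n_discarded=n_discarded,
        ssim_cutoff=ssim_cutoff,
        seed=seed,
        # JSON-normalized (tuples -> lists) so the manifest round-trips the archive
        grid_definition=json.loads(json.dumps(dataclasses.asdict(grid))),
        config_hash=sim.config_hash(),
    )
    return kept, manifest


_PARAM_FIELDS = [
    "mu_x_mm", "mu_y_mm", "sigma_x_mm", "sigma_y_mm",
    "a_x", "a_y", "phi_deg", "t_max_c", "t_min_c",
]


def save_dataset(samples: list[DatasetSample], manifest: DatasetManifest, path) -> None:
    """Persist samples + manifest to HDF5 (losslessly round-trippable)."""
    inputs = np.stack([s.input_c for s in samples])
    targets = np.stack([s.target_c for s in samples])
    ptable = np.zeros(len(samples), dtype=[(f, "f8") for f in _PARAM_FIELDS])
    for i, s in enumerate(samples):
        for f in _PARAM_FIELDS:
            ptable[i][f] = getattr(s.params, f)
    with h5py.File(path, "w") as h5:
        h5.create_dataset("inputs", data=inputs)
        h5.create_dataset("targets", data=targets)
        h5.create_dataset("params", data=ptable)
        h5.attrs["manifest"] = json.dumps(dataclasses.asdict(manifest))
        h5.attrs["schema_version"] = SCHEMA_VERSION


def load_dataset(path) -> tuple[list[DatasetSample], DatasetManifest]:
    try:
        with h5py.File(path, "r") as h5:
            if int(h5.attrs.get("schema_version", -1)) != SCHEMA_VERSION:
                raise SchemaError(
                    f"dataset schema version {h5.attrs.get('schema_version')} != {SCHEMA_VERSION}"
                )
            inputs = h5["inputs"][...]
            targets = h5["targets"][...]
            ptable = h5["params"][...]
            manifest = DatasetManifest(**json.loads(h5.attrs["manifest"]))
    except OSError as exc:
        raise SchemaError(f"cannot read dataset archive {path}: {exc}") from exc
    samples = []
    for i in range(inputs.shape[0]):
        kwargs = {f: float(ptable[i][f]) for f in _PARAM_FIELDS}
        samples.append(
            DatasetSample(
                input_c=inputs[i],
                target_c=targets[i],
                params=SkewedGaussianParams(**kwargs),
                seed=manifest.seed,
            )
        )
    return samples, manifest
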