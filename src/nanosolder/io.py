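"""File formats: spectra (CSV), calibration (JSON), frames (TIFF/PNG +
JSON sidecar), fields/maps/databases (HDF5)."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import imageio.v3 as iio
import numpy as np
import tifffile

from .errors import ParameterError, SchemaError
from .fields import GridSpec, TemperatureField
from .imaging import ChannelFrame, TemperatureMap
from .spectra import CalibrationModel, EmissionDatabase, EmissionSpectrum

__all__ = [
    "read_spectrum",
    "write_spectrum",
    "read_calibration",
    "write_calibration",
    "read_frame",
    "write_frame",
    "read_field",
    "write_field",
    "read_temperature_map",
    "write_temperature_map",
    "read_database",
    "write_database",
]

SPECTRUM_HEADER = "wavelength_nm,intensity_counts"


def write_spectrum(spectrum: EmissionSpectrum, path) -> None:
    with open(path, "w") as fh:
        fh.write(SPECTRUM_HEADER + "\n")
        for wl, it in zip(spectrum.wavelengths_nm, spectrum.intensities):
            fh.write(f"{float(wl)!r},{float(it)!r}\n")


def read_spectrum(path, acquisition_time_ms: float = 500.0) -> EmissionSpectrum:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
        if header != SPECTRUM_HEADER:
            raise SchemaError(f"{path}: expected header '{SPECTRUM_HEADER}', got '{header}'")
        wl, it = [], []
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            try:
                if len(parts) != 2:
                    raise ValueError("expected two columns")
                wl.append(float(parts[0]))
                it.append(float(parts[1]))
            except ValueError as exc:
                raise SchemaError(f"{path}:{lineno}: malformed row ({exc})") from exc
    try:
        return EmissionSpectrum(np.array(wl), np.array(it), acquisition_time_ms=acquisition_time_ms)
    except ParameterError as exc:
        raise SchemaError(f"{path}: invalid spectrum ({exc})") from exc


def write_calibration(model: CalibrationModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {"a": model.a, "b_K": model.b_K, "valid_range_K": list(model.valid_range_K)},
            fh,
            indent=2,
        )


def read_calibration(path) -> CalibrationModel:
    with open(path) as fh:
        data = json.load(fh)
    try:
        return CalibrationModel(
            a=float(data["a"]),
            b_K=float(data["b_K"]),
            valid_range_K=tuple(data.get("valid_range_K", (303.15, 353.15))),
        )
    except (KeyError, TypeError) as exc:
        raise SchemaError(f"{path}: invalid calibration file ({exc})") from exc


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_frame(frame: ChannelFrame, path) -> None:
    """16-bit grayscale TIFF/PNG plus a JSON sidecar with the metadata."""
    path = Path(path)
    counts = np.round(frame.counts)
    if counts.max(initial=0) > np.iinfo(np.uint16).max:
        raise ParameterError("frame counts exceed the 16-bit range")
    img = counts.astype(np.uint16)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, img)
    elif path.suffix.lower() == ".png":
        iio.imwrite(path, img)
    else:
        raise ParameterError(f"unsupported frame format: {path.suffix}")
    meta = {
        "channel": frame.channel,
        "gain_dB": frame.gain_db,
        "acquisition_time_ms": frame.acquisition_time_ms,
        "position_mm": list(frame.position_mm) if frame.position_mm else None,
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(meta, fh, indent=2)


def read_frame(path) -> ChannelFrame:
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise SchemaError(f"missing sidecar metadata file {sidecar}")
    if path.suffix.lower() in (".tif", ".tiff"):
        img = tifffile.imread(path)
    elif path.suffix.lower() == ".png":
        img = iio.imread(path)
    else:
        raise ParameterError(f"unsupported frame format: {path.suffix}")
    if img.dtype != np.uint16:
        raise SchemaError(f"{path}: expected 16-bit grayscale, got {img.dtype}")
    if img.ndim != 2:
        raise SchemaError(f"{path}: expected a single-channel image")
    with open(sidecar) as fh:
        meta = json.load(fh)
    return ChannelFrame(
        counts=img.astype(float),
        channel=meta["channel"],
        gain_db=float(meta["gain_dB"]),
        acquisition_time_ms=float(meta["acquisition_time_ms"]),
        position_mm=tuple(meta["position_mm"]) if meta.get("position_mm") else None,
    )


def write_field(field: TemperatureField, path) -> None:
    with h5py.File(path, "w") as h5:
        ds = h5.create_dataset("field_C", data=field.values_c)
        ds.attrs["pixel_pitch_um"] = field.grid.pixel_pitch_um
        ds.attrs["extent_mm"] = field.grid.extent_mm


def read_field(path) -> TemperatureField:
    with h5py.File(path, "r") as h5:
        values = h5["field_C"][...]
        extent = tuple(h5["field_C"].attrs["extent_mm"])
    return TemperatureField(values, GridSpec(shape=values.shape, extent_mm=extent))


def write_temperature_map(tmap: TemperatureMap, path) -> None:
    with h5py.File(path, "w") as h5:
        h5.create_dataset("temp_C", data=tmap.temp_c)
        h5.create_dataset("valid", data=tmap.valid)
        if tmap.pixel_pitch_um is not None:
            h5.attrs["pixel_pitch_um"] = tmap.pixel_pitch_um


def read_temperature_map(path) -> TemperatureMap:
    with h5py.File(path, "r") as h5:
        return TemperatureMap(
            temp_c=h5["temp_C"][...],
            valid=h5["valid"][...].astype(bool),
            pixel_pitch_um=float(h5.attrs["pixel_pitch_um"]) if "pixel_pitch_um" in h5.attrs else None,
        )


def write_database(db: EmissionDatabase, path) -> None:
    with h5py.File(path, "w") as h5:
        h5.create_dataset("wavelengths_nm", data=db.wavelengths_nm)
        h5.create_dataset("temperatures_K", data=db.temperatures_K)
        h5.create_dataset("intensities", data=db.intensities)


def read_database(path) -> EmissionDatabase:
    with h5py.File(path, "r") as h5:
        return EmissionDatabase(
            temperatures_K=h5["temperatures_K"][...],
            wavelengths_nm=h5["wavelengths_nm"][...],
            intensities=h5["intensities"][...],
        )
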