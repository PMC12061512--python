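"""Container I/O: HDF5 field-series files, TIFF angiogram stacks, TOML config.

A field-series container is a single HDF5 file holding the reconstructed
complex field of one acquisition protocol::

    /field          complex 4-D dataset, axes (z, x, y, t)
    attrs: mode     "repeated_A" | "repeated_B"
           n_repeats, dt_ms, pitch_um (3-vector, z/x/y order)

Angiograms and masks travel as multi-page 32-bit-float TIFF stacks, one
page per z-slice (slice 0 = shallowest), with a plain-text sidecar
``<path>.meta.txt`` recording pitch and provenance.
"""

from __future__ import annotations

import dataclasses
import tomllib
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .core import (
    AcquisitionProtocol,
    AngiogramVolume,
    BinaryMask2D,
    BinaryMask3D,
    FieldSeriesVolume,
    FormatError,
    PipelineConfig,
    ValidationError,
)

__all__ = [
    "save_field_series",
    "load_field_series",
    "save_angiogram",
    "load_angiogram",
    "save_mask2d",
    "save_mask3d",
    "load_mask3d",
    "load_config",
]

_REQUIRED_ATTRS = ("mode", "n_repeats", "dt_ms", "pitch_um")


def save_field_series(vol: FieldSeriesVolume, path: str | Path) -> None:
    """Write a validated field series to an HDF5 container."""
    with h5py.File(path, "w") as f:
        f.create_dataset("field", data=vol.data)
        f.attrs["mode"] = vol.protocol.mode
        f.attrs["n_repeats"] = vol.protocol.n_repeats
        f.attrs["dt_ms"] = vol.protocol.dt_ms
        f.attrs["pitch_um"] = np.asarray(vol.pitch_um, dtype=float)


def load_field_series(path: str | Path) -> FieldSeriesVolume:
    """Read and validate a field-series container.

    Raises
    ------
    FormatError
        If the ``/field`` dataset or any protocol attribute is missing.
    ValidationError
        If the stored data violate the container invariants (e.g. the
        t-axis length disagrees with ``n_repeats``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as f:
        if "field" not in f:
            raise FormatError(f"{path}: missing dataset 'field'")
        for key in _REQUIRED_ATTRS:
            if key not in f.attrs:
                raise FormatError(f"{path}: missing attribute {key!r}")
        data = f["field"][...]
        protocol = AcquisitionProtocol(
            mode=str(f.attrs["mode"]),
            n_repeats=int(f.attrs["n_repeats"]),
            dt_ms=float(f.attrs["dt_ms"]),
        )
        pitch = tuple(float(p) for p in np.atleast_1d(f.attrs["pitch_um"]))
    return FieldSeriesVolume(data=data, pitch_um=pitch, protocol=protocol)


def _write_sidecar(path: Path, pitch_um, provenance: str) -> None:
    lines = [f"pitch_um: {' '.join(f'{p:g}' for p in pitch_um)}", f"provenance: {provenance}"]
    path.with_suffix(path.suffix + ".meta.txt").write_text("\n".join(lines) + "\n")


def _read_sidecar(path: Path) -> dict:
    meta_path = path.with_suffix(path.suffix + ".meta.txt")
    meta: dict = {}
    if meta_path.exists():
        for line in meta_path.read_text().splitlines():
            key, _, value = line.partition(":")
            meta[key.strip()] = value.strip()
    return meta


def save_angiogram(vol: AngiogramVolume, path: str | Path) -> None:
    """Write an angiogram as a multi-page float32 TIFF plus text sidecar."""
    if not np.isfinite(vol.data).all():  # revalidate: data may have been mutated
        raise ValidationError("angiogram contains non-finite values")
    path = Path(path)
    # photometric/metadata force one grayscale page per z-slice even when a
    # small leading dimension could be mistaken for color samples
    tifffile.imwrite(path, vol.data.astype(np.float32),
                     photometric="minisblack", metadata={"axes": "ZYX"})
    _write_sidecar(path, vol.pitch_um, vol.provenance)


def load_angiogram(path: str | Path, provenance: str | None = None,
                   pitch_um=None) -> AngiogramVolume:
    """Read a float TIFF stack back into an :class:`AngiogramVolume`.

    Sidecar metadata is used when present; explicit arguments override it.
    """
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    meta = _read_sidecar(path)
    if provenance is None:
        provenance = meta.get("provenance", "omag")
    if pitch_um is None:
        if "pitch_um" in meta:
            pitch_um = tuple(float(p) for p in meta["pitch_um"].split())
        else:
            pitch_um = (1.0, 1.0, 1.0)
    return AngiogramVolume(data=np.asarray(data, dtype=np.float32),
                           pitch_um=pitch_um, provenance=provenance)


def save_mask2d(mask: BinaryMask2D, path: str | Path) -> None:
    """Write an en-face mask as a 0/1 float32 TIFF."""
    tifffile.imwrite(Path(path), mask.data.astype(np.float32),
                     photometric="minisblack")


def save_mask3d(mask: BinaryMask3D, path: str | Path) -> None:
    """Write a 3-D mask as a 0/1 float32 TIFF stack."""
    tifffile.imwrite(Path(path), mask.data.astype(np.float32),
                     photometric="minisblack", metadata={"axes": "ZYX"})


def load_mask3d(path: str | Path) -> BinaryMask3D:
    data = tifffile.imread(Path(path))
    if data.ndim == 2:
        data = data[None]
    return BinaryMask3D(data=data > 0.5)


_CONFIG_FIELDS = {f.name for f in dataclasses.fields(PipelineConfig)}


def load_config(path: str | Path) -> PipelineConfig:
    """Read a TOML config file, applying defaults for absent keys."""
    path = Path(path)
    with open(path, "rb") as f:
        raw = tomllib.load(f)
    unknown = set(raw) - _CONFIG_FIELDS - {"phantom"}
    if unknown:
        raise FormatError(f"{path}: unknown config keys {sorted(unknown)}")
    kwargs = {k: v for k, v in raw.items() if k in _CONFIG_FIELDS}
    for key in ("oof_scales_um", "mip_z_range"):
        if key in kwargs and kwargs[key] is not None:
            kwargs[key] = tuple(kwargs[key])
    return PipelineConfig(**kwargs)
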