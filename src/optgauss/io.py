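"""TIFF/JSON/YAML input-output for images, sinograms and beam configs."""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .beams import BeamParameters
from .projection import Sinogram

__all__ = [
    "save_image",
    "load_image",
    "save_sinogram",
    "load_sinogram",
    "load_beam_config",
    "beams_from_config",
]


def save_image(path, image: np.ndarray, meta: dict | None = None) -> None:
    """Write a float32 TIFF; metadata goes to a JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))
    if meta is not None:
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_image(path) -> np.ndarray:
    return np.asarray(tifffile.imread(path), dtype=float)


def save_sinogram(path, sinogram: Sinogram) -> None:
    """Float32 TIFF (detector x angle) plus a JSON sidecar with geometry."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(sinogram.values, dtype=np.float32))
    sidecar = {
        "angles_deg": list(map(float, sinogram.angles)),
        "pixel_pitch_um": sinogram.pixel_pitch,
        "meta": _jsonable(sinogram.meta),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_sinogram(path) -> Sinogram:
    path = Path(path)
    values = np.asarray(tifffile.imread(path), dtype=float)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return Sinogram(values, np.asarray(sidecar["angles_deg"]),
                    sidecar["pixel_pitch_um"], meta=sidecar.get("meta", {}))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def load_beam_config(path) -> dict:
    """Read a JSON or YAML experiment/beam configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def beams_from_config(config: dict) -> list[BeamParameters]:
    """Beam parameter sets from config keys.

    Recognized keys: ``na``, ``wavelength_nm``, ``medium_index``,
    ``focal_offset_um``, ``stretch``, ``kernel`` in
    {gbm, sgbm, dirac, multifocal}, ``multifocal_offsets_um``.
    A multifocal entry expands to one beam per focal offset.
    """
    kernel = config.get("kernel", "gbm")
    base = dict(
        numerical_aperture=config.get("na", 0.14),
        wavelength=config.get("wavelength_nm", 600.0) / 1000.0,
        medium_index=config.get("medium_index", 1.0),
        focal_offset_z0=config.get("focal_offset_um", 0.0),
    )
    if kernel == "dirac":
        return [BeamParameters(**base, dirac=True)]
    if kernel == "sgbm":
        stretch = float(config.get("stretch", 5.0))
        if not math.isinf(stretch) and stretch < 1:
            raise ValueError("stretch must be >= 1")
        return [BeamParameters(**base, stretch_cS=stretch)]
    if kernel == "multifocal":
        offsets = config.get("multifocal_offsets_um", [-300.0, 0.0, 300.0])
        return [BeamParameters(**{**base, "focal_offset_z0": float(z0)})
                for z0 in offsets]
    if kernel == "gbm":
        return [BeamParameters(**base)]
    raise ValueError(f"unknown kernel kind {kernel!r}")
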