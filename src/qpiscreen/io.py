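"""File I/O: 32-bit TIFF images with JSON sidecars, designs, results.

Every image on disk is a grayscale float32 TIFF accompanied by a
``<name>.json`` sidecar holding the load-bearing metadata (type, pixel
size, wavelength, carrier or z offsets). Units are not optional: a phase
TIFF without a pixel size cannot be interpreted and is rejected.
Field files follow the pattern ``{plate}_{well}_{field}_{t}.tif``.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import tifffile
import yaml

from .optics import Hologram, IntensityStack
from .phase import PhaseImage
from .synth import PlateDesign, WellSpec

__all__ = [
    "write_phase_tiff",
    "read_phase_tiff",
    "write_hologram_tiff",
    "write_stack_tiff",
    "read_image",
    "field_filename",
    "write_design",
    "read_design",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def _write_sidecar(path: Path, payload: dict[str, Any]) -> None:
    _sidecar_path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def _read_sidecar(path: Path) -> dict[str, Any]:
    side = _sidecar_path(path)
    if not side.exists():
        raise FileNotFoundError(
            f"missing metadata sidecar {side.name}: pixel size and units are "
            "load-bearing and cannot be guessed"
        )
    return json.loads(side.read_text())


def field_filename(plate: str, well: str, fld: int, t_index: int = 0) -> str:
    return f"{plate}_{well}_{fld}_{t_index}.tif"


def write_phase_tiff(phase: PhaseImage, path: str | Path) -> Path:
    """Write an OPD map as float32 TIFF + JSON sidecar (lossless for f32)."""
    path = Path(path)
    tifffile.imwrite(path, phase.opd.astype(np.float32))
    _write_sidecar(
        path,
        {
            "type": "phase",
            "units": "nm",
            "pixel_size_um": phase.pixel_size_um,
            "meta": _jsonable(phase.meta),
        },
    )
    return path


def read_phase_tiff(path: str | Path) -> PhaseImage:
    """Read an OPD TIFF; rejects integer-typed images and missing metadata."""
    path = Path(path)
    side = _read_sidecar(path)
    if side.get("type") != "phase":
        raise ValueError(f"{path.name} is a {side.get('type')!r} image, not phase")
    if "pixel_size_um" not in side:
        raise ValueError(f"{path.name}: sidecar lacks pixel_size_um")
    data = tifffile.imread(path)
    if np.issubdtype(data.dtype, np.integer):
        raise ValueError(
            f"{path.name} is {data.dtype}: expected 32-bit float OPD in nm "
            "(convert with a known calibration before loading)"
        )
    return PhaseImage(
        np.asarray(data, dtype=np.float64),
        pixel_size_um=float(side["pixel_size_um"]),
        meta=side.get("meta", {}),
    )


def write_hologram_tiff(holo: Hologram, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, holo.intensity.astype(np.float32))
    _write_sidecar(
        path,
        {
            "type": "hologram",
            "pixel_size_um": holo.pixel_size_um,
            "wavelength_nm": holo.wavelength_nm,
            "carrier": list(holo.carrier) if holo.carrier else None,
            "meta": _jsonable(holo.meta),
        },
    )
    return path


def write_stack_tiff(stack: IntensityStack, path: str | Path) -> Path:
    """Multi-page TIFF, one page per defocus plane."""
    path = Path(path)
    tifffile.imwrite(
        path,
        stack.planes.astype(np.float32),
        photometric="minisblack",
        planarconfig="contig",
    )
    _write_sidecar(
        path,
        {
            "type": "stack",
            "pixel_size_um": stack.pixel_size_um,
            "wavelength_nm": stack.wavelength_nm,
            "z_offsets_um": list(stack.z_offsets_um),
            "meta": _jsonable(stack.meta),
        },
    )
    return path


def read_image(path: str | Path) -> PhaseImage | Hologram | IntensityStack:
    """Load any package image, dispatching on the sidecar ``type`` tag."""
    path = Path(path)
    side = _read_sidecar(path)
    kind = side.get("type")
    if kind == "phase":
        return read_phase_tiff(path)
    data = np.asarray(tifffile.imread(path), dtype=np.float64)
    if kind == "hologram":
        carrier = side.get("carrier")
        return Hologram(
            data,
            wavelength_nm=float(side["wavelength_nm"]),
            pixel_size_um=float(side["pixel_size_um"]),
            carrier=tuple(carrier) if carrier else None,
            meta=side.get("meta", {}),
        )
    if kind == "stack":
        return IntensityStack(
            data,
            z_offsets_um=tuple(side["z_offsets_um"]),
            wavelength_nm=float(side["wavelength_nm"]),
            pixel_size_um=float(side["pixel_size_um"]),
            meta=side.get("meta", {}),
        )
    raise ValueError(f"unknown image type tag {kind!r} in {path.name}")


def write_design(design: PlateDesign, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "fields_per_well": design.fields_per_well,
        "field_size": list(design.field_size),
        "pixel_size_um": design.pixel_size_um,
        "seed": design.seed,
        "confluency_range": list(design.confluency_range),
        "noise_sd_nm": design.noise_sd_nm,
        "background_offset_sd_nm": design.background_offset_sd_nm,
        "wells": [dataclasses.asdict(w) for w in design.wells],
    }
    path.write_text(yaml.safe_dump(payload, sort_keys=False))
    return path


def read_design(path: str | Path) -> PlateDesign:
    payload = yaml.safe_load(Path(path).read_text())
    wells = [WellSpec(**w) for w in payload.pop("wells")]
    payload["field_size"] = tuple(payload["field_size"])
    payload["confluency_range"] = tuple(payload["confluency_range"])
    return PlateDesign(wells=wells, **payload)


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
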