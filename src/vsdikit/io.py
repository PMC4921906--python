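"""File formats: multi-page TIFF stacks with JSON sidecars, series directories.

Raw stacks are written as 16-bit count TIFFs (rounded), dF/F stacks as 32-bit
float TIFFs; every TIFF gets a ``<name>.json`` sidecar holding the acquisition
metadata and the geometry, so a stack file is self-describing.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import tifffile

from .errors import UsageError
from .geometry import GeometryModel
from .preprocess import DFFStack
from .synthgen import AcquisitionSeries, Condition, FrameStack, Protocol, SimConfig

SCHEMA_VERSION = "1"


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def _base_metadata(obj, geometry: GeometryModel | None) -> dict:
    meta = {
        "schema_version": SCHEMA_VERSION,
        "dt_ms": obj.dt_ms,
        "stim_frame": obj.stim_frame,
        "acquisition_time_min": obj.acquisition_time_min,
        "condition": obj.condition,
    }
    if geometry is not None:
        meta["geometry"] = geometry.to_dict()
    return meta


def save_framestack(stack: FrameStack, path) -> Path:
    """Write a raw stack as a 16-bit multi-page TIFF plus a JSON sidecar."""
    path = Path(path)
    data = np.clip(np.rint(stack.data), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(path, data)
    meta = _base_metadata(stack, stack.geometry)
    meta["kind"] = "raw_counts_uint16"
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def load_framestack(path) -> FrameStack:
    path = Path(path)
    data = tifffile.imread(path).astype(float)
    meta = json.loads(_sidecar_path(path).read_text())
    geometry = GeometryModel.from_dict(meta["geometry"]) if "geometry" in meta else None
    return FrameStack(
        data=data,
        dt_ms=meta["dt_ms"],
        stim_frame=meta["stim_frame"],
        geometry=geometry,
        acquisition_time_min=meta.get("acquisition_time_min", 0.0),
        condition=meta.get("condition", ""),
    )


def save_dff(dff: DFFStack, path) -> Path:
    """Write a dF/F stack as 32-bit float TIFF plus a JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, dff.data.astype(np.float32))
    meta = _base_metadata(dff, dff.geometry)
    meta["kind"] = "dff_float32"
    meta["smoothing_applied"] = dff.smoothing_applied
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    f0_path = path.with_name(path.stem + "_f0.tif")
    tifffile.imwrite(f0_path, dff.f0_map.astype(np.float32))
    return path


def load_dff(path) -> DFFStack:
    path = Path(path)
    data = tifffile.imread(path).astype(float)
    meta = json.loads(_sidecar_path(path).read_text())
    geometry = GeometryModel.from_dict(meta["geometry"]) if "geometry" in meta else None
    f0_path = path.with_name(path.stem + "_f0.tif")
    f0 = tifffile.imread(f0_path).astype(float) if f0_path.exists() else np.ones(data.shape[1:])
    return DFFStack(
        data=data,
        dt_ms=meta["dt_ms"],
        stim_frame=meta["stim_frame"],
        f0_map=f0,
        smoothing_applied=meta.get("smoothing_applied", 0),
        geometry=geometry,
        acquisition_time_min=meta.get("acquisition_time_min", 0.0),
        condition=meta.get("condition", ""),
    )


def save_series(series: AcquisitionSeries, dirpath) -> Path:
    """Write an acquisition series to a directory (one TIFF per acquisition)."""
    dirpath = Path(dirpath)
    dirpath.mkdir(parents=True, exist_ok=True)
    names = []
    for i, stack in enumerate(series):
        name = f"acq{i:02d}_{stack.condition or 'none'}_t{stack.acquisition_time_min:g}.tif"
        save_framestack(stack, dirpath / name)
        names.append(name)
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "acquisitions": names,
        "protocol": dataclasses.asdict(series.protocol),
        "condition": dataclasses.asdict(series.condition),
        "context": (dataclasses.asdict(series.context)
                    if series.context is not None else None),
        "cfg": dataclasses.asdict(series.cfg),
        "geometry": series.geometry.to_dict(),
    }
    (dirpath / "series.json").write_text(json.dumps(manifest, indent=1))
    return dirpath


def load_series(dirpath) -> AcquisitionSeries:
    dirpath = Path(dirpath)
    manifest_path = dirpath / "series.json"
    if not manifest_path.exists():
        raise UsageError(f"{dirpath} does not contain a series.json manifest")
    manifest = json.loads(manifest_path.read_text())
    geometry = GeometryModel.from_dict(manifest["geometry"])
    stacks = [load_framestack(dirpath / name) for name in manifest["acquisitions"]]
    for s in stacks:
        s.geometry = geometry
    def _condition(d: dict | None) -> Condition | None:
        if d is None:
            return None
        d = dict(d)
        d["hyper_scale_by_layer"] = dict(d.get("hyper_scale_by_layer", {}))
        d["potentiation_by_layer"] = {
            k: tuple(v) for k, v in d.get("potentiation_by_layer", {}).items()
        }
        return Condition(**d)

    return AcquisitionSeries(
        stacks=stacks,
        protocol=Protocol(**manifest["protocol"]),
        condition=_condition(manifest["condition"]),
        geometry=geometry,
        cfg=SimConfig(**dict(manifest["cfg"])),
        context=_condition(manifest.get("context")),
    )
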