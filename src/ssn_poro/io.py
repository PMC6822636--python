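"""Readers/writers for the package's on-disk formats and run manifests.

Maps travel as single-channel 32-bit float TIFF plus a JSON sidecar carrying
pixel spacing, units and provenance (TIFF resolution tags are ignored to avoid
dialect ambiguity); masks as 8-bit TIFF.  Radial profiles are 2-column CSV with
a header naming the units; parameter sets and configs are JSON (YAML accepted
on input and normalized to JSON in the manifest).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .boundary_stress import BoundaryStress
from .model_core import GrowthStressParams, PressureProfileParams, RadialProfile
from .phantom import ScalarMap

__all__ = [
    "write_scalar_map",
    "read_scalar_map",
    "write_profile_csv",
    "read_profile_csv",
    "params_to_json",
    "params_from_json",
    "load_config",
    "write_manifest",
]

PathLike = Union[str, Path]


def write_scalar_map(smap: ScalarMap, path: PathLike) -> None:
    """Write ``<path>.tif`` (float32 values), ``<path>_mask.tif`` and ``<path>.json``."""
    path = Path(path)
    base = path.with_suffix("") if path.suffix == ".tif" else path
    tifffile.imwrite(str(base) + ".tif", np.asarray(smap.values, dtype=np.float32))
    if smap.mask is not None:
        tifffile.imwrite(str(base) + "_mask.tif", smap.mask.astype(np.uint8))
    sidecar = {"pixel_mm": smap.pixel_mm, "units": smap.units, "meta": _jsonable(smap.meta)}
    Path(str(base) + ".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def read_scalar_map(path: PathLike, mask_path: Optional[PathLike] = None) -> ScalarMap:
    """Read a map written by :func:`write_scalar_map`; sidecar JSON is mandatory."""
    path = Path(path)
    base = path.with_suffix("") if path.suffix == ".tif" else path
    sidecar_path = Path(str(base) + ".json")
    if not sidecar_path.exists():
        raise ValueError(
            f"missing sidecar {sidecar_path.name}: cannot determine pixel spacing and units"
        )
    sidecar = json.loads(sidecar_path.read_text())
    if "units" not in sidecar or "pixel_mm" not in sidecar:
        raise ValueError(f"sidecar {sidecar_path.name} lacks units/pixel_mm")
    values = tifffile.imread(str(base) + ".tif")
    if mask_path is None:
        candidate = Path(str(base) + "_mask.tif")
        mask_path = candidate if candidate.exists() else None
    mask = tifffile.imread(str(mask_path)).astype(bool) if mask_path is not None else None
    return ScalarMap(
        values=values,
        pixel_mm=float(sidecar["pixel_mm"]),
        units=str(sidecar["units"]),
        mask=mask,
        meta=sidecar.get("meta", {}),
    )


def write_profile_csv(profile: RadialProfile, path: PathLike) -> None:
    df = pd.DataFrame({"r": profile.r, f"value_{_unit_slug(profile.units)}": profile.values})
    if profile.counts is not None:
        df["count"] = profile.counts
    df.to_csv(path, index=False, lineterminator="\n")


def read_profile_csv(path: PathLike) -> RadialProfile:
    df = pd.read_csv(path)
    value_cols = [c for c in df.columns if c.startswith("value")]
    if "r" not in df.columns or not value_cols:
        raise ValueError("profile CSV must have columns r and value_<units>")
    units = value_cols[0].split("_", 1)[1] if "_" in value_cols[0] else "unknown"
    counts = df["count"].to_numpy() if "count" in df.columns else None
    return RadialProfile(
        r=df["r"].to_numpy(), values=df[value_cols[0]].to_numpy(), units=units, counts=counts
    )


def _unit_slug(units: str) -> str:
    return units.replace("/", "_per_").replace(" ", "_").lower() or "unknown"


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def params_to_json(params, path: PathLike) -> None:
    """Serialize a parameter dataclass as a JSON object keyed by its field names."""
    Path(path).write_text(json.dumps(_jsonable(params), indent=2, sort_keys=True))


_PARAM_TYPES = {
    "pressure": PressureProfileParams,
    "growth": GrowthStressParams,
    "boundary": BoundaryStress,
}


def params_from_json(path: PathLike, kind: str):
    """Load a parameter set; ``kind`` is one of 'pressure', 'growth', 'boundary'."""
    if kind not in _PARAM_TYPES:
        raise ValueError(f"kind must be one of {sorted(_PARAM_TYPES)}, got {kind!r}")
    data = json.loads(Path(path).read_text())
    return _PARAM_TYPES[kind](**data)


def load_config(path: PathLike) -> dict:
    """Load a JSON or YAML run configuration into a plain dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        cfg = yaml.safe_load(text)
    else:
        cfg = json.loads(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping at top level")
    return cfg


def write_manifest(out_dir: PathLike, command: str, config: dict, seed: Optional[int]) -> Path:
    """Write the reproducibility manifest (config echo, version, seed) for a run."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "ssn-poro",
        "version": __version__,
        "command": command,
        "seed": seed,
        "config": _jsonable(config),
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
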