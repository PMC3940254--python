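"""Readers and writers: feature tables (CSV), images (TIFF/PNG), volumes
(raw grid + JSON sidecar), YAML configs and result files.

Conventions: UTF-8 CSV with '.' decimal separator, empty cell = missing
value, percentages stored on the 0-100 scale.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .pet import UptakeVolume

__all__ = [
    "SchemaError",
    "read_feature_table",
    "write_feature_table",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "read_volume",
    "write_volume",
    "read_yaml",
    "write_yaml",
    "write_json",
    "file_digest",
]

REQUIRED_TABLE_COLUMNS = ("sample_id", "line")


class SchemaError(ValueError):
    """A file does not match its expected column schema."""


def write_feature_table(path: str | Path, table: pd.DataFrame) -> Path:
    """Write a feature table as CSV; NaN cells become empty strings."""
    path = Path(path)
    for col in REQUIRED_TABLE_COLUMNS:
        if col not in table.columns:
            raise SchemaError(f"feature table lacks required column {col!r}")
    table.to_csv(path, index=False, na_rep="")
    return path


def read_feature_table(path: str | Path,
                       expected_columns: list[str] | None = None) -> pd.DataFrame:
    """Read a feature-table CSV, preserving empty cells as NaN.

    With ``expected_columns`` given, unknown columns raise a SchemaError
    naming the offending column(s).
    """
    table = pd.read_csv(path)
    for col in REQUIRED_TABLE_COLUMNS:
        if col not in table.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    if expected_columns is not None:
        allowed = set(REQUIRED_TABLE_COLUMNS) | set(expected_columns)
        unknown = [c for c in table.columns if c not in allowed]
        if unknown:
            raise SchemaError(f"{path}: unknown column(s) {unknown}")
    return table


def write_image(path: str | Path, pixels: np.ndarray) -> Path:
    """Write a grey-value image as 16-bit TIFF (values rounded)."""
    path = Path(path)
    data = np.clip(np.round(np.asarray(pixels)), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, data)
    return path


def read_image(path: str | Path) -> np.ndarray:
    return np.asarray(tifffile.imread(path)).astype(float)


def write_mask(path: str | Path, mask: np.ndarray) -> Path:
    """Write a binary mask as 8-bit PNG (0/255)."""
    path = Path(path)
    iio.imwrite(path, (np.asarray(mask, bool) * np.uint8(255)))
    return path


def read_mask(path: str | Path) -> np.ndarray:
    return np.asarray(iio.imread(path)) > 0


def write_volume(path: str | Path, volume: UptakeVolume) -> Path:
    """Write an uptake volume as a raw ``.npy`` grid plus a JSON sidecar
    carrying voxel size and injection metadata."""
    path = Path(path)
    if path.suffix != ".npy":
        path = path.with_suffix(".npy")
    np.save(path, volume.voxels)
    sidecar = {
        "voxel_size_mm": list(volume.voxel_size),
        "injected_activity_MBq": volume.injected_activity,
        "body_weight_g": volume.body_weight,
        "sample_id": volume.sample_id,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_volume(path: str | Path) -> UptakeVolume:
    path = Path(path)
    if path.suffix != ".npy":
        path = path.with_suffix(".npy")
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing JSON sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    return UptakeVolume(
        voxels=np.load(path),
        voxel_size=tuple(meta["voxel_size_mm"]),
        injected_activity=meta["injected_activity_MBq"],
        body_weight=meta["body_weight_g"],
        sample_id=meta.get("sample_id", "sample"),
    )


def read_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        obj = yaml.safe_load(fh)
    if obj is None:
        obj = {}
    if not isinstance(obj, dict):
        raise SchemaError(f"{path}: top-level YAML must be a mapping")
    return obj


def write_yaml(path: str | Path, obj: dict) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(obj, sort_keys=True))
    return path


def write_json(path: str | Path, obj) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
    return path


def file_digest(path: str | Path) -> str:
    """SHA-256 hex digest of a file's bytes."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
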