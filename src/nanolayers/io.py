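"""TIFF and tabular I/O with JSON sidecars.

Images travel as TIFF (32-bit float by default, 8-bit with documented
min-max scaling on request) with a companion ``<name>.json`` sidecar
holding the pixel size and provenance/ground-truth dictionary, so that
a written artifact is self-describing.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import tifffile

from nanolayers.containers import ImageStack, InvalidParameterError, SuperResImage

__all__ = [
    "write_stack", "read_stack", "write_image", "read_image",
    "read_roi_table", "write_table",
]

ROI_COLUMNS = ["x_um", "y_um", "width_um", "height_um", "angle_deg",
               "replicate_id"]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _write_sidecar(path: Path, payload: dict[str, Any]) -> None:
    _sidecar_path(path).write_text(json.dumps(payload, indent=2))


def _read_sidecar(path: Path) -> dict[str, Any]:
    sc = _sidecar_path(path)
    return json.loads(sc.read_text()) if sc.exists() else {}


def write_stack(path: str | Path, stack: ImageStack) -> None:
    path = Path(path)
    tifffile.imwrite(path, stack.frames.astype(np.float32))
    _write_sidecar(path, {"pixel_size_nm": stack.pixel_size_nm,
                          "channel_label": stack.channel_label,
                          "metadata": stack.metadata})


def read_stack(path: str | Path, pixel_size_nm: float | None = None) -> ImageStack:
    path = Path(path)
    frames = np.asarray(tifffile.imread(path), dtype=float)
    side = _read_sidecar(path)
    px = pixel_size_nm or side.get("pixel_size_nm")
    if px is None:
        raise InvalidParameterError(
            f"{path}: pixel size not given and no sidecar found")
    return ImageStack(frames=frames, pixel_size_nm=float(px),
                      channel_label=side.get("channel_label", ""),
                      metadata=side.get("metadata", {}))


def write_image(path: str | Path, image: SuperResImage,
                as_uint8: bool = False) -> None:
    """Write a single-frame TIFF (32-bit float, or min-max scaled 8-bit)."""
    path = Path(path)
    if as_uint8:
        v = image.values
        rng = v.max() - v.min()
        scaled = (np.zeros_like(v) if rng == 0
                  else (v - v.min()) / rng * 255.0)
        tifffile.imwrite(path, np.round(scaled).astype(np.uint8))
    else:
        tifffile.imwrite(path, image.values.astype(np.float32))
    _write_sidecar(path, {"pixel_size_nm": image.pixel_size_nm,
                          "provenance": image.provenance,
                          "scaling": "min-max-uint8" if as_uint8 else "float32"})


def read_image(path: str | Path, pixel_size_nm: float | None = None) -> SuperResImage:
    path = Path(path)
    values = np.asarray(tifffile.imread(path), dtype=float)
    side = _read_sidecar(path)
    px = pixel_size_nm or side.get("pixel_size_nm")
    if px is None:
        raise InvalidParameterError(
            f"{path}: pixel size not given and no sidecar found")
    return SuperResImage(values=values, pixel_size_nm=float(px),
                         provenance=side.get("provenance", {}))


def read_roi_table(path: str | Path) -> pd.DataFrame:
    """Read a ROI table CSV with columns x_um, y_um, width_um, height_um,
    angle_deg, replicate_id; numeric fields are validated row by row."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in ROI_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidParameterError(f"{path}: missing columns {missing}")
    for i, row in df.iterrows():
        for col in ROI_COLUMNS[:-1]:
            try:
                float(row[col])
            except (TypeError, ValueError):
                raise InvalidParameterError(
                    f"{path}: row {i + 1}: field {col!r} is not numeric "
                    f"({row[col]!r})") from None
        if row[["width_um", "height_um"]].astype(float).min() <= 0:
            raise InvalidParameterError(
                f"{path}: row {i + 1}: ROI width/height must be > 0")
    return df


def write_table(path: str | Path, df: pd.DataFrame) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
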