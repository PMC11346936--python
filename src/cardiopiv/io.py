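"""Reading and writing of stacks, fields and tabular results."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import ImageStack, PhaseVelocityField

__all__ = [
    "read_stack",
    "write_stack",
    "write_field_csv",
    "read_field_csv",
    "write_series_csv",
    "write_metadata",
]


def read_stack(path, pixel_size_um: float | None = None,
               frame_rate_hz: float | None = None) -> ImageStack:
    """Read a multi-page TIFF; metadata comes from a sidecar JSON if present."""
    path = Path(path)
    frames = tifffile.imread(path)
    meta_path = path.with_suffix(".meta.json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        pixel_size_um = pixel_size_um or meta.get("pixel_size_um")
        frame_rate_hz = frame_rate_hz or meta.get("frame_rate_hz")
    if pixel_size_um is None or frame_rate_hz is None:
        raise ValueError("pixel size and frame rate must be given or stored in sidecar metadata")
    return ImageStack(frames=frames, pixel_size_um=pixel_size_um,
                      frame_rate_hz=frame_rate_hz)


def write_stack(stack: ImageStack, path, extra_meta: dict | None = None) -> Path:
    """Write a grayscale 16-bit multi-page TIFF plus a metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frames = stack.frames
    if frames.dtype != np.uint16:
        top = float(frames.max()) or 1.0
        frames = np.clip(frames / top * 65535, 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, frames, photometric="minisblack")
    meta = {"pixel_size_um": stack.pixel_size_um,
            "frame_rate_hz": stack.frame_rate_hz,
            "n_frames": int(stack.n_frames)}
    if extra_meta:
        meta.update(extra_meta)
    path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=1))
    return path


def write_field_csv(field: PhaseVelocityField, path) -> Path:
    """Per-phase vector table: phase, x, y, u, v, valid."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    xx, yy = np.meshgrid(field.x, field.y)
    rows = []
    for p in range(field.n_phases):
        rows.append(pd.DataFrame({
            "phase": p,
            "t_s": field.times[p],
            "x_um": xx.ravel(),
            "y_um": yy.ravel(),
            "u_um_s": field.u[p].ravel(),
            "v_um_s": field.v[p].ravel(),
            "valid": field.mask[p].ravel().astype(int),
        }))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)
    return path


def read_field_csv(path) -> PhaseVelocityField:
    df = pd.read_csv(path)
    x = np.unique(df["x_um"])
    y = np.unique(df["y_um"])
    phases = np.unique(df["phase"])
    shape = (phases.size, y.size, x.size)
    u = df["u_um_s"].to_numpy().reshape(shape)
    v = df["v_um_s"].to_numpy().reshape(shape)
    mask = df["valid"].to_numpy().reshape(shape).astype(bool)
    times = df.groupby("phase")["t_s"].first().to_numpy()
    return PhaseVelocityField(u=u, v=v, x=x, y=y, times=times, mask=mask)


def write_series_csv(path, **columns) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(columns).to_csv(path, index=False)
    return path


def write_metadata(path, meta: dict) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_jsonable(meta), indent=1))
    return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, Path):
        return str(obj)
    return obj
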