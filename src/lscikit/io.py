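"""Raster I/O: multi-frame TIFF (or NPY) stacks in, float32 TIFF maps out."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .processing import ContrastMap, PIMap

__all__ = ["read_stack", "write_stack", "write_map", "read_map", "read_map_metadata"]


def read_stack(path) -> np.ndarray:
    """Read a (frames, H, W) float64 stack from multi-frame TIFF or 3-D NPY.

    Integer data are promoted to float without rescaling; negative float
    data are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".npy":
        data = np.load(path)
    else:
        data = tifffile.imread(path)
    data = np.asarray(data)
    if data.size == 0:
        raise ValueError(f"{path}: empty stack")
    if data.ndim == 2:
        data = data[None, ...]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected 2-D or 3-D data, got shape {data.shape}")
    out = data.astype(np.float64)
    if np.issubdtype(data.dtype, np.floating) and np.any(out < 0):
        raise ValueError(f"{path}: negative float intensities are invalid")
    return out


def write_stack(frames: np.ndarray, path) -> None:
    """Write a (frames, H, W) array as a float32 multi-frame TIFF (or NPY)."""
    frames = np.asarray(frames, dtype=np.float32)
    if frames.ndim == 2:
        frames = frames[None, ...]
    path = Path(path)
    if path.suffix.lower() == ".npy":
        np.save(path, frames)
    else:
        tifffile.imwrite(path, frames)


def write_map(map_obj: "ContrastMap | PIMap", path, csv_path=None, **extra_metadata) -> None:
    """Write a contrast or PI map as float32 TIFF with JSON metadata.

    The window geometry (and, for PI maps, beta and exposure) is embedded in
    the TIFF description; flagged pixels are stored as NaN.  If ``csv_path``
    is given, also export one CSV row per valid window position.
    """
    meta = {"side": map_obj.window.side, "p": map_obj.window.p, "offset": map_obj.offset}
    if isinstance(map_obj, PIMap):
        meta.update(kind="pi", beta=map_obj.beta, exposure=map_obj.T)
    else:
        meta["kind"] = "contrast"
    meta.update(extra_metadata)
    tifffile.imwrite(
        path,
        np.asarray(map_obj.values, dtype=np.float32),
        description=json.dumps(meta),
    )
    if csv_path is not None:
        values = map_obj.values
        off = map_obj.offset
        with open(csv_path, "w") as fh:
            fh.write("row,col,value\n")
            for (i, j), v in np.ndenumerate(values):
                if np.isfinite(v):
                    fh.write(f"{i + off},{j + off},{float(v)!r}\n")


def read_map_metadata(path) -> dict:
    """Recover the JSON metadata embedded by :func:`write_map`."""
    with tifffile.TiffFile(path) as tif:
        desc = tif.pages[0].description
    return json.loads(desc)


def read_map(path) -> tuple[np.ndarray, dict]:
    """Read a map written by :func:`write_map`: (float array, metadata dict)."""
    data = tifffile.imread(path)
    return np.asarray(data, dtype=np.float64), read_map_metadata(path)
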