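"""Scene and table I/O: multi-channel TIFF volumes with voxel metadata,
CSV tables with the package's um-coordinate column conventions."""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
import tifffile

from .errors import MeiotrackError

__all__ = [
    "write_scene_tiff",
    "read_scene_tiff",
    "write_points_csv",
    "read_points_csv",
    "write_labelmap",
    "read_labelmap",
]


def write_scene_tiff(path, channels: dict, voxel_size_um):
    """Write a multi-channel volume as a TIFF with voxel-size JSON metadata."""
    names = list(channels)
    stack = np.stack([channels[n] for n in names]).astype(np.float32)
    meta = {"voxel_size_zyx_um": list(map(float, voxel_size_um)), "channels": names,
            "shape": list(stack.shape)}
    tifffile.imwrite(path, stack, description=json.dumps(meta),
                     photometric="minisblack", metadata=None)


def read_scene_tiff(path, voxel_size_fallback=None):
    """Read a scene TIFF; returns ``(channels dict, voxel_size)``.

    Voxel size comes from the embedded JSON description, else from the
    fallback; with neither, an error explains how to supply it.
    """
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        desc = tf.pages[0].description or ""
    meta = {}
    try:
        meta = json.loads(desc)
    except (json.JSONDecodeError, TypeError):
        pass
    vs = meta.get("voxel_size_zyx_um", voxel_size_fallback)
    if vs is None:
        raise MeiotrackError(
            f"{path}: no voxel-size metadata; pass voxel_size_fallback or a config value"
        )
    if "shape" in meta:
        arr = arr.reshape(meta["shape"])
    elif arr.ndim == 3 and "channels" not in meta:
        arr = arr[None]
    names = meta.get("channels", [f"ch{i}" for i in range(arr.shape[0])])
    return {n: arr[i] for i, n in enumerate(names)}, np.asarray(vs, dtype=float)


def write_points_csv(path, points_um, extra=None):
    """Write (n, 3) um points (z, y, x) as CSV columns x_um, y_um, z_um."""
    p = np.atleast_2d(np.asarray(points_um, dtype=float))
    df = pd.DataFrame({"x_um": p[:, 2], "y_um": p[:, 1], "z_um": p[:, 0]})
    if extra is not None:
        for k, v in extra.items():
            df[k] = v
    df.to_csv(path, index=False)


def read_points_csv(path):
    df = pd.read_csv(path)
    pts = df[["z_um", "y_um", "x_um"]].to_numpy()
    return pts, df


def write_labelmap(path, labelmap, voxel_size_um):
    lab = np.asarray(labelmap)
    if lab.max() > np.iinfo(np.uint16).max:
        raise MeiotrackError("label map exceeds 16-bit range")
    tifffile.imwrite(path, lab.astype(np.uint16), photometric="minisblack", metadata=None,
                     description=json.dumps({"voxel_size_zyx_um": list(map(float, voxel_size_um))}))


def read_labelmap(path):
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        desc = tf.pages[0].description or ""
    vs = json.loads(desc)["voxel_size_zyx_um"]
    return arr, np.asarray(vs, dtype=float)
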