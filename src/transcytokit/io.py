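"""Reading and writing stacks, sidecar metadata, tables and configs.

Stacks travel as multi-page TIFF with a JSON sidecar carrying physical voxel
sizes (um, axis order (t,)z,y,x) and any generator ground truth as CSV next to
the stack.  Configs are YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = ["write_stack", "read_stack", "load_config", "save_config"]


def write_stack(path, data: np.ndarray, voxel_size_um, truth: pd.DataFrame | None = None) -> None:
    """Write a (z,y,x) or (t,z,y,x) stack as TIFF plus a JSON sidecar.

    ``voxel_size_um`` is the physical size per voxel for the spatial axes
    (z, y, x).  Ground truth, if given, is written as ``<stem>.truth.csv``.
    """
    path = Path(path)
    data = np.asarray(data)
    if data.ndim not in (3, 4):
        raise ValueError("stack must be (z,y,x) or (t,z,y,x)")
    tifffile.imwrite(path, data)
    meta = {
        "axes": "ZYX" if data.ndim == 3 else "TZYX",
        "voxel_size_um": [float(v) for v in voxel_size_um],
        "shape": list(data.shape),
        "dtype": str(data.dtype),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))
    if truth is not None:
        truth.to_csv(path.with_suffix(".truth.csv"), index=False)


def read_stack(path):
    """Read a TIFF stack and its JSON sidecar; returns (array, voxel_size_um)."""
    path = Path(path)
    data = tifffile.imread(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        voxel = tuple(meta["voxel_size_um"])
        data = data.reshape(meta["shape"])
    else:
        voxel = None
    return data, voxel


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def save_config(path, cfg: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
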