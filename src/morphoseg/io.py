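"""Reading and writing of the pipeline's on-disk formats.

Volumes travel as multi-page TIFF (one page per z slice), label fields as
16-bit integer TIFF, lineage tables as CSV with the header
``time,cell,parent,x_um,y_um,z_um``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

LINEAGE_COLUMNS = ["time", "cell", "parent", "x_um", "y_um", "z_um"]


def write_volume(path: str | Path, volume: np.ndarray, *, dtype=np.uint16) -> None:
    """Write a 3D (z, y, x) volume as a multi-page TIFF."""
    arr = np.asarray(volume)
    if arr.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {arr.shape}")
    if np.issubdtype(np.dtype(dtype), np.integer):
        info = np.iinfo(dtype)
        arr = np.clip(np.rint(arr.astype(np.float64)),
                      info.min, info.max).astype(dtype)
    else:
        arr = arr.astype(dtype)
    tifffile.imwrite(str(path), arr, photometric="minisblack")


def read_volume(path: str | Path) -> np.ndarray:
    return np.asarray(tifffile.imread(str(path)))


def write_labels(path: str | Path, labels: np.ndarray) -> None:
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("labels out of uint16 range")
    tifffile.imwrite(str(path), labels.astype(np.uint16),
                     photometric="minisblack")


read_labels = read_volume


def write_lineage(path: str | Path, lineage: pd.DataFrame) -> None:
    missing = [c for c in LINEAGE_COLUMNS if c not in lineage.columns]
    if missing:
        raise ValueError(f"lineage table missing columns: {missing}")
    lineage.to_csv(path, index=False, columns=LINEAGE_COLUMNS)


def read_lineage(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"cell": str, "parent": str})
    df["parent"] = df["parent"].fillna("")
    df["time"] = df["time"].astype(int)
    return df


def write_json(path: str | Path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable))


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, tuple):
        return list(x)
    raise TypeError(f"not JSON serializable: {type(x)}")
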