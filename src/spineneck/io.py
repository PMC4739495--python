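"""File I/O: localization/trajectory tables (CSV), image stacks (TIFF),
ROIs and results (JSON), binary masks (8-bit TIFF)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

TRAJ_COLUMNS = ["traj_id", "frame", "x_nm", "y_nm"]


def write_locs_csv(locs: pd.DataFrame, path: str | Path) -> None:
    locs.to_csv(path, index=False)


def read_locs_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("frame", "x_nm", "y_nm"):
        if col not in df.columns:
            raise ValueError(f"localization table {path} lacks column {col!r}")
    return df


def write_traj_csv(table: pd.DataFrame, path: str | Path) -> None:
    table[TRAJ_COLUMNS].to_csv(path, index=False)


def read_traj_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TRAJ_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trajectory table {path} lacks columns {sorted(missing)}")
    return df


def write_stack_tiff(stack: np.ndarray, path: str | Path) -> None:
    """Write a float stack as 16-bit multi-page TIFF (clipped at uint16 range)."""
    arr = np.clip(np.asarray(stack), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, arr)


def read_stack_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(path).astype(float)


def write_mask_tiff(mask: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(path, (np.asarray(mask, bool) * 255).astype(np.uint8))


def read_mask_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(path) > 0


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default))


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
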