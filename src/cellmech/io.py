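"""File I/O: track CSVs, TIFF images and label maps, JSON configs/reports.

CSV dialect is comma-separated, UTF-8, '.' decimal, header required.
Images go through tifffile and round-trip bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

TRACK_COLUMNS = ["track_id", "frame", "t_s", "x_um", "y_um"]


def read_tracks(path) -> pd.DataFrame:
    """Read a track table; validates required columns and numeric values.

    Raises ``ValueError`` naming missing columns, or the 1-based file line
    of the first malformed (non-numeric) row.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"track file {path} is missing required columns: {missing}")
    for c in ["frame", "t_s", "x_um", "y_um"]:
        coerced = pd.to_numeric(df[c], errors="coerce")
        bad = coerced.isna() & df[c].notna()
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header + 1-based
            raise ValueError(f"malformed value in column '{c}' at line {line} of {path}")
        df[c] = coerced
    return df


def write_tracks(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_image(path) -> np.ndarray:
    return tifffile.imread(path)


def write_image(image: np.ndarray, path) -> None:
    tifffile.imwrite(path, np.asarray(image))


def write_labels(labels: np.ndarray, path) -> None:
    tifffile.imwrite(path, np.asarray(labels, dtype=np.int32))


def read_config(path, allowed_keys=None) -> dict:
    """Read a JSON config; unknown keys are rejected with their names."""
    with open(path, encoding="utf-8") as fh:
        cfg = json.load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a JSON object")
    if allowed_keys is not None:
        unknown = sorted(set(cfg) - set(allowed_keys))
        if unknown:
            raise ValueError(f"config {path} has unknown keys: {unknown}")
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonable) + "\n")


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    return str(x)
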