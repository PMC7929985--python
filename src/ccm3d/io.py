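"""Reading and writing the package's on-disk formats.

Image stacks travel as multi-page TIFF, one channel per file; calibration
is always supplied explicitly (config or CLI flags) and never guessed from
TIFF metadata, whose resolution tags vary between dialects. Colony counts
travel as a comma-separated, UTF-8, headered CSV with columns
``arm,dose_gy,cells_seeded,colonies,dish_id``. Fits are serialized to JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .stacks import ImageStack
from .survival import REQUIRED_COLUMNS, ClonogenicTable, LQFit

__all__ = [
    "read_stack",
    "write_stack",
    "read_clonogenic_csv",
    "write_clonogenic_csv",
    "fit_to_json",
    "fit_from_json",
    "write_centroids_csv",
]


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as a multi-page float32 TIFF, one page per z-slice."""
    path = Path(path)
    tifffile.imwrite(
        path, np.asarray(stack.voxels, dtype=np.float32), photometric="minisblack"
    )
    return path


def read_stack(
    path: str | Path,
    pixel_size_um: float,
    z_step_um: float,
    channel: str = "nuclei",
) -> ImageStack:
    """Read a single-channel multi-page TIFF into a calibrated stack.

    A one-page file becomes a single-slice stack. Ragged page shapes or an
    unreadable file raise a ValueError naming the offending file/slice.
    """
    path = Path(path)
    try:
        tf = tifffile.TiffFile(path)
    except Exception as exc:
        raise ValueError(f"cannot read TIFF stack from {path}: {exc}") from exc
    with tf:
        shapes = {p.shape for p in tf.pages}
        if len(shapes) > 1:
            bad = [i for i, p in enumerate(tf.pages) if p.shape != tf.pages[0].shape]
            raise ValueError(
                f"{path}: ragged slice shapes (first mismatch at slice {bad[0]})"
            )
        vox = tf.asarray()
    if vox.ndim == 2:
        vox = vox[None]
    if vox.ndim != 3:
        raise ValueError(f"{path}: expected a single-channel z-stack, got shape {vox.shape}")
    return ImageStack(
        voxels=vox, pixel_size_um=pixel_size_um, z_step_um=z_step_um, channel=channel
    )


def write_clonogenic_csv(table: ClonogenicTable, path: str | Path) -> Path:
    path = Path(path)
    table.data.loc[:, list(REQUIRED_COLUMNS)].to_csv(path, index=False)
    return path


def read_clonogenic_csv(path: str | Path) -> ClonogenicTable:
    """Read and validate a colony-count CSV; errors name the offending row."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {', '.join(missing)}")
    for col in ("dose_gy", "cells_seeded", "colonies"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(f"{path}: non-numeric {col} at row {row}: {df[col].iloc[row]!r}")
        df[col] = pd.to_numeric(df[col])
    return ClonogenicTable(df)


def fit_to_json(fit: LQFit, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(dataclasses.asdict(fit), indent=2))
    return path


def fit_from_json(path: str | Path) -> LQFit:
    payload = json.loads(Path(path).read_text())
    return LQFit(**payload)


def write_centroids_csv(centroids_um: np.ndarray, path: str | Path, labels=None) -> Path:
    """Write (x, y, z) centroids in µm, with an optional component label."""
    path = Path(path)
    centroids_um = np.asarray(centroids_um, dtype=float).reshape(-1, 3)
    df = pd.DataFrame(centroids_um, columns=["x_um", "y_um", "z_um"])
    if labels is not None:
        df.insert(0, "label", np.asarray(labels))
    df.to_csv(path, index=False)
    return path
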