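"""TIFF and table I/O helpers."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "read_image",
    "read_movie",
    "read_label_mask",
    "write_image",
    "write_label_mask",
    "write_table",
    "sha256_file",
]


def read_image(path: str | Path) -> np.ndarray:
    """Read a single- or multi-channel TIFF as float array."""
    return tifffile.imread(str(path)).astype(np.float32)


def read_movie(path: str | Path) -> np.ndarray:
    """Read a (T, Y, X) time-lapse TIFF."""
    arr = tifffile.imread(str(path))
    if arr.ndim != 3:
        raise ValueError(f"expected a (T, Y, X) stack, got shape {arr.shape}")
    return arr.astype(np.float32)


def read_label_mask(path: str | Path) -> np.ndarray:
    arr = tifffile.imread(str(path))
    if arr.ndim != 2:
        raise ValueError(f"expected a 2D label image, got shape {arr.shape}")
    return arr.astype(np.int32)


def write_image(path: str | Path, image: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(image, dtype=np.float32),
                     photometric="minisblack")


def write_label_mask(path: str | Path, labels: np.ndarray) -> None:
    lab = np.asarray(labels)
    if lab.max() > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 labels; cannot write 16-bit mask")
    tifffile.imwrite(str(path), lab.astype(np.uint16))


def write_table(path: str | Path, table: pd.DataFrame, **meta: str) -> None:
    """CSV export; provenance metadata goes in a sidecar JSON."""
    table.to_csv(path, index=False)
    if meta:
        Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=1))


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
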