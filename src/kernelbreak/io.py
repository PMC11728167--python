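"""Raster and table I/O: 8-bit grayscale PNG/TIFF scenes, CSV tables.

CSV dialect everywhere: comma-separated, UTF-8, header row, '.' decimal,
0-based half-open pixel coordinates.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF raster (grayscale or RGB)."""
    return np.asarray(iio.imread(Path(path)))


def write_image(path: str | Path, image: np.ndarray) -> None:
    """Write an 8-bit grayscale PNG/TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.asarray(image)
    if arr.dtype != np.uint8:
        arr = np.clip(np.round(arr), 0, 255).astype(np.uint8)
    iio.imwrite(path, arr)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    pixels = getattr(mask, "pixels", mask)
    write_image(path, np.asarray(pixels).astype(np.uint8) * 255)


def write_table(path: str | Path, frame: pd.DataFrame) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path))
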