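"""Image reading/writing helpers (PNG, PGM, TIFF).

Colour inputs are reduced to grey with the ITU-R BT.601 luminance weights
(0.299 R + 0.587 G + 0.114 B); edge maps are written as bilevel 0/255
rasters.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = ["read_grey", "write_grey", "write_edge_map"]

_LUMA = np.array([0.299, 0.587, 0.114])


def read_grey(path) -> np.ndarray:
    """Read an image file as a 2-D uint8 grey raster."""
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[:, :, :3]
        if arr.shape[2] != 3:
            raise ValueError(f"unsupported channel count {arr.shape[2]} in {path}")
        arr = arr.astype(np.float64) @ _LUMA
    elif arr.ndim != 2:
        raise ValueError(f"unsupported image dimensionality {arr.ndim} in {path}")
    if np.issubdtype(np.asarray(arr).dtype, np.floating):
        arr = np.rint(arr)
    arr = np.asarray(arr)
    if arr.max(initial=0) > 255 or arr.min(initial=0) < 0:
        raise ValueError(f"{path} is not an 8-bit intensity image")
    return arr.astype(np.uint8)


def write_grey(path, image) -> None:
    """Write a 2-D grey raster as an 8-bit image file."""
    arr = np.asarray(image)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D grey image, got shape {arr.shape}")
    iio.imwrite(Path(path), np.clip(arr, 0, 255).astype(np.uint8))


def write_edge_map(path, edges) -> None:
    """Write a boolean edge map as a bilevel 0/255 image file."""
    arr = np.asarray(edges)
    if arr.dtype != bool:
        raise ValueError("edge map must be boolean")
    iio.imwrite(Path(path), (arr.astype(np.uint8)) * 255)
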