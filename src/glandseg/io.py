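"""Raster I/O: 8-bit images, 16-bit label PNGs, float TIFF probability maps."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

__all__ = [
    "read_rgb",
    "read_labels",
    "write_gray_png",
    "write_labels_png",
    "write_float_tiff",
    "read_float_tiff",
]


def read_rgb(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF/BMP raster as HxWx3 uint8 (alpha dropped)."""
    img = np.asarray(iio.imread(path))
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    if img.shape[2] == 4:
        img = img[..., :3]
    return img.astype(np.uint8)


def read_labels(path: str | Path) -> np.ndarray:
    """Read an integer label raster (single channel)."""
    img = np.asarray(iio.imread(path))
    if img.ndim == 3:
        img = img[..., 0]
    return img.astype(np.int32)


def write_gray_png(path: str | Path, raster: np.ndarray) -> None:
    iio.imwrite(path, np.clip(np.rint(raster), 0, 255).astype(np.uint8))


def write_labels_png(path: str | Path, labels: np.ndarray) -> None:
    labels = np.asarray(labels)
    if labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("more instances than a 16-bit label PNG can hold")
    iio.imwrite(path, labels.astype(np.uint16))


def write_float_tiff(path: str | Path, raster: np.ndarray) -> None:
    # photometric is pinned so a (4, H, W) map stack round-trips as pages,
    # not as an RGB image with separate component planes
    tifffile.imwrite(path, np.asarray(raster, dtype=np.float32),
                     photometric="minisblack")


def read_float_tiff(path: str | Path) -> np.ndarray:
    return np.asarray(tifffile.imread(path), dtype=np.float64)
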