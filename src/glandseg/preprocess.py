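"""Preprocessing of H&E RGB histology images.

The pipeline input to the pixel classifiers is a single "structure" channel:
the hematoxylin-dominated channel of a color deconvolution of the RGB image,
contrast-normalized with CLAHE.  Color deconvolution follows the
Ruifrok–Johnston optical-density model

    OD = -log10(I / 255),   OD = D @ M,

where ``M`` is a 3x3 matrix whose rows are unit-norm stain absorption vectors
and ``D`` holds per-pixel stain densities.  Inverting ``M`` recovers the
densities; the first channel (hematoxylin for an H&E preset) carries most of
the tissue-structure signal and is the only one retained.

Images are processed at half resolution by the classifiers and the resulting
probability maps are upsampled back to the original grid, so this module also
provides the down/upsampling used by that policy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import exposure, transform

__all__ = [
    "HE2_STAIN_MATRIX",
    "RGBImage",
    "StainDensityImage",
    "StructureChannel",
    "color_deconvolve",
    "density_to_intensity",
    "extract_structure_channel",
    "apply_clahe",
    "resample",
    "resample_to",
]

# "H&E 2" preset of the Fiji/ImageJ colour-deconvolution plugin (G. Landini):
# rows = hematoxylin, eosin, residual.  The residual row is all-zero in the
# preset and is completed by orthogonalization in `_normalize_stain_matrix`.
HE2_STAIN_MATRIX = np.array(
    [
        [0.49015734, 0.76897085, 0.41040173],
        [0.04615336, 0.84206840, 0.53739250],
        [0.0, 0.0, 0.0],
    ]
)

#: Smallest transmitted intensity used in the optical-density transform;
#: keeps log10 finite for black pixels.
_MIN_TRANSMISSION = 0.5


@dataclass
class RGBImage:
    """An 8-bit RGB raster with optional acquisition metadata."""

    pixels: np.ndarray
    source: str | None = None
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(
                f"RGB image must be HxWx3, got shape {self.pixels.shape}"
            )
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("image must contain at least one pixel")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class StainDensityImage:
    """Per-pixel stain densities together with the stain matrix used."""

    channels: np.ndarray  # HxWx3 float
    stain_matrix: np.ndarray  # 3x3, unit-norm rows

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.channels)):
            raise ValueError("stain densities must be finite")


@dataclass
class StructureChannel:
    """Single-channel structure image with intensities in [0, 255].

    ``scale`` records the resolution relative to the source image (1.0 for
    full resolution, 0.5 after the half-resolution downsampling policy).
    """

    pixels: np.ndarray
    scale: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("structure channel must be a single 2-D channel")
        if self.pixels.min() < 0 or self.pixels.max() > 255:
            raise ValueError("structure channel values must lie in [0, 255]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def _normalize_stain_matrix(stain_matrix: np.ndarray) -> np.ndarray:
    """Unit-normalize rows; complete an all-zero third row orthogonally."""
    m = np.array(stain_matrix, dtype=float)
    if m.shape != (3, 3):
        raise ValueError("stain matrix must be 3x3")
    norms = np.linalg.norm(m, axis=1)
    if norms[0] == 0 or norms[1] == 0:
        raise ValueError("first two stain vectors must be non-zero")
    if norms[2] == 0:
        m[2] = np.cross(m[0] / norms[0], m[1] / norms[1])
        norms[2] = np.linalg.norm(m[2])
        if norms[2] == 0:
            raise ValueError("first two stain vectors are collinear")
    m = m / norms[:, None]
    if np.linalg.cond(m) > 1e8:
        raise ValueError("stain matrix is singular after normalization")
    return m


def color_deconvolve(
    image: RGBImage | np.ndarray,
    stain_matrix: np.ndarray | None = None,
) -> StainDensityImage:
    """Separate an RGB image into per-stain density channels.

    Parameters
    ----------
    image
        RGB raster with intensities in [0, 255].
    stain_matrix
        Rows are stain absorption vectors (need not be pre-normalized); the
        default is the "H&E 2" preset.  A zero third row is completed with
        the unit vector orthogonal to the first two.

    Returns
    -------
    StainDensityImage
        ``channels[..., i]`` is the optical density attributed to stain *i*.
    """
    if not isinstance(image, RGBImage):
        image = RGBImage(np.asarray(image))
    m = _normalize_stain_matrix(
        HE2_STAIN_MATRIX if stain_matrix is None else stain_matrix
    )
    rgb = np.asarray(image.pixels, dtype=float)
    od = -np.log10(np.maximum(rgb, _MIN_TRANSMISSION) / 255.0)
    densities = od @ np.linalg.inv(m)
    return StainDensityImage(channels=densities, stain_matrix=m)


def density_to_intensity(density: np.ndarray) -> np.ndarray:
    """Map a stain-density channel back to transmitted 8-bit intensity.

    Follows the plugin convention ``I = 255 * 10**(-density)``: zero density
    is white, dense stain is dark.
    """
    return np.clip(255.0 * np.power(10.0, -np.asarray(density, dtype=float)), 0, 255)


def reconstruct_rgb(deconvolved: StainDensityImage) -> np.ndarray:
    """Forward stain model: densities back to an RGB image in [0, 255]."""
    od = deconvolved.channels @ deconvolved.stain_matrix
    return np.clip(255.0 * np.power(10.0, -od), 0, 255)


def extract_structure_channel(
    image: RGBImage | np.ndarray,
    stain_matrix: np.ndarray | None = None,
    channel: int = 0,
) -> StructureChannel:
    """Deconvolve and keep a single stain channel as an intensity image.

    The hematoxylin channel (index 0) is kept by default; the eosin and
    residual channels carry little tissue-structure contrast for H&E.
    """
    dec = color_deconvolve(image, stain_matrix)
    return StructureChannel(density_to_intensity(dec.channels[..., channel]), scale=1.0)


def apply_clahe(
    channel: StructureChannel,
    clip_limit: float = 2.0,
    tile_grid: tuple[int, int] = (8, 8),
) -> StructureChannel:
    """Contrast-limited adaptive histogram equalization of a structure channel.

    ``clip_limit`` uses the common histogram-clipping convention where the
    per-tile histogram is clipped at ``clip_limit / n_bins`` of the tile's
    pixel count (2.0 with 256 bins by default); ``tile_grid`` is the number
    of (rows, cols) of contextual tiles.
    """
    if clip_limit <= 0:
        raise ValueError("clip limit must be positive")
    h, w = channel.shape
    rows, cols = tile_grid
    if rows > h or cols > w:
        raise ValueError(f"tile grid {tile_grid} larger than image {channel.shape}")
    kernel = (max(h // rows, 1), max(w // cols, 1))
    img = np.asarray(channel.pixels, dtype=float) / 255.0
    out = exposure.equalize_adapthist(
        img, kernel_size=kernel, clip_limit=clip_limit / 256.0
    )
    return StructureChannel(np.clip(out * 255.0, 0, 255), scale=channel.scale)


def _output_shape(shape: tuple[int, ...], factor: float) -> tuple[int, ...]:
    return tuple(max(int(np.floor(s * factor)), 1) for s in shape)


def resample(raster: np.ndarray, factor: float, mode: str = "bilinear") -> np.ndarray:
    """Rescale a 2-D raster by ``factor`` (output dims = floor(dim * factor)).

    ``mode="bilinear"`` is for intensity/probability rasters (local-mean area
    averaging when shrinking, bilinear interpolation when enlarging);
    ``mode="nearest"`` preserves the label alphabet of integer rasters.
    """
    if factor <= 0:
        raise ValueError("resampling factor must be positive")
    raster = np.asarray(raster)
    return resample_to(raster, _output_shape(raster.shape[:2], factor), mode)


def resample_to(raster: np.ndarray, shape: tuple[int, int], mode: str = "bilinear") -> np.ndarray:
    """Resample a 2-D raster to an explicit output shape (see `resample`)."""
    raster = np.asarray(raster)
    if tuple(raster.shape[:2]) == tuple(shape):
        return raster.copy()
    if mode == "nearest":
        out = transform.resize(
            raster, shape, order=0, anti_aliasing=False, preserve_range=True
        )
        return out.astype(raster.dtype)
    if mode == "bilinear":
        shrinking = shape[0] <= raster.shape[0] and shape[1] <= raster.shape[1]
        if shrinking:
            out = transform.resize_local_mean(
                raster.astype(float), shape, preserve_range=True
            )
        else:
            out = transform.resize(
                raster.astype(float), shape, order=1,
                anti_aliasing=False, preserve_range=True,
            )
        return out
    raise ValueError(f"unknown resampling mode: {mode!r}")
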