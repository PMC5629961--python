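"""Training-data construction for the pixel classifiers.

Ground truth comes as integer-labeled object images (0 = background, k > 0 =
gland instance k) plus an image-level benign/malignant flag.  For the
four-class gland classifier the labels are collapsed to

    C0 benign background, C1 benign gland,
    C2 malignant background, C3 malignant gland,

so benign images contain only {0, 1} and malignant images only {2, 3}.  The
separator classifier uses a binary raster of gland-separating structures,
rasterized from polyline annotations.

Patch sampling is class-balanced: the same number of patch centers is drawn
uniformly from the eligible pixels of every class.  Centers closer than half
a patch to the border are served by mirror padding.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import draw, morphology

logger = logging.getLogger(__name__)

__all__ = [
    "ObjectLabelImage",
    "FourClassLabelImage",
    "SeparatorMask",
    "PatchDataset",
    "transform_labels",
    "rasterize_separators",
    "sample_balanced_patches",
    "augment_rotations",
]

BENIGN = "benign"
MALIGNANT = "malignant"


@dataclass
class ObjectLabelImage:
    """Integer object labels plus an image-level malignancy flag."""

    pixels: np.ndarray
    malignancy: str | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("object label image must be 2-D")
        if self.pixels.min() < 0:
            raise ValueError("object labels must be non-negative integers")

    @property
    def object_ids(self) -> np.ndarray:
        ids = np.unique(self.pixels)
        return ids[ids > 0]

    def binary_mask(self) -> np.ndarray:
        return self.pixels > 0


@dataclass
class FourClassLabelImage:
    """Per-pixel class raster in {0, 1, 2, 3}."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if not np.isin(np.unique(self.pixels), [0, 1, 2, 3]).all():
            raise ValueError("four-class labels must lie in {0, 1, 2, 3}")

    def gland_mask(self) -> np.ndarray:
        """Binary gland mask: classes C1 and C3."""
        return np.isin(self.pixels, (1, 3))


@dataclass
class SeparatorMask:
    """Binary mask of gland-separating structures."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels).astype(bool)
        if self.pixels.ndim != 2:
            raise ValueError("separator mask must be 2-D")


def transform_labels(labels: ObjectLabelImage) -> FourClassLabelImage:
    """Collapse object labels to the four benign/malignant classes.

    Raises ``ValueError`` if the image-level malignancy flag is missing.
    """
    if labels.malignancy not in (BENIGN, MALIGNANT):
        raise ValueError(
            "malignancy flag must be 'benign' or 'malignant', "
            f"got {labels.malignancy!r}"
        )
    gland = labels.pixels > 0
    offset = 0 if labels.malignancy == BENIGN else 2
    return FourClassLabelImage(np.where(gland, offset + 1, offset).astype(np.uint8))


def rasterize_separators(
    polylines: list[np.ndarray],
    shape: tuple[int, int],
    thickness: int = 3,
) -> SeparatorMask:
    """Rasterize polyline annotations into a binary separator mask.

    Each polyline is a sequence of (row, col) points; consecutive points are
    connected with discrete line segments and the union is dilated with a
    disk to the requested thickness.  Out-of-bounds points are clipped to
    the image domain with a warning.
    """
    if thickness < 1:
        raise ValueError("thickness must be at least 1 pixel")
    mask = np.zeros(shape, dtype=bool)
    h, w = shape
    for pts in polylines:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        if pts.shape[1] != 2:
            raise ValueError("polyline points must be (row, col) pairs")
        if (pts[:, 0] < 0).any() or (pts[:, 0] > h - 1).any() or \
           (pts[:, 1] < 0).any() or (pts[:, 1] > w - 1).any():
            warnings.warn("separator polyline points outside image; clipping")
            pts[:, 0] = np.clip(pts[:, 0], 0, h - 1)
            pts[:, 1] = np.clip(pts[:, 1], 0, w - 1)
        pts = np.rint(pts).astype(int)
        if len(pts) == 1:
            mask[pts[0, 0], pts[0, 1]] = True
            continue
        for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
            rr, cc = draw.line(r0, c0, r1, c1)
            mask[rr, cc] = True
    radius = (thickness - 1) // 2
    if radius > 0:
        mask = ndimage.binary_dilation(mask, structure=morphology.disk(radius))
    return SeparatorMask(mask)


def load_polylines_json(path: str | Path) -> list[np.ndarray]:
    """Read separator polylines from a JSON list of point arrays."""
    with open(path) as fh:
        data = json.load(fh)
    return [np.asarray(p, dtype=float) for p in data]


@dataclass
class PatchDataset:
    """Class-balanced patch samples from one structure channel.

    ``patches`` has shape (N, patch, patch) with intensities scaled to
    [0, 1]; ``labels[i]`` is the class of the raster at ``centers[i]``.
    """

    patches: np.ndarray
    labels: np.ndarray
    centers: np.ndarray  # (N, 2) rows/cols in the source raster
    per_class_count: int
    seed: int | None = None
    patch_size: int = 101

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def save(self, path: str | Path) -> None:
        """Persist to a single .npz container with a sampling manifest."""
        np.savez_compressed(
            path,
            patches=self.patches.astype(np.float32),
            labels=self.labels,
            centers=self.centers,
            manifest=json.dumps(
                {
                    "per_class_count": int(self.per_class_count),
                    "seed": None if self.seed is None else int(self.seed),
                    "patch_size": int(self.patch_size),
                }
            ),
        )

    @classmethod
    def load(cls, path: str | Path) -> "PatchDataset":
        with np.load(path, allow_pickle=False) as z:
            manifest = json.loads(str(z["manifest"]))
            return cls(
                patches=z["patches"],
                labels=z["labels"],
                centers=z["centers"],
                per_class_count=manifest["per_class_count"],
                seed=manifest["seed"],
                patch_size=manifest["patch_size"],
            )


def _extract_patches(
    channel: np.ndarray, centers: np.ndarray, patch_size: int
) -> np.ndarray:
    half = patch_size // 2
    padded = np.pad(channel, half, mode="reflect")
    out = np.empty((len(centers), patch_size, patch_size), dtype=np.float32)
    for i, (r, c) in enumerate(centers):
        out[i] = padded[r : r + patch_size, c : c + patch_size]
    return out


def sample_balanced_patches(
    channel,
    labels: np.ndarray,
    per_class: int = 125_000,
    patch_size: int = 101,
    seed: int | None = None,
    classes: list[int] | None = None,
) -> PatchDataset:
    """Draw an equal number of patch centers from every class of a raster.

    Centers are drawn uniformly without replacement from the eligible pixels
    of each class; if a class has fewer eligible pixels than ``per_class``,
    sampling falls back to with-replacement and logs a warning.  The default
    ``per_class`` matches the full-scale training regime (125,000 per class);
    pass a small value for reduced experiments.
    """
    pixels = np.asarray(getattr(channel, "pixels", channel), dtype=np.float32)
    labels = np.asarray(labels)
    if pixels.shape != labels.shape:
        raise ValueError("channel and label raster must share their shape")
    if per_class < 1:
        raise ValueError("per_class must be at least 1")
    if classes is None:
        classes = [int(c) for c in np.unique(labels)]

    rng = np.random.default_rng(seed)
    all_centers, all_labels = [], []
    for cls in classes:
        rows, cols = np.nonzero(labels == cls)
        if len(rows) == 0:
            raise ValueError(f"class {cls} has no eligible pixels to sample from")
        if len(rows) < per_class:
            logger.warning(
                "class %d has only %d eligible pixels for %d requested patches; "
                "sampling with replacement", cls, len(rows), per_class,
            )
            idx = rng.choice(len(rows), size=per_class, replace=True)
        else:
            idx = rng.choice(len(rows), size=per_class, replace=False)
        all_centers.append(np.column_stack([rows[idx], cols[idx]]))
        all_labels.append(np.full(per_class, cls, dtype=np.int64))

    centers = np.concatenate(all_centers)
    labs = np.concatenate(all_labels)
    patches = _extract_patches(pixels / 255.0, centers, patch_size)
    return PatchDataset(
        patches=patches,
        labels=labs,
        centers=centers,
        per_class_count=per_class,
        seed=seed,
        patch_size=patch_size,
    )


def augment_rotations(
    patch: np.ndarray, count: int = 9, step_degrees: float = 36.0
) -> list[np.ndarray]:
    """Rotated copies of a square patch at angles step, 2*step, ..., count*step.

    The original (0 deg) patch is not included.  Rotation uses bilinear
    interpolation about the patch center with mirrored boundary, so the
    center pixel — whose label the patch carries — is preserved up to
    interpolation error.
    """
    patch = np.asarray(patch)
    if patch.ndim != 2 or patch.shape[0] != patch.shape[1]:
        raise ValueError("patch must be square")
    return [
        ndimage.rotate(
            patch, angle=(i + 1) * step_degrees, reshape=False,
            order=1, mode="reflect",
        )
        for i in range(count)
    ]
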