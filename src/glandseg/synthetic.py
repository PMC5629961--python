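"""Synthetic H&E-like scenes with complete ground truth.

Real colon-gland histology shows glands as a bright lumen wrapped in a dark
epithelial-cell ring, embedded in pink stroma; malignant glands lose the
regular ring geometry and their lumina may be occluded.  The generator
emulates exactly those features — elliptical (benign) or boundary-perturbed
non-convex (malignant) glands with lumen/epithelium rings over textured
stroma — together with integer instance labels, an image-level malignancy
flag, and a separator mask covering the stroma corridor between gland pairs
whose boundary gap falls below a threshold (the "touching" configurations
that make instance separation hard).

It also simulates classifier outputs: softened, noise-corrupted one-hot
class probability maps derived from the labels, so the refinement,
segmentation, classification and evaluation stages are testable without any
trained network or external dataset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import draw

from .dataset import (
    BENIGN,
    MALIGNANT,
    ObjectLabelImage,
    SeparatorMask,
    transform_labels,
)
from .networks import ClassProbabilityMaps, SeparatorMap
from .preprocess import RGBImage

__all__ = ["SceneConfig", "generate_scene", "generate_probability_fixtures"]

# H&E-like mean colors (R, G, B).  Malignant epithelium is rendered darker
# and more blue-purple (hyperchromatic, densely packed nuclei), as in
# carcinoma tissue.
_STROMA = np.array([232.0, 185.0, 205.0])
_EPITHELIUM = np.array([130.0, 70.0, 160.0])
_EPITHELIUM_MALIGNANT = np.array([95.0, 45.0, 135.0])
_LUMEN = np.array([243.0, 238.0, 243.0])


@dataclass
class SceneConfig:
    """Parameters of one synthetic scene.

    ``touching_fraction`` is the fraction of glands placed as near-touching
    pairs (boundary gap ``touch_gap`` pixels); the separator ground truth
    covers stroma corridors between glands closer than ``separator_gap``.
    """

    shape: tuple[int, int] = (256, 256)
    n_glands: int = 6
    radius_range: tuple[float, float] = (18.0, 30.0)
    min_gap: float = 12.0
    touching_fraction: float = 0.0
    touch_gap: float = 3.0
    malignant: bool = False
    noise: float = 0.03
    separator_gap: float = 10.0
    separator_thickness: int = 3
    seed: int | None = None
    max_attempts: int = 500

    def __post_init__(self):
        if self.radius_range[0] <= 0 or self.radius_range[1] < self.radius_range[0]:
            raise ValueError("gland radii must be positive and ordered")
        if not 0 <= self.touching_fraction <= 1:
            raise ValueError("touching fraction must lie in [0, 1]")
        if self.n_glands < 1:
            raise ValueError("need at least one gland")


def _gland_mask(
    shape: tuple[int, int],
    center: np.ndarray,
    radius: float,
    rng: np.random.Generator,
    malignant: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Filled gland mask and its lumen mask.

    Benign glands are smooth ellipses with a concentric lumen; malignant
    glands get a low-order Fourier perturbation of the boundary radius
    (non-convex outline) and a shrunken, off-center or absent lumen.
    """
    theta = np.linspace(0.0, 2.0 * np.pi, 256, endpoint=False)
    aspect = rng.uniform(0.75, 1.0)
    angle = rng.uniform(0.0, np.pi)
    r = radius * np.ones_like(theta)
    if malignant:
        for k in range(2, 6):
            r += radius * rng.uniform(0.03, 0.10) * np.cos(
                k * theta + rng.uniform(0, 2 * np.pi)
            )
    # elliptical distortion
    rr_dir = np.cos(theta - angle)
    cc_dir = np.sin(theta - angle)
    scale = 1.0 / np.sqrt(rr_dir**2 + (cc_dir / aspect) ** 2)
    r = np.clip(r * scale, 3.0, None)
    rows = center[0] + r * np.cos(theta)
    cols = center[1] + r * np.sin(theta)
    gland = np.zeros(shape, dtype=bool)
    pr, pc = draw.polygon(rows, cols, shape=shape)
    gland[pr, pc] = True

    lumen = np.zeros(shape, dtype=bool)
    if malignant and rng.random() < 0.4:
        return gland, lumen  # fully occluded lumen
    lumen_scale = rng.uniform(0.45, 0.6) if not malignant else rng.uniform(0.2, 0.4)
    offset = (
        np.zeros(2)
        if not malignant
        else rng.uniform(-0.2, 0.2, size=2) * radius
    )
    lr = center[0] + offset[0] + lumen_scale * r * np.cos(theta)
    lc = center[1] + offset[1] + lumen_scale * r * np.sin(theta)
    pr, pc = draw.polygon(lr, lc, shape=shape)
    lumen[pr, pc] = True
    return gland, lumen & gland


def _place_centers(config: SceneConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Gland centers and radii honoring gap constraints; pairs first."""
    h, w = config.shape
    r_lo, r_hi = config.radius_range
    n_pairs = int(round(config.touching_fraction * config.n_glands / 2.0))
    centers: list[np.ndarray] = []
    radii: list[float] = []

    def fits(c: np.ndarray, r: float, required_gap: float, skip: set[int]) -> bool:
        for j, (cj, rj) in enumerate(zip(centers, radii)):
            if j in skip:
                continue
            if np.linalg.norm(c - cj) < r + rj + required_gap:
                return False
        return True

    def sample_center(r: float) -> np.ndarray:
        margin = r + 2
        return np.array([rng.uniform(margin, h - margin), rng.uniform(margin, w - margin)])

    for _ in range(n_pairs):
        for attempt in range(config.max_attempts):
            r1, r2 = rng.uniform(r_lo, r_hi, size=2)
            c1 = sample_center(r1)
            phi = rng.uniform(0, 2 * np.pi)
            c2 = c1 + (r1 + r2 + config.touch_gap) * np.array([np.cos(phi), np.sin(phi)])
            if not (r2 + 2 <= c2[0] <= h - r2 - 2 and r2 + 2 <= c2[1] <= w - r2 - 2):
                continue
            if fits(c1, r1, config.min_gap, skip=set()) and fits(
                c2, r2, config.min_gap, skip={len(centers)}
            ):
                centers += [c1, c2]
                radii += [r1, r2]
                break
        else:
            raise RuntimeError("could not place a touching gland pair; scene too crowded")

    while len(centers) < config.n_glands:
        for attempt in range(config.max_attempts):
            r = rng.uniform(r_lo, r_hi)
            c = sample_center(r)
            if fits(c, r, config.min_gap, skip=set()):
                centers.append(c)
                radii.append(r)
                break
        else:
            raise RuntimeError(
                f"could not place gland {len(centers) + 1} of {config.n_glands}; "
                "reduce n_glands or radii"
            )
    return np.asarray(centers), np.asarray(radii)


def _separator_mask(labels: np.ndarray, config: SceneConfig) -> np.ndarray:
    """Stroma midline between gland pairs with boundary gap below threshold."""
    mask = np.zeros(labels.shape, dtype=bool)
    ids = np.unique(labels)
    ids = ids[ids > 0]
    dist = {i: ndimage.distance_transform_edt(labels != i) for i in ids}
    stroma = labels == 0
    for a_idx in range(len(ids)):
        for b_idx in range(a_idx + 1, len(ids)):
            da, db = dist[ids[a_idx]], dist[ids[b_idx]]
            corridor = stroma & (da + db < config.separator_gap)
            if not corridor.any():
                continue
            midline = corridor & (np.abs(da - db) <= 1.0)
            mask |= midline
    radius = (config.separator_thickness - 1) // 2
    if radius > 0 and mask.any():
        mask = ndimage.binary_dilation(mask, iterations=radius) & stroma
    return mask


def generate_scene(
    config: SceneConfig,
) -> tuple[RGBImage, ObjectLabelImage, SeparatorMask]:
    """Render one synthetic H&E-like scene with full ground truth.

    Returns the RGB image, integer gland-instance labels carrying the
    image-level malignancy flag, and the separator ground-truth mask.
    Identical configs (including seed) give bit-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.shape
    centers, radii = _place_centers(config, rng)

    labels = np.zeros(config.shape, dtype=np.int32)
    epithelium = np.zeros(config.shape, dtype=bool)
    lumen_all = np.zeros(config.shape, dtype=bool)
    for k, (c, r) in enumerate(zip(centers, radii), start=1):
        gland, lumen = _gland_mask(config.shape, c, r, rng, config.malignant)
        gland &= labels == 0  # defensive: no overlap between instances
        labels[gland] = k
        lumen &= gland
        lumen_all |= lumen
        epithelium |= gland & ~lumen

    # low-frequency stroma texture + pixel noise
    texture = ndimage.gaussian_filter(rng.normal(0.0, 1.0, config.shape), 6.0)
    texture = texture / max(np.abs(texture).max(), 1e-12)
    epi_color = _EPITHELIUM_MALIGNANT if config.malignant else _EPITHELIUM
    rgb = np.empty((h, w, 3))
    for ch in range(3):
        base = np.full(config.shape, _STROMA[ch])
        base[epithelium] = epi_color[ch]
        base[lumen_all] = _LUMEN[ch]
        base += 18.0 * texture * (labels == 0)
        base += rng.normal(0.0, config.noise * 255.0, config.shape)
        rgb[..., ch] = base
    image = RGBImage(np.clip(rgb, 0, 255).astype(np.uint8), source="synthetic")

    sep = _separator_mask(labels, config)
    flag = MALIGNANT if config.malignant else BENIGN
    return image, ObjectLabelImage(labels, malignancy=flag), SeparatorMask(sep)


def generate_probability_fixtures(
    labels: ObjectLabelImage,
    separator: SeparatorMask | np.ndarray | None = None,
    flip_noise: float = 0.0,
    blur: float = 0.0,
    bridge_radius: float = 0.0,
    seed: int | None = None,
    scale: float = 1.0,
) -> tuple[ClassProbabilityMaps, SeparatorMap]:
    """Simulated classifier outputs from ground-truth labels.

    The four-class one-hot transform of the labels is softened with a
    Gaussian blur (``blur`` in pixels), then a fraction ``flip_noise`` of
    pixels is replaced with a random distribution, and the maps are
    renormalized per pixel.  The separator map is the blurred separator
    ground truth (zero when absent).

    ``bridge_radius > 0`` emulates the characteristic confusion of a real
    gland classifier between adjacent glands: the gland class is
    morphologically closed with a disk of that radius, so narrow background
    corridors (gap below about twice the radius) read as foreground — the
    merge failure that separator refinement is there to undo.
    """
    if not 0 <= flip_noise < 1:
        raise ValueError("flip_noise must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    four = transform_labels(labels).pixels.copy()
    if bridge_radius > 0:
        from skimage.morphology import disk

        gland = np.isin(four, (1, 3))
        bridged = ndimage.binary_closing(
            gland, structure=disk(int(round(bridge_radius)))
        ) & ~gland
        gland_class = 3 if labels.malignancy == MALIGNANT else 1
        four[bridged] = gland_class
    maps = np.stack([(four == l).astype(float) for l in range(4)])
    if blur > 0:
        maps = np.stack([ndimage.gaussian_filter(m, blur) for m in maps])
    if flip_noise > 0:
        corrupt = rng.random(four.shape) < flip_noise
        random_dist = rng.random((4,) + four.shape)
        maps = np.where(corrupt[None], random_dist, maps)
    maps = np.clip(maps, 1e-12, None)
    maps /= maps.sum(axis=0, keepdims=True)

    if separator is None:
        sep = np.zeros(four.shape)
    else:
        sep = np.asarray(getattr(separator, "pixels", separator), dtype=float)
        if blur > 0:
            sep = ndimage.gaussian_filter(sep, blur)
        sep = np.clip(sep / max(sep.max(), 1e-12), 0, 1) if sep.max() > 0 else sep
    return (
        ClassProbabilityMaps(maps=maps, scale=scale),
        SeparatorMap(map=sep, scale=scale),
    )
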