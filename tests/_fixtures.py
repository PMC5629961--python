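"""Shared fixture builders for the test suite."""

import numpy as np

from glandseg.dataset import PatchDataset
from glandseg.networks import LayerSpec, NetworkSpec


def tiny_spec(n_classes: int = 4, patch_size: int = 9) -> NetworkSpec:
    """A miniature 2-conv network for fast unit tests."""
    return NetworkSpec(
        "object" if n_classes == 4 else "separator",
        (
            LayerSpec("conv", 3, 3), LayerSpec("pool"),
            LayerSpec("conv", 4, 3),
            LayerSpec("fc", 8), LayerSpec("fc", n_classes),
        ),
        patch_size=patch_size,
    )


def small_spec(n_classes: int = 4) -> NetworkSpec:
    """A reduced-width replica of the canonical 4-conv/3-fc layout."""
    return NetworkSpec(
        "object" if n_classes == 4 else "separator",
        (
            LayerSpec("conv", 8, 7), LayerSpec("pool"),
            LayerSpec("conv", 12, 5), LayerSpec("pool"),
            LayerSpec("conv", 16, 3), LayerSpec("pool"),
            LayerSpec("conv", 20, 3),
            LayerSpec("fc", 64), LayerSpec("fc", 32), LayerSpec("fc", n_classes),
        ),
        patch_size=53,
    )


def oriented_patches(
    n_per_class: int,
    n_classes: int,
    patch: int,
    seed: int,
    period: float = 8.0,
    sigma: float = 0.05,
) -> PatchDataset:
    """Separable texture classes: one grating orientation per class.

    Oriented sinusoids (random phase per patch, additive noise) give the
    convolutional features real structure to separate, unlike flat
    intensity levels whose features are collinear.
    """
    gen = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:patch, 0:patch]
    xs, ys = [], []
    for c in range(n_classes):
        angle = np.pi * c / n_classes
        u, v = np.cos(angle), np.sin(angle)
        phases = gen.uniform(0, 2 * np.pi, n_per_class)
        waves = 0.5 + 0.35 * np.sin(
            2 * np.pi * (u * xx + v * yy)[None] / period + phases[:, None, None]
        )
        waves += gen.normal(0, sigma, waves.shape)
        xs.append(waves.astype(np.float32))
        ys.append(np.full(n_per_class, c))
    return PatchDataset(
        patches=np.concatenate(xs),
        labels=np.concatenate(ys),
        centers=np.zeros((n_per_class * n_classes, 2), dtype=int),
        per_class_count=n_per_class,
        seed=seed,
        patch_size=patch,
    )


def separable_patches(
    n_per_class: int,
    n_classes: int,
    patch: int,
    seed: int,
    sigma: float = 0.05,
) -> PatchDataset:
    """Trivially separable classes: distinct mean intensity per class."""
    gen = np.random.default_rng(seed)
    xs, ys = [], []
    for c in range(n_classes):
        level = (c + 0.5) / n_classes
        xs.append(gen.normal(level, sigma, (n_per_class, patch, patch)).astype(np.float32))
        ys.append(np.full(n_per_class, c))
    return PatchDataset(
        patches=np.concatenate(xs),
        labels=np.concatenate(ys),
        centers=np.zeros((n_per_class * n_classes, 2), dtype=int),
        per_class_count=n_per_class,
        seed=seed,
        patch_size=patch,
    )
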