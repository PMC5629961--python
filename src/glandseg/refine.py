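"""Fusion of the two classifiers into figure/ground probability maps.

The four-class gland maps give a foreground probability (benign gland +
malignant gland) and a background probability (both background classes).
The separator map S is subtracted from the foreground and added to the
background, clamped to [0, 1]:

    p_fg = max{(I_C1 + I_C3) - S, 0}
    p_bg = min{(I_C0 + I_C2) + S, 1}

which carves low-foreground corridors along predicted gland-separating
structures so the subsequent segmentation does not merge adjacent glands.
Running without a separator model (S = 0) gives the unrefined variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .networks import ClassProbabilityMaps, SeparatorMap

__all__ = ["FigureGroundMaps", "combine_maps"]


@dataclass
class FigureGroundMaps:
    """Foreground/background probability maps in [0, 1]."""

    p_fg: np.ndarray
    p_bg: np.ndarray
    scale: float = 1.0

    def __post_init__(self):
        self.p_fg = np.asarray(self.p_fg, dtype=float)
        self.p_bg = np.asarray(self.p_bg, dtype=float)
        if self.p_fg.shape != self.p_bg.shape:
            raise ValueError("foreground and background maps must share shape")
        for m in (self.p_fg, self.p_bg):
            if m.min() < -1e-9 or m.max() > 1 + 1e-9:
                raise ValueError("probability maps must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.p_fg.shape


def combine_maps(
    obj: ClassProbabilityMaps,
    sep: SeparatorMap | np.ndarray | None = None,
) -> FigureGroundMaps:
    """Combine gland-class maps and an optional separator map.

    With ``sep=None`` the separator term is zero, which reproduces the
    "without separator refinement" ablation.
    """
    maps = obj.maps
    if sep is None:
        s = np.zeros(obj.shape)
    else:
        s = np.asarray(getattr(sep, "map", sep), dtype=float)
        if s.shape != obj.shape:
            raise ValueError(
                f"separator map shape {s.shape} != class map shape {obj.shape}"
            )
    p_fg = np.maximum(maps[1] + maps[3] - s, 0.0)
    p_bg = np.minimum(maps[0] + maps[2] + s, 1.0)
    return FigureGroundMaps(p_fg=p_fg, p_bg=p_bg, scale=obj.scale)
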