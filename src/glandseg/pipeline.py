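"""End-to-end orchestration of the segmentation/classification pipeline.

The full pipeline runs in three steps: (1) preprocess the RGB image to the
CLAHE-normalized hematoxylin structure channel and downsample it to the
classifier resolution; (2) slide the two pixel classifiers over it and fuse
their outputs into figure/ground probability maps; (3) upsample the maps to
full resolution and extract gland instances with the weighted-TV
segmentation, while the whole-image benign/malignant decision is taken from
the spatially averaged class maps.

`grid_search_tv` tunes (alpha, beta, lambda) on images with ground truth by
maximizing the pixel-level Dice coefficient of the thresholded solution.
"""

from __future__ import annotations

import itertools
import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import TissueDecision, classify_tissue
from .config import RunConfig
from .dataset import ObjectLabelImage
from .metrics import dice
from .networks import ClassProbabilityMaps, Network, SeparatorMap, predict_maps
from .preprocess import (
    RGBImage,
    StructureChannel,
    apply_clahe,
    extract_structure_channel,
    resample,
    resample_to,
)
from .refine import FigureGroundMaps, combine_maps
from .tvseg import (
    LabeledSegmentation,
    SegmentationField,
    TVParams,
    binarize_and_label,
    compute_edge_map,
    compute_weight_map,
    solve_wtv,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineResult",
    "preprocess_image",
    "segment_from_maps",
    "run_pipeline",
    "grid_search_tv",
    "tune_tau",
    "DEFAULT_GRID",
    "TAU_CANDIDATES",
]

#: Grid-search ranges for the TV parameters.
DEFAULT_GRID = {
    "alpha": np.linspace(0.5, 15.0, 6),
    "beta": np.linspace(0.35, 0.95, 4),
    "lam": np.geomspace(0.01, 10.0, 6),
}

#: Confidence-threshold candidates (steps of 0.15 starting from 0.5).
TAU_CANDIDATES = (0.5, 0.65, 0.8, 0.95)


@dataclass
class PipelineResult:
    segmentation: LabeledSegmentation
    decision: TissueDecision
    field: SegmentationField
    object_maps: ClassProbabilityMaps
    separator_map: SeparatorMap | None
    timings: dict[str, float] = field(default_factory=dict)


def preprocess_image(
    image: RGBImage | np.ndarray, config: RunConfig | None = None
) -> tuple[StructureChannel, StructureChannel]:
    """Full-resolution and classifier-resolution structure channels."""
    config = config or RunConfig()
    pp = config.preprocess
    channel = extract_structure_channel(
        image, stain_matrix=np.asarray(pp.stain_matrix), channel=pp.structure_channel
    )
    channel = apply_clahe(channel, pp.clahe_clip_limit, tuple(pp.clahe_tile_grid))
    if pp.scale == 1.0:
        half = channel
    else:
        half = StructureChannel(
            np.clip(resample(channel.pixels, pp.scale, mode="bilinear"), 0, 255),
            scale=pp.scale,
        )
    return channel, half


def segment_from_maps(
    obj_maps: ClassProbabilityMaps,
    sep_map: SeparatorMap | None,
    channel: StructureChannel,
    tv: TVParams | None = None,
    min_area: int = 500,
) -> tuple[LabeledSegmentation, SegmentationField]:
    """Weighted-TV segmentation from (possibly low-resolution) class maps.

    The figure/ground combination happens at the classifier scale; the
    combined maps are bilinearly upsampled to the full-resolution channel
    grid before confidence thresholding, logit weighting and TV solving.
    """
    tv = tv or TVParams()
    fg = combine_maps(obj_maps, sep_map)
    shape = channel.shape
    p_fg = np.clip(resample_to(fg.p_fg, shape, mode="bilinear"), 0, 1)
    p_bg = np.clip(resample_to(fg.p_bg, shape, mode="bilinear"), 0, 1)
    fg_full = FigureGroundMaps(p_fg=p_fg, p_bg=p_bg, scale=1.0)
    w = compute_weight_map(fg_full, tau=tv.tau)
    g = compute_edge_map(channel, alpha=tv.alpha, beta=tv.beta)
    u = solve_wtv(g, w, lam=tv.lam, params=tv)
    labels = binarize_and_label(u, threshold=0.5, min_area=min_area)
    return labels, u


def run_pipeline(
    image: RGBImage | np.ndarray,
    object_net: Network,
    separator_net: Network | None = None,
    config: RunConfig | None = None,
    stride: int = 1,
) -> PipelineResult:
    """Segment and classify one image with trained networks.

    ``separator_net=None`` runs the without-separator ablation (S = 0).
    """
    config = config or RunConfig()
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    channel, half = preprocess_image(image, config)
    timings["preprocess"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    obj_maps = predict_maps(object_net, half, stride=stride)
    sep_map = (
        predict_maps(separator_net, half, stride=stride)
        if separator_net is not None
        else None
    )
    timings["classify_pixels"] = time.perf_counter() - t0

    # image-level decision from the classifier-resolution maps
    decision = classify_tissue(obj_maps)

    t0 = time.perf_counter()
    labels, field_u = segment_from_maps(
        obj_maps, sep_map, channel, tv=config.tv, min_area=config.min_area
    )
    timings["tv_segmentation"] = time.perf_counter() - t0
    logger.info(
        "pipeline done: %d objects, %s (confidence %.3f); timings %s",
        labels.n_objects, decision.label, decision.confidence,
        {k: round(v, 3) for k, v in timings.items()},
    )
    return PipelineResult(
        segmentation=labels,
        decision=decision,
        field=field_u,
        object_maps=obj_maps,
        separator_map=sep_map,
        timings=timings,
    )


def _pixel_dice_for_params(
    channels: list[StructureChannel],
    fg_maps: list[FigureGroundMaps],
    gt_masks: list[np.ndarray],
    alpha: float,
    beta: float,
    lam: float,
    tau: float,
    tv_template: TVParams,
) -> tuple[float, float]:
    """(per-image-mean, micro-averaged) pixel Dice for one parameter triple."""
    dices = []
    inter_total = size_total = 0
    params = TVParams(
        alpha=alpha, beta=beta, lam=lam, tau=tau,
        max_iters=tv_template.max_iters, tol=tv_template.tol,
    )
    for channel, fg, gt in zip(channels, fg_maps, gt_masks):
        w = compute_weight_map(fg, tau=tau)
        g = compute_edge_map(channel, alpha=alpha, beta=beta)
        u = solve_wtv(g, w, lam=lam, params=params)
        pred = u.u >= 0.5
        gt = np.asarray(gt, dtype=bool)
        dices.append(dice(gt, pred))
        inter_total += int((gt & pred).sum())
        size_total += int(gt.sum()) + int(pred.sum())
    micro = 2.0 * inter_total / size_total if size_total else 1.0
    return float(np.mean(dices)), float(micro)


def grid_search_tv(
    channels: list[StructureChannel],
    gt_labels: list[ObjectLabelImage | np.ndarray],
    fg_maps: list[FigureGroundMaps],
    alphas=None,
    betas=None,
    lams=None,
    tau: float = 0.65,
    tv_template: TVParams | None = None,
) -> tuple[TVParams, pd.DataFrame]:
    """Grid search over (alpha, beta, lambda) maximizing pixel-level Dice.

    Both the per-image mean and the micro-averaged (all pixels pooled) Dice
    are reported for every grid point; the argmax uses the per-image mean.
    Figure/ground maps must already be at the channels' resolution.
    """
    alphas = DEFAULT_GRID["alpha"] if alphas is None else np.atleast_1d(alphas)
    betas = DEFAULT_GRID["beta"] if betas is None else np.atleast_1d(betas)
    lams = DEFAULT_GRID["lam"] if lams is None else np.atleast_1d(lams)
    if len(alphas) == 0 or len(betas) == 0 or len(lams) == 0:
        raise ValueError("grid must contain at least one point per axis")
    tv_template = tv_template or TVParams()
    gt_masks = [np.asarray(getattr(g, "pixels", g)) > 0 for g in gt_labels]

    rows = []
    for a, b, l in itertools.product(alphas, betas, lams):
        mean_dice, micro_dice = _pixel_dice_for_params(
            channels, fg_maps, gt_masks, a, b, l, tau, tv_template
        )
        rows.append({"alpha": a, "beta": b, "lam": l,
                     "mean_dice": mean_dice, "micro_dice": micro_dice})
        logger.debug("grid point a=%g b=%g l=%g: dice %.4f / %.4f",
                     a, b, l, mean_dice, micro_dice)
    table = pd.DataFrame(rows)
    best = table.loc[table["mean_dice"].idxmax()]
    best_params = TVParams(
        alpha=float(best["alpha"]), beta=float(best["beta"]),
        lam=float(best["lam"]), tau=tau,
        max_iters=tv_template.max_iters, tol=tv_template.tol,
    )
    return best_params, table


def tune_tau(
    channels,
    gt_labels,
    fg_maps,
    base: TVParams | None = None,
    candidates=TAU_CANDIDATES,
) -> tuple[float, pd.DataFrame]:
    """Pick the confidence threshold tau by per-image-mean pixel Dice."""
    base = base or TVParams()
    gt_masks = [np.asarray(getattr(g, "pixels", g)) > 0 for g in gt_labels]
    rows = []
    for tau in candidates:
        mean_dice, micro_dice = _pixel_dice_for_params(
            channels, fg_maps, gt_masks, base.alpha, base.beta, base.lam, tau, base
        )
        rows.append({"tau": tau, "mean_dice": mean_dice, "micro_dice": micro_dice})
    table = pd.DataFrame(rows)
    return float(table.loc[table["mean_dice"].idxmax(), "tau"]), table
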