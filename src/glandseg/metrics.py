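"""Object-level segmentation and image-level classification metrics.

Implements the GlaS-style evaluation: a segmented object is associated to
the ground-truth object it maximally overlaps; an area overlap of at least
50% makes it a true positive, otherwise a false positive, and uncovered
ground-truth objects are false negatives.  Detection is summarized by
precision/recall/F1; segmentation quality by the pixel Dice index and its
area-weighted object-level aggregation; shape similarity by the Hausdorff
distance and its object-level aggregation.  Benign/malignant classification
is scored from a 2x2 confusion matrix (overall accuracy = trace / total,
plus class-wise precision/recall/F1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import directed_hausdorff

__all__ = [
    "SegmentationObjects",
    "MatchResult",
    "ConfusionMatrix",
    "match_objects",
    "detection_scores",
    "dice",
    "object_dice",
    "hausdorff",
    "object_hausdorff",
    "classification_metrics",
    "evaluate_image",
    "evaluate_dataset",
]


@dataclass
class SegmentationObjects:
    """Disjoint labeled instances of one image side (ground truth or result)."""

    ids: np.ndarray            # instance ids, sorted
    areas: np.ndarray          # pixel counts per instance
    label_image: np.ndarray    # the source integer raster

    @classmethod
    def from_labels(cls, labels) -> "SegmentationObjects":
        arr = np.asarray(getattr(labels, "pixels", labels))
        ids = np.unique(arr)
        ids = ids[ids > 0]
        areas = np.array([(arr == i).sum() for i in ids])
        return cls(ids=ids, areas=areas, label_image=arr)

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def weights(self) -> np.ndarray:
        """Relative areas; sum to 1 when any instance exists."""
        total = self.areas.sum()
        return self.areas / total if total else self.areas.astype(float)

    def mask(self, instance_id: int) -> np.ndarray:
        return self.label_image == instance_id

    def points(self, instance_id: int) -> np.ndarray:
        return np.argwhere(self.label_image == instance_id)


@dataclass
class MatchResult:
    """Detection counts plus the per-object association table."""

    tp: int
    fp: int
    fn: int
    pairs: list[tuple[int, int, float]]  # (gt id, seg id, overlap fraction)

    @property
    def counts(self) -> tuple[int, int, int]:
        return self.tp, self.fp, self.fn


def _intersections(gt: np.ndarray, seg: np.ndarray) -> dict[tuple[int, int], int]:
    """Pixel counts of every co-occurring (gt id > 0, seg id > 0) pair."""
    both = (gt > 0) & (seg > 0)
    pairs, counts = np.unique(
        np.stack([gt[both], seg[both]]), axis=1, return_counts=True
    )
    return {(int(g), int(s)): int(c) for (g, s), c in zip(pairs.T, counts)}


def match_objects(
    gt,
    seg,
    min_overlap: float = 0.5,
    overlap: str = "gt_area",
) -> MatchResult:
    """Associate segmented objects with ground-truth objects.

    Each segmented object is paired with the ground-truth object it shares
    the most pixels with.  The pair is a true positive when the overlap
    fraction reaches ``min_overlap``; the fraction is the intersection over
    the ground-truth object's area (``overlap="gt_area"``, the default) or
    intersection over union (``overlap="iou"``).  Ground-truth objects not
    claimed by any true positive are false negatives.
    """
    gt_arr = np.asarray(getattr(gt, "pixels", gt))
    seg_arr = np.asarray(getattr(seg, "pixels", seg))
    if gt_arr.shape != seg_arr.shape:
        raise ValueError("ground truth and segmentation must share shape")
    if overlap not in ("gt_area", "iou"):
        raise ValueError("overlap must be 'gt_area' or 'iou'")
    g_obj = SegmentationObjects.from_labels(gt_arr)
    s_obj = SegmentationObjects.from_labels(seg_arr)
    inter = _intersections(gt_arr, seg_arr)
    g_area = dict(zip(g_obj.ids.tolist(), g_obj.areas.tolist()))
    s_area = dict(zip(s_obj.ids.tolist(), s_obj.areas.tolist()))

    tp = 0
    pairs: list[tuple[int, int, float]] = []
    matched_gt: set[int] = set()
    for s in s_obj.ids.tolist():
        overlaps = {g: c for (g, ss), c in inter.items() if ss == s}
        if not overlaps:
            pairs.append((0, s, 0.0))
            continue
        g_best = max(overlaps, key=lambda g: (overlaps[g], -g))
        c = overlaps[g_best]
        if overlap == "gt_area":
            frac = c / g_area[g_best]
        else:
            frac = c / (g_area[g_best] + s_area[s] - c)
        pairs.append((g_best, s, float(frac)))
        if frac >= min_overlap:
            tp += 1
            matched_gt.add(g_best)
    fp = len(s_obj) - tp
    fn = len(g_obj) - len(matched_gt)
    return MatchResult(tp=tp, fp=fp, fn=fn, pairs=pairs)


def detection_scores(m: MatchResult) -> tuple[float, float, float]:
    """(precision, recall, F1) with 0/0 guarded to 0."""
    prc = m.tp / (m.tp + m.fp) if (m.tp + m.fp) else 0.0
    rec = m.tp / (m.tp + m.fn) if (m.tp + m.fn) else 0.0
    f1 = 2 * prc * rec / (prc + rec) if (prc + rec) else 0.0
    return prc, rec, f1


def dice(g: np.ndarray, s: np.ndarray) -> float:
    """Dice overlap of two binary masks; two empty sets give 1 by convention."""
    g = np.asarray(g, dtype=bool)
    s = np.asarray(s, dtype=bool)
    total = int(g.sum()) + int(s.sum())
    if total == 0:
        return 1.0
    return 2.0 * int((g & s).sum()) / total


def _max_overlap_partner(
    inter: dict[tuple[int, int], int], instance: int, axis: int
) -> int | None:
    """Id on the other side with maximal shared pixels, or None."""
    overlaps = {
        key[1 - axis]: c for key, c in inter.items() if key[axis] == instance
    }
    if not overlaps:
        return None
    return max(overlaps, key=lambda k: (overlaps[k], -k))


def object_dice(gt, seg) -> float:
    """Area-weighted two-sided object-level Dice.

    Every instance is paired with its maximally overlapping partner on the
    other side (an instance with no overlap contributes Dice 0) and the two
    directed, area-weighted sums are averaged.
    """
    g_obj = SegmentationObjects.from_labels(getattr(gt, "pixels", gt))
    s_obj = SegmentationObjects.from_labels(getattr(seg, "pixels", seg))
    if len(g_obj) == 0 and len(s_obj) == 0:
        return 1.0
    if len(g_obj) == 0 or len(s_obj) == 0:
        return 0.0
    inter = _intersections(g_obj.label_image, s_obj.label_image)

    def directed(a: SegmentationObjects, b: SegmentationObjects, axis: int) -> float:
        total = 0.0
        for inst, wgt in zip(a.ids.tolist(), a.weights):
            partner = _max_overlap_partner(inter, inst, axis)
            if partner is not None:
                total += wgt * dice(a.mask(inst), b.mask(partner))
        return total

    return 0.5 * (directed(g_obj, s_obj, 0) + directed(s_obj, g_obj, 1))


def _as_points(x: np.ndarray) -> np.ndarray:
    """Coordinate array from a binary mask or an (N, 2) point list."""
    x = np.asarray(x)
    if x.dtype == bool:
        return np.argwhere(x)
    if x.ndim == 2 and x.shape[1] == 2 and x.dtype.kind == "f":
        return x  # already a list of (row, col) coordinates
    return np.argwhere(x != 0)


def hausdorff(g: np.ndarray, s: np.ndarray) -> float:
    """Symmetric Hausdorff distance (Euclidean, pixels) of two pixel sets."""
    gp = _as_points(g)
    sp = _as_points(s)
    if len(gp) == 0 or len(sp) == 0:
        raise ValueError("Hausdorff distance is undefined for empty sets")
    return max(
        directed_hausdorff(gp, sp)[0],
        directed_hausdorff(sp, gp)[0],
    )


def object_hausdorff(gt, seg) -> float:
    """Area-weighted two-sided object-level Hausdorff distance.

    Instance pairs follow the maximum-overlap rule; an instance with no
    overlapping partner is scored against the instance on the other side
    with the smallest Hausdorff distance, keeping the aggregate finite while
    penalizing spurious and missed objects.  Returns NaN when either side
    has no instances at all.
    """
    g_obj = SegmentationObjects.from_labels(getattr(gt, "pixels", gt))
    s_obj = SegmentationObjects.from_labels(getattr(seg, "pixels", seg))
    if len(g_obj) == 0 or len(s_obj) == 0:
        return float("nan")
    inter = _intersections(g_obj.label_image, s_obj.label_image)

    def directed(a: SegmentationObjects, b: SegmentationObjects, axis: int) -> float:
        total = 0.0
        for inst, wgt in zip(a.ids.tolist(), a.weights):
            partner = _max_overlap_partner(inter, inst, axis)
            if partner is not None:
                hd = hausdorff(a.mask(inst), b.mask(partner))
            else:
                hd = min(hausdorff(a.mask(inst), b.mask(other))
                         for other in b.ids.tolist())
            total += wgt * hd
        return total

    return 0.5 * (directed(g_obj, s_obj, 0) + directed(s_obj, g_obj, 1))


@dataclass
class ConfusionMatrix:
    """2x2 counts, rows = predicted class, columns = ground truth."""

    m: np.ndarray
    classes: tuple[str, str] = ("benign", "malignant")

    def __post_init__(self):
        self.m = np.asarray(self.m)
        if self.m.shape != (2, 2) or (self.m < 0).any():
            raise ValueError("confusion matrix must be 2x2 with counts >= 0")

    @property
    def total(self) -> int:
        return int(self.m.sum())

    @classmethod
    def from_predictions(cls, predicted, truth,
                         classes: tuple[str, str] = ("benign", "malignant")
                         ) -> "ConfusionMatrix":
        m = np.zeros((2, 2), dtype=int)
        for p, t in zip(predicted, truth):
            m[int(p), int(t)] += 1
        return cls(m=m, classes=classes)


def classification_metrics(matrix: ConfusionMatrix | np.ndarray) -> dict:
    """Overall accuracy plus class-wise precision/recall/F1.

    Rows of the matrix are predictions, columns ground truth.  For class k,
    TP = M[k, k], FP = row k off-diagonal, FN = column k off-diagonal.
    """
    cm = matrix if isinstance(matrix, ConfusionMatrix) else ConfusionMatrix(np.asarray(matrix))
    if cm.total == 0:
        raise ValueError("confusion matrix is empty")
    m = cm.m.astype(float)
    out: dict = {"accuracy": float(np.trace(m) / m.sum()), "per_class": {}}
    for k, name in enumerate(cm.classes):
        tp = m[k, k]
        fp = m[k].sum() - tp
        fn = m[:, k].sum() - tp
        prc = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prc * rec / (prc + rec) if prc + rec else 0.0
        out["per_class"][name] = {
            "precision": float(prc), "recall": float(rec), "f1": float(f1)
        }
    return out


def evaluate_image(gt, seg, min_overlap: float = 0.5) -> dict:
    """All segmentation metrics of one image as a flat record."""
    gt_arr = np.asarray(getattr(gt, "pixels", gt))
    seg_arr = np.asarray(getattr(seg, "pixels", seg))
    m = match_objects(gt_arr, seg_arr, min_overlap=min_overlap)
    prc, rec, f1 = detection_scores(m)
    return {
        "tp": m.tp, "fp": m.fp, "fn": m.fn,
        "precision": prc, "recall": rec, "f1": f1,
        "pixel_dice": dice(gt_arr > 0, seg_arr > 0),
        "object_dice": object_dice(gt_arr, seg_arr),
        "object_hausdorff": object_hausdorff(gt_arr, seg_arr),
    }


def evaluate_dataset(gt_images, seg_images, names=None) -> pd.DataFrame:
    """Per-image metric table; aggregate with ``df.mean()`` / ``df.std()``.

    The reporting convention for a dataset is mean (SD) over the individual
    images of each metric column.
    """
    records = []
    for i, (g, s) in enumerate(zip(gt_images, seg_images)):
        rec = evaluate_image(g, s)
        rec["image"] = names[i] if names is not None else str(i)
        records.append(rec)
    return pd.DataFrame.from_records(records).set_index("image")
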