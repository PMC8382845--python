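"""Recovery metrics comparing segmentation output against simulator truth.

Clump regions are excluded from every comparison: the pipeline deliberately
refuses to quantify them, so cells and neurite sections inside a true clump
are neither credited nor penalised.
"""

from __future__ import annotations

import numpy as np

from .segment import SegmentationMasks
from .simulate import GroundTruth


def mask_iou(pred: np.ndarray, true: np.ndarray,
             exclude: np.ndarray | None = None) -> float:
    """Intersection-over-union of two binary masks (NaN when both empty)."""
    pred = np.asarray(pred, bool)
    true = np.asarray(true, bool)
    if exclude is not None:
        keep = ~np.asarray(exclude, bool)
        pred = pred & keep
        true = true & keep
    union = (pred | true).sum()
    if union == 0:
        return float("nan")
    return float((pred & true).sum() / union)


def _label_matches(pred_labels: np.ndarray, true_labels: np.ndarray,
                   iou_min: float = 0.5) -> tuple[int, int, int]:
    """Greedy one-to-one object matching by IoU; returns (tp, fp, fn)."""
    pred_ids = np.unique(pred_labels)
    pred_ids = pred_ids[pred_ids != 0]
    true_ids = np.unique(true_labels)
    true_ids = true_ids[true_ids != 0]
    if pred_ids.size == 0 or true_ids.size == 0:
        return 0, int(pred_ids.size), int(true_ids.size)
    # joint histogram of (pred, true) label pairs
    both = (pred_labels > 0) & (true_labels > 0)
    pairs, counts = np.unique(
        np.stack([pred_labels[both], true_labels[both]]), axis=1,
        return_counts=True)
    pred_areas = {i: int((pred_labels == i).sum()) for i in pred_ids}
    true_areas = {i: int((true_labels == i).sum()) for i in true_ids}
    cands = []
    for (p, t), inter in zip(pairs.T, counts):
        union = pred_areas[int(p)] + true_areas[int(t)] - int(inter)
        iou = inter / union if union else 0.0
        if iou >= iou_min:
            cands.append((iou, int(p), int(t)))
    cands.sort(reverse=True)
    used_p: set[int] = set()
    used_t: set[int] = set()
    tp = 0
    for _, p, t in cands:
        if p in used_p or t in used_t:
            continue
        used_p.add(p)
        used_t.add(t)
        tp += 1
    return tp, int(pred_ids.size) - tp, int(true_ids.size) - tp


def soma_f1(masks: SegmentationMasks, truth: GroundTruth,
            iou_min: float = 0.5) -> float:
    """Object-level F1 for soma detection (IoU >= iou_min match), outside clumps."""
    excl = np.asarray(truth.clump_mask, bool)
    pred = np.where(excl, 0, masks.soma_labels)
    true = np.where(excl, 0, truth.soma_labels)
    # drop somata (either side) mostly hidden by the clump
    for lab in np.unique(truth.soma_labels[excl]):
        if lab == 0:
            continue
        if (true == lab).sum() < 0.5 * (truth.soma_labels == lab).sum():
            true[true == lab] = 0
    for lab in np.unique(masks.soma_labels[excl]):
        if lab == 0:
            continue
        if (pred == lab).sum() < 0.5 * (masks.soma_labels == lab).sum():
            pred[pred == lab] = 0
    tp, fp, fn = _label_matches(pred, true, iou_min)
    denom = 2 * tp + fp + fn
    return float(2 * tp / denom) if denom else float("nan")


def neurite_quant_iou(masks: SegmentationMasks, truth: GroundTruth) -> float:
    """IoU of the final neurite quantification mask vs truth minus somata/clumps."""
    true_quant = (np.asarray(truth.neurite_mask, bool)
                  & ~(np.asarray(truth.soma_labels) > 0)
                  & ~np.asarray(truth.clump_mask, bool))
    return mask_iou(masks.neurite_quant_mask, true_quant,
                    exclude=truth.clump_mask)


def live_nucleus_counts(masks: SegmentationMasks,
                        truth: GroundTruth) -> tuple[int, int]:
    """(detected, true) live nucleus counts, excluding dead and clumped nuclei."""
    clump = np.asarray(truth.clump_mask, bool)
    true_n = 0
    for lab, klass in truth.nucleus_classes.items():
        if klass == "dead":
            continue
        px = truth.nucleus_labels == lab
        if not px.any() or clump[px].mean() > 0.5:
            continue   # fully overwritten by an overlapping clump sibling
        true_n += 1
    pred_n = sum(1 for r in masks.nuclei
                 if r.klass in ("neuronal_live", "nonneuronal"))
    return pred_n, true_n


def nucleus_count_error(masks: SegmentationMasks, truth: GroundTruth) -> float:
    """Relative error of the live (non-dead, non-clumped) nucleus count."""
    pred_n, true_n = live_nucleus_counts(masks, truth)
    if true_n == 0:
        return float("nan")
    return float((pred_n - true_n) / true_n)


def dead_exclusion_rate(masks: SegmentationMasks, truth: GroundTruth) -> tuple[int, int]:
    """(dead nuclei flagged dead_excluded, dead nuclei in truth).

    A truth dead nucleus counts as excluded when the detected object covering
    its centre is classed dead_excluded, or when it was rejected outright.
    """
    dead_ids = [l for l, c in truth.nucleus_classes.items() if c == "dead"]
    dead_records = {r.label for r in masks.nuclei if r.klass == "dead_excluded"}
    live_records = {r.label for r in masks.nuclei if r.klass != "dead_excluded"}
    n_excluded = 0
    for lab in dead_ids:
        px = truth.nucleus_labels == lab
        covering = np.unique(masks.nucleus_labels[px])
        covering = {int(c) for c in covering if c != 0}
        if not covering & live_records or covering & dead_records:
            n_excluded += 1
    return n_excluded, len(dead_ids)


def clump_coverage(masks: SegmentationMasks, truth: GroundTruth) -> float:
    """Fraction of truth clump pixels covered by the detected clump mask."""
    true = np.asarray(truth.clump_mask, bool)
    if not true.any():
        return float("nan")
    return float((np.asarray(masks.clump_mask, bool) & true).sum() / true.sum())
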