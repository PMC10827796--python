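"""Evaluation battery: classification metrics, segmentation IoU, the joint
classification+localization criterion, lesion-size / quadrant stratification,
and class-merge analysis.

Conventions fixed here and used everywhere else in the package:

* Quadrants split the image at its centre and are numbered counterclockwise
  starting from the upper right: 1 = upper-right, 2 = upper-left,
  3 = lower-left, 4 = lower-right.  A point exactly on the centre lands in
  quadrant 1 (>= / <= tie-break; y grows downward).
* Joint diagnosis is correct iff the class matches AND (the reference is
  Normal, or the segmentation IoU is strictly greater than the threshold,
  default 0.5).  The heatmap of a correctly predicted Normal case is ignored.
* Size stratification uses equal-frequency bins of total lesion pixel count.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import CLASSES

__all__ = [
    "quadrant_of",
    "classification_metrics",
    "segmentation_iou",
    "joint_accuracy",
    "stratified_report",
    "merge_classes",
]


def quadrant_of(x: float, y: float, cx: float, cy: float) -> int:
    """Quadrant id of point (x, y) relative to centre (cx, cy); y downward."""
    right = x >= cx
    upper = y <= cy
    if upper:
        return 1 if right else 2
    return 4 if right else 3


# ----------------------------------------------------------------------


def _per_class_counts(pred, true, cls):
    pred = np.asarray(pred)
    true = np.asarray(true)
    tp = int(np.sum((pred == cls) & (true == cls)))
    fp = int(np.sum((pred == cls) & (true != cls)))
    fn = int(np.sum((pred != cls) & (true == cls)))
    tn = int(np.sum((pred != cls) & (true != cls)))
    return tp, fp, fn, tn


def classification_metrics(predictions, labels, classes=CLASSES) -> dict:
    """One-vs-rest accuracy / precision / recall / F1 per class plus macro
    (and micro) aggregates.

    A class absent from both predictions and references gets NaN (undefined)
    rather than zero, and NaNs are excluded from the macro averages.
    """
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.size == 0 or predictions.shape != labels.shape:
        raise ValueError("predictions and labels must be equal-length and nonempty")

    rows = {}
    for cls in classes:
        tp, fp, fn, tn = _per_class_counts(predictions, labels, cls)
        if tp + fp + fn == 0:
            acc = prec = rec = f1 = float("nan")
        else:
            acc = (tp + tn) / (tp + fp + fn + tn)
            prec = tp / (tp + fp) if tp + fp else float("nan")
            rec = tp / (tp + fn) if tp + fn else float("nan")
            f1 = (2 * prec * rec / (prec + rec)
                  if prec == prec and rec == rec and (prec + rec) > 0 else
                  (0.0 if (prec == prec and rec == rec) else float("nan")))
        rows[cls] = {"accuracy": acc, "precision": prec, "recall": rec, "f1": f1,
                     "support": int(np.sum(labels == cls))}
    per_class = pd.DataFrame(rows).T

    overall_acc = float(np.mean(predictions == labels))
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore", RuntimeWarning)   # all-NaN columns
        macro = {m: float(np.nanmean(per_class[m].to_numpy(dtype=float)))
                 for m in ("precision", "recall", "f1")}
    macro["accuracy"] = overall_acc
    # micro over one-vs-rest counts
    tps = fps = fns = 0
    for cls in classes:
        tp, fp, fn, _ = _per_class_counts(predictions, labels, cls)
        tps, fps, fns = tps + tp, fps + fp, fns + fn
    micro_p = tps / (tps + fps) if tps + fps else float("nan")
    micro_r = tps / (tps + fns) if tps + fns else float("nan")
    micro = {"precision": micro_p, "recall": micro_r,
             "f1": (2 * micro_p * micro_r / (micro_p + micro_r)
                    if (micro_p + micro_r) > 0 else float("nan")),
             "accuracy": overall_acc}
    return {"per_class": per_class, "macro": macro, "micro": micro,
            "accuracy": overall_acc}


def segmentation_iou(pred_mask: np.ndarray, ref_mask: np.ndarray) -> float:
    """|A intersect B| / |A union B|; defined as 1.0 when both masks are empty."""
    pred_mask = np.asarray(pred_mask, bool)
    ref_mask = np.asarray(ref_mask, bool)
    if pred_mask.shape != ref_mask.shape:
        raise ValueError("mask shapes differ")
    union = np.logical_or(pred_mask, ref_mask).sum()
    if union == 0:
        return 1.0
    inter = np.logical_and(pred_mask, ref_mask).sum()
    return float(inter / union)


def joint_accuracy(predictions, references, iou_threshold: float = 0.5) -> float:
    """Fraction of samples with the correct class AND successful localization.

    ``predictions``: iterable of (label, mask); ``references``: iterable of
    (label, mask-or-None).  Localization succeeds when IoU is strictly greater
    than ``iou_threshold``; Normal references are judged on the class alone.
    """
    n = correct = 0
    for (p_label, p_mask), (r_label, r_mask) in zip(predictions, references,
                                                    strict=True):
        n += 1
        if p_label != r_label:
            continue
        if r_label == "Normal":
            correct += 1
            continue
        if r_mask is None:
            raise ValueError("abnormal reference sample without a mask")
        if segmentation_iou(p_mask, r_mask) > iou_threshold:
            correct += 1
    if n == 0:
        raise ValueError("empty evaluation set")
    return correct / n


def _cell_metrics(sub: pd.DataFrame) -> dict:
    m = classification_metrics(sub["pred_label"].to_numpy(),
                               sub["label"].to_numpy())
    return {"f1": m["macro"]["f1"], "accuracy": m["accuracy"],
            "iou": float(sub["iou"].mean()), "n": len(sub)}


def stratified_report(records: pd.DataFrame, n_bins: int = 10,
                      image_size: tuple[int, int] | None = None
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-size-bin and per-quadrant tables of mean F1 (classification) and
    mean IoU (localization) over abnormal samples.

    ``records`` needs columns: label, pred_label, iou, lesion_pixels,
    center_x, center_y (largest-lesion centre), plus ``image_w``/``image_h``
    unless ``image_size`` is given.  Bins are equal-frequency by lesion pixel
    count; bin ids grow with lesion size (1..n_bins).
    """
    ab = records[records["label"] != "Normal"].copy()
    if ab.empty:
        raise ValueError("no abnormal samples to stratify")
    k = min(n_bins, len(ab))
    if k < n_bins:
        import warnings
        warnings.warn(f"only {len(ab)} abnormal samples; using {k} bins", stacklevel=2)
    order = np.argsort(ab["lesion_pixels"].to_numpy(), kind="stable")
    chunks = np.array_split(order, k)
    bin_id = np.empty(len(ab), int)
    for b, chunk in enumerate(chunks, start=1):
        bin_id[chunk] = b
    ab["size_bin"] = bin_id

    if image_size is not None:
        cx, cy = image_size[0] / 2.0, image_size[1] / 2.0
        ab["quadrant"] = [quadrant_of(x, y, cx, cy)
                          for x, y in zip(ab["center_x"], ab["center_y"])]
    else:
        ab["quadrant"] = [quadrant_of(x, y, w / 2.0, h / 2.0)
                          for x, y, w, h in zip(ab["center_x"], ab["center_y"],
                                                ab["image_w"], ab["image_h"])]

    size_table = pd.DataFrame({b: _cell_metrics(g)
                               for b, g in ab.groupby("size_bin")}).T
    size_table.index.name = "size_bin"
    quad_table = pd.DataFrame({q: _cell_metrics(g)
                               for q, g in ab.groupby("quadrant")}).T
    quad_table = quad_table.reindex([q for q in (1, 2, 3, 4)
                                     if q in quad_table.index])
    quad_table.index.name = "quadrant"
    return size_table, quad_table


def merge_classes(predictions, labels, merge_set, classes=CLASSES) -> dict:
    """Relabel every class in ``merge_set`` to one merged class in both the
    predictions and the references, then recompute metrics on the coarser
    problem (e.g. treating AB and OKC as one class)."""
    merge_set = set(merge_set)
    if not merge_set:
        return classification_metrics(predictions, labels, classes)
    if not merge_set <= set(classes):
        raise ValueError("merge_set must be a subset of the class set")
    merged_name = "+".join(c for c in classes if c in merge_set)
    remap = {c: (merged_name if c in merge_set else c) for c in classes}
    new_classes = []
    for c in classes:
        name = remap[c]
        if name not in new_classes:
            new_classes.append(name)
    pred2 = [remap[p] for p in predictions]
    true2 = [remap[t] for t in labels]
    return classification_metrics(pred2, true2, tuple(new_classes))
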