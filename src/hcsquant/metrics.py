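"""Ground-truth matching metrics for validating segmentation and detection
against synthetic scenes."""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist


def match_labels(
    true_labels: np.ndarray, pred_labels: np.ndarray, iou_min: float = 0.7
) -> list[tuple[int, int, float]]:
    """One-to-one matching of label maps by IoU (Hungarian assignment).

    Returns (true_id, pred_id, iou) triples with iou >= iou_min.
    """
    true_ids = np.unique(true_labels)
    true_ids = true_ids[true_ids > 0]
    pred_ids = np.unique(pred_labels)
    pred_ids = pred_ids[pred_ids > 0]
    if len(true_ids) == 0 or len(pred_ids) == 0:
        return []
    iou = np.zeros((len(true_ids), len(pred_ids)))
    for i, t in enumerate(true_ids):
        tm = true_labels == t
        t_area = tm.sum()
        overlapping = np.unique(pred_labels[tm])
        for p in overlapping[overlapping > 0]:
            j = int(np.searchsorted(pred_ids, p))
            inter = np.logical_and(tm, pred_labels == p).sum()
            union = t_area + (pred_labels == p).sum() - inter
            iou[i, j] = inter / union
    ti, pj = linear_sum_assignment(-iou)
    return [
        (int(true_ids[i]), int(pred_ids[j]), float(iou[i, j]))
        for i, j in zip(ti, pj)
        if iou[i, j] >= iou_min
    ]


def match_points(
    true_points: np.ndarray, pred_points: np.ndarray, max_dist: float
) -> list[tuple[int, int, float]]:
    """One-to-one nearest matching of point sets within max_dist (pixels)."""
    true_points = np.atleast_2d(np.asarray(true_points, dtype=float))
    pred_points = np.atleast_2d(np.asarray(pred_points, dtype=float))
    if true_points.size == 0 or pred_points.size == 0:
        return []
    d = cdist(true_points, pred_points)
    ti, pj = linear_sum_assignment(d)
    return [
        (int(i), int(j), float(d[i, j]))
        for i, j in zip(ti, pj)
        if d[i, j] <= max_dist
    ]


def recall_precision(n_true: int, n_pred: int, n_matched: int) -> tuple[float, float]:
    recall = n_matched / n_true if n_true else 0.0
    precision = n_matched / n_pred if n_pred else 0.0
    return recall, precision
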