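"""Benchmarking segmentations against ground truth.

Labels are first unified by an optimal one-to-one assignment maximizing
the total voxel overlap; per-cell agreement is then scored by the dice
ratio and the bidirectional Hausdorff distance, and object-level quality
by TP/FN/FP grouping at IoU thresholds 0.50..0.95 (F1 = 2TP/(2TP+FN+FP))
plus split/merge/precision/recall counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import linear_sum_assignment


def _contingency(pred: np.ndarray, truth: np.ndarray):
    """Overlap counts between nonzero labels of two same-shape label fields."""
    pred = np.asarray(pred).ravel()
    truth = np.asarray(truth).ravel()
    p_ids = np.unique(pred[pred > 0])
    t_ids = np.unique(truth[truth > 0])
    p_idx = {v: i for i, v in enumerate(p_ids)}
    t_idx = {v: i for i, v in enumerate(t_ids)}
    M = np.zeros((len(p_ids), len(t_ids)), dtype=np.int64)
    sel = (pred > 0) & (truth > 0)
    pair = pred[sel].astype(np.int64) * (truth.max() + 1) + truth[sel]
    vals, counts = np.unique(pair, return_counts=True)
    for v, c in zip(vals, counts):
        p, t = divmod(int(v), int(truth.max() + 1))
        M[p_idx[p], t_idx[t]] = c
    p_sizes = np.array([(pred == v).sum() for v in p_ids])
    t_sizes = np.array([(truth == v).sum() for v in t_ids])
    return M, p_ids, t_ids, p_sizes, t_sizes


@dataclass
class MatchedSegmentation:
    relabeled: np.ndarray               # pred volume on the truth label space
    mapping: dict[int, int]             # pred label -> truth label
    unmatched_pred: list[int]
    unmatched_truth: list[int]
    overlap: np.ndarray                 # contingency matrix
    pred_ids: np.ndarray
    truth_ids: np.ndarray
    pred_sizes: np.ndarray
    truth_sizes: np.ndarray


def unify_labels(pred: np.ndarray, truth: np.ndarray) -> MatchedSegmentation:
    """Relabel a predicted field onto the ground-truth label space.

    Matched labels are chosen by the one-to-one assignment maximizing the
    total overlapping voxel count (optimal, not greedy); pairs with zero
    overlap are not matched. Unmatched predicted labels keep fresh ids
    above the truth range; background (0) is excluded throughout.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("shape mismatch")
    M, p_ids, t_ids, p_sizes, t_sizes = _contingency(pred, truth)
    mapping: dict[int, int] = {}
    if M.size:
        rows, cols = linear_sum_assignment(M, maximize=True)
        for r, c in zip(rows, cols):
            if M[r, c] > 0:
                mapping[int(p_ids[r])] = int(t_ids[c])
    relabeled = np.zeros_like(pred)
    nxt = int(truth.max()) + 1
    for p in p_ids:
        p = int(p)
        if p in mapping:
            relabeled[pred == p] = mapping[p]
        else:
            relabeled[pred == p] = nxt
            nxt += 1
    unmatched_pred = [int(p) for p in p_ids if int(p) not in mapping]
    unmatched_truth = [int(t) for t in t_ids if t not in mapping.values()]
    return MatchedSegmentation(relabeled, mapping, unmatched_pred,
                               unmatched_truth, M, p_ids, t_ids,
                               p_sizes, t_sizes)


def dice(pred_region: np.ndarray, truth_region: np.ndarray) -> float:
    """Dice ratio 2|A n B| / (|A| + |B|) of two binary regions."""
    a = np.asarray(pred_region).astype(bool)
    b = np.asarray(truth_region).astype(bool)
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        raise ValueError("both regions empty")
    return 2.0 * int((a & b).sum()) / (na + nb)


def hausdorff(pred_region: np.ndarray, truth_region: np.ndarray,
              spacing: float, surface_only: bool = False) -> float:
    """Bidirectional Hausdorff distance (um) between two voxel regions.

    max of the two directed sup-inf distances over the full voxel sets
    (``surface_only`` restricts to boundary voxels; the attained sup-inf
    pairs are the same, it is just faster on large regions).
    """
    a = np.asarray(pred_region).astype(bool)
    b = np.asarray(truth_region).astype(bool)
    if not a.any() or not b.any():
        raise ValueError("empty region")
    if surface_only:
        a = a & ~ndimage.binary_erosion(a)
        b = b & ~ndimage.binary_erosion(b)

    def directed(src, dst):
        # distance field to dst evaluated at src voxels (exact on the grid)
        d = ndimage.distance_transform_edt(~dst)
        return d[src].max()

    return float(max(directed(a, b), directed(b, a)) * spacing)


def _iou_of_matches(matched: MatchedSegmentation):
    ious = {}
    for p, t in matched.mapping.items():
        r = np.where(matched.pred_ids == p)[0][0]
        c = np.where(matched.truth_ids == t)[0][0]
        inter = matched.overlap[r, c]
        union = matched.pred_sizes[r] + matched.truth_sizes[c] - inter
        ious[(p, t)] = inter / union
    return ious


def f1_curve(matched: MatchedSegmentation,
             thresholds=None) -> pd.DataFrame:
    """F1 = 2TP/(2TP+FN+FP) at IoU thresholds 0.50..0.95 (step 0.05)."""
    if thresholds is None:
        thresholds = np.arange(0.50, 0.951, 0.05)
    ious = _iou_of_matches(matched)
    n_truth = len(matched.truth_ids)
    n_pred = len(matched.pred_ids)
    rows = []
    for t in thresholds:
        tp = sum(1 for v in ious.values() if v >= t)
        fn = n_truth - tp
        fp = n_pred - tp
        f1 = 2 * tp / (2 * tp + fn + fp) if (2 * tp + fn + fp) else 1.0
        rows.append({"threshold": float(t), "TP": tp, "FN": fn, "FP": fp,
                     "F1": f1})
    return pd.DataFrame(rows)


def object_scores(matched: MatchedSegmentation, t0: float = 0.7,
                  coverage: float = 0.2) -> dict:
    """Object-level split/merge counts and precision/recall at IoU ``t0``.

    A truth cell is split if >= 2 predicted labels each cover at least
    ``coverage`` of it; a predicted label merges if it covers at least
    ``coverage`` of >= 2 truth cells.
    """
    ious = _iou_of_matches(matched)
    tp = sum(1 for v in ious.values() if v >= t0)
    fn = len(matched.truth_ids) - tp
    fp = len(matched.pred_ids) - tp
    precision = tp / (tp + fp) if tp + fp else 1.0
    recall = tp / (tp + fn) if tp + fn else 1.0
    M = matched.overlap
    frac_of_truth = M / np.maximum(matched.truth_sizes[None, :], 1)
    frac_of_truth_ = frac_of_truth >= coverage
    split = int(((frac_of_truth_.sum(axis=0)) >= 2).sum())
    merge = int(((frac_of_truth_.sum(axis=1)) >= 2).sum())
    return {"split": split, "merge": merge, "precision": precision,
            "recall": recall, "TP": tp, "FN": fn, "FP": fp}


def score_segmentation(pred: np.ndarray, truth: np.ndarray,
                       spacing: float) -> pd.DataFrame:
    """Per-cell dice and Hausdorff after label unification."""
    matched = unify_labels(pred, truth)
    rows = []
    for p, t in sorted(matched.mapping.items(), key=lambda kv: kv[1]):
        pr = matched.relabeled == t
        tr = truth == t
        rows.append({"truth_label": t, "dice": dice(pr, tr),
                     "hausdorff_um": hausdorff(pr, tr, spacing)})
    return pd.DataFrame(rows)
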