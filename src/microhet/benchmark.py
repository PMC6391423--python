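"""Ground-truth benchmarking: IoU matching of segmentations against truth."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np

__all__ = ["MatchResult", "match_labels"]


@dataclass
class MatchResult:
    n_truth: int
    n_pred: int
    matches: List[Tuple[int, int, float]]  # (truth label, pred label, IoU)
    recovery: float        # matched truth fraction
    false_positive_rate: float  # unmatched predictions / predictions


def match_labels(truth: np.ndarray, pred: np.ndarray,
                 iou_threshold: float = 0.5) -> MatchResult:
    """Greedy one-to-one matching of predicted to ground-truth labels by IoU.

    Candidate pairs are all (truth, pred) label pairs that share pixels;
    pairs are accepted in descending IoU order, each label used once, and
    only pairs with IoU ≥ ``iou_threshold`` count as matches.
    """
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    if truth.shape != pred.shape:
        raise ValueError("label images differ in shape")
    t_ids, t_areas = np.unique(truth[truth > 0], return_counts=True)
    p_ids, p_areas = np.unique(pred[pred > 0], return_counts=True)
    t_area = dict(zip(t_ids.tolist(), t_areas.tolist()))
    p_area = dict(zip(p_ids.tolist(), p_areas.tolist()))
    both = (truth > 0) & (pred > 0)
    pairs, counts = np.unique(
        np.stack([truth[both], pred[both]]), axis=1, return_counts=True)
    ious = []
    for (ti, pi), inter in zip(pairs.T, counts):
        union = t_area[int(ti)] + p_area[int(pi)] - int(inter)
        ious.append((int(ti), int(pi), inter / union))
    ious.sort(key=lambda x: -x[2])
    used_t, used_p = set(), set()
    matches = []
    for ti, pi, iou in ious:
        if iou < iou_threshold:
            break
        if ti in used_t or pi in used_p:
            continue
        used_t.add(ti)
        used_p.add(pi)
        matches.append((ti, pi, float(iou)))
    n_t, n_p = len(t_ids), len(p_ids)
    recovery = len(matches) / n_t if n_t else 1.0
    fpr = (n_p - len(matches)) / n_p if n_p else 0.0
    return MatchResult(n_t, n_p, matches, recovery, fpr)
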