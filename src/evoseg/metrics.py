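"""Segmentation evaluation against ground truth.

Metrics for comparing a predicted label map P (p segments) with a
ground-truth label map Gamma (t segments):

matched IoU
    the label correspondence between P and Gamma is found by maximising
    total intersection-over-union over one-to-one assignments (optimal
    linear assignment, equivalent to searching all label permutations).
    Mode ``all`` averages the matched IoUs over max(p, t) slots so every
    unmatched segment contributes zero; mode ``matched_only`` averages
    over matched pairs only.
homogeneity H
    voxel precision: the fraction of predicted-segment voxels that lie
    inside their matched ground-truth subunit.  Voxels of unmatched
    predicted segments count as false positives.
proportion P
    mean over ground-truth subunits of the number of distinct predicted
    segments overlapping each; 1.0 is ideal.
consistency C
    the per-subunit overlap count s_i for one designated subunit:
    the largest-volume subunit by default, or the subunit with maximal
    s_i (``variant="max_si"``).

A perfect segmentation scores IoU = 1, H = 1, P = 1, C = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .volume_io import LabelMap

__all__ = [
    "MetricsReport",
    "iou_matrix",
    "matched_iou",
    "homogeneity",
    "proportion",
    "consistency",
    "volume_ratio_filter",
    "evaluate",
]


def _contingency(pred: LabelMap, truth: LabelMap):
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth shapes differ")
    p_lab = pred.labels.ravel()
    t_lab = truth.labels.ravel()
    p_ids = np.unique(p_lab)
    p_ids = p_ids[p_ids > 0]
    t_ids = np.unique(t_lab)
    t_ids = t_ids[t_ids > 0]
    p_index = np.searchsorted(p_ids, p_lab)
    t_index = np.searchsorted(t_ids, t_lab)
    inter = np.zeros((p_ids.size, t_ids.size), dtype=np.int64)
    both = (p_lab > 0) & (t_lab > 0)
    np.add.at(inter, (p_index[both], t_index[both]), 1)
    p_sizes = np.bincount(p_index[p_lab > 0], minlength=p_ids.size)
    t_sizes = np.bincount(t_index[t_lab > 0], minlength=t_ids.size)
    return p_ids, t_ids, inter, p_sizes, t_sizes


def iou_matrix(pred: LabelMap, truth: LabelMap):
    """Pairwise IoU between every predicted and every truth segment."""
    p_ids, t_ids, inter, p_sizes, t_sizes = _contingency(pred, truth)
    union = p_sizes[:, None] + t_sizes[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        iou = np.where(union > 0, inter / union, 0.0)
    return p_ids, t_ids, iou


def matched_iou(pred: LabelMap, truth: LabelMap, mode: str = "all"):
    """Permutation-matched IoU and the optimal label matching.

    Returns ``(value, matching)`` where matching is a list of
    ``(pred_label, truth_label)`` pairs with positive IoU under the
    assignment that maximises total IoU.
    """
    if mode not in ("all", "matched_only"):
        raise ValueError(f"unknown mode {mode!r}")
    p_ids, t_ids, iou = iou_matrix(pred, truth)
    if p_ids.size == 0:
        return 0.0, []
    rows, cols = linear_sum_assignment(-iou)
    matching = [(int(p_ids[r]), int(t_ids[c]))
                for r, c in zip(rows, cols) if iou[r, c] > 0]
    matched_sum = float(sum(iou[r, c] for r, c in zip(rows, cols)))
    if mode == "all":
        value = matched_sum / max(p_ids.size, t_ids.size)
    else:
        value = matched_sum / len(matching) if matching else 0.0
    return value, matching


def homogeneity(pred: LabelMap, truth: LabelMap, matching=None) -> float:
    """Voxel precision of predicted segments w.r.t. their matched subunit."""
    if matching is None:
        _, matching = matched_iou(pred, truth)
    p_lab = pred.labels
    t_lab = truth.labels
    total_pred = int(np.sum(p_lab > 0))
    if total_pred == 0:
        raise ValueError("empty prediction foreground")
    tp = 0
    for p, t in matching:
        tp += int(np.sum((p_lab == p) & (t_lab == t)))
    return tp / total_pred


def _overlap_counts(pred: LabelMap, truth: LabelMap):
    """s_i: number of distinct predicted segments overlapping each subunit."""
    p_ids, t_ids, inter, _, t_sizes = _contingency(pred, truth)
    if t_ids.size == 0:
        raise ValueError("empty ground truth")
    s = (inter > 0).sum(axis=0)
    return t_ids, s, t_sizes


def proportion(pred: LabelMap, truth: LabelMap) -> float:
    """Mean number of predicted segments per ground-truth subunit."""
    _, s, _ = _overlap_counts(pred, truth)
    return float(np.mean(s))


def consistency(pred: LabelMap, truth: LabelMap, variant: str = "largest_volume") -> int:
    """Overlap count of one designated subunit.

    ``largest_volume`` (default) reports s_i of the biggest subunit,
    ``max_si`` reports the maximum s_i over subunits.
    """
    t_ids, s, t_sizes = _overlap_counts(pred, truth)
    if variant == "largest_volume":
        return int(s[int(np.argmax(t_sizes))])
    if variant == "max_si":
        return int(s.max())
    raise ValueError(f"unknown variant {variant!r}")


def volume_ratio_filter(map_volume: int, model_volume: int,
                        lo: float = 0.8, hi: float = 1.2) -> bool:
    """Accept a map/model pair when their volume ratio is within [lo, hi]."""
    if map_volume <= 0 or model_volume <= 0:
        raise ValueError("volumes must be positive")
    ratio = map_volume / model_volume
    return lo <= ratio <= hi


@dataclass
class MetricsReport:
    """Full evaluation of one (prediction, ground truth) pair."""

    matched_iou_all: float
    matched_iou_matched_only: float
    homogeneity: float
    proportion: float
    consistency: int
    consistency_max_si: int
    n_predicted: int
    n_truth: int
    matching: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "matched_iou_all": self.matched_iou_all,
            "matched_iou_matched_only": self.matched_iou_matched_only,
            "homogeneity": self.homogeneity,
            "proportion": self.proportion,
            "consistency": self.consistency,
            "consistency_max_si": self.consistency_max_si,
            "n_predicted": self.n_predicted,
            "n_truth": self.n_truth,
            "matching": [list(m) for m in self.matching],
        }


def evaluate(pred: LabelMap, truth: LabelMap) -> MetricsReport:
    """Compute every metric for a (prediction, truth) pair."""
    iou_all, matching = matched_iou(pred, truth, mode="all")
    iou_matched, _ = matched_iou(pred, truth, mode="matched_only")
    return MetricsReport(
        matched_iou_all=iou_all,
        matched_iou_matched_only=iou_matched,
        homogeneity=homogeneity(pred, truth, matching),
        proportion=proportion(pred, truth),
        consistency=consistency(pred, truth, "largest_volume"),
        consistency_max_si=consistency(pred, truth, "max_si"),
        n_predicted=pred.n_segments(),
        n_truth=truth.n_segments(),
        matching=matching,
    )
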