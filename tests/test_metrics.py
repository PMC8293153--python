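import itertools

import numpy as np
import pytest

from evoseg.metrics import (consistency, evaluate, homogeneity, iou_matrix,
                            matched_iou, proportion, volume_ratio_filter)
from evoseg.volume_io import LabelMap


def _lm(flat, shape=(1, 2, 4)):
    return LabelMap(labels=np.array(flat, dtype=np.int32).reshape(shape))


@pytest.fixture()
def toy():
    """8-voxel worked example: two 4-voxel subunits, predictions off by one.

    truth: g1 = v1..v4, g2 = v5..v8
    pred:  r1 = v1,v2,v3,v5  r2 = v4,v6,v7,v8
    Pairwise IoU of each matched pair is 3/5.
    """
    truth = _lm([1, 1, 1, 1, 2, 2, 2, 2])
    pred = _lm([1, 1, 1, 2, 1, 2, 2, 2])
    return pred, truth


def _all_assignments(n_pred, n_truth):
    """Every maximal one-to-one matching as (pred_idx, truth_idx) pairs."""
    if n_pred <= n_truth:
        for cols in itertools.permutations(range(n_truth), n_pred):
            yield list(enumerate(cols))
    else:
        for rows in itertools.permutations(range(n_pred), n_truth):
            yield [(r, c) for c, r in enumerate(rows)]


def exhaustive_matched_iou(pred, truth, mode):
    """Oracle: search all one-to-one label assignments explicitly."""
    p_ids, t_ids, iou = iou_matrix(pred, truth)
    best_total, best_pairs = -1.0, 0
    for pairs in _all_assignments(p_ids.size, t_ids.size):
        total = sum(iou[r, c] for r, c in pairs)
        if total > best_total + 1e-12:
            best_total = total
            best_pairs = sum(iou[r, c] > 0 for r, c in pairs)
    if mode == "all":
        return best_total / max(p_ids.size, t_ids.size)
    return best_total / best_pairs if best_pairs else 0.0


def test_perfect_segmentation_identities(small_pair):
    truth = small_pair.truth
    report = evaluate(truth, truth)
    assert report.matched_iou_all == pytest.approx(1.0)
    assert report.matched_iou_matched_only == pytest.approx(1.0)
    assert report.homogeneity == pytest.approx(1.0)
    assert report.proportion == pytest.approx(1.0)
    assert report.consistency == 1
    assert report.consistency_max_si == 1


def test_label_swap_is_invisible(toy):
    _, truth = toy
    swapped = np.where(truth.labels == 1, 2, np.where(truth.labels == 2, 1, 0))
    value, _ = matched_iou(LabelMap(labels=swapped), truth, mode="all")
    assert value == pytest.approx(1.0)


def test_toy_worked_example(toy):
    pred, truth = toy
    value, matching = matched_iou(pred, truth, mode="matched_only")
    assert value == pytest.approx(0.6)
    assert len(matching) == 2
    assert homogeneity(pred, truth, matching) == pytest.approx(0.75)
    assert proportion(pred, truth) == pytest.approx(2.0)
    assert consistency(pred, truth, "largest_volume") == 2
    assert consistency(pred, truth, "max_si") == 2


def test_each_subunit_split_in_three():
    truth = _lm([1, 1, 1, 2, 2, 2], shape=(1, 1, 6))
    pred = _lm([1, 2, 3, 4, 5, 6], shape=(1, 1, 6))
    assert proportion(pred, truth) == pytest.approx(3.0)


def test_consistency_variants_can_disagree():
    # big subunit covered by one prediction; small one shattered into 4
    truth = _lm([1] * 10 + [2] * 4, shape=(1, 1, 14))
    pred = _lm([1] * 10 + [2, 3, 4, 5], shape=(1, 1, 14))
    assert consistency(pred, truth, "largest_volume") == 1
    assert consistency(pred, truth, "max_si") == 4


def test_single_prediction_spanning_two_subunits():
    truth = _lm([1, 1, 1, 1, 2, 2, 2, 2])
    pred = _lm([1] * 8)
    assert homogeneity(pred, truth) == pytest.approx(0.5)


def test_assignment_matches_exhaustive_oracle():
    rng = np.random.default_rng(7)
    for _ in range(30):
        p = int(rng.integers(1, 6))
        t = int(rng.integers(1, 6))
        pred = _lm(rng.integers(0, p + 1, size=24), shape=(2, 3, 4))
        truth = _lm(rng.integers(0, t + 1, size=24), shape=(2, 3, 4))
        if not truth.labels.any() or not pred.labels.any():
            continue
        for mode in ("all", "matched_only"):
            got, _ = matched_iou(pred, truth, mode=mode)
            assert got == pytest.approx(exhaustive_matched_iou(pred, truth, mode))


def test_matched_only_at_least_all():
    rng = np.random.default_rng(8)
    for _ in range(20):
        pred = _lm(rng.integers(0, 5, size=27), shape=(3, 3, 3))
        truth = _lm(rng.integers(0, 4, size=27), shape=(3, 3, 3))
        if not truth.labels.any() or not pred.labels.any():
            continue
        a, _ = matched_iou(pred, truth, mode="all")
        m, _ = matched_iou(pred, truth, mode="matched_only")
        assert m >= a - 1e-12


def test_relabeling_invariance_mode_all():
    rng = np.random.default_rng(9)
    pred = _lm(rng.integers(0, 4, size=27), shape=(3, 3, 3))
    truth = _lm(rng.integers(0, 3, size=27), shape=(3, 3, 3))
    perm = {0: 0, 1: 3, 2: 1, 3: 2}
    relabeled = _lm([perm[v] for v in pred.labels.ravel()], shape=(3, 3, 3))
    a, _ = matched_iou(pred, truth, mode="all")
    b, _ = matched_iou(relabeled, truth, mode="all")
    assert a == pytest.approx(b)


def test_shape_mismatch_and_empty_prediction():
    with pytest.raises(ValueError):
        matched_iou(_lm([1] * 8), _lm([1] * 6, shape=(1, 1, 6)))
    value, matching = matched_iou(_lm([0] * 8), _lm([1] * 8))
    assert value == 0.0 and matching == []


def test_volume_ratio_filter_bounds():
    assert volume_ratio_filter(100, 100)
    assert not volume_ratio_filter(50, 100)
    assert volume_ratio_filter(80, 100)       # inclusive boundary
    assert volume_ratio_filter(120, 100)
    assert not volume_ratio_filter(121, 100)
    with pytest.raises(ValueError):
        volume_ratio_filter(0, 100)
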