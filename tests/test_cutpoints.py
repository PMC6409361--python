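"""Cutpoint criteria and metrics against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from absig import (
    CutpointCriterion,
    choose_best_criterion,
    confusion_metrics,
    r_squared,
    roc_auc,
    select_cutoff,
)
from absig.cutpoints import CRITERION_ORDER


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------


def _auc_pair_oracle(scores, labels):
    """O(n^2) pair-counting AUC with half-credit for ties."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def test_auc_matches_pair_oracle_random():
    rng = np.random.default_rng(0)
    for trial in range(20):
        n = int(rng.integers(5, 60))
        labels = rng.integers(0, 2, n)
        if labels.sum() in (0, n):
            labels[0], labels[1] = 0, 1
        # coarse grid forces plenty of ties
        scores = rng.integers(0, 6, n).astype(float)
        assert roc_auc(scores, labels) == pytest.approx(
            _auc_pair_oracle(scores, labels), abs=1e-12
        )


def test_auc_extremes():
    labels = np.array([0, 0, 1, 1])
    assert roc_auc(np.array([1.0, 2.0, 3.0, 4.0]), labels) == 1.0
    assert roc_auc(np.array([4.0, 3.0, 2.0, 1.0]), labels) == 0.0
    assert roc_auc(np.array([1.0, 1.0, 1.0, 1.0]), labels) == 0.5


def test_auc_requires_both_classes():
    with pytest.raises(ValueError):
        roc_auc(np.array([1.0, 2.0]), np.array([1, 1]))


@settings(max_examples=50, deadline=None)
@given(st.lists(st.integers(0, 9), min_size=4, max_size=40))
def test_auc_pair_oracle_property(raw):
    scores = np.asarray(raw, dtype=float)
    labels = (np.arange(len(scores)) % 2).astype(int)
    assert roc_auc(scores, labels) == pytest.approx(
        _auc_pair_oracle(scores, labels), abs=1e-12
    )


# ---------------------------------------------------------------------------
# confusion metrics / r_squared
# ---------------------------------------------------------------------------


def test_confusion_metrics_known_table():
    pred = np.array([1, 1, 0, 0, 1, 0])
    true = np.array([1, 0, 0, 1, 1, 0])
    acc, sens, spec = confusion_metrics(pred, true)
    assert acc == pytest.approx(4 / 6)
    assert sens == pytest.approx(2 / 3)
    assert spec == pytest.approx(2 / 3)


def test_confusion_metrics_absent_class_is_nan():
    acc, sens, spec = confusion_metrics(np.array([1, 1]), np.array([1, 1]))
    assert acc == 1.0 and sens == 1.0 and np.isnan(spec)


def test_r_squared_matches_definition():
    rng = np.random.default_rng(1)
    actual = rng.normal(size=30)
    pred = actual + rng.normal(scale=0.3, size=30)
    expected = 1 - np.sum((actual - pred) ** 2) / np.sum((actual - actual.mean()) ** 2)
    assert r_squared(pred, actual) == pytest.approx(expected, abs=1e-12)


def test_r_squared_constant_actual_raises():
    with pytest.raises(ValueError):
        r_squared(np.array([1.0, 2.0]), np.array([3.0, 3.0]))


# ---------------------------------------------------------------------------
# cutoff selection against an exhaustive oracle
# ---------------------------------------------------------------------------


def _objective_oracle(criterion, levels, status, threshold):
    """Direct evaluation of each published criterion at one threshold.

    Predicted abnormal iff level < threshold.
    """
    pred = (levels < threshold).astype(int)
    tp = int(np.sum((pred == 1) & (status == 1)))
    fp = int(np.sum((pred == 1) & (status == 0)))
    fn = int(np.sum((pred == 0) & (status == 1)))
    tn = int(np.sum((pred == 0) & (status == 0)))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    n = tp + fp + fn + tn
    if criterion == CutpointCriterion.YOUDEN:
        return sens + spec - 1, True
    if criterion == CutpointCriterion.ROC01:
        return (1 - sens) ** 2 + (1 - spec) ** 2, False
    if criterion == CutpointCriterion.MAX_SP_SE:
        return min(sens, spec), True
    if criterion == CutpointCriterion.MAX_PROD_SP_SE:
        return sens * spec, True
    if criterion == CutpointCriterion.MAX_EFFICIENCY:
        return (tp + tn) / n, True
    po = (tp + tn) / n
    pe = ((tp + fp) * (tp + fn) + (tn + fn) * (tn + fp)) / n**2
    return (po - pe) / (1 - pe) if pe != 1 else 0.0, True


def _brute_force_best(criterion, levels, status):
    uniq = np.unique(levels)
    mids = (uniq[:-1] + uniq[1:]) / 2
    cands = np.concatenate(([uniq[0] - 1], mids, [uniq[-1] + 1]))
    vals = np.array([_objective_oracle(criterion, levels, status, t)[0] for t in cands])
    maximize = _objective_oracle(criterion, levels, status, cands[0])[1]
    best = vals.max() if maximize else vals.min()
    return cands[np.isclose(vals, best, rtol=0, atol=1e-12)]


def test_select_cutoff_matches_exhaustive_oracle():
    rng = np.random.default_rng(2)
    for trial in range(15):
        n = int(rng.integers(10, 80))
        levels = np.round(rng.normal(190, 30, n), 0)
        status = (levels + rng.normal(0, 25, n) < 192).astype(int)
        if status.sum() in (0, n):
            continue
        for criterion in CRITERION_ORDER:
            res = select_cutoff(levels, status, criterion)
            optima = _brute_force_best(criterion, levels, status)
            assert np.any(np.isclose(res.threshold, optima, atol=1e-9)), (
                f"trial {trial}, {criterion}: got {res.threshold}, oracle {optima}"
            )
            # tie-break: closest optimal threshold to the median level
            med = np.median(levels)
            assert abs(res.threshold - med) <= np.min(np.abs(optima - med)) + 1e-9


def test_select_cutoff_orientation():
    # low level = abnormal: a clean separation puts the threshold between
    levels = np.array([150.0, 160.0, 230.0, 240.0])
    status = np.array([1, 1, 0, 0])
    res = select_cutoff(levels, status, CutpointCriterion.YOUDEN)
    assert 160 < res.threshold < 230
    assert list(res.apply(levels)) == [1, 1, 0, 0]


def test_select_cutoff_degenerate():
    res = select_cutoff(np.full(6, 5.0), np.array([0, 1, 0, 1, 0, 1]),
                        CutpointCriterion.YOUDEN)
    assert res.degenerate
    assert res.threshold == 5.0


def test_select_cutoff_requires_both_classes():
    with pytest.raises(ValueError):
        select_cutoff(np.array([1.0, 2.0]), np.array([1, 1]), CutpointCriterion.YOUDEN)


def test_cutoff_classification_affine_invariant():
    rng = np.random.default_rng(3)
    levels = rng.normal(190, 25, 50)
    status = (levels < 192).astype(int)
    status[:5] = 1 - status[:5]
    for criterion in CRITERION_ORDER:
        base = select_cutoff(levels, status, criterion)
        scaled = select_cutoff(levels * 2 + 10, status, criterion)
        assert np.array_equal(base.apply(levels), scaled.apply(levels * 2 + 10))


# ---------------------------------------------------------------------------
# criterion choice
# ---------------------------------------------------------------------------


def test_choose_best_criterion_arithmetic():
    accs = {
        CutpointCriterion.YOUDEN: [0.7, 0.8],
        CutpointCriterion.MAX_EFFICIENCY: [0.9, 0.8],
        CutpointCriterion.MAX_KAPPA: [0.6, 0.6],
    }
    assert choose_best_criterion(accs) == CutpointCriterion.MAX_EFFICIENCY


def test_choose_best_criterion_tie_uses_fixed_order():
    accs = {c: [0.8] for c in CRITERION_ORDER}
    assert choose_best_criterion(accs) == CRITERION_ORDER[0]


def test_choose_best_criterion_validates():
    with pytest.raises(ValueError):
        choose_best_criterion({})
    with pytest.raises(ValueError):
        choose_best_criterion({CutpointCriterion.YOUDEN: []})
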