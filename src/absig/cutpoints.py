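"""Classification metrics and data-driven cutoffs on predicted CSF levels.

A regression model of CSF Aβ1-42 emits continuous predictions that must be
dichotomised: a subject is called *abnormal* when the predicted level falls
strictly below a threshold.  Six standard ROC-based criteria for choosing
that threshold are implemented; which criterion to use is itself selected
by inner cross-validation accuracy (:func:`choose_best_criterion`).

All metrics treat abnormal as the positive class, and AUC is the
tie-corrected Mann-Whitney concordance probability.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata


class CutpointCriterion(str, enum.Enum):
    """The closed set of six cutoff-selection criteria.

    The fixed declaration order below is also the deterministic tie-break
    order when criteria reach equal inner-CV accuracy.
    """

    YOUDEN = "Youden"
    ROC01 = "ROC01"
    MAX_SP_SE = "MaxSpSe"
    MAX_PROD_SP_SE = "MaxProdSpSe"
    MAX_EFFICIENCY = "MaxEfficiency"
    MAX_KAPPA = "MaxKappa"


CRITERION_ORDER = tuple(CutpointCriterion)


@dataclass(frozen=True)
class CutpointResult:
    """A selected threshold; predicted level < threshold means abnormal."""

    criterion: CutpointCriterion
    threshold: float
    degenerate: bool = False

    def apply(self, predicted_levels) -> np.ndarray:
        """Dichotomise predicted levels (1 = abnormal)."""
        return (np.asarray(predicted_levels, dtype=float) < self.threshold).astype(int)


@dataclass(frozen=True)
class MetricSet:
    auc: float
    accuracy: float
    sensitivity: float
    specificity: float
    r_squared: float = float("nan")

    def as_dict(self) -> dict:
        return {
            "auc": self.auc,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "r_squared": self.r_squared,
        }


def _check_binary(labels) -> np.ndarray:
    y = np.asarray(labels).astype(int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary (0 = normal, 1 = abnormal)")
    return y


def roc_auc(scores, labels) -> float:
    """Tie-corrected Mann-Whitney AUC: (wins + ties/2) / (n_pos * n_neg).

    ``scores`` are oriented so that higher means more abnormal; ``labels``
    use 1 for abnormal.  Both classes must be present.
    """
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires both classes")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def confusion_metrics(predicted_status, true_status) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) with abnormal as positive class.

    Sensitivity (specificity) is NaN when no true-abnormal (true-normal)
    subjects are present, rather than silently zero.
    """
    yp = _check_binary(predicted_status)
    yt = _check_binary(true_status)
    if yp.size == 0 or yp.size != yt.size:
        raise ValueError("inputs must be non-empty and aligned")
    tp = int(np.sum((yp == 1) & (yt == 1)))
    tn = int(np.sum((yp == 0) & (yt == 0)))
    n_pos = int(np.sum(yt == 1))
    n_neg = int(np.sum(yt == 0))
    accuracy = (tp + tn) / yt.size
    sensitivity = tp / n_pos if n_pos else float("nan")
    specificity = tn / n_neg if n_neg else float("nan")
    return accuracy, sensitivity, specificity


def r_squared(predicted, actual) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot; may be negative out of sample."""
    yhat = np.asarray(predicted, dtype=float)
    y = np.asarray(actual, dtype=float)
    if y.size < 2:
        raise ValueError("r_squared requires n >= 2")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("actual values are constant; R^2 undefined")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot


def _threshold_scan(levels: np.ndarray, status: np.ndarray):
    """Candidate thresholds and the confusion counts of 'level < t => abnormal'.

    Candidates are the midpoints of adjacent distinct predicted levels plus
    one finite sentinel below the minimum (nobody abnormal) and one above
    the maximum (everybody abnormal).
    """
    uniq = np.unique(levels)
    span = uniq[-1] - uniq[0]
    pad = span / uniq.size if span > 0 else 1.0
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    candidates = np.concatenate(([uniq[0] - pad], mids, [uniq[-1] + pad]))

    order = np.argsort(levels, kind="stable")
    status_sorted = status[order]
    levels_sorted = levels[order]
    cum_pos = np.concatenate(([0], np.cumsum(status_sorted)))
    n = levels.size
    n_pos = int(status.sum())
    n_neg = n - n_pos
    # number of subjects with level < t, per candidate
    k = np.searchsorted(levels_sorted, candidates, side="left")
    tp = cum_pos[k].astype(float)  # abnormal and predicted abnormal
    fp = k - tp
    fn = n_pos - tp
    tn = n_neg - fp
    return candidates, tp, fp, fn, tn


def _criterion_objective(
    criterion: CutpointCriterion, tp, fp, fn, tn
) -> tuple[np.ndarray, bool]:
    """Objective values per candidate and whether larger is better."""
    n = tp + fp + fn + tn
    n_pos = tp + fn
    n_neg = tn + fp
    sens = tp / n_pos
    spec = tn / n_neg
    if criterion is CutpointCriterion.YOUDEN:
        return sens + spec - 1.0, True
    if criterion is CutpointCriterion.ROC01:
        return (1.0 - sens) ** 2 + (1.0 - spec) ** 2, False
    if criterion is CutpointCriterion.MAX_SP_SE:
        return np.minimum(sens, spec), True
    if criterion is CutpointCriterion.MAX_PROD_SP_SE:
        return sens * spec, True
    if criterion is CutpointCriterion.MAX_EFFICIENCY:
        return (tp + tn) / n, True
    if criterion is CutpointCriterion.MAX_KAPPA:
        po = (tp + tn) / n
        pe = ((tp + fp) * n_pos + (tn + fn) * n_neg) / n**2
        with np.errstate(invalid="ignore", divide="ignore"):
            kappa = np.where(pe < 1.0, (po - pe) / (1.0 - pe), 0.0)
        return kappa, True
    raise ValueError(f"unknown criterion {criterion!r}")


def select_cutoff(
    predicted_levels, true_status, criterion: CutpointCriterion
) -> CutpointResult:
    """Optimal threshold on predicted CSF levels under one criterion.

    Every candidate threshold (midpoints of adjacent distinct predicted
    levels plus sentinels beyond the range) is scored and the optimiser
    returned; exact ties are broken toward the threshold closest to the
    median predicted level.  With all predictions identical the problem is
    degenerate and the common value itself is returned, flagged.
    """
    criterion = CutpointCriterion(criterion)
    levels = np.asarray(predicted_levels, dtype=float)
    status = _check_binary(true_status)
    if status.sum() == 0 or status.sum() == status.size:
        raise ValueError("select_cutoff requires both classes")
    if np.unique(levels).size == 1:
        return CutpointResult(criterion, float(levels[0]), degenerate=True)

    candidates, tp, fp, fn, tn = _threshold_scan(levels, status)
    obj, maximize = _criterion_objective(criterion, tp, fp, fn, tn)
    best = obj.max() if maximize else obj.min()
    optimal = np.flatnonzero(np.isclose(obj, best, rtol=0, atol=1e-12))
    med = float(np.median(levels))
    pick = optimal[np.argmin(np.abs(candidates[optimal] - med))]
    return CutpointResult(criterion, float(candidates[pick]))


def choose_best_criterion(inner_fold_accuracies) -> CutpointCriterion:
    """Criterion with the highest mean accuracy over inner test folds.

    ``inner_fold_accuracies`` maps each criterion to its per-fold accuracy
    sequence; exact ties fall back to the fixed criterion order.
    """
    if not inner_fold_accuracies:
        raise ValueError("no inner-fold results supplied")
    means = {}
    for crit, accs in inner_fold_accuracies.items():
        accs = np.asarray(list(accs), dtype=float)
        if accs.size == 0:
            raise ValueError(f"criterion {crit!r} has no inner-fold accuracies")
        means[CutpointCriterion(crit)] = float(np.mean(accs))
    best = max(means.values())
    for crit in CRITERION_ORDER:
        if crit in means and np.isclose(means[crit], best, rtol=0, atol=1e-12):
            return crit
    raise AssertionError("unreachable: no criterion attained the maximum")
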