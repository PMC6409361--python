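"""Nested cross-validation of the CSF Aβ1-42 prediction models.

Performance is estimated with repeated k-fold CV in the outer loop
(10 repetitions × 10 folds by default) while the only free modelling
choice — which cutoff criterion dichotomises the regression predictions —
is made inside an inner repeated CV (3 × 3) run on each outer training
set.  Feature sets are coded by the modalities they include: B (age and
APOEε4 carrier status, always present), P (protein analytes) and
M (metabolite analytes).

Everything selected for an outer fold (forest, criterion, threshold) is
derived from that fold's training subjects only; thresholds come from
out-of-bag predictions rather than resubstitution, whose near-perfect fit
would push them toward degenerate values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from sklearn.model_selection import KFold, StratifiedKFold

from ._seeds import derive_seed
from .cohort import CohortTable
from .cutpoints import (
    CRITERION_ORDER,
    CutpointCriterion,
    CutpointResult,
    MetricSet,
    choose_best_criterion,
    confusion_metrics,
    r_squared,
    roc_auc,
    select_cutoff,
)
from .forest import FittedForest, ForestSpec, abnormality_score, fit_forest, predict_forest

FEATURE_SET_CODES = ("B", "BM", "BP", "BPM")
BASELINE_COLUMNS = ["age", "apoe4_carrier"]


def feature_columns(cohort: CohortTable, code) -> list[str]:
    """Columns for a feature-set code; the baseline block B is always included.

    An explicit list of column names passes through unchanged, which is how
    reduced models (e.g. a five-marker panel) are evaluated.
    """
    if isinstance(code, (list, tuple)):
        unknown = [c for c in code if c not in cohort.data.columns]
        if unknown:
            raise ValueError(f"unknown feature columns: {unknown}")
        return list(code)
    code = code.upper()
    if code not in FEATURE_SET_CODES:
        raise ValueError(f"unknown feature set {code!r}; expected one of {FEATURE_SET_CODES}")
    cols = list(BASELINE_COLUMNS)
    if "P" in code:
        cols += list(cohort.protein_cols)
    if "M" in code:
        cols += list(cohort.metabolite_cols)
    return cols


@dataclass
class FoldPlan:
    """Repeated k-fold assignments for the outer loop plus the inner-loop shape.

    ``assignments[r]`` holds, per repetition ``r``, the outer fold label of
    every subject.  Inner folds are re-drawn per outer training set from
    seeds derived from ``seed``, so the plan object stays small.
    """

    subject_ids: np.ndarray
    k: int
    reps: int
    assignments: list[np.ndarray]
    seed: int
    stratified: bool = True
    inner_k: int = 3
    inner_reps: int = 3

    def splits(self) -> Iterator[tuple[int, int, np.ndarray, np.ndarray]]:
        """Yield (repetition, fold, train_positions, test_positions)."""
        for r, labels in enumerate(self.assignments):
            for f in range(self.k):
                test = np.flatnonzero(labels == f)
                train = np.flatnonzero(labels != f)
                yield r, f, train, test


def make_fold_plan(
    subject_ids: Sequence,
    true_status: Sequence | None,
    k: int,
    reps: int,
    seed: int,
    stratified: bool = True,
    inner_k: int = 3,
    inner_reps: int = 3,
) -> FoldPlan:
    """Draw ``reps`` independent partitions of the cohort into ``k`` folds.

    With ``stratified`` (the default) each fold carries the cohort's
    abnormal/normal mix to within one subject, which stabilises the fold
    metrics at modest cohort sizes.
    """
    ids = np.asarray(subject_ids)
    n = ids.size
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"cannot split {n} subjects into {k} folds")
    y = None
    if stratified:
        if true_status is None:
            raise ValueError("stratified fold plans need the true status")
        y = np.asarray(true_status).astype(int)
        counts = np.bincount(y)
        if counts.min() < k:
            raise ValueError("a class has fewer members than the number of folds")
    assignments = []
    for r in range(reps):
        rs = derive_seed(seed, "fold-plan", r)
        if stratified:
            splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=rs)
            it = splitter.split(np.zeros(n), y)
        else:
            splitter = KFold(n_splits=k, shuffle=True, random_state=rs)
            it = splitter.split(np.zeros(n))
        labels = np.empty(n, dtype=int)
        for f, (_, test) in enumerate(it):
            labels[test] = f
        assignments.append(labels)
    return FoldPlan(
        subject_ids=ids,
        k=k,
        reps=reps,
        assignments=assignments,
        seed=seed,
        stratified=stratified,
        inner_k=inner_k,
        inner_reps=inner_reps,
    )


@dataclass
class CVRunResult:
    """Per-fold metrics and pooled test predictions of one nested-CV run."""

    task: str
    feature_set: str
    fold_metrics: pd.DataFrame
    pooled: pd.DataFrame
    extras: dict = field(default_factory=dict)

    METRICS = ("auc", "accuracy", "sensitivity", "specificity", "r_squared")

    def summary(self) -> pd.DataFrame:
        """Mean and SD of each metric over the outer folds."""
        rows = []
        for m in self.METRICS:
            if m in self.fold_metrics:
                vals = self.fold_metrics[m].to_numpy(dtype=float)
                rows.append(
                    {"metric": m, "mean": np.nanmean(vals), "sd": np.nanstd(vals, ddof=1)}
                )
        return pd.DataFrame(rows)

    @property
    def pooled_auc(self) -> float:
        return roc_auc(self.pooled["score"], self.pooled["status"])

    @property
    def thresholds(self) -> np.ndarray:
        if "threshold" not in self.fold_metrics:
            raise AttributeError("threshold records exist only for the regression task")
        return self.fold_metrics["threshold"].to_numpy(dtype=float)


def _derive_threshold(
    forest: FittedForest, status_train: np.ndarray, criterion: CutpointCriterion
) -> CutpointResult:
    """Cutoff from the training fold's out-of-bag predicted levels."""
    return select_cutoff(forest.oob_predictions, status_train, criterion)


def _inner_criterion_selection(
    X: np.ndarray,
    level: np.ndarray,
    status: np.ndarray,
    plan: FoldPlan,
    spec: ForestSpec,
    outer_rep: int,
    outer_fold: int,
    criteria: Sequence[CutpointCriterion],
) -> CutpointCriterion:
    inner_plan = make_fold_plan(
        np.arange(len(status)),
        status,
        k=plan.inner_k,
        reps=plan.inner_reps,
        seed=derive_seed(plan.seed, "inner", outer_rep, outer_fold),
        stratified=plan.stratified,
    )
    accuracies: dict[CutpointCriterion, list[float]] = {c: [] for c in criteria}
    for ir, if_, itrain, itest in inner_plan.splits():
        fit = fit_forest(
            X[itrain],
            level[itrain],
            spec.replace(seed=derive_seed(spec.seed, "inner-fit", outer_rep, outer_fold, ir, if_)),
        )
        pred_test = fit.estimator.predict(X[itest])
        for crit in criteria:
            cut = _derive_threshold(fit, status[itrain], crit)
            acc, _, _ = confusion_metrics(cut.apply(pred_test), status[itest])
            accuracies[crit].append(acc)
    return choose_best_criterion(accuracies)


def run_nested_cv(
    cohort: CohortTable,
    feature_set: str,
    task: str,
    plan: FoldPlan,
    spec: ForestSpec,
    criteria: Sequence[CutpointCriterion] = CRITERION_ORDER,
) -> CVRunResult:
    """Estimate out-of-sample performance of one feature set × task.

    The binary task fits on each outer training set and scores the test
    fold directly.  The regression task additionally runs the inner CV to
    pick the cutoff criterion, refits on the full outer training set,
    derives the threshold from OOB predictions under the winning criterion
    and dichotomises the test predictions with it.
    """
    if task not in ("regression", "binary"):
        raise ValueError("task must be 'regression' or 'binary'")
    cols = feature_columns(cohort, feature_set)
    X_df = cohort.data[cols]
    if X_df.isna().any().any():
        raise ValueError("cohort features contain missing values; run QC first")
    if cohort.data["csf_ab42"].isna().any():
        raise ValueError("nested CV requires CSF for every subject (training cohort)")
    X = X_df.to_numpy(dtype=float)
    level = cohort.data["csf_ab42"].to_numpy(dtype=float)
    status = cohort.csf_status().to_numpy().astype(int)

    rows = []
    pooled_rows = []
    for rep, fold, train, test in plan.splits():
        fold_seed = derive_seed(spec.seed, "outer-fit", rep, fold)
        try:
            if task == "binary":
                fit = fit_forest(X[train], status[train], spec.replace(task="binary", seed=fold_seed))
                score = predict_forest(fit, X[test])
                pred_status = (score >= 0.5).astype(int)
                acc, sens, sp = confusion_metrics(pred_status, status[test])
                row = {
                    "rep": rep,
                    "fold": fold,
                    "auc": roc_auc(score, status[test]),
                    "accuracy": acc,
                    "sensitivity": sens,
                    "specificity": sp,
                }
            else:
                criterion = _inner_criterion_selection(
                    X[train], level[train], status[train], plan,
                    spec.replace(task="regression"), rep, fold, list(criteria),
                )
                fit = fit_forest(X[train], level[train], spec.replace(task="regression", seed=fold_seed))
                cut = _derive_threshold(fit, status[train], criterion)
                pred = fit.estimator.predict(X[test])
                score = -pred
                acc, sens, sp = confusion_metrics(cut.apply(pred), status[test])
                row = {
                    "rep": rep,
                    "fold": fold,
                    "auc": roc_auc(score, status[test]),
                    "accuracy": acc,
                    "sensitivity": sens,
                    "specificity": sp,
                    "r_squared": r_squared(pred, level[test]),
                    "criterion": criterion.value,
                    "threshold": cut.threshold,
                }
        except ValueError as e:
            raise ValueError(f"outer repetition {rep}, fold {fold}: {e}") from e
        rows.append(row)
        pooled_rows.append(
            pd.DataFrame(
                {
                    "subject_id": np.asarray(plan.subject_ids)[test],
                    "rep": rep,
                    "fold": fold,
                    "score": score,
                    "status": status[test],
                }
            )
        )
    label = feature_set if isinstance(feature_set, str) else "custom"
    return CVRunResult(
        task=task,
        feature_set=label,
        fold_metrics=pd.DataFrame(rows),
        pooled=pd.concat(pooled_rows, ignore_index=True),
    )


def compare_models_wilcoxon(aucs_model_a, aucs_model_b) -> float:
    """One-tailed Wilcoxon signed-rank p-value for 'model A beats model B'.

    Fold-paired AUCs; zero differences are dropped (the standard
    convention).  For up to 25 informative pairs the exact null
    distribution of the positive-rank sum is enumerated (valid under ties
    via midranks); larger samples use the normal approximation with tie
    correction and continuity correction.  All-zero differences leave the
    test undefined: NaN is returned with a warning.
    """
    a = np.asarray(aucs_model_a, dtype=float)
    b = np.asarray(aucs_model_b, dtype=float)
    if a.size != b.size or a.size < 6:
        raise ValueError("paired samples of equal length >= 6 required")
    d = a - b
    d = d[d != 0]
    n = d.size
    if n == 0:
        warnings.warn("all paired differences are zero; Wilcoxon p undefined")
        return float("nan")
    ranks = rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    if n <= 25:
        return _exact_signed_rank_p(ranks, w_pos)
    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(tie_counts**3 - tie_counts) / 48.0
    z = (w_pos - mean - 0.5) / np.sqrt(var)
    return float(norm.sf(z))


def _exact_signed_rank_p(ranks: np.ndarray, w_pos: float) -> float:
    """P(W+ >= observed) by convolving the sign-flip distribution of the ranks."""
    r2 = np.round(ranks * 2).astype(int)  # doubled ranks are integers even with ties
    dist = np.zeros(int(r2.sum()) + 1, dtype=float)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: dist.size - r]
        dist = 0.5 * (dist + shifted)
    target = int(np.ceil(round(w_pos * 2, 8) - 1e-8))
    return float(dist[target:].sum())


def aggregate_roc(pooled_scores, pooled_status) -> tuple[pd.DataFrame, float]:
    """ROC step curve and AUC of the pooled outer-test predictions."""
    from sklearn.metrics import roc_curve

    y = np.asarray(pooled_status).astype(int)
    s = np.asarray(pooled_scores, dtype=float)
    if y.size == 0 or len(set(y)) < 2:
        raise ValueError("pooled ROC requires both classes")
    fpr, tpr, thr = roc_curve(y, s)
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return curve, roc_auc(s, y)


def summarize_runs(results: Mapping[tuple[str, str], CVRunResult]) -> pd.DataFrame:
    """Long-format mean/SD table over runs keyed by (feature_set, task)."""
    rows = []
    for (fs, task), res in results.items():
        for _, r in res.summary().iterrows():
            rows.append(
                {
                    "feature_set": fs,
                    "task": task,
                    "metric": r["metric"],
                    "mean": r["mean"],
                    "sd": r["sd"],
                }
            )
    return pd.DataFrame(rows)
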