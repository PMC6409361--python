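"""Recursive feature elimination with a parsimony rule.

Features are ranked by OOB permutation importance and the lowest-ranked
are removed stepwise — 20% of the remainder per step while more than 30
features survive, then one at a time — with the forest refitted and the
importances recomputed after every step.  The subset size is chosen inside
cross-validation as the smallest size whose mean inner-test AUC comes
within 4% (relative, by default) of the best AUC observed anywhere on the
elimination path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seeds import derive_seed
from .cohort import CohortTable
from .crossval import FoldPlan, feature_columns, make_fold_plan
from .cutpoints import CutpointCriterion, confusion_metrics, r_squared, roc_auc, select_cutoff
from .forest import ForestSpec, fit_forest


def elimination_schedule(p: int) -> list[int]:
    """Strictly decreasing subset sizes from ``p`` down to 1."""
    if p < 1:
        raise ValueError("p must be >= 1")
    sizes = [p]
    s = p
    while s > 30:
        s = max(30, int(np.floor(s * 0.8)))
        sizes.append(s)
    while s > 1:
        s -= 1
        sizes.append(s)
    return sizes


@dataclass
class RFEProfile:
    """AUC along the elimination path plus the chosen subset.

    ``auc_by_size`` maps subset size to mean inner-test AUC;
    ``selected_features`` comes from re-running the elimination on the full
    supplied data down to ``selected_size``.
    """

    schedule: list[int]
    auc_by_size: dict[int, float]
    selected_size: int
    selected_features: list[str]
    fold_aucs: pd.DataFrame = field(default_factory=pd.DataFrame, repr=False)


def _rank_features(fit) -> np.ndarray:
    """Feature order worst-first; importance ties fall back to column order."""
    imp = fit.importances.to_numpy()
    return np.argsort(imp, kind="stable")  # ascending: least important first


def _eliminate_path(X: np.ndarray, y, spec: ForestSpec, names: list[str],
                    schedule: list[int], seed_tokens: tuple, score_fn=None):
    """Walk the elimination schedule on one training matrix.

    Yields (size, kept_names, fitted_forest, score) where ``score`` is
    ``score_fn(fit, kept_idx)`` if given (test-fold AUC) else None.
    Importances are recomputed after every elimination step.
    """
    kept = np.arange(len(names))
    for step, size in enumerate(schedule):
        if size < kept.size:
            # previous fit's ranking decides which features to drop
            order = _rank_features(fit)  # noqa: F821 - set on the prior iteration
            kept = kept[np.sort(order[kept.size - size :])]
        fit = fit_forest(
            X[:, kept],
            y,
            spec.replace(seed=derive_seed(spec.seed, "rfe", *seed_tokens, step)),
            feature_names=[names[i] for i in kept],
        )
        score = score_fn(fit, kept) if score_fn is not None else None
        yield size, [names[i] for i in kept], fit, score


def rfe_profile(
    X,
    y_level,
    y_status,
    spec: ForestSpec,
    inner_plan: FoldPlan,
    tolerance: float = 0.04,
    relative: bool = True,
) -> RFEProfile:
    """Elimination profile from inner CV plus the full-data selected subset.

    Within each inner training fold the forest is fitted, features are
    ranked by permutation importance, the schedule is walked and the
    inner-test AUC recorded at every size; profile AUCs are means over the
    inner folds.  The subset size then follows the parsimony rule and the
    member features come from one elimination run on all supplied rows.
    """
    X_df = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
    names = [str(c) for c in X_df.columns]
    Xm = X_df.to_numpy(dtype=float)
    level = np.asarray(y_level, dtype=float)
    status = np.asarray(y_status).astype(int)
    if status.sum() in (0, status.size):
        raise ValueError("rfe_profile requires both classes")
    schedule = elimination_schedule(Xm.shape[1])
    y = level if spec.task == "regression" else status

    rows = []
    for rep, fold, train, test in inner_plan.splits():
        def test_auc(fit, kept, _test=test, _train=train):
            pred = fit.estimator.predict(Xm[np.ix_(_test, kept)])
            score = -pred if spec.task == "regression" else _positive_proba(fit, Xm[np.ix_(_test, kept)])
            return roc_auc(score, status[_test])

        for size, feats, fit, auc in _eliminate_path(
            Xm[train], y[train], spec, names, schedule, (rep, fold), test_auc
        ):
            rows.append({"rep": rep, "fold": fold, "size": size, "auc": auc})
    fold_aucs = pd.DataFrame(rows)
    auc_by_size = fold_aucs.groupby("size")["auc"].mean().to_dict()

    profile = RFEProfile(schedule, auc_by_size, selected_size=0, selected_features=[], fold_aucs=fold_aucs)
    profile.selected_size = select_subset_size(profile, tolerance, relative)
    profile.selected_features = eliminate_to_size(
        X_df, y, spec, profile.selected_size
    )
    return profile


def _positive_proba(fit, Xsub):
    abn_col = int(np.flatnonzero(fit.estimator.classes_ == 1)[0])
    return fit.estimator.predict_proba(Xsub)[:, abn_col]


def select_subset_size(profile: RFEProfile, tolerance: float = 0.04, relative: bool = True) -> int:
    """Smallest size whose AUC is within ``tolerance`` of the maximum.

    ``relative`` reads "within 4%" as ``auc >= (1 - tol) * max``; the
    absolute reading ``auc >= max - tol`` is available with
    ``relative=False``.
    """
    if not profile.auc_by_size:
        raise ValueError("empty RFE profile")
    max_auc = max(profile.auc_by_size.values())
    floor = (1.0 - tolerance) * max_auc if relative else max_auc - tolerance
    eligible = [s for s, a in profile.auc_by_size.items() if a >= floor - 1e-12]
    return min(eligible)


def eliminate_to_size(X, y, spec: ForestSpec, target_size: int) -> list[str]:
    """Run the elimination on all supplied rows down to ``target_size`` features."""
    X_df = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
    names = [str(c) for c in X_df.columns]
    Xm = X_df.to_numpy(dtype=float)
    schedule = [s for s in elimination_schedule(Xm.shape[1]) if s >= target_size]
    feats: list[str] = names
    for size, feats, fit, _ in _eliminate_path(Xm, np.asarray(y), spec, names, schedule, ("full",)):
        pass
    return feats


def run_rfe_nested(
    cohort: CohortTable,
    plan: FoldPlan,
    spec: ForestSpec,
    feature_set: str = "BP",
    tolerance: float = 0.04,
    relative: bool = True,
):
    """Nested-CV evaluation of the feature-selected model.

    Per outer fold: build the inner-CV elimination profile on the outer
    training set, pick the subset size with the parsimony rule, re-run the
    elimination on the outer training set to identify the subset, refit on
    it and score the outer test fold.  For the regression task the
    accuracy/sensitivity/specificity are derived from an OOB
    accuracy-maximising threshold on the training fold.

    Returns a :class:`~absig.crossval.CVRunResult` whose ``fold_metrics``
    carries the per-fold selected size and features.
    """
    from .crossval import CVRunResult

    cols = feature_columns(cohort, feature_set)
    X_df = cohort.data[cols]
    if X_df.isna().any().any():
        raise ValueError("cohort features contain missing values; run QC first")
    Xm = X_df.to_numpy(dtype=float)
    level = cohort.data["csf_ab42"].to_numpy(dtype=float)
    status = cohort.csf_status().to_numpy().astype(int)
    y = level if spec.task == "regression" else status

    rows = []
    pooled_rows = []
    for rep, fold, train, test in plan.splits():
        inner_plan = make_fold_plan(
            np.arange(train.size),
            status[train],
            k=plan.inner_k,
            reps=plan.inner_reps,
            seed=derive_seed(plan.seed, "rfe-inner", rep, fold),
            stratified=plan.stratified,
        )
        profile = rfe_profile(
            pd.DataFrame(Xm[train], columns=cols),
            level[train],
            status[train],
            spec.replace(seed=derive_seed(spec.seed, "rfe-outer", rep, fold)),
            inner_plan,
            tolerance,
            relative,
        )
        feats = profile.selected_features
        idx = [cols.index(f) for f in feats]
        fit = fit_forest(
            Xm[np.ix_(train, idx)],
            y[train],
            spec.replace(seed=derive_seed(spec.seed, "rfe-refit", rep, fold)),
            feature_names=feats,
        )
        if spec.task == "regression":
            pred = fit.estimator.predict(Xm[np.ix_(test, idx)])
            score = -pred
            cut = select_cutoff(fit.oob_predictions, status[train], CutpointCriterion.MAX_EFFICIENCY)
            pred_status = cut.apply(pred)
            extra = {"r_squared": r_squared(pred, level[test]), "threshold": cut.threshold}
        else:
            score = _positive_proba(fit, Xm[np.ix_(test, idx)])
            pred_status = (score >= 0.5).astype(int)
            extra = {}
        acc, sens, sp = confusion_metrics(pred_status, status[test])
        rows.append(
            {
                "rep": rep,
                "fold": fold,
                "auc": roc_auc(score, status[test]),
                "accuracy": acc,
                "sensitivity": sens,
                "specificity": sp,
                "selected_size": profile.selected_size,
                "selected_features": ";".join(feats),
                **extra,
            }
        )
        pooled_rows.append(
            pd.DataFrame(
                {
                    "subject_id": cohort.data["subject_id"].to_numpy()[test],
                    "rep": rep,
                    "fold": fold,
                    "score": score,
                    "status": status[test],
                }
            )
        )
    return CVRunResult(
        task=spec.task,
        feature_set=f"{feature_set}-rfe",
        fold_metrics=pd.DataFrame(rows),
        pooled=pd.concat(pooled_rows, ignore_index=True),
    )


def final_feature_set(
    cohort: CohortTable,
    spec: ForestSpec,
    feature_set: str = "BP",
    tolerance: float = 0.04,
    relative: bool = True,
    inner_k: int = 3,
    inner_reps: int = 3,
) -> list[str]:
    """The production feature subset from the full training cohort.

    Runs the inner-CV elimination profile once on all training subjects,
    applies the parsimony rule, and returns the features surviving the
    elimination at the selected size.
    """
    if cohort.data["csf_ab42"].isna().any():
        raise ValueError(
            "cohort contains subjects without a CSF measurement; "
            "select features on the training arm only"
        )
    cols = feature_columns(cohort, feature_set)
    X_df = cohort.data[cols]
    status = cohort.csf_status().to_numpy().astype(int)
    level = cohort.data["csf_ab42"].to_numpy(dtype=float)
    inner_plan = make_fold_plan(
        np.arange(len(status)),
        status,
        k=inner_k,
        reps=inner_reps,
        seed=derive_seed(spec.seed, "final-inner"),
        stratified=True,
    )
    profile = rfe_profile(X_df, level, status, spec, inner_plan, tolerance, relative)
    return profile.selected_features
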