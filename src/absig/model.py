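"""Model/Results front end for the blood-based CSF Aβ1-42 signature.

:class:`CSFSignatureModel` bundles a training cohort with a feature-set
code and task mode; :meth:`~CSFSignatureModel.fit` estimates out-of-sample
performance by nested cross-validation and refits a production forest on
the full cohort, returning a :class:`CSFSignatureResults` that carries the
per-fold metrics, the selected cutoff, the fitted forest and convenience
prediction, feature-selection, partial-dependence and plotting methods.

Example
-------
>>> from absig import GeneratorConfig, generate_cohort, split_cohorts
>>> from absig.model import CSFSignatureModel
>>> cohort = generate_cohort(GeneratorConfig(n_subjects=200, seed=7))
>>> train, valid = split_cohorts(cohort)
>>> model = CSFSignatureModel(train, feature_set="BP", task="regression")
>>> res = model.fit(outer=(2, 5), inner=(2, 3), n_trees=200, seed=7)  # doctest: +SKIP
>>> print(res.summary())  # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seeds import derive_seed
from .cohort import CohortTable
from .crossval import (
    CVRunResult,
    feature_columns,
    make_fold_plan,
    run_nested_cv,
)
from .cutpoints import CutpointCriterion, CutpointResult, select_cutoff
from .forest import (
    FittedForest,
    ForestSpec,
    abnormality_score,
    fit_forest,
    partial_dependence,
    predict_forest,
)
from .selection import final_feature_set


class CSFSignatureModel:
    """A random-forest model of CSF Aβ1-42 built from a training cohort.

    Parameters
    ----------
    cohort:
        Training cohort; every subject must have a measured CSF level and
        complete (imputed) features.
    feature_set:
        Modality code among {"B", "BM", "BP", "BPM"}; B (age + APOEε4) is
        always included.
    task:
        "regression" learns the continuous level and dichotomises it with a
        data-driven cutoff; "binary" learns the dichotomised status
        directly.
    features:
        Optional explicit feature list overriding the code (used for
        reduced models such as the five-marker panel).
    """

    def __init__(
        self,
        cohort: CohortTable,
        feature_set: str = "BP",
        task: str = "regression",
        features: list[str] | None = None,
    ):
        if cohort.data["csf_ab42"].isna().any():
            raise ValueError("training cohort must have CSF for every subject")
        self.cohort = cohort
        self.feature_set = feature_set
        self.task = task
        self.feature_names = (
            list(features) if features is not None else feature_columns(cohort, feature_set)
        )
        X = cohort.data[self.feature_names]
        if X.isna().any().any():
            raise ValueError("features contain missing values; run QC/imputation first")
        self._X = X
        self._level = cohort.data["csf_ab42"].to_numpy(dtype=float)
        self._status = cohort.csf_status().to_numpy().astype(int)

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        protein_cols: list[str],
        metabolite_cols: list[str],
        pet: pd.DataFrame | None = None,
        clinical_threshold: float = 192.0,
        **kwargs,
    ) -> "CSFSignatureModel":
        """Build directly from a per-subject data frame."""
        from .cohort import _empty_pet

        table = CohortTable(
            data=data,
            protein_cols=protein_cols,
            metabolite_cols=metabolite_cols,
            pet=pet if pet is not None else _empty_pet(),
            clinical_threshold=clinical_threshold,
        )
        return cls(table, **kwargs)

    def fit(
        self,
        outer: tuple[int, int] = (10, 10),
        inner: tuple[int, int] = (3, 3),
        n_trees: int = 2000,
        seed: int = 0,
        stratified: bool = True,
    ) -> "CSFSignatureResults":
        """Nested-CV performance estimate plus a production refit.

        ``outer`` and ``inner`` are (repetitions, folds); ``outer=None``
        skips the outer CV and only builds the production model.  The
        production forest is refitted on the full cohort; for the
        regression task its cutoff criterion is chosen by one inner CV on
        the full cohort and the threshold derived from out-of-bag
        predictions.
        """
        inner_reps, inner_k = inner
        spec = ForestSpec(n_trees=n_trees, task=self.task, seed=derive_seed(seed, "forest"))
        reps, k = outer if outer is not None else (1, 2)
        plan = make_fold_plan(
            self.cohort.data["subject_id"].to_numpy(),
            self._status,
            k=k,
            reps=reps,
            seed=derive_seed(seed, "plan"),
            stratified=stratified,
            inner_k=inner_k,
            inner_reps=inner_reps,
        )
        cv = None
        if outer is not None:
            cv = _run_cv_on_features(self.cohort, self.feature_names, self.task, plan, spec)

        forest = fit_forest(
            self._X, self._level if self.task == "regression" else self._status,
            spec.replace(seed=derive_seed(seed, "final-fit")),
        )
        criterion = None
        cutpoint = None
        if self.task == "regression":
            from .crossval import _inner_criterion_selection

            criterion = _inner_criterion_selection(
                self._X.to_numpy(dtype=float),
                self._level,
                self._status,
                plan,
                spec,
                outer_rep=-1,
                outer_fold=-1,
                criteria=list(CutpointCriterion),
            )
            cutpoint = select_cutoff(forest.oob_predictions, self._status, criterion)
        return CSFSignatureResults(
            model=self, cv=cv, forest=forest, criterion=criterion, cutpoint=cutpoint
        )


def _run_cv_on_features(cohort, features, task, plan, spec) -> CVRunResult:
    """Nested CV restricted to an explicit feature list."""
    return run_nested_cv(cohort, list(features), task, plan, spec)


@dataclass
class CSFSignatureResults:
    """Fitted signature: cross-validated metrics and the production forest."""

    model: CSFSignatureModel
    cv: CVRunResult | None
    forest: FittedForest
    criterion: CutpointCriterion | None = None
    cutpoint: CutpointResult | None = None

    @property
    def fold_metrics(self) -> pd.DataFrame:
        if self.cv is None:
            raise AttributeError("model was fitted with outer=None (no CV metrics)")
        return self.cv.fold_metrics

    @property
    def threshold(self) -> float | None:
        return None if self.cutpoint is None else self.cutpoint.threshold

    def metrics(self) -> pd.DataFrame:
        if self.cv is None:
            raise AttributeError("model was fitted with outer=None (no CV metrics)")
        return self.cv.summary()

    def predict(self, cohort_or_X) -> np.ndarray:
        """Predicted CSF level (regression) or abnormal probability (binary)."""
        return predict_forest(self.forest, _features_of(cohort_or_X, self.model.feature_names))

    def score(self, cohort_or_X) -> np.ndarray:
        """Abnormality-oriented score (higher = more likely abnormal)."""
        return abnormality_score(self.forest, _features_of(cohort_or_X, self.model.feature_names))

    def predict_status(self, cohort_or_X) -> np.ndarray:
        """Dichotomised prediction: 1 = abnormal CSF Aβ1-42."""
        pred = self.predict(cohort_or_X)
        if self.model.task == "regression":
            if self.cutpoint is None:
                raise RuntimeError("no cutoff available")
            return self.cutpoint.apply(pred)
        return (pred >= 0.5).astype(int)

    def select_features(
        self,
        tolerance: float = 0.04,
        relative: bool = True,
        inner: tuple[int, int] = (3, 3),
    ) -> list[str]:
        """Smallest feature subset within tolerance of the best RFE AUC."""
        return final_feature_set(
            self.model.cohort,
            self.forest.spec,
            feature_set=self.model.feature_set,
            tolerance=tolerance,
            relative=relative,
            inner_reps=inner[0],
            inner_k=inner[1],
        )

    def partial_dependence(self, feature: str, grid=None) -> tuple[np.ndarray, np.ndarray]:
        """Partial-dependence curve of one feature over the training rows."""
        if grid is None:
            col = self.model._X[feature].to_numpy(dtype=float)
            grid = np.linspace(np.quantile(col, 0.05), np.quantile(col, 0.95), 25)
        grid = np.asarray(grid, dtype=float)
        return grid, partial_dependence(self.forest, feature, grid)

    def plot_roc(self, ax=None):
        """Pooled outer-test ROC curve."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        from .crossval import aggregate_roc

        curve, auc = aggregate_roc(self.cv.pooled["score"], self.cv.pooled["status"])
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(curve["fpr"], curve["tpr"], label=f"{self.model.feature_set} (AUC {auc:.2f})")
        ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.legend()
        return ax

    def summary(self) -> str:
        """Plain-text summary of the cross-validated performance."""
        lines = [
            "CSF Aβ1-42 signature (random forest)",
            "=" * 52,
            f"feature set:      {self.model.feature_set}  ({len(self.model.feature_names)} features)",
            f"task:             {self.model.task}",
            f"subjects:         {self.model.cohort.n_subjects}",
            f"trees:            {self.forest.spec.n_trees}",
        ]
        if self.cv is not None:
            lines.append(f"outer folds:      {len(self.cv.fold_metrics)}")
        if self.criterion is not None:
            lines.append(f"cutoff criterion: {self.criterion.value}")
            lines.append(f"threshold:        {self.threshold:.1f} pg/ml (level < threshold = abnormal)")
        if self.cv is not None:
            lines.append(f"pooled AUC:       {self.cv.pooled_auc:.3f}")
            lines.append("-" * 52)
            lines.append(f"{'metric':<14}{'mean':>10}{'sd':>10}")
            for _, row in self.cv.summary().iterrows():
                if np.isnan(row["mean"]):
                    continue
                lines.append(f"{row['metric']:<14}{row['mean']:>10.3f}{row['sd']:>10.3f}")
        lines.append("=" * 52)
        return "\n".join(lines)


def _features_of(cohort_or_X, feature_names: list[str]) -> pd.DataFrame:
    if isinstance(cohort_or_X, CohortTable):
        return cohort_or_X.data[feature_names]
    if isinstance(cohort_or_X, pd.DataFrame):
        return cohort_or_X[feature_names]
    return pd.DataFrame(np.asarray(cohort_or_X, dtype=float), columns=feature_names)
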