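"""End-to-end orchestration of the study analogue.

``run_full_study`` chains every stage — simulate, QC + imputation,
cohort split, nested CV over feature sets and tasks, paired Wilcoxon model
comparisons, recursive feature elimination, and the survival + PET
validation — writing plain CSV/JSON reports (and static plots) under an
output directory.  Every random draw descends from ``global_seed`` via
per-stage derived seeds, so adding a stage never perturbs earlier ones and
two runs with an identical config produce identical result files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._seeds import derive_seed
from .cohort import (
    CohortTable,
    GeneratorConfig,
    config_from_dict,
    config_to_dict,
    generate_cohort,
    load_cohort,
    split_cohorts,
    write_cohort,
)
from .crossval import (
    FEATURE_SET_CODES,
    aggregate_roc,
    compare_models_wilcoxon,
    make_fold_plan,
    run_nested_cv,
    summarize_runs,
)
from .forest import ForestSpec
from .model import CSFSignatureModel
from .preprocessing import QCConfig, run_qc
from .selection import final_feature_set
from .survival import pet_concordance_auc, validate_survival_stratification

log = logging.getLogger("absig")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    qc: QCConfig = field(default_factory=QCConfig)
    n_trees: int = 2000
    outer: tuple[int, int] = (10, 10)  # (repetitions, folds)
    inner: tuple[int, int] = (3, 3)
    feature_sets: tuple[str, ...] = FEATURE_SET_CODES
    tasks: tuple[str, ...] = ("regression", "binary")
    rfe_tolerance: float = 0.04
    rfe_relative: bool = True
    comparison_alpha: float = 0.05
    bonferroni_divisor: int = 5
    stratified: bool = True
    make_plots: bool = True
    output_dir: str = "absig_results"
    global_seed: int = 0

    def __post_init__(self) -> None:
        if self.bonferroni_divisor < 1:
            raise ValueError("bonferroni_divisor must be >= 1")
        for fs in self.feature_sets:
            if fs not in FEATURE_SET_CODES:
                raise ValueError(f"unknown feature set {fs!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["generator"] = config_to_dict(self.generator)
        d["outer"] = list(self.outer)
        d["inner"] = list(self.inner)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "generator" in d:
            d["generator"] = config_from_dict(d["generator"])
        if "qc" in d and not isinstance(d["qc"], QCConfig):
            d["qc"] = QCConfig(**d["qc"])
        for key in ("outer", "inner", "feature_sets", "tasks"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def impute_cohort(
    cohort: CohortTable, qc: QCConfig | None = None, seed: int = 0
) -> tuple[CohortTable, dict]:
    """QC + imputation on one cohort (applied independently per cohort).

    Returns the cohort with filtered, fully imputed analytes plus the QC
    report (removed analytes, flagged samples, imputation convergence).
    """
    qc = qc or QCConfig()
    qc = QCConfig(
        max_analyte_missing_frac=qc.max_analyte_missing_frac,
        max_sample_missing_frac=qc.max_sample_missing_frac,
        impute_max_iter=qc.impute_max_iter,
        impute_n_trees=qc.impute_n_trees,
        impute_seed=seed,
    )
    imputed, report = run_qc(cohort.analytes, qc)
    data = cohort.data.copy()
    data = data.drop(columns=cohort.analyte_cols)
    data = pd.concat([data, imputed], axis=1)
    out = CohortTable(
        data=data,
        protein_cols=[c for c in cohort.protein_cols if c in imputed.columns],
        metabolite_cols=[c for c in cohort.metabolite_cols if c in imputed.columns],
        pet=cohort.pet,
        clinical_threshold=cohort.clinical_threshold,
        truth=cohort.truth,
    )
    return out, report


def run_full_study(config: RunConfig) -> dict:
    """Run every stage and write the report bundle; returns the results in memory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.global_seed
    results: dict = {}

    # --- simulate -----------------------------------------------------
    log.info("stage simulate")
    gen = dataclasses.replace(config.generator, seed=derive_seed(seed, "generator"))
    cohort = generate_cohort(gen)
    write_cohort(cohort, out / "cohort")
    results["cohort"] = cohort

    # --- qc + split ---------------------------------------------------
    log.info("stage qc")
    training_raw, validation_raw = split_cohorts(cohort)
    training, qc_train = impute_cohort(training_raw, config.qc, derive_seed(seed, "qc", "train"))
    validation, qc_valid = impute_cohort(validation_raw, config.qc, derive_seed(seed, "qc", "valid"))
    (out / "qc_report.json").write_text(
        json.dumps({"training": qc_train, "validation": qc_valid}, indent=2, default=str)
    )
    results["training"], results["validation"] = training, validation

    # --- nested CV over feature sets × tasks --------------------------
    log.info("stage cv")
    status = training.csf_status().to_numpy().astype(int)
    plan = make_fold_plan(
        training.data["subject_id"].to_numpy(),
        status,
        k=config.outer[1],
        reps=config.outer[0],
        seed=derive_seed(seed, "plan"),
        stratified=config.stratified,
        inner_k=config.inner[1],
        inner_reps=config.inner[0],
    )
    runs = {}
    for fs in config.feature_sets:
        for task in config.tasks:
            spec = ForestSpec(n_trees=config.n_trees, task=task, seed=derive_seed(seed, "cv", fs, task))
            log.info("  nested CV: %s / %s", fs, task)
            runs[(fs, task)] = run_nested_cv(training, fs, task, plan, spec)
    results["cv"] = runs
    fold_frames = []
    for (fs, task), res in runs.items():
        df = res.fold_metrics.copy()
        df.insert(0, "task", task)
        df.insert(0, "feature_set", fs)
        fold_frames.append(df)
    pd.concat(fold_frames, ignore_index=True).to_csv(out / "cv_fold_metrics.csv", index=False)
    summary = summarize_runs(runs)
    summary.to_csv(out / "cv_summary.csv", index=False)

    # pooled ROC points per run
    roc_frames = []
    for (fs, task), res in runs.items():
        curve, auc = aggregate_roc(res.pooled["score"], res.pooled["status"])
        curve.insert(0, "task", task)
        curve.insert(0, "feature_set", fs)
        curve["pooled_auc"] = auc
        roc_frames.append(curve)
    pd.concat(roc_frames, ignore_index=True).to_csv(out / "cv_pooled_roc.csv", index=False)

    # --- Wilcoxon comparisons on per-fold AUCs ------------------------
    comp_rows = []
    for task in config.tasks:
        sets = [fs for fs in config.feature_sets if (fs, task) in runs]
        for a in sets:
            for b in sets:
                if a == b:
                    continue
                auc_a = runs[(a, task)].fold_metrics["auc"]
                auc_b = runs[(b, task)].fold_metrics["auc"]
                if len(auc_a) < 6:
                    log.warning(
                        "skipping %s vs %s comparison: only %d folds (need >= 6)",
                        a, b, len(auc_a),
                    )
                    p = float("nan")
                else:
                    p = compare_models_wilcoxon(auc_a, auc_b)
                comp_rows.append(
                    {
                        "task": task,
                        "model_a": a,
                        "model_b": b,
                        "p_one_sided_a_gt_b": p,
                        "significant": bool(p < config.comparison_alpha / config.bonferroni_divisor),
                    }
                )
    comparisons = pd.DataFrame(comp_rows)
    comparisons.to_csv(out / "model_comparisons.csv", index=False)
    results["comparisons"] = comparisons

    # --- recursive feature elimination --------------------------------
    log.info("stage rfe")
    rfe_spec = ForestSpec(
        n_trees=config.n_trees, task="regression", seed=derive_seed(seed, "rfe")
    )
    selected = final_feature_set(
        training,
        rfe_spec,
        feature_set="BP",
        tolerance=config.rfe_tolerance,
        relative=config.rfe_relative,
        inner_k=config.inner[1],
        inner_reps=config.inner[0],
    )
    (out / "selected_features.json").write_text(json.dumps({"BP_fs": selected}, indent=2))
    results["selected_features"] = selected

    # --- clinical validation ------------------------------------------
    log.info("stage validate")
    validation_models = {"B": "B", "BP": "BP"}
    predicted = {}
    scores = {}
    fits = {}
    for label, fs in validation_models.items():
        m = CSFSignatureModel(training, feature_set=fs, task="regression")
        fit = m.fit(outer=None, inner=config.inner,
                    n_trees=config.n_trees, seed=derive_seed(seed, "validate", label))
        fits[label] = fit
        predicted[label] = pd.Series(fit.predict_status(validation), index=validation.data.index)
        scores[label] = pd.Series(
            fit.score(validation), index=validation.data["subject_id"].to_numpy()
        )
    m5 = CSFSignatureModel(training, task="regression", features=selected)
    fit5 = m5.fit(outer=None, inner=config.inner,
                  n_trees=config.n_trees, seed=derive_seed(seed, "validate", "BP5"))
    fits["BP5"] = fit5
    predicted["BP5"] = pd.Series(fit5.predict_status(validation), index=validation.data.index)
    scores["BP5"] = pd.Series(
        fit5.score(validation), index=validation.data["subject_id"].to_numpy()
    )

    survival = validate_survival_stratification(validation, predicted, training)
    surv_rows = []
    for label, res in survival.items():
        cmp_ = res["comparison"]
        if cmp_ is None:
            n1 = int((res["records"]["stratum"] == 1).sum())
            surv_rows.append(
                {
                    "analysis": label,
                    "n_normal": len(res["records"]) - n1,
                    "n_abnormal": n1,
                }
            )
            continue
        row = {
            "analysis": label,
            "hazard_ratio": cmp_.hazard_ratio,
            "hr_ci_low": cmp_.hr_ci95[0],
            "hr_ci_high": cmp_.hr_ci95[1],
            "logrank_stat": cmp_.logrank_stat,
            "logrank_p": cmp_.logrank_p,
            "n_normal": cmp_.n_normal,
            "n_abnormal": cmp_.n_abnormal,
        }
        if "equivalence" in res:
            row["equiv_normal_p"] = res["equivalence"]["normal"]["p"]
            row["equiv_abnormal_p"] = res["equivalence"]["abnormal"]["p"]
        surv_rows.append(row)
    surv_df = pd.DataFrame(surv_rows)
    surv_df.to_csv(out / "survival_validation.csv", index=False)
    results["survival"] = survival

    pet_rows = []
    for label in scores:
        for cohort_name, cohort_obj, fit in (
            ("training", training, fits[label]),
            ("validation", validation, fits[label]),
        ):
            sc = pd.Series(
                fit.score(cohort_obj), index=cohort_obj.data["subject_id"].to_numpy()
            )
            try:
                auc, _ = pet_concordance_auc(sc, cohort_obj.pet)
            except ValueError:
                auc = float("nan")
            pet_rows.append({"model": label, "cohort": cohort_name, "pet_auc": auc})
    pet_df = pd.DataFrame(pet_rows)
    pet_df.to_csv(out / "pet_concordance.csv", index=False)
    results["pet"] = pet_df

    if config.make_plots:
        _write_plots(out, runs, survival)

    # --- manifest ------------------------------------------------------
    cfg_dict = config.to_dict()
    manifest = {
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()
        ).hexdigest(),
        "global_seed": seed,
        "versions": _versions(),
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return results


def _versions() -> dict:
    import lifelines
    import sklearn

    import absig

    return {
        "absig": absig.__version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
        "lifelines": lifelines.__version__,
    }


def _write_plots(out: Path, runs: dict, survival: dict) -> None:
    import matplotlib

    matplotlib.use("Agg", force=True)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for (fs, task), res in runs.items():
        if task != "regression":
            continue
        curve, auc = aggregate_roc(res.pooled["score"], res.pooled["status"])
        ax.plot(curve["fpr"], curve["tpr"], label=f"{fs} (AUC {auc:.2f})")
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "roc_regression.png", dpi=120)
    plt.close(fig)

    n = len(survival)
    fig, axes = plt.subplots(1, n, figsize=(3.2 * n, 3.2), sharey=True)
    axes = np.atleast_1d(axes)
    for ax, (label, res) in zip(axes, survival.items()):
        cmp_ = res["comparison"]
        if cmp_ is None:
            ax.set_title(f"{label}\n(single stratum)", fontsize=8)
            ax.set_xlabel("months")
            continue
        for curve, name, color in (
            (cmp_.km_normal, "normal", "tab:blue"),
            (cmp_.km_abnormal, "abnormal", "tab:red"),
        ):
            ax.step(curve.times, curve.survival, where="post", label=name, color=color)
            ax.fill_between(
                curve.times, curve.lower, curve.upper, step="post", alpha=0.2, color=color
            )
        ax.set_title(f"{label}\nHR {cmp_.hazard_ratio:.1f}, p={cmp_.logrank_p:.2g}", fontsize=8)
        ax.set_xlabel("months")
    axes[0].set_ylabel("P(not converted to AD)")
    axes[0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out / "km_validation.png", dpi=120)
    plt.close(fig)


__all__ = [
    "RunConfig",
    "run_full_study",
    "load_cohort",
    "write_cohort",
]
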