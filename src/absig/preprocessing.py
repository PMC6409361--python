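"""Quality control and random-forest imputation of analyte panels.

QC mirrors common immunoassay practice: analytes with high missingness are
dropped outright (strictly more than 15% by default), subjects with high
residual missingness are flagged for the caller to review, and the
remaining gaps are filled with iterative chained regression forests in the
style of missForest: initialise with column medians, visit variables in
increasing-missingness order, regress each on all others over its observed
rows, and stop when the imputed values stop changing (first increase of the
summed squared change) or a maximum number of sweeps is reached.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from ._seeds import derive_seed
from .forest import compute_mtry


@dataclass(frozen=True)
class QCConfig:
    max_analyte_missing_frac: float = 0.15
    max_sample_missing_frac: float = 0.05
    impute_max_iter: int = 10
    impute_n_trees: int = 100
    impute_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("max_analyte_missing_frac", "max_sample_missing_frac"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.impute_max_iter < 1:
            raise ValueError("impute_max_iter must be >= 1")
        if self.impute_n_trees < 1:
            raise ValueError("impute_n_trees must be >= 1")


def filter_analytes_by_missingness(
    analytes: pd.DataFrame, max_frac: float
) -> tuple[pd.DataFrame, list[str]]:
    """Drop analytes whose missing fraction strictly exceeds ``max_frac``.

    Returns the reduced matrix (surviving column order preserved) and the
    names of the removed analytes.  An analyte missing exactly ``max_frac``
    of its values is retained ("more than" read strictly).
    """
    if analytes.shape[1] == 0:
        raise ValueError("analyte matrix has no columns")
    frac = analytes.isna().mean(axis=0)
    removed = [c for c in analytes.columns if frac[c] > max_frac]
    kept = [c for c in analytes.columns if frac[c] <= max_frac]
    if not kept:
        raise ValueError("all analytes removed by the missingness filter")
    return analytes[kept], removed


def flag_samples_by_missingness(analytes: pd.DataFrame, max_frac: float) -> list:
    """Subjects (index labels) whose missing fraction strictly exceeds ``max_frac``.

    Intended to run after the analyte filter; the caller decides whether the
    flagged samples are dropped.
    """
    frac = analytes.isna().mean(axis=1)
    return list(analytes.index[frac > max_frac])


def impute_rf(
    analytes: pd.DataFrame, config: QCConfig | None = None
) -> tuple[pd.DataFrame, dict]:
    """Fill missing analyte values with iterative chained regression forests.

    Observed cells are never altered; the returned matrix has no missing
    values and is deterministic given ``config.impute_seed``.  The second
    return value is a small report with the per-sweep convergence deltas.

    Raises on non-numeric columns and on columns that are entirely missing.
    """
    config = config or QCConfig()
    non_numeric = [
        c for c in analytes.columns if not pd.api.types.is_numeric_dtype(analytes[c])
    ]
    if non_numeric:
        raise TypeError(f"non-numeric analyte columns: {non_numeric}")
    all_missing = [c for c in analytes.columns if analytes[c].isna().all()]
    if all_missing:
        raise ValueError(f"columns entirely missing: {all_missing}")

    X = analytes.to_numpy(dtype=float, copy=True)
    miss = np.isnan(X)
    report = {"n_missing": int(miss.sum()), "deltas": [], "iterations": 0}
    if not miss.any():
        return analytes.copy(), report

    # median initialisation, then visit columns by increasing missingness
    medians = np.nanmedian(X, axis=0)
    X[miss] = np.take(medians, np.nonzero(miss)[1])
    order = np.argsort(miss.mean(axis=0), kind="stable")
    order = [j for j in order if miss[:, j].any()]

    prev_delta = np.inf
    best = X.copy()
    others = {j: np.delete(np.arange(X.shape[1]), j) for j in order}
    mtry = compute_mtry(max(X.shape[1] - 1, 1))
    for sweep in range(config.impute_max_iter):
        X_old = X.copy()
        for j in order:
            obs = ~miss[:, j]
            forest = RandomForestRegressor(
                n_estimators=config.impute_n_trees,
                max_features=mtry,
                min_samples_leaf=5,
                random_state=derive_seed(config.impute_seed, "impute", sweep, int(j)),
                n_jobs=1,
            )
            forest.fit(X[obs][:, others[j]], X[obs, j])
            X[miss[:, j], j] = forest.predict(X[miss[:, j]][:, others[j]])
        delta = float(np.sum((X[miss] - X_old[miss]) ** 2))
        report["deltas"].append(delta)
        report["iterations"] = sweep + 1
        if delta >= prev_delta:
            # imputation started to diverge: keep the previous sweep
            X = best
            break
        prev_delta = delta
        best = X.copy()

    orig = analytes.to_numpy(dtype=float)
    X[~miss] = orig[~miss]
    out = pd.DataFrame(X, index=analytes.index, columns=analytes.columns)
    if not np.isfinite(out.to_numpy()).all():
        raise RuntimeError("imputation produced non-finite values")
    return out, report


def run_qc(analytes: pd.DataFrame, config: QCConfig | None = None):
    """Full QC: analyte filter, sample flagging, imputation.

    Returns ``(imputed_matrix, report)`` where the report lists removed
    analytes, flagged samples and imputation convergence information.
    """
    config = config or QCConfig()
    reduced, removed = filter_analytes_by_missingness(
        analytes, config.max_analyte_missing_frac
    )
    flagged = flag_samples_by_missingness(reduced, config.max_sample_missing_frac)
    imputed, impute_report = impute_rf(reduced, config)
    report = {
        "removed_analytes": removed,
        "flagged_samples": flagged,
        "imputation": impute_report,
    }
    return imputed, report
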