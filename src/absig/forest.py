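"""Random-forest learners for continuous and dichotomised CSF Aβ1-42.

Forests follow the study's hyperparameter rules: 2000 trees by default and
``floor(p^0.75)`` candidate features per split, with all other tree
parameters at library defaults.  Fitting populates out-of-bag (OOB) error,
per-row OOB predictions and Breiman-style OOB permutation importances (mean
increase in OOB error when one feature is shuffled), the quantities the
downstream cutpoint derivation and recursive feature elimination consume.

Tree induction itself is delegated to scikit-learn's CART forests; the OOB
bookkeeping is computed here from each tree's bootstrap sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from ._seeds import derive_seed

def _sample_indices(tree_random_state: int, n_samples: int) -> np.ndarray:
    """Reconstruct a tree's bootstrap sample from its stored random state.

    scikit-learn draws each tree's bootstrap as ``randint(0, n, n)`` from a
    ``RandomState`` seeded with the tree's ``random_state`` (unweighted,
    full-size bootstrap); replaying that draw identifies the out-of-bag
    rows without storing any indices.
    """
    rng = np.random.RandomState(tree_random_state)
    return rng.randint(0, n_samples, n_samples)


def compute_mtry(p: int) -> int:
    """Number of split candidates for ``p`` features: ``floor(p^0.75)``, min 1."""
    if p < 1:
        raise ValueError("p must be >= 1")
    return max(1, int(np.floor(p**0.75 + 1e-9)))


@dataclass(frozen=True)
class ForestSpec:
    """Hyperparameter bundle: tree count, the mtry rule and the task mode.

    ``min_node_size=None`` applies the reference forest implementation's
    defaults: terminal nodes of at least 5 observations for regression and
    1 for classification.
    """

    n_trees: int = 2000
    task: str = "regression"
    seed: int = 0
    min_node_size: int | None = None
    mtry_rule: str = "floor(p^0.75)"

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.task not in ("regression", "binary"):
            raise ValueError("task must be 'regression' or 'binary'")

    @property
    def resolved_min_node_size(self) -> int:
        if self.min_node_size is not None:
            return self.min_node_size
        return 5 if self.task == "regression" else 1

    def replace(self, **kw) -> "ForestSpec":
        d = {
            "n_trees": self.n_trees,
            "task": self.task,
            "seed": self.seed,
            "min_node_size": self.min_node_size,
        }
        d.update(kw)
        return ForestSpec(**d)


@dataclass
class FittedForest:
    """A fitted forest plus its OOB diagnostics.

    ``oob_error`` is the OOB mean squared error (regression) or the OOB
    misclassification rate (binary).  ``oob_predictions`` holds, per
    training row, the mean prediction (regression) or abnormal-vote
    fraction (binary) over the trees for which that row was out of bag.
    ``importances`` is the OOB permutation importance per feature.
    """

    estimator: object
    spec: ForestSpec
    feature_names: list[str]
    oob_error: float
    oob_predictions: np.ndarray
    importances: pd.Series
    X_train: np.ndarray
    y_train: np.ndarray
    degenerate: bool = False

    @property
    def oob_r2(self) -> float:
        """OOB R² (regression task only); NaN for a constant target."""
        y = self.y_train
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        if ss_tot == 0:
            return float("nan")
        ss_res = float(np.sum((y - self.oob_predictions) ** 2))
        return 1.0 - ss_res / ss_tot


def _as_matrix(X, feature_names=None):
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    if feature_names is None:
        feature_names = [f"x{i}" for i in range(X.shape[1])]
    return X, list(feature_names)


def _encode_binary(y) -> np.ndarray:
    """Encode status labels as 1 = abnormal, 0 = normal."""
    y = np.asarray(y)
    if y.dtype.kind in "OU":
        mapping = {"normal": 0, "abnormal": 1}
        try:
            return np.array([mapping[str(v)] for v in y], dtype=int)
        except KeyError as e:  # noqa: F841
            raise ValueError("binary labels must be {normal, abnormal} or {0, 1}")
    return y.astype(float).astype(int)


def _tree_predict(tree, X32: np.ndarray, task: str) -> np.ndarray:
    values = tree.tree_.predict(X32)
    if values.ndim == 3:  # (n, n_outputs, n_classes)
        values = values[:, 0, :]
    if task == "regression":
        return values[:, 0]
    return np.argmax(values, axis=1)


def _oob_err(pred: np.ndarray, y: np.ndarray, task: str) -> float:
    if task == "regression":
        return float(np.mean((pred - y) ** 2))
    return float(np.mean(pred != y))


def fit_forest(X, y, spec: ForestSpec, feature_names: Sequence[str] | None = None) -> FittedForest:
    """Fit a CART forest under ``spec`` and compute its OOB diagnostics.

    ``X`` must be complete (run imputation first); ``y`` is the continuous
    CSF level for the regression task or the dichotomised status for the
    binary task.  A single-class binary target is rejected; a constant
    regression target is fitted but flagged degenerate.
    """
    Xm, names = _as_matrix(X, feature_names)
    if np.isnan(Xm).any():
        raise ValueError("X contains missing values; impute before fitting")
    p = Xm.shape[1]
    mtry = compute_mtry(p)
    degenerate = False
    if spec.task == "regression":
        y_enc = np.asarray(y, dtype=float)
        if np.unique(y_enc).size == 1:
            degenerate = True
        est = RandomForestRegressor(
            n_estimators=spec.n_trees,
            max_features=mtry,
            min_samples_leaf=spec.resolved_min_node_size,
            random_state=spec.seed,
            n_jobs=1,
        )
    else:
        y_enc = _encode_binary(y)
        if np.unique(y_enc).size < 2:
            raise ValueError("binary task requires both classes in y")
        est = RandomForestClassifier(
            n_estimators=spec.n_trees,
            max_features=mtry,
            min_samples_leaf=spec.resolved_min_node_size,
            random_state=spec.seed,
            n_jobs=1,
        )
    est.fit(Xm, y_enc)

    oob_pred, oob_error, importances = _oob_diagnostics(est, Xm, y_enc, spec)
    return FittedForest(
        estimator=est,
        spec=spec,
        feature_names=names,
        oob_error=oob_error,
        oob_predictions=oob_pred,
        importances=pd.Series(importances, index=names, name="permutation_importance"),
        X_train=Xm,
        y_train=y_enc.astype(float),
        degenerate=degenerate,
    )


def _oob_diagnostics(est, Xm, y_enc, spec: ForestSpec):
    """Per-row OOB predictions, OOB error and OOB permutation importances.

    For each tree, only the features that actually appear in its splits are
    permuted: shuffling a feature a tree never tests cannot change its
    predictions, so those features contribute exactly zero for that tree.
    """
    n, p = Xm.shape
    task = spec.task
    X32 = np.ascontiguousarray(Xm, dtype=np.float32)
    imp = np.zeros(p)
    if task == "regression":
        pred_sum = np.zeros(n)
        pred_cnt = np.zeros(n)
    else:
        n_classes = len(est.classes_)
        votes = np.zeros((n, n_classes))

    for t_idx, tree in enumerate(est.estimators_):
        sampled = _sample_indices(tree.random_state, n)
        oob_mask = np.ones(n, dtype=bool)
        oob_mask[sampled] = False
        oob = np.flatnonzero(oob_mask)
        if oob.size < 2:
            continue
        Xo = X32[oob]
        base_pred = _tree_predict(tree, Xo, task)
        if task == "regression":
            pred_sum[oob] += base_pred
            pred_cnt[oob] += 1
        else:
            votes[oob, base_pred.astype(int)] += 1
        yo = y_enc[oob]
        base_err = _oob_err(base_pred, yo, task)
        rng = np.random.default_rng(derive_seed(spec.seed, "permimp", t_idx))
        used = np.unique(tree.tree_.feature)
        used = used[used >= 0]
        if used.size:
            # one batched traversal per tree: stack a permuted copy of the
            # OOB block per used feature
            m = oob.size
            block = np.empty((used.size * m, p), dtype=np.float32)
            for i, j in enumerate(used):
                sub = block[i * m : (i + 1) * m]
                sub[:] = Xo
                sub[:, j] = Xo[rng.permutation(m), j]
            preds = _tree_predict(tree, block, task)
            for i, j in enumerate(used):
                perm_err = _oob_err(preds[i * m : (i + 1) * m], yo, task)
                imp[j] += perm_err - base_err
    imp /= len(est.estimators_)

    if task == "regression":
        never = pred_cnt == 0
        oob_pred = np.where(never, np.nan, pred_sum / np.maximum(pred_cnt, 1))
        if never.any():  # rare for >= 100 trees; fall back to in-bag prediction
            oob_pred[never] = est.predict(Xm[never])
        oob_error = float(np.mean((oob_pred - y_enc) ** 2))
    else:
        total = votes.sum(axis=1)
        never = total == 0
        abn_col = int(np.flatnonzero(est.classes_ == 1)[0])
        oob_pred = np.where(
            never, np.nan, votes[:, abn_col] / np.maximum(total, 1)
        )
        if never.any():
            oob_pred[never] = est.predict_proba(Xm[never])[:, abn_col]
        oob_error = float(np.mean((oob_pred >= 0.5).astype(int) != y_enc))
    return oob_pred, oob_error, imp


def predict_forest(forest: FittedForest, X_new) -> np.ndarray:
    """Predicted CSF level (regression) or abnormal-class probability (binary)."""
    if isinstance(X_new, pd.DataFrame):
        missing = [c for c in forest.feature_names if c not in X_new.columns]
        if missing:
            raise ValueError(f"X_new lacks training features: {missing}")
        Xm = X_new[forest.feature_names].to_numpy(dtype=float)
    else:
        Xm = np.asarray(X_new, dtype=float)
        if Xm.shape[1] != len(forest.feature_names):
            raise ValueError(
                f"X_new has {Xm.shape[1]} features, expected {len(forest.feature_names)}"
            )
    if forest.spec.task == "regression":
        return forest.estimator.predict(Xm)
    abn_col = int(np.flatnonzero(forest.estimator.classes_ == 1)[0])
    return forest.estimator.predict_proba(Xm)[:, abn_col]


def abnormality_score(forest: FittedForest, X_new) -> np.ndarray:
    """Orientation-fixed score: higher = more likely abnormal.

    Regression forests predict the CSF level, where *low* means abnormal,
    so their predictions are negated; binary forests already emit the
    abnormal-class probability.
    """
    pred = predict_forest(forest, X_new)
    return -pred if forest.spec.task == "regression" else pred


def partial_dependence(
    forest: FittedForest, feature: str, grid: Sequence[float]
) -> np.ndarray:
    """Mean prediction over the training rows with ``feature`` forced to each grid value."""
    if feature not in forest.feature_names:
        raise KeyError(f"unknown feature {feature!r}")
    j = forest.feature_names.index(feature)
    curve = np.empty(len(grid))
    X = forest.X_train.copy()
    for i, v in enumerate(grid):
        X[:, j] = v
        if forest.spec.task == "regression":
            curve[i] = float(np.mean(forest.estimator.predict(X)))
        else:
            abn_col = int(np.flatnonzero(forest.estimator.classes_ == 1)[0])
            curve[i] = float(np.mean(forest.estimator.predict_proba(X)[:, abn_col]))
    return curve
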