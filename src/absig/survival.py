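"""Clinical validation: survival stratification and PET concordance.

A useful amyloid-status predictor must reproduce the clinical behaviour of
the measured status on subjects for whom no CSF is available.  Two
read-outs are implemented: (i) time from baseline MCI to a clinical AD
diagnosis, stratified by predicted status and summarised by Kaplan-Meier
curves, a single-covariate Cox hazard ratio and log-rank tests (including
cross-cohort tests of predicted strata against the measured strata); and
(ii) concordance of the model's continuous scores with PET-derived amyloid
status, dichotomised at tracer-specific SUVR thresholds.

Kaplan-Meier estimation and the log-rank test are delegated to lifelines;
the Cox model is a purpose-built single-binary-covariate partial-likelihood
maximiser with Breslow tie handling, solved by Newton's method with a Wald
confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .cohort import PET_THRESHOLDS, CohortTable
from .cutpoints import roc_auc

TRACER_ORDER = ("PiB", "AV45")  # tie-break preference for same-day scans


@dataclass
class KMCurve:
    """Product-limit curve with 95% bands (Greenwood on the log(-log) scale)."""

    times: np.ndarray
    survival: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    n: int
    n_events: int

    def at(self, t: float) -> float:
        """Survival probability at time ``t`` (step-function convention)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class SurvivalComparison:
    hazard_ratio: float
    hr_ci95: tuple[float, float]
    logrank_stat: float
    logrank_p: float
    km_normal: KMCurve
    km_abnormal: KMCurve
    n_normal: int
    n_abnormal: int


def kaplan_meier(time, event) -> KMCurve:
    """Kaplan-Meier estimator for one stratum.

    With no events the curve is flat at 1.  Confidence bands are the
    log(-log)-transformed Greenwood intervals, clipped to [0, 1].
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    if time.size == 0:
        raise ValueError("empty stratum")
    km = KaplanMeierFitter()
    km.fit(time, event)
    surv = km.survival_function_
    ci = km.confidence_interval_
    return KMCurve(
        times=surv.index.to_numpy(dtype=float),
        survival=surv.iloc[:, 0].to_numpy(dtype=float),
        lower=np.clip(ci.iloc[:, 0].to_numpy(dtype=float), 0, 1),
        upper=np.clip(ci.iloc[:, 1].to_numpy(dtype=float), 0, 1),
        n=int(time.size),
        n_events=int(event.sum()),
    )


def cox_hr(time, event, stratum) -> tuple[float, tuple[float, float]]:
    """Hazard ratio (abnormal vs normal) from a one-covariate Cox model.

    Breslow tie handling; the log partial likelihood is maximised by
    Newton's method and the 95% CI is Wald-based on the observed
    information.  Monotone likelihood (a stratum without events) is
    reported as an error rather than a silently diverging estimate.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    x = np.asarray(stratum).astype(float)
    if set(np.unique(x)) - {0.0, 1.0}:
        raise ValueError("stratum indicator must be binary")
    for grp in (0.0, 1.0):
        if event[x == grp].sum() == 0:
            raise ValueError(
                "no events in one stratum: Cox likelihood is monotone and the HR diverges"
            )

    beta = 0.0
    for _ in range(50):
        score, info = _breslow_score_info(beta, time, event, x)
        if info <= 0:
            break
        step = score / info
        beta += np.clip(step, -5.0, 5.0)
        if abs(step) < 1e-12:
            break
    _, info = _breslow_score_info(beta, time, event, x)
    se = 1.0 / np.sqrt(info)
    hr = float(np.exp(beta))
    ci = (float(np.exp(beta - 1.959963984540054 * se)), float(np.exp(beta + 1.959963984540054 * se)))
    return hr, ci


def breslow_log_partial_likelihood(beta: float, time, event, stratum) -> float:
    """Breslow log partial likelihood of a single binary covariate."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    x = np.asarray(stratum).astype(float)
    ll = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        dead = (time == t) & (event == 1)
        d = int(dead.sum())
        ll += beta * float(x[dead].sum())
        ll -= d * np.log(np.sum(np.exp(beta * x[at_risk])))
    return float(ll)


def _breslow_score_info(beta: float, time, event, x) -> tuple[float, float]:
    score = 0.0
    info = 0.0
    ebx = np.exp(beta * x)
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        dead = (time == t) & (event == 1)
        d = int(dead.sum())
        s0 = float(ebx[at_risk].sum())
        s1 = float((x * ebx)[at_risk].sum())
        mu = s1 / s0
        score += float(x[dead].sum()) - d * mu
        info += d * (mu - mu**2)  # x is binary, so s2 = s1
    return score, info


def logrank_test(time_a, event_a, time_b, event_b) -> tuple[float, float]:
    """Two-group log-rank chi-square statistic (1 df) and p-value.

    With no events in either group the statistic is 0 and p is 1.
    """
    time_a = np.asarray(time_a, dtype=float)
    time_b = np.asarray(time_b, dtype=float)
    event_a = np.asarray(event_a).astype(int)
    event_b = np.asarray(event_b).astype(int)
    if time_a.size == 0 or time_b.size == 0:
        raise ValueError("both groups must be non-empty")
    if event_a.sum() + event_b.sum() == 0:
        return 0.0, 1.0
    res = _ll_logrank(time_a, time_b, event_observed_A=event_a, event_observed_B=event_b)
    return float(res.test_statistic), float(res.p_value)


def compare_strata(records: pd.DataFrame) -> SurvivalComparison:
    """KM curves, Cox HR and log-rank test for a two-stratum survival table.

    ``records`` needs columns ``time``, ``event`` and ``stratum`` (1 =
    predicted/measured abnormal).
    """
    nrm = records[records["stratum"] == 0]
    abn = records[records["stratum"] == 1]
    if len(nrm) == 0 or len(abn) == 0:
        raise ValueError("both strata must be non-empty")
    hr, ci = cox_hr(records["time"], records["event"], records["stratum"])
    stat, p = logrank_test(abn["time"], abn["event"], nrm["time"], nrm["event"])
    return SurvivalComparison(
        hazard_ratio=hr,
        hr_ci95=ci,
        logrank_stat=stat,
        logrank_p=p,
        km_normal=kaplan_meier(nrm["time"], nrm["event"]),
        km_abnormal=kaplan_meier(abn["time"], abn["event"]),
        n_normal=len(nrm),
        n_abnormal=len(abn),
    )


def _survival_records(cohort: CohortTable, status: pd.Series, mci_only: bool = True) -> pd.DataFrame:
    data = cohort.data
    keep = data["diagnosis"] != "AD"
    if mci_only:
        keep &= data["diagnosis"] == "MCI"  # CN subjects are excluded from survival analyses
    keep &= status.notna().to_numpy()
    return pd.DataFrame(
        {
            "subject_id": data.loc[keep, "subject_id"].to_numpy(),
            "time": data.loc[keep, "conversion_months"].to_numpy(dtype=float),
            "event": data.loc[keep, "conversion_event"].to_numpy(dtype=int),
            "stratum": status[keep].to_numpy().astype(int),
        }
    )


def validate_survival_stratification(
    validation_cohort: CohortTable,
    predicted_status: dict[str, pd.Series],
    training_cohort: CohortTable,
) -> dict:
    """The four-way survival validation plus cross-cohort equivalence tests.

    One analysis uses the measured CSF status on the training cohort's MCI
    subjects; one analysis per model in ``predicted_status`` (a mapping
    from model label to a per-subject 0/1 series aligned with the
    validation cohort) uses the predicted status on the validation MCI
    subjects.  For each predicted model, log-rank tests compare its
    predicted-normal stratum with the measured-normal stratum and likewise
    for the abnormal strata.
    """
    actual = _survival_records(training_cohort, training_cohort.csf_status())
    out = {"actual": {"comparison": compare_strata(actual), "records": actual}}
    for label, status in predicted_status.items():
        if status.isna().any():
            raise ValueError(f"model {label!r}: predicted status missing for some subjects")
        rec = _survival_records(validation_cohort, status)
        if (rec["stratum"] == 0).sum() == 0 or (rec["stratum"] == 1).sum() == 0:
            # a model that puts every MCI subject in one stratum cannot be
            # assessed for separation; report it as such instead of failing
            out[label] = {"comparison": None, "records": rec, "equivalence": {}}
            continue
        cmp_ = compare_strata(rec)
        equiv = {}
        for name, flag in (("normal", 0), ("abnormal", 1)):
            a = rec[rec["stratum"] == flag]
            b = actual[actual["stratum"] == flag]
            stat, p = logrank_test(a["time"], a["event"], b["time"], b["event"])
            equiv[name] = {"stat": stat, "p": p}
        out[label] = {"comparison": cmp_, "records": rec, "equivalence": equiv}
    return out


# ---------------------------------------------------------------------------
# PET concordance
# ---------------------------------------------------------------------------


def earliest_pet(pet_records: pd.DataFrame) -> pd.DataFrame:
    """One PET record per subject: the earliest scan, PiB preferred on ties."""
    if pet_records.empty:
        return pet_records.copy()
    rec = pet_records.copy()
    rec["_tracer_rank"] = rec["tracer"].map({t: i for i, t in enumerate(TRACER_ORDER)})
    if rec["_tracer_rank"].isna().any():
        bad = sorted(set(rec.loc[rec["_tracer_rank"].isna(), "tracer"]))
        raise ValueError(f"unknown tracer(s): {bad}")
    rec = rec.sort_values(
        ["subject_id", "months_from_baseline", "_tracer_rank"], kind="stable"
    )
    first = rec.groupby("subject_id", as_index=False).first()
    return first.drop(columns="_tracer_rank")


def pet_status(record) -> int:
    """PET amyloid status from one record: abnormal (1) iff SUVR >= tracer threshold."""
    tracer = record["tracer"]
    if tracer not in PET_THRESHOLDS:
        raise ValueError(f"unknown tracer {tracer!r}")
    return int(float(record["suvr"]) >= PET_THRESHOLDS[tracer])


def pet_status_table(pet_records: pd.DataFrame) -> pd.Series:
    """Per-subject PET status from each subject's earliest scan."""
    first = earliest_pet(pet_records)
    if first.empty:
        return pd.Series(dtype=float)
    status = first.apply(pet_status, axis=1)
    return pd.Series(status.to_numpy(), index=first["subject_id"].to_numpy())


def pet_concordance_auc(scores: pd.Series, pet_records: pd.DataFrame) -> tuple[float, pd.DataFrame]:
    """AUC of model abnormality scores against PET-derived status.

    ``scores`` is indexed by subject_id (higher = more abnormal); only
    subjects with a PET record contribute.  Returns the AUC and the ROC
    step curve of the matched subjects.
    """
    from .crossval import aggregate_roc

    status = pet_status_table(pet_records)
    common = status.index.intersection(scores.index)
    if len(common) == 0:
        raise ValueError("no subjects with both a model score and a PET record")
    y = status.loc[common].to_numpy().astype(int)
    s = scores.loc[common].to_numpy(dtype=float)
    curve, auc = aggregate_roc(s, y)
    return auc, curve
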