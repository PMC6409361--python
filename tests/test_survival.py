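"""Survival analysis and PET concordance."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from absig import (
    GeneratorConfig,
    cox_hr,
    earliest_pet,
    generate_cohort,
    kaplan_meier,
    logrank_test,
    pet_concordance_auc,
    pet_status,
    split_cohorts,
    validate_survival_stratification,
)
from absig.survival import (
    breslow_log_partial_likelihood,
    compare_strata,
    pet_status_table,
)


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------


def test_km_exact_toy_values():
    # four subjects: death at 2 (4 at risk), censor at 3, death at 4
    # (2 at risk), censor at 6 -> S(2) = 3/4, S(4) = 3/4 * 1/2 = 0.375
    curve = kaplan_meier([2, 3, 4, 6], [1, 0, 1, 0])
    assert curve.at(2.0) == pytest.approx(0.75)
    assert curve.at(3.5) == pytest.approx(0.75)
    assert curve.at(4.0) == pytest.approx(0.375)
    assert curve.at(0.0) == pytest.approx(1.0)
    assert curve.n == 4 and curve.n_events == 2


def test_km_no_events_flat():
    curve = kaplan_meier([5, 6, 7], [0, 0, 0])
    assert curve.at(7.0) == pytest.approx(1.0)


def test_km_bands_contain_estimate():
    rng = np.random.default_rng(0)
    t = rng.exponential(50, 80)
    e = (t < 60).astype(int)
    curve = kaplan_meier(np.minimum(t, 60), e)
    assert np.all(curve.lower <= curve.survival + 1e-12)
    assert np.all(curve.upper >= curve.survival - 1e-12)
    assert np.all((0 <= curve.lower) & (curve.upper <= 1))


# ---------------------------------------------------------------------------
# Cox (Breslow ties) against a brute-force likelihood oracle
# ---------------------------------------------------------------------------


def test_cox_matches_likelihood_oracle():
    rng = np.random.default_rng(1)
    for trial in range(5):
        n = 60
        x = rng.integers(0, 2, n)
        t = rng.exponential(1.0 / (0.05 * np.exp(0.9 * x)))
        e = (t < 30).astype(int)
        t = np.round(np.minimum(t, 30), 0) + 1  # force ties
        if e[x == 1].sum() == 0 or e[x == 0].sum() == 0:
            continue
        hr, (lo, hi) = cox_hr(t, e, x)
        res = optimize.minimize_scalar(
            lambda b: -breslow_log_partial_likelihood(b, t, e, x),
            bounds=(-5, 5), method="bounded",
            options={"xatol": 1e-10},
        )
        assert np.log(hr) == pytest.approx(res.x, abs=1e-6)
        assert lo < hr < hi


def test_cox_recovers_true_hazard_ratio():
    rng = np.random.default_rng(2)
    n = 4000
    x = rng.integers(0, 2, n)
    t = rng.exponential(1.0 / (0.01 * np.exp(np.log(3.0) * x)))
    e = (t < 120).astype(int)
    hr, (lo, hi) = cox_hr(np.minimum(t, 120), e, x)
    assert hr == pytest.approx(3.0, rel=0.15)
    assert lo < 3.0 < hi


def test_cox_monotone_likelihood_raises():
    # no events among the exposed: beta diverges
    t = np.array([1.0, 2.0, 3.0, 4.0])
    e = np.array([1, 1, 0, 0])
    x = np.array([0, 0, 1, 1])
    with pytest.raises(ValueError):
        cox_hr(t, e, x)


# ---------------------------------------------------------------------------
# log-rank
# ---------------------------------------------------------------------------


def test_logrank_identical_groups_null():
    rng = np.random.default_rng(3)
    t = rng.exponential(30, 100)
    e = (t < 40).astype(int)
    stat, p = logrank_test(np.minimum(t, 40), e, np.minimum(t, 40), e)
    assert stat == pytest.approx(0.0, abs=1e-9)
    assert p == pytest.approx(1.0, abs=1e-9)


def test_logrank_detects_separation():
    rng = np.random.default_rng(4)
    ta = rng.exponential(10, 80)
    tb = rng.exponential(40, 80)
    stat, p = logrank_test(ta, np.ones(80, int), tb, np.ones(80, int))
    assert p < 1e-6


def test_logrank_no_events():
    stat, p = logrank_test([5, 6], [0, 0], [4, 7], [0, 0])
    assert (stat, p) == (0.0, 1.0)
    with pytest.raises(ValueError):
        logrank_test([], [], [1], [1])


def test_compare_strata_structure():
    rng = np.random.default_rng(5)
    n = 120
    stratum = rng.integers(0, 2, n)
    t = rng.exponential(1.0 / (0.01 * np.exp(1.2 * stratum)))
    rec = pd.DataFrame({
        "time": np.minimum(t, 120),
        "event": (t < 120).astype(int),
        "stratum": stratum,
    })
    cmp_ = compare_strata(rec)
    assert cmp_.hazard_ratio > 1
    assert cmp_.logrank_p < 0.05
    assert cmp_.n_normal + cmp_.n_abnormal == n
    with pytest.raises(ValueError):
        compare_strata(rec.assign(stratum=1))


# ---------------------------------------------------------------------------
# end-to-end survival validation on a synthetic cohort
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def survival_cohort():
    cfg = GeneratorConfig(
        n_subjects=500, n_validation=200, n_protein_analytes=8,
        n_metabolite_analytes=0, missing_rate=0.0, seed=44,
    )
    return split_cohorts(generate_cohort(cfg))


def test_validate_survival_stratification(survival_cohort):
    training, validation = survival_cohort
    truth = validation.truth.set_index("subject_id")["true_abnormal"]
    predicted = pd.Series(
        truth.loc[validation.data["subject_id"]].to_numpy(),
        index=validation.data.index,
    )
    out = validate_survival_stratification(validation, {"oracle": predicted}, training)
    # measured status is a noisy proxy of the true status that drives the
    # hazard, so only direction is asserted here; power is covered by the
    # acceptance tests at full size
    assert out["actual"]["comparison"].hazard_ratio > 1
    assert out["oracle"]["comparison"].logrank_p < 0.05
    assert out["oracle"]["comparison"].hazard_ratio > 1
    assert set(out["oracle"]["equivalence"]) == {"normal", "abnormal"}
    # survival records come from MCI subjects only
    rec = out["oracle"]["records"]
    mci_ids = set(validation.data.loc[validation.data["diagnosis"] == "MCI", "subject_id"])
    assert set(rec["subject_id"]) <= mci_ids


def test_validate_survival_single_stratum_degrades(survival_cohort):
    training, validation = survival_cohort
    all_abn = pd.Series(1, index=validation.data.index)
    out = validate_survival_stratification(validation, {"m": all_abn}, training)
    assert out["m"]["comparison"] is None


# ---------------------------------------------------------------------------
# PET
# ---------------------------------------------------------------------------


def test_pet_status_thresholds():
    assert pet_status({"tracer": "PiB", "suvr": 1.5}) == 1
    assert pet_status({"tracer": "PiB", "suvr": 1.499}) == 0
    assert pet_status({"tracer": "AV45", "suvr": 1.11}) == 1
    assert pet_status({"tracer": "AV45", "suvr": 1.109}) == 0
    with pytest.raises(ValueError):
        pet_status({"tracer": "FDG", "suvr": 1.0})


def test_earliest_pet_prefers_pib_on_ties():
    rec = pd.DataFrame({
        "subject_id": ["s1", "s1", "s2", "s2"],
        "tracer": ["AV45", "PiB", "AV45", "PiB"],
        "suvr": [1.2, 1.6, 1.0, 1.4],
        "months_from_baseline": [6.0, 6.0, 3.0, 12.0],
    })
    first = earliest_pet(rec)
    s1 = first[first["subject_id"] == "s1"].iloc[0]
    s2 = first[first["subject_id"] == "s2"].iloc[0]
    assert s1["tracer"] == "PiB"  # tie on time: PiB preferred
    assert s2["tracer"] == "AV45"  # earliest scan wins
    with pytest.raises(ValueError):
        earliest_pet(rec.assign(tracer="XX"))


def test_pet_status_table_and_auc():
    rec = pd.DataFrame({
        "subject_id": ["a", "b", "c", "d"],
        "tracer": ["PiB", "PiB", "AV45", "AV45"],
        "suvr": [1.8, 1.2, 1.3, 0.9],
        "months_from_baseline": [0.0, 0.0, 0.0, 0.0],
    })
    status = pet_status_table(rec)
    assert status.to_dict() == {"a": 1, "b": 0, "c": 1, "d": 0}
    scores = pd.Series({"a": 0.9, "b": 0.1, "c": 0.8, "d": 0.2})
    auc, curve = pet_concordance_auc(scores, rec)
    assert auc == 1.0
    with pytest.raises(ValueError):
        pet_concordance_auc(pd.Series({"zz": 1.0}), rec)
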