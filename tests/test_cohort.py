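"""Synthetic cohort generator: determinism, calibration, structure, IO."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from absig import (
    CLINICAL_THRESHOLD,
    GeneratorConfig,
    InformativeFeature,
    binormal_auc,
    generate_cohort,
    inject_missingness,
    load_cohort,
    split_cohorts,
    write_cohort,
)
from absig.cohort import config_from_dict, config_to_dict


def test_same_seed_identical(small_config):
    a = generate_cohort(small_config)
    b = generate_cohort(small_config)
    pd.testing.assert_frame_equal(a.data, b.data)
    pd.testing.assert_frame_equal(a.pet, b.pet)
    pd.testing.assert_frame_equal(a.truth, b.truth)


def test_different_seed_differs(small_config):
    import dataclasses

    other = dataclasses.replace(small_config, seed=small_config.seed + 1)
    a = generate_cohort(small_config)
    b = generate_cohort(other)
    assert not a.data["csf_ab42"].equals(b.data["csf_ab42"])


def test_default_shape(default_config):
    c = generate_cohort(default_config)
    assert c.n_subjects == 566
    assert len(c.protein_cols) == 149
    assert len(c.metabolite_cols) == 138
    training, validation = split_cohorts(c)
    assert training.n_subjects == 566 - 210
    assert validation.n_subjects == 210
    assert validation.data["csf_ab42"].isna().all()
    assert training.data["csf_ab42"].notna().all()
    # the validation arm is MCI by construction
    assert (validation.data["diagnosis"] == "MCI").all()


def test_prevalence_near_calibrated_value():
    cfg = GeneratorConfig(
        n_subjects=6000, n_validation=0, n_protein_analytes=10,
        n_metabolite_analytes=0, missing_rate=0.0, seed=101,
    )
    c = generate_cohort(cfg)
    prev = c.csf_status().mean()
    assert abs(prev - 0.674) < 0.03


def test_uninformative_analytes_uncorrelated_with_level():
    cfg = GeneratorConfig(
        n_subjects=5000, n_validation=0, n_protein_analytes=10,
        n_metabolite_analytes=5, missing_rate=0.0, seed=17,
    )
    c = generate_cohort(cfg)
    informative = {f.name for f in cfg.informative_features}
    noise = [a for a in c.analyte_cols if a not in informative]
    level = c.data["csf_ab42"]
    for a in noise[:8]:
        r = np.corrcoef(c.data[a], level)[0, 1]
        assert abs(r) < 0.05, f"{a} correlates with the level (r={r:.3f})"


def test_informative_analytes_carry_signal():
    cfg = GeneratorConfig(
        n_subjects=5000, n_validation=0, n_protein_analytes=10,
        n_metabolite_analytes=0, missing_rate=0.0, seed=18,
    )
    c = generate_cohort(cfg)
    level = c.data["csf_ab42"]
    for f in cfg.informative_features:
        r = np.corrcoef(c.data[f.name], level)[0, 1]
        assert np.sign(r) == f.effect_sign
        assert abs(r) > 0.1


def test_carrier_lowers_level():
    cfg = GeneratorConfig(
        n_subjects=4000, n_validation=0, n_protein_analytes=6,
        n_metabolite_analytes=0, missing_rate=0.0, seed=19,
    )
    c = generate_cohort(cfg)
    carrier = c.data["apoe4_carrier"] == 1
    diff = c.data.loc[carrier, "csf_ab42"].mean() - c.data.loc[~carrier, "csf_ab42"].mean()
    assert diff == pytest.approx(cfg.apoe4_effect, abs=4.0)


def test_binormal_discriminability_of_latent_score():
    """Carrier-only design: AUC of the latent group difference matches the
    closed-form binormal value Phi(delta / (sqrt(2) * sigma))."""
    cfg = GeneratorConfig(
        n_subjects=60000, n_validation=0, n_protein_analytes=2,
        n_metabolite_analytes=0,
        informative_features=(),
        apoe4_effect=-28.0, csf_sd=27.0, missing_rate=0.0, seed=23,
    )
    c = generate_cohort(cfg)
    carrier = c.data["apoe4_carrier"].to_numpy() == 1
    level = c.data["csf_ab42"].to_numpy()
    # carriers sit 28 pg/ml lower on average; empirical AUC of (non-carrier
    # level > carrier level) should match the binormal formula
    u = stats.mannwhitneyu(level[~carrier], level[carrier], alternative="greater")
    n1, n0 = carrier.sum(), (~carrier).sum()
    emp_auc = u.statistic / (n1 * n0)
    assert emp_auc == pytest.approx(binormal_auc(28.0, 27.0), abs=0.01)


def test_binormal_auc_closed_form():
    assert binormal_auc(0.0, 1.0) == pytest.approx(0.5)
    assert binormal_auc(2.0, 1.0) == pytest.approx(stats.norm.cdf(2 / np.sqrt(2)))
    assert binormal_auc(1e9, 1.0) == pytest.approx(1.0)


def test_status_threshold_strictly_below(small_cohort):
    level = small_cohort.data["csf_ab42"]
    status = small_cohort.csf_status()
    measured = level.notna()
    expected = level[measured] < CLINICAL_THRESHOLD
    assert (status[measured].astype(bool) == expected).all()
    assert status[~measured].isna().all()


def test_truth_matches_observed_training_levels(small_cohort):
    merged = small_cohort.data.merge(small_cohort.truth, on="subject_id")
    measured = merged["csf_ab42"].notna()
    assert np.allclose(
        merged.loc[measured, "csf_ab42"], merged.loc[measured, "csf_ab42_full"]
    )


def test_pet_discordance_rate():
    cfg = GeneratorConfig(
        n_subjects=8000, n_validation=0, n_protein_analytes=4,
        n_metabolite_analytes=0, missing_rate=0.0, pet_fraction=1.0, seed=31,
    )
    c = generate_cohort(cfg)
    t = c.truth.dropna(subset=["pet_abnormal"])
    disc = (t["pet_abnormal"] != t["true_abnormal"]).mean()
    assert disc == pytest.approx(7 / 108, abs=0.015)


def test_pet_suvr_sides():
    from absig.cohort import PET_THRESHOLDS

    cfg = GeneratorConfig(
        n_subjects=2000, n_validation=0, n_protein_analytes=4,
        n_metabolite_analytes=0, missing_rate=0.0, pet_fraction=1.0, seed=37,
    )
    c = generate_cohort(cfg)
    pet = c.pet.merge(c.truth[["subject_id", "pet_abnormal"]], on="subject_id")
    thr = pet["tracer"].map(PET_THRESHOLDS)
    abn = pet["pet_abnormal"] == 1
    assert (pet.loc[abn, "suvr"] >= thr[abn]).all()
    assert (pet.loc[~abn, "suvr"] < thr[~abn]).all()


def test_baseline_ad_converts_at_time_zero(small_cohort):
    ad = small_cohort.data["diagnosis"] == "AD"
    if ad.any():
        assert (small_cohort.data.loc[ad, "conversion_months"] == 0).all()
        assert (small_cohort.data.loc[ad, "conversion_event"] == 1).all()


def test_censoring_at_followup(small_cohort, small_config):
    d = small_cohort.data
    assert (d["conversion_months"] <= small_config.followup_months).all()
    censored = d["conversion_event"] == 0
    assert (d.loc[censored, "conversion_months"] == small_config.followup_months).all()


def test_abnormal_converts_faster():
    cfg = GeneratorConfig(
        n_subjects=6000, n_validation=0, n_protein_analytes=4,
        n_metabolite_analytes=0, missing_rate=0.0, seed=41,
    )
    c = generate_cohort(cfg)
    t = c.data.merge(c.truth, on="subject_id")
    mci = t["diagnosis"] == "MCI"
    rate_abn = t.loc[mci & (t["true_abnormal"] == 1), "conversion_event"].mean()
    rate_nrm = t.loc[mci & (t["true_abnormal"] == 0), "conversion_event"].mean()
    assert rate_abn > rate_nrm * 1.5


def test_inject_missingness_scalar(small_cohort):
    out = inject_missingness(small_cohort, 0.25, seed=5)
    frac = out.analytes.isna().mean().mean()
    assert frac == pytest.approx(0.25, abs=0.04)
    # non-analyte columns untouched
    pd.testing.assert_series_equal(out.data["csf_ab42"], small_cohort.data["csf_ab42"])


def test_inject_missingness_per_analyte(small_cohort):
    name = small_cohort.protein_cols[0]
    out = inject_missingness(small_cohort, {name: 0.5}, seed=5)
    assert out.data[name].isna().mean() == pytest.approx(0.5, abs=0.12)
    other = small_cohort.protein_cols[1]
    assert out.data[other].notna().all()


def test_inject_missingness_validates(small_cohort):
    with pytest.raises(KeyError):
        inject_missingness(small_cohort, {"no_such_analyte": 0.1}, seed=0)
    with pytest.raises(ValueError):
        inject_missingness(small_cohort, {small_cohort.protein_cols[0]: 1.5}, seed=0)


def test_roundtrip_io(tmp_path, small_cohort):
    path = write_cohort(small_cohort, tmp_path / "cohort")
    loaded = load_cohort(path)
    pd.testing.assert_frame_equal(loaded.data, small_cohort.data)
    pd.testing.assert_frame_equal(loaded.pet, small_cohort.pet)
    pd.testing.assert_frame_equal(loaded.truth, small_cohort.truth)
    assert loaded.protein_cols == small_cohort.protein_cols
    assert loaded.metabolite_cols == small_cohort.metabolite_cols
    assert loaded.clinical_threshold == small_cohort.clinical_threshold


def test_config_roundtrip(small_config):
    assert config_from_dict(config_to_dict(small_config)) == small_config


def test_config_validation():
    with pytest.raises(ValueError):
        GeneratorConfig(n_subjects=5)
    with pytest.raises(ValueError):
        GeneratorConfig(n_validation=600)
    with pytest.raises(ValueError):
        GeneratorConfig(missing_rate=1.5)
    with pytest.raises(ValueError):
        InformativeFeature("x", 0, 1.0)
    with pytest.raises(ValueError):
        InformativeFeature("x", 1, -2.0)


def test_split_requires_training_arm(small_cohort):
    data = small_cohort.data.copy()
    data["csf_ab42"] = np.nan
    with pytest.raises(ValueError):
        split_cohorts(small_cohort.with_data(data))
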