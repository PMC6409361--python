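"""Synthetic cohorts with the statistical structure of an amyloid biomarker study.

The generator draws per-subject blood analyte panels (proteins and
metabolites), an APOEε4 carrier flag and age, and ties a latent continuous
CSF Aβ1-42 level (pg/ml) to a small set of informative analytes among many
pure-noise ones.  Dichotomising the latent level at a clinical threshold
yields the abnormal/normal amyloid status that drives two clinical
read-outs: a PET amyloid status that agrees with the CSF status up to a
small discordance rate, and an exponential time-to-AD-conversion whose
hazard is elevated for abnormal subjects.

A cohort is split into a *training* arm (continuous CSF available) and a
*validation* arm (CSF withheld), mirroring the design in which models are
built where lumbar punctures were performed and validated where they were
not.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._seeds import derive_seed

#: Luminex clinical threshold on CSF Aβ1-42 (pg/ml); below = abnormal.
CLINICAL_THRESHOLD = 192.0

#: Tracer-specific SUVR thresholds for PET amyloid abnormality.
PET_THRESHOLDS = {"PiB": 1.5, "AV45": 1.11}

#: Arbitrary-unit location/scale on which analytes are simulated.
_ANALYTE_MEAN = 100.0
_ANALYTE_SD = 15.0

# Baseline-diagnosis mixture conditional on true CSF status, for subjects
# in the training arm.  Abnormal amyloid is heavily enriched in MCI/AD.
_DIAG_GIVEN_NORMAL = {"CN": 0.50, "MCI": 0.45, "AD": 0.05}
_DIAG_GIVEN_ABNORMAL = {"CN": 0.0, "MCI": 0.61, "AD": 0.39}

NON_ANALYTE_COLUMNS = (
    "subject_id",
    "age",
    "apoe4_carrier",
    "diagnosis",
    "csf_ab42",
    "conversion_months",
    "conversion_event",
)


@dataclass(frozen=True)
class InformativeFeature:
    """An analyte that contributes to the latent CSF level.

    ``effect_size`` is expressed in latent-CSF pg/ml per standard deviation
    of the analyte; ``effect_sign`` is +1 or -1.
    """

    name: str
    effect_sign: int
    effect_size: float

    def __post_init__(self) -> None:
        if self.effect_sign not in (-1, 1):
            raise ValueError("effect_sign must be +1 or -1")
        if not np.isfinite(self.effect_size) or self.effect_size < 0:
            raise ValueError(f"effect_size for {self.name!r} must be finite and >= 0")


def _default_informative() -> tuple[InformativeFeature, ...]:
    # Effect signs follow the known directions of the four plasma markers
    # most associated with CSF amyloid: chromogranin A, plasma Aβ1-42 and
    # apolipoprotein E positive, eotaxin-3 negative.  Magnitudes are
    # calibrated so the oracle linear score separates statuses with
    # AUC ~ 0.85 under the default noise level.
    return (
        InformativeFeature("CGA", +1, 14.0),
        InformativeFeature("AB42", +1, 12.0),
        InformativeFeature("APOE", +1, 10.0),
        InformativeFeature("Eotaxin3", -1, 12.0),
    )


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic cohort generator.

    Defaults reproduce the headline structure of the source cohort: 566
    subjects of whom 210 lack CSF, 149 protein and 138 metabolite analytes,
    dichotomisation at 192 pg/ml, an abnormal prevalence near 0.674 in the
    CSF arm, PET/CSF discordance near 7/108, and a 120-month conversion
    follow-up.
    """

    n_subjects: int = 566
    n_validation: int = 210
    n_protein_analytes: int = 149
    n_metabolite_analytes: int = 138
    informative_features: tuple[InformativeFeature, ...] = field(
        default_factory=_default_informative
    )
    apoe4_effect: float = -28.0
    carrier_prevalence: float = 0.5
    csf_mean: float = 188.5
    csf_sd: float = 27.0
    clinical_threshold: float = CLINICAL_THRESHOLD
    pet_fraction: float = 0.31
    pet_discordance_rate: float = 7.0 / 108.0
    hazard_rate_normal: float = 0.003
    hazard_ratio_abnormal: float = 3.0
    followup_months: float = 120.0
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 20:
            raise ValueError("n_subjects must be >= 20 (too small for any CV plan)")
        if not (0 <= self.n_validation < self.n_subjects):
            raise ValueError("n_validation must be in [0, n_subjects)")
        if self.clinical_threshold <= 0:
            raise ValueError("clinical_threshold must be positive")
        if self.hazard_ratio_abnormal <= 0:
            raise ValueError("hazard_ratio_abnormal must be positive")
        if self.hazard_rate_normal < 0:
            raise ValueError("hazard_rate_normal must be non-negative")
        for name, value in [
            ("carrier_prevalence", self.carrier_prevalence),
            ("pet_fraction", self.pet_fraction),
            ("pet_discordance_rate", self.pet_discordance_rate),
            ("missing_rate", self.missing_rate),
        ]:
            if not 0 <= value <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        feats = tuple(
            f if isinstance(f, InformativeFeature) else InformativeFeature(*f)
            for f in self.informative_features
        )
        object.__setattr__(self, "informative_features", feats)
        names = [f.name for f in feats]
        if len(set(names)) != len(names):
            raise ValueError("informative feature names must be unique")
        total = self.n_protein_analytes + self.n_metabolite_analytes
        if len(names) > total:
            raise ValueError("more informative features than analytes")
        for f in feats:
            if not np.isfinite(f.effect_size):
                raise ValueError("effect sizes must be finite")


@dataclass
class CohortTable:
    """A per-subject cohort with analytes, outcomes and PET records.

    ``data`` holds one row per subject: identifiers, covariates, analyte
    levels (NaN = missing), the continuous CSF Aβ1-42 level where measured,
    the baseline diagnosis and the conversion outcome.  ``pet`` is a
    long-format table of PET scans.  ``truth`` (synthetic cohorts only)
    records the latent level and true statuses used to generate the data.
    """

    data: pd.DataFrame
    protein_cols: list[str]
    metabolite_cols: list[str]
    pet: pd.DataFrame
    clinical_threshold: float = CLINICAL_THRESHOLD
    truth: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.data["subject_id"].duplicated().any():
            raise ValueError("subject_id must be unique")
        missing = [c for c in NON_ANALYTE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"cohort table lacks required columns: {missing}")
        if (self.data["conversion_months"] < 0).any():
            raise ValueError("conversion_months must be non-negative")

    @property
    def analyte_cols(self) -> list[str]:
        return list(self.protein_cols) + list(self.metabolite_cols)

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    @property
    def analytes(self) -> pd.DataFrame:
        """The subjects × analytes matrix (NaN = missing)."""
        return self.data[self.analyte_cols]

    def csf_status(self) -> pd.Series:
        """Observed amyloid status: True where CSF Aβ1-42 < threshold."""
        level = self.data["csf_ab42"]
        return pd.Series(
            np.where(level.isna(), np.nan, (level < self.clinical_threshold)),
            index=level.index,
            name="csf_abnormal",
        )

    def with_data(self, data: pd.DataFrame) -> "CohortTable":
        truth = None
        if self.truth is not None:
            truth = self.truth[
                self.truth["subject_id"].isin(data["subject_id"])
            ].reset_index(drop=True)
        pet = self.pet[self.pet["subject_id"].isin(data["subject_id"])].reset_index(
            drop=True
        )
        return CohortTable(
            data=data.reset_index(drop=True),
            protein_cols=list(self.protein_cols),
            metabolite_cols=list(self.metabolite_cols),
            pet=pet,
            clinical_threshold=self.clinical_threshold,
            truth=truth,
        )


def binormal_auc(delta: float, sigma: float) -> float:
    """AUC of an equal-variance two-group Gaussian score: Φ(Δ / √(2σ²))."""
    return float(norm.cdf(delta / np.sqrt(2.0 * sigma**2)))


def _analyte_names(config: GeneratorConfig) -> tuple[list[str], list[str]]:
    info = [f.name for f in config.informative_features]
    proteins = list(info[: config.n_protein_analytes])
    proteins += [
        f"prot_{i:03d}" for i in range(len(proteins) + 1, config.n_protein_analytes + 1)
    ]
    overflow = info[config.n_protein_analytes :]
    metabolites = list(overflow)
    metabolites += [
        f"metab_{i:03d}"
        for i in range(len(metabolites) + 1, config.n_metabolite_analytes + 1)
    ]
    return proteins, metabolites


def _draw_diagnosis(rng: np.random.Generator, abnormal: np.ndarray) -> np.ndarray:
    labels = np.array(["CN", "MCI", "AD"])
    p_nrm = np.array([_DIAG_GIVEN_NORMAL[d] for d in labels])
    p_abn = np.array([_DIAG_GIVEN_ABNORMAL[d] for d in labels])
    u = rng.random(abnormal.shape[0])
    probs = np.where(abnormal[:, None], p_abn[None, :], p_nrm[None, :])
    cum = probs.cumsum(axis=1)
    idx = (u[:, None] > cum).sum(axis=1)
    return labels[idx]


def generate_cohort(config: GeneratorConfig) -> CohortTable:
    """Simulate a cohort under ``config``; fully reproducible from its seed.

    The latent CSF level is
    ``csf_mean + apoe4_effect·carrier + Σ_j sign_j·size_j·z_j + N(0, csf_sd)``
    with ``z_j`` the standardised informative analytes.  True status is
    ``level < clinical_threshold`` (strictly below).  PET status equals the
    CSF status except for a Bernoulli(pet_discordance_rate) flip, with SUVR
    drawn in a half-unit band on the matching side of the tracer threshold.
    Conversion times are exponential with hazard
    ``hazard_rate_normal · hazard_ratio_abnormal^status``, administratively
    censored at ``followup_months``.
    """
    rng = np.random.default_rng(derive_seed(config.seed, "cohort"))
    n = config.n_subjects
    proteins, metabolites = _analyte_names(config)
    analyte_names = proteins + metabolites

    raw = rng.normal(_ANALYTE_MEAN, _ANALYTE_SD, size=(n, len(analyte_names)))
    analytes = pd.DataFrame(raw, columns=analyte_names)

    latent = np.full(n, config.csf_mean)
    for f in config.informative_features:
        z = (analytes[f.name].to_numpy() - _ANALYTE_MEAN) / _ANALYTE_SD
        latent = latent + f.effect_sign * f.effect_size * z
    carrier = (rng.random(n) < config.carrier_prevalence).astype(int)
    latent = latent + config.apoe4_effect * carrier
    level = latent + rng.normal(0.0, config.csf_sd, n)
    abnormal = level < config.clinical_threshold

    age = np.clip(rng.normal(74.7, 7.5, n), 55.0, 90.0).round(1)

    # validation arm: CSF withheld; all MCI by construction, since the
    # clinical validation is run on MCI subjects.
    validation_idx = rng.choice(n, size=config.n_validation, replace=False)
    is_validation = np.zeros(n, dtype=bool)
    is_validation[validation_idx] = True
    diagnosis = _draw_diagnosis(rng, abnormal)
    diagnosis[is_validation] = "MCI"

    csf = level.round(2).astype(float)
    csf[is_validation] = np.nan

    # conversion to AD: subjects already AD at baseline convert at time 0
    hazard = config.hazard_rate_normal * np.where(
        abnormal, config.hazard_ratio_abnormal, 1.0
    )
    with np.errstate(divide="ignore"):
        t = rng.exponential(1.0, n) / np.where(hazard > 0, hazard, np.inf)
    event = (t <= config.followup_months).astype(int)
    months = np.minimum(t, config.followup_months).round(1)
    baseline_ad = diagnosis == "AD"
    months[baseline_ad] = 0.0
    event[baseline_ad] = 1

    data = pd.DataFrame(
        {
            "subject_id": [f"S{i:04d}" for i in range(1, n + 1)],
            "age": age,
            "apoe4_carrier": carrier,
            "diagnosis": diagnosis,
            "csf_ab42": csf,
            "conversion_months": months,
            "conversion_event": event,
        }
    )
    data = pd.concat([data, analytes.round(4)], axis=1)

    # PET records for a subset of subjects
    has_pet = rng.random(n) < config.pet_fraction
    flip = rng.random(n) < config.pet_discordance_rate
    pet_abnormal = abnormal ^ flip
    pet_rows = []
    for i in np.flatnonzero(has_pet):
        n_rec = int(rng.integers(1, 3))
        months_seen = np.sort(rng.uniform(0.0, 72.0, n_rec).round(1))
        for m in months_seen:
            tracer = "PiB" if rng.random() < 0.5 else "AV45"
            thr = PET_THRESHOLDS[tracer]
            if pet_abnormal[i]:
                suvr = rng.uniform(thr, thr + 0.5)
            else:
                suvr = rng.uniform(thr - 0.5, thr)
            pet_rows.append((data.loc[i, "subject_id"], tracer, round(suvr, 3), m))
    pet = pd.DataFrame(
        pet_rows, columns=["subject_id", "tracer", "suvr", "months_from_baseline"]
    )

    truth = pd.DataFrame(
        {
            "subject_id": data["subject_id"],
            "latent_csf": latent.round(4),
            "csf_ab42_full": level.round(2),
            "true_abnormal": abnormal.astype(int),
            "pet_abnormal": np.where(has_pet, pet_abnormal.astype(float), np.nan),
        }
    )

    table = CohortTable(
        data=data,
        protein_cols=proteins,
        metabolite_cols=metabolites,
        pet=pet,
        clinical_threshold=config.clinical_threshold,
        truth=truth,
    )
    if config.missing_rate > 0:
        table = inject_missingness(
            table, config.missing_rate, seed=derive_seed(config.seed, "missing")
        )
    return table


def inject_missingness(
    table: CohortTable,
    per_analyte_rates: Mapping[str, float] | float,
    seed: int,
) -> CohortTable:
    """Blank analyte cells completely at random (MCAR) at the given rates.

    ``per_analyte_rates`` is either a single rate applied to every analyte
    or a mapping from analyte name to rate; analytes absent from the
    mapping are untouched.  Non-analyte columns are never modified.
    """
    if isinstance(per_analyte_rates, (int, float)):
        rates = {c: float(per_analyte_rates) for c in table.analyte_cols}
    else:
        rates = {str(k): float(v) for k, v in per_analyte_rates.items()}
    for name, rate in rates.items():
        if not 0 <= rate <= 1:
            raise ValueError(f"missingness rate for {name!r} outside [0, 1]")
        if name not in table.analyte_cols:
            raise KeyError(f"unknown analyte {name!r}")
    rng = np.random.default_rng(seed)
    data = table.data.copy()
    for name in table.analyte_cols:  # fixed iteration order for determinism
        rate = rates.get(name)
        if not rate:
            continue
        mask = rng.random(len(data)) < rate
        data.loc[mask, name] = np.nan
    return table.with_data(data)


def split_cohorts(table: CohortTable) -> tuple[CohortTable, CohortTable]:
    """Partition into (training = CSF measured, validation = CSF absent)."""
    has_csf = table.data["csf_ab42"].notna()
    if not has_csf.any():
        raise ValueError("training cohort would be empty: no subject has CSF")
    if has_csf.all():
        warnings.warn("validation cohort is empty: every subject has CSF")
    training = table.with_data(table.data[has_csf])
    validation = table.with_data(table.data[~has_csf])
    return training, validation


# ---------------------------------------------------------------------------
# Serialisation: cohort CSV + long-format PET CSV + JSON metadata sidecar.
# ---------------------------------------------------------------------------


def write_cohort(table: CohortTable, directory: str | Path) -> Path:
    """Write a cohort as plain-text files under ``directory``.

    Files: ``cohort.csv`` (one row per subject, empty cell = missing),
    ``pet.csv`` (long format), ``meta.json`` (column classification and
    clinical threshold) and, for synthetic cohorts, ``truth.csv``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    table.data.to_csv(directory / "cohort.csv", index=False)
    table.pet.to_csv(directory / "pet.csv", index=False)
    meta = {
        "protein_cols": list(table.protein_cols),
        "metabolite_cols": list(table.metabolite_cols),
        "clinical_threshold": table.clinical_threshold,
    }
    (directory / "meta.json").write_text(json.dumps(meta, indent=2))
    if table.truth is not None:
        table.truth.to_csv(directory / "truth.csv", index=False)
    return directory


def load_cohort(directory: str | Path) -> CohortTable:
    """Read a cohort written by :func:`write_cohort`."""
    directory = Path(directory)
    meta = json.loads((directory / "meta.json").read_text())
    data = pd.read_csv(directory / "cohort.csv")
    missing = [c for c in NON_ANALYTE_COLUMNS if c not in data.columns]
    if missing:
        raise ValueError(f"cohort.csv lacks required columns: {missing}")
    pet_path = directory / "pet.csv"
    if pet_path.exists():
        pet = pd.read_csv(pet_path)
        if pet.empty:
            pet = _empty_pet()
    else:
        pet = _empty_pet()
    truth_path = directory / "truth.csv"
    truth = pd.read_csv(truth_path) if truth_path.exists() else None
    return CohortTable(
        data=data,
        protein_cols=list(meta["protein_cols"]),
        metabolite_cols=list(meta["metabolite_cols"]),
        pet=pet,
        clinical_threshold=float(meta["clinical_threshold"]),
        truth=truth,
    )


def _empty_pet() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["subject_id", "tracer", "suvr", "months_from_baseline"]
    )


def config_to_dict(config: GeneratorConfig) -> dict:
    d = dataclasses.asdict(config)
    d["informative_features"] = [
        [f.name, f.effect_sign, f.effect_size] for f in config.informative_features
    ]
    return d


def config_from_dict(d: Mapping) -> GeneratorConfig:
    d = dict(d)
    if "informative_features" in d:
        d["informative_features"] = tuple(
            InformativeFeature(name, int(sign), float(size))
            for name, sign, size in d["informative_features"]
        )
    return GeneratorConfig(**d)
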