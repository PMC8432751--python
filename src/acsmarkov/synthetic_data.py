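"""Seeded synthetic claims-style cohorts with known ground truth.

Emulates the merged structure of state Medicaid claims, an ACS referral
registry, and vital-statistics death records for a hospitalized-OUD
cohort: a patient table with demographic and clinical covariates, an
admissions table with ICD diagnosis codes, a pharmacy-fill table, and a
death table with underlying-cause codes.  Referral, post-discharge
treatment engagement, and 12-month death are drawn from logistic models
with user-supplied true coefficients, and the event tables are constructed
so that the claims-based classifiers in :mod:`acsmarkov.cohort_measures`
recover the latent truth exactly.  Identical config and seed give
identical output.

Covariate marginals default to the observed cohort: mean age 44.5 (SD
15.4, truncated at 18), 43% male, 70.1% White / 6.4% not White / 23.5%
unknown race, 3.5% Hispanic, 3.6% alcohol and 8.2% stimulant use disorder,
mean length of stay 6.6 days (log-normal), 26.4% rural, 17.8% with a MOUD
fill in the month before admission, 22.4% previously admitted, and a
gamma-distributed CDPS score with mean 2.5 (SD 1.6).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from acsmarkov.errors import ConfigurationError, DataError
from acsmarkov.model_design import design_matrix, model_terms
from acsmarkov.timebase import WINDOW_END_DAY

__all__ = [
    "SimConfig",
    "SyntheticCohort",
    "default_covariate_params",
    "default_true_coefficients",
    "generate_cohort",
    "generate_expert_responses",
    "write_cohort",
    "read_cohort",
]

#: Underlying-cause ICD-10 codes used for drug-related deaths
#: (accidental/intentional/undetermined poisoning).
DRUG_CAUSE_CODES = ("X42", "X44", "X41", "X61", "X64", "Y12", "X85")

#: Non-drug causes spanning the circulatory / neoplasm / infectious /
#: digestive / external / respiratory categories.
NONDRUG_CAUSE_CODES = ("I219", "C349", "A419", "K703", "V031", "J189", "E119")

_PROPORTION_PARAMS = (
    "p_male",
    "p_white",
    "p_not_white",
    "p_hispanic",
    "p_aud",
    "p_stud",
    "p_rural",
    "p_moud_at_admission",
    "p_prior_admission",
    "p_naloxone_30d",
)


def default_covariate_params() -> dict[str, float]:
    return {
        "age_mean": 44.5,
        "age_sd": 15.4,
        "p_male": 0.430,
        "p_white": 0.701,
        "p_not_white": 0.064,
        "p_hispanic": 0.035,
        "p_aud": 0.036,
        "p_stud": 0.082,
        "los_mean": 6.6,
        "los_sd": 11.2,
        "p_rural": 0.264,
        "p_moud_at_admission": 0.178,
        "p_prior_admission": 0.224,
        "p_naloxone_30d": 0.05,
        "cdps_mean": 2.5,
        "cdps_sd": 1.6,
    }


def default_true_coefficients(
    covariate_params: Mapping[str, float] | None = None,
) -> dict[str, dict[str, float]]:
    """Log-odds coefficient vectors targeting the observed transition rates.

    Intercepts are set so that the linear predictor at the covariate means
    equals the target logit: 4% referral, 20% engagement without referral
    (47% with), and 15% 12-month death among the non-engaged (10% among
    the engaged).
    """
    cp = dict(default_covariate_params(), **(covariate_params or {}))
    means = {
        "age": cp["age_mean"],
        "male": cp["p_male"],
        "race_not_white": cp["p_not_white"],
        "race_unknown": 1.0 - cp["p_white"] - cp["p_not_white"],
        "hispanic": cp["p_hispanic"],
        "aud": cp["p_aud"],
        "stud": cp["p_stud"],
        "length_of_stay": cp["los_mean"],
        "rural": cp["p_rural"],
        "moud_at_admission": cp["p_moud_at_admission"],
        "prior_admission": cp["p_prior_admission"],
        "cdps": cp["cdps_mean"],
        "referral": 0.0,
        "engagement": 0.0,
        "naloxone_fill_30d": 0.0,
    }
    slopes = {
        "referral": {
            "age": -0.015,
            "male": 0.4,
            "stud": 0.5,
            "length_of_stay": 0.04,
            "rural": -0.6,
            "prior_admission": 0.6,
            "cdps": 0.10,
        },
        "engagement": {
            "age": -0.01,
            "male": 0.1,
            "moud_at_admission": 0.8,
            "rural": -0.3,
            "referral": float(logit(0.47) - logit(0.20)),
        },
        "death": {
            "age": 0.03,
            "cdps": 0.20,
            "aud": 0.3,
            "engagement": float(logit(0.10) - logit(0.15)),
            "naloxone_fill_30d": -0.1,
        },
    }
    targets = {"referral": 0.04, "engagement": 0.20, "death": 0.15}
    out: dict[str, dict[str, float]] = {}
    for model, coef in slopes.items():
        at_mean = sum(v * means[k] for k, v in coef.items())
        out[model] = {"intercept": float(logit(targets[model])) - at_mean, **coef}
    return out


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one synthetic cohort draw."""

    n_patients: int
    seed: int
    covariate_params: dict[str, float] = field(default_factory=default_covariate_params)
    true_coefficients: dict[str, dict[str, float]] = field(
        default_factory=default_true_coefficients
    )
    #: P(drug-related | death) by engagement status.
    mortality_split: dict[str, float] = field(
        default_factory=lambda: {"engaged": 0.30, "not_engaged": 0.40}
    )
    #: Inclusive range of index admission days within the study window.
    admit_day_range: tuple[int, int] = (30, WINDOW_END_DAY)

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        cp = self.covariate_params
        for name in _PROPORTION_PARAMS:
            p = cp.get(name)
            if p is None or not (0.0 <= p <= 1.0):
                raise ConfigurationError(f"covariate_params[{name!r}] must be in [0, 1]")
        if cp["p_white"] + cp["p_not_white"] > 1.0:
            raise ConfigurationError("race proportions p_white + p_not_white exceed 1")
        for name in ("age_sd", "los_mean", "los_sd", "cdps_mean", "cdps_sd"):
            if cp.get(name, 0.0) <= 0.0:
                raise ConfigurationError(f"covariate_params[{name!r}] must be positive")
        for model in ("referral", "engagement", "death"):
            if model not in self.true_coefficients:
                raise ConfigurationError(f"true_coefficients missing model {model!r}")
            allowed = {"intercept", *model_terms(model)}
            unknown = set(self.true_coefficients[model]) - allowed
            if unknown:
                raise ConfigurationError(
                    f"true_coefficients[{model!r}] names unknown covariates {sorted(unknown)}"
                )
        for key, p in self.mortality_split.items():
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError(f"mortality_split[{key!r}] must be in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "n_patients": self.n_patients,
            "seed": self.seed,
            "covariate_params": dict(self.covariate_params),
            "true_coefficients": {k: dict(v) for k, v in self.true_coefficients.items()},
            "mortality_split": dict(self.mortality_split),
            "admit_day_range": list(self.admit_day_range),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        kwargs = dict(d)
        if "admit_day_range" in kwargs:
            kwargs["admit_day_range"] = tuple(kwargs["admit_day_range"])
        return cls(**kwargs)


@dataclass
class SyntheticCohort:
    """Patient, admission, fill, and death tables plus latent truth."""

    patients: pd.DataFrame
    admissions: pd.DataFrame
    fills: pd.DataFrame
    deaths: pd.DataFrame
    truth: pd.DataFrame
    config: SimConfig | None = None


def _linear_predictor(
    table: pd.DataFrame, coef: Mapping[str, float], outcome: str
) -> np.ndarray:
    terms = model_terms(outcome)
    X = design_matrix(table, terms)
    beta = np.array([coef.get("intercept", 0.0)] + [coef.get(t, 0.0) for t in terms])
    return X @ beta


def generate_cohort(config: SimConfig) -> SyntheticCohort:
    """Draw a full synthetic cohort from ``config``.

    Covariates come from the configured marginal distributions; referral,
    engagement, and death are Bernoulli draws from the logistic models
    with the configured true coefficients; pharmacy fills and death codes
    are constructed so the claims-based classifiers invert the latent
    assignments exactly.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    cp = config.covariate_params

    # --- covariates -------------------------------------------------------
    age = cp["age_mean"] + cp["age_sd"] * rng.standard_normal(n)
    age = np.clip(age, 18.0, None).round(1)
    race = rng.choice(
        np.array(["white", "not_white", "unknown"]),
        size=n,
        p=[
            cp["p_white"],
            cp["p_not_white"],
            1.0 - cp["p_white"] - cp["p_not_white"],
        ],
    )
    # log-normal length of stay matched to the configured mean/sd, >= 1 day
    sigma2 = np.log1p((cp["los_sd"] / cp["los_mean"]) ** 2)
    mu = np.log(cp["los_mean"]) - sigma2 / 2.0
    los = np.maximum(1, np.round(rng.lognormal(mu, np.sqrt(sigma2), n)).astype(int))
    cdps_shape = (cp["cdps_mean"] / cp["cdps_sd"]) ** 2
    cdps_scale = cp["cdps_sd"] ** 2 / cp["cdps_mean"]
    cdps = rng.gamma(cdps_shape, cdps_scale, n).round(2)

    tbl = pd.DataFrame(
        {
            "patient_id": np.arange(1, n + 1),
            "age": age,
            "male": (rng.random(n) < cp["p_male"]).astype(int),
            "race": race,
            "hispanic": (rng.random(n) < cp["p_hispanic"]).astype(int),
            "aud": (rng.random(n) < cp["p_aud"]).astype(int),
            "stud": (rng.random(n) < cp["p_stud"]).astype(int),
            "length_of_stay": los,
            "rural": (rng.random(n) < cp["p_rural"]).astype(int),
            "moud_at_admission": (rng.random(n) < cp["p_moud_at_admission"]).astype(int),
            "prior_admission": (rng.random(n) < cp["p_prior_admission"]).astype(int),
            "cdps": cdps,
            "naloxone_fill_30d": (rng.random(n) < cp["p_naloxone_30d"]).astype(int),
        }
    )

    # --- latent outcomes --------------------------------------------------
    coef = config.true_coefficients
    referral = rng.random(n) < expit(_linear_predictor(tbl, coef["referral"], "referral"))
    tbl["referral"] = referral.astype(int)
    engagement = rng.random(n) < expit(
        _linear_predictor(tbl, coef["engagement"], "engagement")
    )
    tbl["engagement"] = engagement.astype(int)
    death = rng.random(n) < expit(_linear_predictor(tbl, coef["death"], "death"))
    p_drug = np.where(
        engagement,
        config.mortality_split["engaged"],
        config.mortality_split["not_engaged"],
    )
    drug_death = death & (rng.random(n) < p_drug)

    # --- admissions -------------------------------------------------------
    lo, hi = config.admit_day_range
    admit = rng.integers(lo, hi + 1, n)
    discharge = admit + los
    adm_rows = []
    for i in range(n):
        pid = int(tbl.at[i, "patient_id"])
        number = 1
        if tbl.at[i, "prior_admission"]:
            gap = int(rng.integers(30, 181))
            prior_admit = max(0, int(admit[i]) - gap)
            prior_los = int(rng.integers(1, 6))
            adm_rows.append(
                {
                    "patient_id": pid,
                    "admit_date": prior_admit,
                    "discharge_date": prior_admit + prior_los,
                    "diagnosis_codes": "I10",  # non-OUD, so the OUD admission stays index
                    "admission_number": 1,
                }
            )
            number = 2
        adm_rows.append(
            {
                "patient_id": pid,
                "admit_date": int(admit[i]),
                "discharge_date": int(discharge[i]),
                "diagnosis_codes": "F1120;I10",
                "admission_number": number,
            }
        )
    admissions = pd.DataFrame(
        adm_rows,
        columns=["patient_id", "admit_date", "discharge_date", "diagnosis_codes", "admission_number"],
    )

    # --- pharmacy fills ---------------------------------------------------
    fill_rows = []
    moud_classes = np.array(["buprenorphine", "xr_naltrexone", "methadone_otp"])
    for i in range(n):
        pid = int(tbl.at[i, "patient_id"])
        d = int(discharge[i])
        if tbl.at[i, "moud_at_admission"]:
            fill_rows.append((pid, "buprenorphine", int(admit[i]) - 10, 14))
        if engagement[i]:
            if rng.random() < 0.5:
                # clause (a): two qualifying fills inside days 1..30
                pair = rng.choice(moud_classes, size=2)
                fill_rows.append((pid, str(pair[0]), d + 5, 14))
                fill_rows.append((pid, str(pair[1]), d + 20, 10))
            else:
                # clause (b): a single 30-day supply covering the window
                cls = str(rng.choice(moud_classes[:2]))
                fill_rows.append((pid, cls, d + 1, 30))
        elif rng.random() < 0.5:
            # a single short fill that satisfies neither clause
            fill_rows.append(
                (pid, "buprenorphine", d + int(rng.integers(1, 26)), int(rng.integers(1, 8)))
            )
        if tbl.at[i, "naloxone_fill_30d"]:
            fill_rows.append((pid, "naloxone", d + int(rng.integers(1, 31)), 1))
    fills = pd.DataFrame(
        fill_rows, columns=["patient_id", "drug_class", "fill_date", "days_supply"]
    )

    # --- deaths -----------------------------------------------------------
    death_rows = []
    for i in np.flatnonzero(death):
        code_pool = DRUG_CAUSE_CODES if drug_death[i] else NONDRUG_CAUSE_CODES
        death_rows.append(
            (
                int(tbl.at[i, "patient_id"]),
                int(discharge[i]) + int(rng.integers(1, 366)),
                str(rng.choice(np.array(code_pool))),
            )
        )
    deaths = pd.DataFrame(
        death_rows, columns=["patient_id", "death_date", "underlying_cause_code"]
    )

    truth = pd.DataFrame(
        {
            "patient_id": tbl["patient_id"],
            "referral": referral.astype(int),
            "engagement": engagement.astype(int),
            "death_category": np.where(
                death, np.where(drug_death, "drug", "non_drug"), "none"
            ),
        }
    )
    # Claims-derivable covariates (length of stay, MOUD at admission, prior
    # admission, naloxone fill) live in the event tables only, so the
    # measures layer genuinely reconstructs them.
    patients = tbl[
        ["patient_id", "age", "male", "race", "hispanic", "aud", "stud", "rural", "cdps"]
    ].copy()
    return SyntheticCohort(patients, admissions, fills, deaths, truth, config)


def generate_expert_responses(
    true_probs: Mapping[str, float],
    n_experts: int,
    noise_scale: float,
    seed: int,
) -> pd.DataFrame:
    """Simulated expert survey: one row per expert, one column per vignette.

    Each response is the vignette's true probability perturbed on the
    logit scale by centred normal noise with SD ``noise_scale``, so the
    marginal response distribution is logit-normal.
    """
    probs = np.asarray(list(true_probs.values()), dtype=float)
    if np.any((probs <= 0.0) | (probs >= 1.0)):
        raise DataError("true_probs must lie strictly inside (0, 1)")
    if n_experts < 1:
        raise ConfigurationError("n_experts must be >= 1")
    if noise_scale < 0:
        raise ConfigurationError("noise_scale must be non-negative")
    rng = np.random.default_rng(seed)
    noise = noise_scale * rng.standard_normal((n_experts, probs.size))
    resp = expit(logit(probs)[None, :] + noise)
    return pd.DataFrame(
        resp,
        index=pd.Index([f"expert_{i + 1}" for i in range(n_experts)], name="expert_id"),
        columns=list(true_probs.keys()),
    )


_TABLES = ("patients", "admissions", "fills", "deaths", "truth")


def write_cohort(cohort: SyntheticCohort, directory: str | Path) -> None:
    """Write the cohort as one CSV per table plus a config sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name in _TABLES:
        getattr(cohort, name).to_csv(directory / f"{name}.csv", index=False)
    if cohort.config is not None:
        (directory / "sim_config.json").write_text(
            json.dumps(cohort.config.to_dict(), indent=2)
        )


def read_cohort(directory: str | Path) -> SyntheticCohort:
    """Read a cohort previously written by :func:`write_cohort`."""
    directory = Path(directory)
    tables = {}
    for name in _TABLES:
        tables[name] = pd.read_csv(directory / f"{name}.csv")
    config = None
    sidecar = directory / "sim_config.json"
    if sidecar.exists():
        config = SimConfig.from_dict(json.loads(sidecar.read_text()))
    return SyntheticCohort(config=config, **tables)
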