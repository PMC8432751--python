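"""Claims-style cohort construction and outcome measures.

Turns raw admissions / pharmacy-fill / death tables into the one-row-per-
patient analysis table used by the transition models:

* eligibility — adults (>= 18) with an OUD diagnosis (ICD-9 ``304*`` or
  ICD-10 ``F11*``) on an admission inside the study window, one index
  admission per person (the first eligible one), with a flag for the
  subset admitted early enough to have 12 months of mortality follow-up;
* engagement — a modified HEDIS measure: at least two fills of
  buprenorphine, extended-release naltrexone, or OTP methadone in the 30
  days after discharge, or buprenorphine/XR-naltrexone supply covering at
  least 28 of those 30 days;
* death classification — drug-related versus non-drug-related by
  underlying-cause ICD-10 code prefix, with per-patient overrides standing
  in for manual chart review;
* matched controls — up to ``ratio`` non-referred controls per referred
  case, matched exactly on admission quarter and admission number, without
  replacement.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from acsmarkov.errors import ClassificationError, DataError, MatchingError, SchemaError
from acsmarkov.synthetic_data import read_cohort  # re-exported reader
from acsmarkov.timebase import MORTALITY_CUTOFF_DAY, WINDOW_END_DAY, admission_quarter

__all__ = [
    "EligibilityWindow",
    "CauseMap",
    "DEFAULT_DRUG_CODE_PREFIXES",
    "select_eligible",
    "classify_engagement",
    "classify_death",
    "match_controls",
    "build_covariates",
    "read_cohort",
]

logger = logging.getLogger(__name__)

#: Qualifying medication classes for the two engagement clauses.
ENGAGEMENT_FILL_CLASSES = frozenset({"buprenorphine", "xr_naltrexone", "methadone_otp"})
COVERAGE_FILL_CLASSES = frozenset({"buprenorphine", "xr_naltrexone"})

#: Underlying-cause ICD-10 prefixes counted as drug-related: accidental
#: (X40-X44), intentional (X60-X64), assault (X85) and undetermined
#: (Y10-Y14) poisoning.
DEFAULT_DRUG_CODE_PREFIXES = frozenset(
    [f"X{i}" for i in range(40, 45)]
    + [f"X{i}" for i in range(60, 65)]
    + ["X85"]
    + [f"Y{i}" for i in range(10, 15)]
)


@dataclass(frozen=True)
class EligibilityWindow:
    """Admission window and the mortality-follow-up cutoff (day offsets)."""

    start_date: int = 0
    end_date: int = WINDOW_END_DAY
    mortality_cutoff_date: int = MORTALITY_CUTOFF_DAY

    def __post_init__(self) -> None:
        if not (self.start_date < self.mortality_cutoff_date <= self.end_date):
            raise ValueError("need start < mortality_cutoff <= end")


@dataclass(frozen=True)
class CauseMap:
    """Drug-related cause-code prefixes plus per-patient overrides."""

    drug_related_codes: frozenset[str] = DEFAULT_DRUG_CODE_PREFIXES
    overrides: dict[int, str] = field(default_factory=dict)

    def category(self, patient_id: int, code: str | None) -> str:
        """'drug' or 'non_drug' for one death record; overrides win."""
        if patient_id in self.overrides:
            cat = self.overrides[patient_id]
            if cat not in ("drug", "non_drug"):
                raise ClassificationError(
                    f"override for patient {patient_id} must be 'drug' or 'non_drug'"
                )
            return cat
        if code is None or (isinstance(code, float) and np.isnan(code)) or str(code) == "":
            raise ClassificationError(
                f"death of patient {patient_id} has no cause code and no override"
            )
        code = str(code).strip().upper()
        return "drug" if any(code.startswith(p) for p in self.drug_related_codes) else "non_drug"


def _has_oud_code(codes: object) -> bool:
    """True if a semicolon-delimited code list contains an OUD diagnosis."""
    if not isinstance(codes, str) or not codes.strip():
        warnings.warn(f"malformed diagnosis code list {codes!r}; row excluded from OUD match")
        return False
    for code in codes.split(";"):
        c = code.strip().upper().replace(".", "")
        if c.startswith("F11") or c.startswith("304"):
            return True
    return False


def select_eligible(
    admissions: pd.DataFrame,
    window: EligibilityWindow,
    patients: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Index-admission table of eligible patients.

    Keeps patients aged >= 18 with an OUD-coded admission inside the
    window; the index admission is the first such admission.  The returned
    table adds ``in_mortality_cohort`` flagging admission on or before the
    mortality cutoff.  Age is read from ``admissions`` or joined from
    ``patients``.
    """
    required = {"patient_id", "admit_date", "diagnosis_codes"}
    missing = required - set(admissions.columns)
    if missing:
        raise SchemaError(f"admissions table missing columns {sorted(missing)}")
    adm = admissions.copy()
    if "age" not in adm.columns:
        if patients is None or "age" not in patients.columns:
            raise SchemaError("patient ages not found in admissions or patients table")
        adm = adm.merge(patients[["patient_id", "age"]], on="patient_id", how="left")

    in_window = adm["admit_date"].between(window.start_date, window.end_date)
    has_oud = adm["diagnosis_codes"].map(_has_oud_code)
    adult = adm["age"] >= 18
    eligible = adm[in_window & has_oud & adult]
    index_adm = (
        eligible.sort_values(["patient_id", "admit_date"])
        .groupby("patient_id", as_index=False)
        .first()
    )
    index_adm["in_mortality_cohort"] = (
        index_adm["admit_date"] <= window.mortality_cutoff_date
    )
    return index_adm.reset_index(drop=True)


def classify_engagement(discharge_day: int, fills: pd.DataFrame) -> bool:
    """Modified HEDIS engagement over days 1..30 after discharge.

    Clause (a): >= 2 fills of a qualifying MOUD class with fill date in the
    window.  Clause (b): buprenorphine/XR-naltrexone supplied-day overlap
    with the window (summed across fills, capped at 30) >= 28.
    """
    if fills.empty:
        return False
    if (fills["days_supply"] < 0).any():
        raise DataError("negative days_supply in fills table")
    start, end = discharge_day + 1, discharge_day + 30

    qualifying = fills[fills["drug_class"].isin(ENGAGEMENT_FILL_CLASSES)]
    in_window = qualifying[qualifying["fill_date"].between(start, end)]
    if len(in_window) >= 2:
        return True

    cover = fills[fills["drug_class"].isin(COVERAGE_FILL_CLASSES)]
    if cover.empty:
        return False
    fill_start = cover["fill_date"].to_numpy()
    fill_end = fill_start + cover["days_supply"].to_numpy() - 1
    overlap = np.clip(
        np.minimum(fill_end, end) - np.maximum(fill_start, start) + 1, 0, None
    )
    return bool(min(int(overlap.sum()), 30) >= 28)


def classify_death(
    death: pd.Series | dict | None,
    index_discharge_day: int,
    cause_map: CauseMap,
) -> str:
    """'none', 'drug', or 'non_drug' for one patient's 12-month outcome.

    Deaths more than 365 days after the index discharge (or no death
    record at all) classify as 'none'.
    """
    if death is None:
        return "none"
    death_day = int(death["death_date"])
    if death_day - index_discharge_day > 365:
        return "none"
    return cause_map.category(int(death["patient_id"]), death.get("underlying_cause_code"))


def match_controls(
    cases: pd.DataFrame, pool: pd.DataFrame, ratio: int = 3
) -> pd.DataFrame:
    """Match each case to up to ``ratio`` controls without replacement.

    Matching is exact on ``(admission_quarter, admission_number)``; the
    quarter is derived from ``admit_date`` when absent.  Controls within a
    stratum are taken in (admission date, patient id) order and cases are
    processed in ascending admission-date order, so the output is
    deterministic.  Under-matched cases are flagged.

    Returns the stacked case+control table with ``role`` ('case' or
    'control'), ``case_id``, and ``under_matched`` columns.
    """
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    if pool.empty:
        raise MatchingError("control pool is empty")

    def prep(df: pd.DataFrame) -> pd.DataFrame:
        df = df.copy()
        if "admission_quarter" not in df.columns:
            df["admission_quarter"] = df["admit_date"].map(admission_quarter)
        if "admission_number" not in df.columns:
            raise SchemaError("admission_number column required for matching")
        return df

    cases = prep(cases).sort_values(["admit_date", "patient_id"])
    pool = prep(pool)

    available = {
        key: sub.sort_values(["admit_date", "patient_id"])["patient_id"].tolist()
        for key, sub in pool.groupby(["admission_quarter", "admission_number"])
    }
    pool_indexed = pool.set_index("patient_id")

    rows = []
    for _, case in cases.iterrows():
        key = (case["admission_quarter"], case["admission_number"])
        stratum = available.get(key, [])
        chosen = stratum[:ratio]
        available[key] = stratum[len(chosen):]
        under = len(chosen) < ratio
        case_row = case.to_dict()
        case_row.update(role="case", case_id=case["patient_id"], under_matched=under)
        rows.append(case_row)
        for pid in chosen:
            ctrl = pool_indexed.loc[pid].to_dict()
            ctrl.update(
                patient_id=pid, role="control", case_id=case["patient_id"], under_matched=under
            )
            rows.append(ctrl)
    return pd.DataFrame(rows).reset_index(drop=True)


def build_covariates(
    eligible: pd.DataFrame,
    admissions: pd.DataFrame,
    fills: pd.DataFrame,
    deaths: pd.DataFrame,
    cause_map: CauseMap | None = None,
    patients: pd.DataFrame | None = None,
    referrals: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assemble the analysis table: one row per eligible patient.

    Claims-derived covariates — length of stay, MOUD fill in the 30 days
    before admission, prior admission (index admission number > 1), and a
    naloxone fill in days 1..30 after discharge — are computed from the
    event tables; demographic covariates are joined from ``patients``;
    engagement and the death category come from the classifiers.  Referral
    is joined from ``referrals`` (patient_id, referral) or taken from a
    ``referral`` column already present.
    """
    cause_map = cause_map or CauseMap()
    out = eligible.copy()
    if patients is not None:
        demo_cols = [c for c in patients.columns if c not in out.columns or c == "patient_id"]
        out = out.merge(patients[demo_cols], on="patient_id", how="left")

    for col in ("discharge_date", "admit_date", "admission_number"):
        if col not in out.columns:
            raise SchemaError(f"missing covariate source column {col!r}")

    out["length_of_stay"] = out["discharge_date"] - out["admit_date"]
    out["prior_admission"] = (out["admission_number"] > 1).astype(int)

    fills_by_patient = dict(tuple(fills.groupby("patient_id"))) if not fills.empty else {}
    deaths_by_patient = (
        deaths.set_index("patient_id") if not deaths.empty else pd.DataFrame()
    )

    moud, naloxone, engaged, death_cat = [], [], [], []
    for _, row in out.iterrows():
        pid = row["patient_id"]
        pf = fills_by_patient.get(pid, fills.iloc[0:0])
        admit, discharge = row["admit_date"], row["discharge_date"]
        pre = pf[
            pf["drug_class"].isin(ENGAGEMENT_FILL_CLASSES)
            & pf["fill_date"].between(admit - 30, admit - 1)
        ]
        moud.append(int(len(pre) > 0))
        nal = pf[
            (pf["drug_class"] == "naloxone")
            & pf["fill_date"].between(discharge + 1, discharge + 30)
        ]
        naloxone.append(int(len(nal) > 0))
        engaged.append(int(classify_engagement(discharge, pf)))
        if len(deaths_by_patient) and pid in deaths_by_patient.index:
            rec = deaths_by_patient.loc[pid]
            death = {
                "patient_id": pid,
                "death_date": rec["death_date"],
                "underlying_cause_code": rec.get("underlying_cause_code"),
            }
        else:
            death = None
        death_cat.append(classify_death(death, discharge, cause_map))

    out["moud_at_admission"] = moud
    out["naloxone_fill_30d"] = naloxone
    out["engagement"] = engaged
    out["death_category"] = death_cat

    if referrals is not None:
        out = out.drop(columns=["referral"], errors="ignore").merge(
            referrals[["patient_id", "referral"]], on="patient_id", how="left"
        )
        out["referral"] = out["referral"].fillna(0).astype(int)
    elif "referral" not in out.columns:
        raise SchemaError("no referral flag: pass `referrals` or include a 'referral' column")
    return out
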