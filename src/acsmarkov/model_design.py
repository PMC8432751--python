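"""Covariate lists and design matrices shared by the transition models.

All three transition models adjust for the same patient covariates: age,
gender, race (three levels, White as reference), Hispanic ethnicity,
concurrent alcohol and stimulant use disorders, hospital length of stay,
rural residence, a MOUD fill in the month before admission, any prior
hospital admission, and the CDPS comorbidity score.  The engagement model
additionally includes ACS referral; the two mortality models additionally
include post-discharge treatment engagement and a naloxone fill in the 30
days after discharge.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from acsmarkov.errors import SchemaError

#: Design-matrix terms shared by every transition model (intercept excluded).
BASE_TERMS: tuple[str, ...] = (
    "age",
    "male",
    "race_not_white",
    "race_unknown",
    "hispanic",
    "aud",
    "stud",
    "length_of_stay",
    "rural",
    "moud_at_admission",
    "prior_admission",
    "cdps",
)

#: Extra terms per outcome, appended after the base terms.
EXTRA_TERMS: dict[str, tuple[str, ...]] = {
    "referral": (),
    "engagement": ("referral",),
    "drug_death": ("engagement", "naloxone_fill_30d"),
    "nondrug_death": ("engagement", "naloxone_fill_30d"),
    # the generator's single latent mortality model shares the death terms
    "death": ("engagement", "naloxone_fill_30d"),
}

RACE_LEVELS = ("white", "not_white", "unknown")


def model_terms(outcome: str) -> tuple[str, ...]:
    """Term names (without intercept) for one transition model."""
    if outcome not in EXTRA_TERMS:
        raise SchemaError(f"unknown model outcome {outcome!r}")
    return BASE_TERMS + EXTRA_TERMS[outcome]


def design_matrix(table: pd.DataFrame, terms: tuple[str, ...]) -> np.ndarray:
    """Dense design matrix (intercept first) for the given terms.

    ``race`` is expanded to not-White / unknown dummies with White as the
    reference level; all other terms are taken as numeric columns.
    """
    n = len(table)
    cols = [np.ones(n)]
    for term in terms:
        if term in ("race_not_white", "race_unknown"):
            if "race" not in table.columns:
                raise SchemaError("missing covariate source column 'race'")
            level = term.removeprefix("race_")
            cols.append((table["race"].to_numpy() == level).astype(float))
        else:
            if term not in table.columns:
                raise SchemaError(f"missing covariate source column {term!r}")
            cols.append(table[term].to_numpy(dtype=float))
    return np.column_stack(cols)


def parameter_names(terms: tuple[str, ...]) -> list[str]:
    return ["intercept", *terms]
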