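"""Single-cycle Markov model of ACS care and 12-month mortality.

The model is a decision tree evaluated over one 12-month cycle: a
hospitalized patient with OUD is referred to an addiction consult service
(ACS) or not, engages in post-discharge OUD treatment or not (with an
engagement probability that depends on referral), and then dies of a
drug-related cause, dies of a non-drug-related cause, or survives the
year.  There are no recurrent transitions, so expected state occupancy is
closed-form algebra on the five branch probabilities.

Uncertainty is carried as deterministic Low/High bound scenarios rather
than a probabilistic sensitivity analysis: the "High death" scenario
combines the *lower* referral and engagement bounds with the *upper*
mortality bounds (fewer patients reach protective treatment, mortality at
its worst), and the "Low death" scenario is the mirror image.

Two conventions for the engaged fraction coexist deliberately.  The
expected engaged *count* uses the not-referred engagement probability
alone, while expected *deaths* mix the two referral branches
(``p_ref * p_eng_ref + (1 - p_ref) * p_eng_noref``).  Both are exposed via
the ``convention`` argument; see docs/methods.md for why the defaults
differ per quantity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "ProbInterval",
    "TransitionProbabilities",
    "CohortProjection",
    "engaged_fraction",
    "project_cohort",
    "project_external",
    "microsim_oracle",
]

Convention = Literal["combined", "not_referred_only"]
Bound = Literal["point", "low_death_scenario", "high_death_scenario"]


@dataclass(frozen=True)
class ProbInterval:
    """A probability with a 95% interval: ``lower <= point <= upper``."""

    point: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.lower <= self.point <= self.upper <= 1.0):
            raise ValueError(
                f"invalid probability interval ({self.lower}, {self.point}, "
                f"{self.upper}); need 0 <= lower <= point <= upper <= 1"
            )

    @classmethod
    def of(cls, value: "ProbInterval | tuple | float") -> "ProbInterval":
        if isinstance(value, ProbInterval):
            return value
        if isinstance(value, (int, float)):
            return cls(float(value), float(value), float(value))
        point, lower, upper = value
        return cls(float(point), float(lower), float(upper))


@dataclass(frozen=True)
class TransitionProbabilities:
    """The five branch probabilities of the care-pathway model.

    Each field is a :class:`ProbInterval` (or anything ``ProbInterval.of``
    accepts).  Within each engagement stratum the point drug and non-drug
    death probabilities must sum to at most 1.
    """

    p_referral: ProbInterval
    p_engage_given_referral: ProbInterval
    p_engage_given_no_referral: ProbInterval
    p_drug_death_given_engaged: ProbInterval
    p_drug_death_given_not_engaged: ProbInterval
    p_nondrug_death_given_engaged: ProbInterval
    p_nondrug_death_given_not_engaged: ProbInterval

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            object.__setattr__(self, name, ProbInterval.of(getattr(self, name)))
        for eng, non in (
            (self.p_drug_death_given_engaged, self.p_nondrug_death_given_engaged),
            (
                self.p_drug_death_given_not_engaged,
                self.p_nondrug_death_given_not_engaged,
            ),
        ):
            if eng.point + non.point > 1.0 + 1e-12:
                raise ValueError(
                    "drug + non-drug death probabilities exceed 1 within an "
                    "engagement stratum"
                )

    @classmethod
    def from_dict(cls, d: dict) -> "TransitionProbabilities":
        """Build from a plain mapping, e.g. parsed YAML/JSON.

        Each entry may be a scalar, a ``[point, lower, upper]`` list, or a
        ``{point, lower, upper}`` mapping.
        """

        def coerce(v):
            if isinstance(v, dict):
                return ProbInterval(float(v["point"]), float(v["lower"]), float(v["upper"]))
            return ProbInterval.of(v)

        return cls(**{k: coerce(d[k]) for k in cls.__dataclass_fields__})


@dataclass(frozen=True)
class Bounded:
    """A point estimate with deterministic Low/High scenario bounds."""

    point: float
    low: float
    high: float


@dataclass(frozen=True)
class CohortProjection:
    """Expected 12-month state counts for a closed cohort."""

    cohort_n: int
    expected_engaged: Bounded
    expected_drug_deaths: Bounded
    expected_nondrug_deaths: Bounded
    expected_total_deaths: Bounded
    death_percent: Bounded
    survivors: float = field(default=0.0)


def _scenario_probs(probs: TransitionProbabilities, bound: Bound) -> dict[str, float]:
    """Pick the per-branch probabilities for a bound scenario.

    High-death: referral and engagement at their lower bounds, death
    probabilities at their upper bounds.  Low-death: the mirror image.
    """
    p = probs
    if bound == "point":
        return {
            "ref": p.p_referral.point,
            "eng_ref": p.p_engage_given_referral.point,
            "eng_noref": p.p_engage_given_no_referral.point,
            "drug_eng": p.p_drug_death_given_engaged.point,
            "drug_noeng": p.p_drug_death_given_not_engaged.point,
            "nondrug_eng": p.p_nondrug_death_given_engaged.point,
            "nondrug_noeng": p.p_nondrug_death_given_not_engaged.point,
        }
    if bound == "high_death_scenario":
        return {
            "ref": p.p_referral.lower,
            "eng_ref": p.p_engage_given_referral.lower,
            "eng_noref": p.p_engage_given_no_referral.lower,
            "drug_eng": p.p_drug_death_given_engaged.upper,
            "drug_noeng": p.p_drug_death_given_not_engaged.upper,
            "nondrug_eng": p.p_nondrug_death_given_engaged.upper,
            "nondrug_noeng": p.p_nondrug_death_given_not_engaged.upper,
        }
    if bound == "low_death_scenario":
        return {
            "ref": p.p_referral.upper,
            "eng_ref": p.p_engage_given_referral.upper,
            "eng_noref": p.p_engage_given_no_referral.upper,
            "drug_eng": p.p_drug_death_given_engaged.lower,
            "drug_noeng": p.p_drug_death_given_not_engaged.lower,
            "nondrug_eng": p.p_nondrug_death_given_engaged.lower,
            "nondrug_noeng": p.p_nondrug_death_given_not_engaged.lower,
        }
    raise ValueError(f"unknown bound scenario {bound!r}")


def engaged_fraction(
    probs: TransitionProbabilities,
    convention: Convention = "combined",
    bound: Bound = "point",
) -> float:
    """Fraction of the cohort engaging in post-discharge OUD treatment.

    ``combined`` mixes the referral branches,
    ``p_ref * p_eng_ref + (1 - p_ref) * p_eng_noref``;
    ``not_referred_only`` returns the not-referred engagement probability
    alone.  ``bound`` selects the point values or a Low/High scenario's
    endpoint combination.
    """
    s = _scenario_probs(probs, bound)
    if convention == "combined":
        return s["ref"] * s["eng_ref"] + (1.0 - s["ref"]) * s["eng_noref"]
    if convention == "not_referred_only":
        return s["eng_noref"]
    raise ValueError(f"unknown convention {convention!r}")


def _death_rate(s: dict[str, float], category: str) -> float:
    """Per-person death probability through the two-branch algebra."""
    f = s["ref"] * s["eng_ref"] + (1.0 - s["ref"]) * s["eng_noref"]
    return f * s[f"{category}_eng"] + (1.0 - f) * s[f"{category}_noeng"]


def project_cohort(cohort_n: int, probs: TransitionProbabilities) -> CohortProjection:
    """Expected 12-month counts for a closed cohort of ``cohort_n``.

    Expected engaged uses the not-referred engagement probability with its
    interval; expected deaths use the combined two-branch engaged fraction
    with the Low/High bound-scenario combinations.  Counts are reported to
    one decimal; probabilities enter at full precision.
    """
    if cohort_n < 1:
        raise ValueError("cohort_n must be >= 1")
    n = float(cohort_n)

    eng = probs.p_engage_given_no_referral
    expected_engaged = Bounded(
        round(n * eng.point, 1), round(n * eng.lower, 1), round(n * eng.upper, 1)
    )

    rates = {
        bound: {cat: _death_rate(_scenario_probs(probs, bound), cat) for cat in ("drug", "nondrug")}
        for bound in ("point", "low_death_scenario", "high_death_scenario")
    }

    def bounded(cat: str) -> Bounded:
        return Bounded(
            round(n * rates["point"][cat], 1),
            round(n * rates["low_death_scenario"][cat], 1),
            round(n * rates["high_death_scenario"][cat], 1),
        )

    drug = bounded("drug")
    nondrug = bounded("nondrug")

    def total(bound: str) -> float:
        return n * (rates[bound]["drug"] + rates[bound]["nondrug"])

    tot = Bounded(
        round(total("point"), 1),
        round(total("low_death_scenario"), 1),
        round(total("high_death_scenario"), 1),
    )
    pct = Bounded(
        round(100.0 * total("point") / n, 1),
        round(100.0 * total("low_death_scenario") / n, 1),
        round(100.0 * total("high_death_scenario") / n, 1),
    )
    return CohortProjection(
        cohort_n=cohort_n,
        expected_engaged=expected_engaged,
        expected_drug_deaths=drug,
        expected_nondrug_deaths=nondrug,
        expected_total_deaths=tot,
        death_percent=pct,
        survivors=n - total("point"),
    )


OutputKey = Literal[
    "count_engaged", "count_all_deaths", "rate_drug_per100py", "rate_nondrug_per100py"
]
Rounding = Literal["one_decimal", "truncate_integer", "one_decimal_rate"]


def _apply_rounding(x: float, rounding: Rounding) -> float:
    if rounding == "truncate_integer":
        return float(math.trunc(x))
    if rounding in ("one_decimal", "one_decimal_rate"):
        return round(x, 1)
    raise ValueError(f"unknown rounding {rounding!r}")


def project_external(
    cohort_n: int,
    probs: TransitionProbabilities,
    output: OutputKey,
    rounding: Rounding | None = None,
) -> Bounded:
    """Project the model onto an external cohort of ``cohort_n`` members.

    Death rates per 100 person-years treat each cohort member as one
    person-year, i.e. ``100 * expected deaths / cohort_n``.  Default
    rounding is one decimal for ``count_engaged`` and the rates, and
    truncation toward zero for ``count_all_deaths``.  ``rounding`` governs
    the point estimate; Low/High bounds of the count outputs are always
    truncated toward zero (the convention of the published tables), while
    rate bounds share the point's one-decimal rounding.
    """
    if cohort_n < 1:
        raise ValueError("cohort_n must be >= 1")
    n = float(cohort_n)
    defaults: dict[str, Rounding] = {
        "count_engaged": "one_decimal",
        "count_all_deaths": "truncate_integer",
        "rate_drug_per100py": "one_decimal_rate",
        "rate_nondrug_per100py": "one_decimal_rate",
    }
    if output not in defaults:
        raise ValueError(f"unknown output key {output!r}")
    rounding = rounding or defaults[output]

    if output == "count_engaged":
        eng = probs.p_engage_given_no_referral
        raw = (n * eng.point, n * eng.lower, n * eng.upper)
    else:
        vals = []
        for bound in ("point", "low_death_scenario", "high_death_scenario"):
            s = _scenario_probs(probs, bound)
            drug = _death_rate(s, "drug")
            nondrug = _death_rate(s, "nondrug")
            if output == "count_all_deaths":
                vals.append(n * (drug + nondrug))
            elif output == "rate_drug_per100py":
                vals.append(100.0 * drug)
            else:
                vals.append(100.0 * nondrug)
        raw = tuple(vals)
    bound_rounding: Rounding = rounding if output.startswith("rate") else "truncate_integer"
    return Bounded(
        _apply_rounding(raw[0], rounding),
        _apply_rounding(raw[1], bound_rounding),
        _apply_rounding(raw[2], bound_rounding),
    )


def microsim_oracle(
    cohort_n: int, probs: TransitionProbabilities, seed: int
) -> dict[str, int]:
    """Individual-level sampler through the decision tree at point values.

    Returns sampled counts for referral, engagement, and the three
    terminal states.  Serves as a stochastic oracle for the expected-count
    algebra of :func:`project_cohort`.
    """
    if cohort_n < 1:
        raise ValueError("cohort_n must be >= 1")
    rng = np.random.default_rng(seed)
    s = _scenario_probs(probs, "point")
    referred = rng.random(cohort_n) < s["ref"]
    p_eng = np.where(referred, s["eng_ref"], s["eng_noref"])
    engaged = rng.random(cohort_n) < p_eng
    p_drug = np.where(engaged, s["drug_eng"], s["drug_noeng"])
    p_nondrug = np.where(engaged, s["nondrug_eng"], s["nondrug_noeng"])
    u = rng.random(cohort_n)
    drug_death = u < p_drug
    nondrug_death = (~drug_death) & (u < p_drug + p_nondrug)
    return {
        "referred": int(referred.sum()),
        "engaged": int(engaged.sum()),
        "drug_deaths": int(drug_death.sum()),
        "nondrug_deaths": int(nondrug_death.sum()),
        "survivors": int(cohort_n - drug_death.sum() - nondrug_death.sum()),
    }
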