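"""Expert-elicited beta priors for the transition probabilities.

Experts rate the probability of an event (ACS referral, post-discharge
engagement, 12-month death) for a set of clinical vignettes.  Per
vignette, the responses are summarised by their mean and min/max range,
and a beta distribution is fitted to those quantities by one of two
strength conventions:

* ``sample_size`` — the prior is worth a fixed fraction ``f`` of the study
  cohort: ``alpha = mean * f * N``, ``beta = (1 - mean) * f * N``, so the
  effective prior sample size ``alpha + beta`` is exactly ``f * N``;
* ``confidence_interval`` — ``[min, max]`` is read as the central interval
  at a chosen level; with the mean held fixed, a 1-D search over ``alpha``
  minimises the squared distance between the beta central-interval
  endpoints and the observed range.

Fitted priors enter the regression models as pseudo-data: each vignette
contributes ``alpha`` pseudo-successes and ``beta`` pseudo-failures at its
covariate profile (a power-prior-style bridge that keeps the prior's
effective sample size interpretable).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from acsmarkov.errors import ConfigurationError, ElicitationError

__all__ = [
    "ExpertSummary",
    "BetaPrior",
    "PriorStrengthSpec",
    "PseudoData",
    "summarize_responses",
    "fit_beta_interval",
    "fit_beta_samplesize",
    "priors_to_pseudodata",
]

SAMPLE_SIZE_FRACTIONS = (0.001, 0.01, 0.05, 0.10)
CI_LEVELS = (0.80, 0.85, 0.90, 0.95)


@dataclass(frozen=True)
class ExpertSummary:
    """Per-vignette mean / min / max of expert probability ratings."""

    transition: str
    vignette_id: str
    mean: float
    minimum: float
    maximum: float
    n_experts: int
    vignette_profile: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.minimum <= self.mean <= self.maximum <= 1.0):
            raise ElicitationError(
                f"vignette {self.vignette_id}: need 0 <= min <= mean <= max <= 1"
            )

    @property
    def degenerate(self) -> bool:
        return self.minimum == self.maximum


@dataclass(frozen=True)
class BetaPrior:
    """Beta(alpha, beta) prior on one transition probability."""

    alpha: float
    beta: float
    source: str
    feasible: bool = True
    vignette_profile: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ElicitationError("beta prior requires alpha > 0 and beta > 0")

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    @property
    def effective_sample_size(self) -> float:
        return self.alpha + self.beta


@dataclass(frozen=True)
class PriorStrengthSpec:
    """Which strength convention to use and its parameter."""

    method: Literal["sample_size", "confidence_interval"]
    sample_size_fraction: float | None = None
    ci_level: float | None = None
    cohort_n: int | None = None

    def __post_init__(self) -> None:
        if self.method == "sample_size":
            if self.sample_size_fraction is None or self.cohort_n is None:
                raise ConfigurationError(
                    "sample_size method requires sample_size_fraction and cohort_n"
                )
            if self.sample_size_fraction <= 0:
                raise ConfigurationError("sample_size_fraction must be positive")
        elif self.method == "confidence_interval":
            if self.ci_level is None or not (0.0 < self.ci_level < 1.0):
                raise ConfigurationError("confidence_interval method requires ci_level in (0,1)")
        else:
            raise ConfigurationError(f"unknown prior strength method {self.method!r}")


@dataclass(frozen=True)
class PseudoData:
    """Weighted pseudo-observations realising vignette priors in a model."""

    profiles: tuple[Mapping[str, float], ...]
    successes: tuple[float, ...]
    failures: tuple[float, ...]

    @property
    def total_weight(self) -> float:
        return float(sum(self.successes) + sum(self.failures))

    def __len__(self) -> int:
        return len(self.successes)


def summarize_responses(
    responses: pd.DataFrame,
    transition: str = "",
    vignette_profiles: Mapping[str, Mapping[str, float]] | None = None,
) -> list[ExpertSummary]:
    """Summarise an expert x vignette response table.

    ``responses`` has one row per expert and one column per vignette, with
    probabilities in [0, 1].  Single-expert vignettes come back with
    ``min == mean == max`` and are flagged degenerate.
    """
    summaries = []
    for vignette in responses.columns:
        vals = responses[vignette].dropna()
        if vals.empty:
            raise ElicitationError(f"vignette {vignette!r} has no responses")
        bad = vals[(vals < 0) | (vals > 1)]
        if not bad.empty:
            raise ElicitationError(
                f"response outside [0,1] for expert {bad.index[0]!r}, vignette {vignette!r}"
            )
        profile = dict((vignette_profiles or {}).get(vignette, {}))
        summaries.append(
            ExpertSummary(
                transition=transition,
                vignette_id=str(vignette),
                mean=float(vals.mean()),
                minimum=float(vals.min()),
                maximum=float(vals.max()),
                n_experts=int(len(vals)),
                vignette_profile=profile,
            )
        )
    return summaries


def _interval_loss(log_alpha: float, mean: float, lo: float, hi: float, level: float) -> float:
    alpha = np.exp(log_alpha)
    beta = alpha * (1.0 - mean) / mean
    tail = (1.0 - level) / 2.0
    q_lo, q_hi = stats.beta.ppf([tail, 1.0 - tail], alpha, beta)
    return (q_lo - lo) ** 2 + (q_hi - hi) ** 2


def fit_beta_interval(
    summary: ExpertSummary, level: float, tol: float = 1e-3
) -> BetaPrior:
    """Fit Beta(alpha, beta) whose central interval at ``level`` is [min, max].

    The expert mean is a hard constraint (``alpha / (alpha+beta) = mean``),
    leaving a 1-D search over ``alpha``; ties break toward the smaller
    (weaker) ``alpha``.  When no beta with the given mean can place both
    endpoints within ``tol``, the best-fitting prior is returned with
    ``feasible=False``.
    """
    if summary.degenerate:
        raise ElicitationError(
            f"vignette {summary.vignette_id} has min == max; the interval method "
            "cannot set a strength — use the sample_size method instead"
        )
    m, lo, hi = summary.mean, summary.minimum, summary.maximum
    if not (0.0 < m < 1.0):
        raise ElicitationError("interval fit requires mean strictly inside (0, 1)")

    # coarse grid over log alpha, then local refinement; grid-first keeps the
    # search deterministic and avoids local minima of the two-endpoint loss
    grid = np.linspace(np.log(1e-3), np.log(1e6), 400)
    losses = [_interval_loss(g, m, lo, hi, level) for g in grid]
    best = int(np.argmin(losses))
    span = grid[1] - grid[0]
    res = optimize.minimize_scalar(
        _interval_loss,
        bounds=(grid[best] - 2 * span, grid[best] + 2 * span),
        args=(m, lo, hi, level),
        method="bounded",
        options={"xatol": 1e-10},
    )
    alpha = float(np.exp(res.x))
    beta = alpha * (1.0 - m) / m
    tail = (1.0 - level) / 2.0
    q_lo, q_hi = stats.beta.ppf([tail, 1.0 - tail], alpha, beta)
    feasible = abs(q_lo - lo) <= tol and abs(q_hi - hi) <= tol
    return BetaPrior(
        alpha=alpha,
        beta=beta,
        source=f"confidence_interval(level={level})",
        feasible=feasible,
        vignette_profile=summary.vignette_profile,
    )


def fit_beta_samplesize(summary: ExpertSummary, spec: PriorStrengthSpec) -> BetaPrior:
    """Beta prior worth ``sample_size_fraction`` of the study cohort."""
    if spec.method != "sample_size":
        raise ConfigurationError("fit_beta_samplesize requires a sample_size spec")
    f, n = spec.sample_size_fraction, spec.cohort_n
    m = summary.mean
    ess = f * n
    if ess * min(m, 1.0 - m) <= 0.0:
        raise ElicitationError(
            f"vignette {summary.vignette_id}: degenerate prior "
            f"(f={f}, cohort_n={n}, mean={m})"
        )
    return BetaPrior(
        alpha=m * ess,
        beta=(1.0 - m) * ess,
        source=f"sample_size(fraction={f}, cohort_n={n})",
        vignette_profile=summary.vignette_profile,
    )


def priors_to_pseudodata(priors: Sequence[BetaPrior], offset: float = 0.0) -> PseudoData:
    """Express vignette priors as pseudo-observations at their profiles.

    Each prior contributes ``alpha - offset`` successes and ``beta -
    offset`` failures at its vignette's covariate row (offset 0 by
    default), so total pseudo-weight equals the summed effective prior
    sample size.
    """
    profiles, succ, fail = [], [], []
    for prior in priors:
        s, f = prior.alpha - offset, prior.beta - offset
        if s < 0 or f < 0:
            raise ElicitationError("pseudo-count offset exceeds alpha or beta")
        profiles.append(dict(prior.vignette_profile))
        succ.append(float(s))
        fail.append(float(f))
    return PseudoData(tuple(profiles), tuple(succ), tuple(fail))
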