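"""Bayesian logistic regression for the Markov model's transitions.

Each transition (ACS referral, post-discharge engagement, drug-related and
non-drug-related 12-month death) is a logistic regression of the binary
outcome on the shared covariate list (see :mod:`acsmarkov.model_design`).
Expert-elicited priors enter as weighted pseudo-observations: a vignette's
Beta(alpha, beta) prior contributes ``alpha`` successes and ``beta``
failures at the vignette's covariate profile, so the likelihood of the
augmented data is the posterior kernel.  Two reference priors are also
available: ``"flat"`` (no augmentation; the posterior mode is the MLE) and
``"kerman"`` (a neutral Beta(1/3, 1/3) worth of pseudo-data at the
covariate-mean row, which keeps the posterior proper under separation
while staying close to the classical fit).

Sampling is adaptive random-walk Metropolis: chains are initialised at the
(penalised) maximum-likelihood estimate, proposals are multivariate normal
with covariance proportional to the Laplace approximation
(scaled ``2.38^2 / d``), and each chain's global step scale is adapted
toward a 30% acceptance rate during burn-in only, so the retained chains
are draws from a fixed Markov kernel.  Convergence diagnostics
(rank-normalised split R-hat, effective sample size, autocorrelation) and
PSIS-LOO model comparison are computed with ``arviz``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import arviz as az
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from acsmarkov.elicitation import PseudoData
from acsmarkov.errors import DataError, SchemaError
from acsmarkov.model_design import design_matrix, model_terms, parameter_names

__all__ = [
    "TransitionModelSpec",
    "MCMCConfig",
    "PosteriorFit",
    "MarginalProbability",
    "fit_bayes_logistic",
    "fit_classical_logistic",
    "diagnose",
    "loo_compare",
    "marginal_prob_observed",
]

logger = logging.getLogger(__name__)

Prior = "PseudoData | Literal['kerman', 'flat']"


@dataclass(frozen=True)
class TransitionModelSpec:
    """One transition model: outcome, covariate terms, and prior."""

    outcome: Literal["referral", "engagement", "drug_death", "nondrug_death"]
    covariates: tuple[str, ...] | None = None
    prior: PseudoData | str = "flat"

    @property
    def terms(self) -> tuple[str, ...]:
        return self.covariates if self.covariates is not None else model_terms(self.outcome)


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings.  ``n_draws`` is the total retained across chains."""

    n_draws: int = 10_000
    n_burnin: int = 2_000
    n_chains: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_draws <= 0 or self.n_burnin < 0 or self.n_chains < 1:
            raise ValueError("need n_draws > 0, n_burnin >= 0, n_chains >= 1")


@dataclass
class PosteriorFit:
    """Posterior draws and the data needed for diagnostics and LOO."""

    draws: np.ndarray  # (chains, draws_per_chain, n_params)
    parameter_names: list[str]
    spec: TransitionModelSpec | None = None
    X: np.ndarray | None = None
    y: np.ndarray | None = None
    acceptance_rate: float = float("nan")
    n_dropped_rows: int = 0
    separation_flag: bool = False

    @property
    def flat_draws(self) -> np.ndarray:
        """Draws pooled across chains, shape (total_draws, n_params)."""
        return self.draws.reshape(-1, self.draws.shape[-1])

    def to_inference_data(self, with_log_likelihood: bool = False) -> az.InferenceData:
        posterior = {
            name: self.draws[:, :, j] for j, name in enumerate(self.parameter_names)
        }
        groups: dict = {"posterior": posterior}
        if with_log_likelihood:
            groups["log_likelihood"] = {"y": self.pointwise_log_likelihood()}
        return az.from_dict(**groups)

    def pointwise_log_likelihood(self) -> np.ndarray:
        """Per-observation log-likelihood, shape (chains, draws, n_obs).

        Computed over the observed rows only — pseudo-data rows are prior,
        not data, and are excluded from predictive comparisons.
        """
        if self.X is None or self.y is None:
            raise ValueError("fit carries no observed data")
        chains, per_chain, _ = self.draws.shape
        eta = np.einsum("cdk,nk->cdn", self.draws, self.X)
        return self.y[None, None, :] * eta - np.logaddexp(0.0, eta)


@dataclass(frozen=True)
class MarginalProbability:
    """Observed-case-averaged probability with a central 95% interval."""

    point: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.lower <= self.point <= self.upper <= 1.0):
            raise ValueError("need 0 <= lower <= point <= upper <= 1")


# --------------------------------------------------------------------------
# design assembly


def _prepare_design(
    table: pd.DataFrame, spec: TransitionModelSpec
) -> tuple[np.ndarray, np.ndarray, int]:
    terms = spec.terms
    needed = {"race" if t.startswith("race_") else t for t in terms} | {spec.outcome}
    missing = needed - set(table.columns)
    if missing:
        raise SchemaError(f"analysis table missing columns {sorted(missing)}")
    complete = table.dropna(subset=sorted(needed))
    n_dropped = len(table) - len(complete)
    if n_dropped:
        logger.info("dropped %d rows with missing covariates", n_dropped)
    y = complete[spec.outcome].to_numpy(dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise SchemaError(f"outcome column {spec.outcome!r} is not binary 0/1")
    X = design_matrix(complete, terms)
    return X, y, n_dropped


def _profile_row(
    profile: Mapping[str, float], terms: tuple[str, ...], col_means: np.ndarray
) -> np.ndarray:
    """Design row for a vignette profile; unspecified terms sit at the
    observed covariate means."""
    unknown = set(profile) - set(terms)
    if unknown:
        raise SchemaError(f"vignette profile names covariates {sorted(unknown)} "
                          "absent from the model")
    row = col_means.copy()
    for j, t in enumerate(terms, start=1):
        if t in profile:
            row[j] = float(profile[t])
    row[0] = 1.0
    return row


def _pseudo_arrays(
    spec: TransitionModelSpec, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pseudo-data design rows with success/failure weights for the prior."""
    terms = spec.terms
    col_means = X.mean(axis=0)
    prior = spec.prior
    if isinstance(prior, PseudoData):
        if len(prior) == 0:
            return np.empty((0, X.shape[1])), np.empty(0), np.empty(0)
        rows = np.array([_profile_row(p, terms, col_means) for p in prior.profiles])
        return rows, np.asarray(prior.successes), np.asarray(prior.failures)
    if prior == "kerman":
        # Kerman's neutral Beta(1/3, 1/3), attached at the covariate means
        return col_means[None, :], np.array([1.0 / 3.0]), np.array([1.0 / 3.0])
    if prior == "flat":
        return np.empty((0, X.shape[1])), np.empty(0), np.empty(0)
    raise SchemaError(f"unknown prior {prior!r}")


def _penalized_mle(
    X: np.ndarray, y: np.ndarray, Xp: np.ndarray, s: np.ndarray, f: np.ndarray
):
    """Weighted-binomial GLM over observed rows plus pseudo rows."""
    if len(Xp):
        w = s + f
        endog = np.concatenate([y, s / w])
        exog = np.vstack([X, Xp])
        weights = np.concatenate([np.ones(len(y)), w])
    else:
        endog, exog, weights = y, X, np.ones(len(y))
    model = sm.GLM(endog, exog, family=sm.families.Binomial(), var_weights=weights)
    return model.fit()


def fit_classical_logistic(table: pd.DataFrame, spec: TransitionModelSpec):
    """Classical maximum-likelihood logistic fit (internal-validity oracle).

    Returns a pandas DataFrame with ``coef`` and ``se`` per parameter.
    """
    X, y, _ = _prepare_design(table, spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    if not np.all(np.isfinite(res.bse)):
        warnings.warn(f"{spec.outcome}: possible separation, standard errors unstable")
    return pd.DataFrame(
        {"coef": res.params, "se": res.bse}, index=parameter_names(spec.terms)
    )


# --------------------------------------------------------------------------
# sampler


def _log_posterior(B, X, y, Xp, s, f):
    """Log posterior kernel for coefficient columns ``B`` (d, n_chains)."""
    eta = X @ B
    ll = y @ eta - np.logaddexp(0.0, eta).sum(axis=0)
    if len(Xp):
        etap = Xp @ B
        ll = ll + s @ etap - (s + f) @ np.logaddexp(0.0, etap)
    return ll


def fit_bayes_logistic(
    table: pd.DataFrame, spec: TransitionModelSpec, mcmc: MCMCConfig
) -> PosteriorFit:
    """Sample the posterior of one transition model.

    Rows with missing covariates are dropped (count logged and recorded on
    the fit).  Identical ``(table, spec, mcmc)`` including the seed give
    identical draws.
    """
    X, y, n_dropped = _prepare_design(table, spec)
    Xp, s, f = _pseudo_arrays(spec, X)
    d = X.shape[1]

    separation = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=sm.tools.sm_exceptions.PerfectSeparationWarning)
            mle = _penalized_mle(X, y, Xp, s, f)
        beta0 = np.asarray(mle.params, dtype=float)
        cov = np.asarray(mle.cov_params(), dtype=float)
        if not (np.all(np.isfinite(beta0)) and np.all(np.isfinite(cov))):
            raise ValueError("non-finite MLE")
    except Exception:  # separation or other MLE failure: fall back, flag it
        separation = True
        warnings.warn(
            f"{spec.outcome}: MLE initialisation failed (possible complete "
            "separation with a weak prior); falling back to a ridge start"
        )
        beta0 = np.zeros(d)
        cov = np.eye(d)
    # symmetrise + jitter so Cholesky always succeeds
    cov = (cov + cov.T) / 2.0 + 1e-10 * np.eye(d)
    L = np.linalg.cholesky(cov)

    rng = np.random.default_rng(mcmc.seed)
    C = mcmc.n_chains
    per_chain = int(np.ceil(mcmc.n_draws / C))
    scale = np.full(C, 2.38 / np.sqrt(d))

    B = beta0[:, None] + 0.1 * (L @ rng.standard_normal((d, C)))
    lp = _log_posterior(B, X, y, Xp, s, f)

    kept = np.empty((C, per_chain, d))
    accepted_post = 0
    acc_window = np.zeros(C)
    total = mcmc.n_burnin + per_chain
    for t in range(total):
        prop = B + scale[None, :] * (L @ rng.standard_normal((d, C)))
        lp_prop = _log_posterior(prop, X, y, Xp, s, f)
        accept = np.log(rng.random(C)) < (lp_prop - lp)
        B[:, accept] = prop[:, accept]
        lp[accept] = lp_prop[accept]
        acc_window += accept
        if t < mcmc.n_burnin:
            if (t + 1) % 50 == 0:  # adapt step scale during burn-in only
                rate = acc_window / 50.0
                scale *= np.exp(rate - 0.30)
                acc_window[:] = 0.0
        else:
            kept[:, t - mcmc.n_burnin, :] = B.T
            accepted_post += int(accept.sum())

    return PosteriorFit(
        draws=kept,
        parameter_names=parameter_names(spec.terms),
        spec=spec,
        X=X,
        y=y,
        acceptance_rate=accepted_post / (per_chain * C),
        n_dropped_rows=n_dropped,
        separation_flag=separation,
    )


# --------------------------------------------------------------------------
# diagnostics, model comparison, marginal probabilities

RHAT_THRESHOLD = 1.01
ESS_THRESHOLD = 1_000.0
PARETO_K_THRESHOLD = 0.7


def diagnose(fit: PosteriorFit, autocorr_lags: tuple[int, ...] = (1, 5, 10)) -> dict:
    """Per-parameter convergence report.

    Uses rank-normalised split R-hat and bulk effective sample size; for a
    single chain, R-hat is the split-chain version (noted in the report).
    ``passed`` requires every R-hat < 1.01 and every ESS > 1,000.
    """
    idata = fit.to_inference_data()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = az.rhat(idata)
        ess = az.ess(idata)
    report: dict = {"parameters": {}, "notes": []}
    if fit.draws.shape[0] == 1:
        report["notes"].append("single chain: R-hat computed by the split-chain method")
    if fit.separation_flag:
        report["notes"].append("possible separation flagged during initialisation")
    for j, name in enumerate(fit.parameter_names):
        chain_draws = fit.draws[:, :, j]
        acf = {
            f"lag_{k}": float(
                np.mean([az.autocorr(chain_draws[c])[k] for c in range(chain_draws.shape[0])])
            )
            for k in autocorr_lags
        }
        report["parameters"][name] = {
            "rhat": float(rhat[name].values),
            "ess": float(ess[name].values),
            "autocorrelation": acf,
        }
    report["max_rhat"] = max(p["rhat"] for p in report["parameters"].values())
    report["min_ess"] = min(p["ess"] for p in report["parameters"].values())
    report["passed"] = bool(
        report["max_rhat"] < RHAT_THRESHOLD and report["min_ess"] > ESS_THRESHOLD
    )
    return report


def loo_compare(fits: Sequence[PosteriorFit], names: Sequence[str] | None = None):
    """PSIS-LOO comparison of fits sharing the same observed rows.

    Returns ``(table, loos)``: an ``arviz.compare``-style ranking (higher
    elpd ranks first) and the per-model ``ELPDData`` with Pareto-k values.
    Models with any Pareto k above 0.7 are flagged unreliable.
    """
    if names is None:
        names = [f"model_{i}" for i in range(len(fits))]
    n_obs = {len(f.y) for f in fits if f.y is not None}
    if len(n_obs) != 1:
        raise ValueError("fits must share identical observed data rows")
    loos = {}
    for name, fit in zip(names, fits):
        idata = fit.to_inference_data(with_log_likelihood=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            loos[name] = az.loo(idata, pointwise=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = az.compare(loos, ic="loo")
    table = table.copy()
    table["reliable"] = [
        bool((loos[n].pareto_k < PARETO_K_THRESHOLD).all()) for n in table.index
    ]
    return table, loos


def marginal_prob_observed(
    fit: PosteriorFit,
    table: pd.DataFrame,
    covariate: str | None = None,
    value: float | None = None,
) -> MarginalProbability:
    """Posterior of the observed-case-averaged predicted probability.

    For each posterior draw, the inverse-logit linear predictor is
    averaged over the observed covariate rows — optionally with
    ``covariate`` forced to ``value`` for every row — and the resulting
    draw-level averages are summarised by their mean and central 95%
    interval.
    """
    if fit.spec is None:
        raise ValueError("fit carries no model spec")
    terms = fit.spec.terms
    work = table.copy()
    if covariate is not None:
        if covariate not in terms:
            raise SchemaError(f"covariate {covariate!r} not in the model")
        if value is None:
            raise ValueError("value required when covariate is given")
        col = work[covariate]
        if set(np.unique(col.dropna())) <= {0, 1} and value not in (0, 1):
            raise DataError(f"value {value!r} outside the domain of binary covariate {covariate!r}")
        work[covariate] = value
    X = design_matrix(work.dropna(subset=[c for c in work.columns if c in terms or c == "race"]),
                      terms)
    draws = fit.flat_draws
    p = expit(X @ draws.T).mean(axis=0)  # (total_draws,)
    lower, upper = np.percentile(p, [2.5, 97.5])
    return MarginalProbability(float(p.mean()), float(lower), float(upper))
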