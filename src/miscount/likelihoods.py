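"""Log-likelihoods and log-priors of the joint misclassification model.

Three sub-models multiply into the joint posterior:

* outcome model — Poisson counts with log-linear rate and a cluster random
  intercept: ``y_ij ~ Poisson(r_ij * lambda_ij)``,
  ``log lambda_ij = beta0 + u_j + beta1 * x_ij + sum_k beta_k z_ijk``;
* exposure model — Bernoulli true exposure with a logistic link and its own
  cluster random intercept:
  ``logit pi_ij = gamma0 + v_j + sum_k gamma_k z_ijk``;
* measurement model — nondifferential misclassification: given true
  exposure x = 1 an assessment reports 1 with probability S (sensitivity);
  given x = 0 it reports 1 with probability 1 - C (specificity C).  Two
  assessments are conditionally independent given x.

All functions return sums of per-subject log-densities.  The Poisson and
Bernoulli kernels are written out explicitly (they are also the sampler's
hot path); tests cross-check them against scipy.stats.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, gammaln
from scipy.stats import beta as beta_dist
from scipy.stats import norm

from .data import (
    Dataset,
    DimensionError,
    InvalidParameterError,
    Mode,
    ParameterState,
    PriorSpec,
)

__all__ = [
    "outcome_loglik",
    "exposure_loglik",
    "measurement_loglik_one",
    "measurement_loglik_two",
    "prior_logdensity",
    "joint_log_posterior",
]


def outcome_linpred(data: Dataset, state: ParameterState, x: np.ndarray) -> np.ndarray:
    """Linear predictor of the outcome model, ``log lambda`` per subject."""
    if data.z_outcome.shape[1] != state.beta.shape[0]:
        raise DimensionError(
            f"z_outcome has {data.z_outcome.shape[1]} columns but beta has "
            f"{state.beta.shape[0]} coefficients"
        )
    return (
        state.beta0
        + state.u[data.cluster_index]
        + state.beta1 * np.asarray(x, dtype=float)
        + data.z_outcome @ state.beta
    )


def outcome_loglik(data: Dataset, state: ParameterState, x: np.ndarray) -> float:
    """Poisson log-likelihood of the counts given exposure vector ``x``."""
    eta = outcome_linpred(data, state, x)
    mu = data.r * np.exp(eta)
    return float(np.sum(data.y * np.log(mu) - mu - gammaln(data.y + 1.0)))


def exposure_linpred(data: Dataset, state: ParameterState) -> np.ndarray:
    if data.z_exposure.shape[1] != state.gamma.shape[0]:
        raise DimensionError(
            f"z_exposure has {data.z_exposure.shape[1]} columns but gamma has "
            f"{state.gamma.shape[0]} coefficients"
        )
    return state.gamma0 + state.v[data.cluster_index] + data.z_exposure @ state.gamma


def exposure_loglik(data: Dataset, state: ParameterState, x: np.ndarray) -> float:
    """Bernoulli-logit log-likelihood of true exposure vector ``x``."""
    eta = exposure_linpred(data, state)
    x = np.asarray(x, dtype=float)
    # x*log(pi) + (1-x)*log(1-pi) = x*eta - log(1 + e^eta), stable form
    return float(np.sum(x * eta - np.logaddexp(0.0, eta)))


def _check_sc(name: str, value: float) -> None:
    if not 0.0 < value < 1.0:
        raise InvalidParameterError(f"{name} must lie in the open interval (0, 1)")


def measurement_loglik_one(
    x1: np.ndarray, x: np.ndarray, S1: float, C1: float
) -> float:
    """Log-likelihood of one fallible assessment given true exposure.

    Given x = 1 the assessment is Bernoulli(S1); given x = 0 it reports 1
    with probability 1 - C1 (nondifferential misclassification).
    """
    _check_sc("S1", S1)
    _check_sc("C1", C1)
    x1 = np.asarray(x1)
    x = np.asarray(x)
    if x1.shape != x.shape:
        raise DimensionError(
            f"assessment vector has length {x1.shape} but x has {x.shape}"
        )
    ll_exposed = x1 * np.log(S1) + (1 - x1) * np.log1p(-S1)
    ll_unexposed = (1 - x1) * np.log(C1) + x1 * np.log1p(-C1)
    return float(np.sum(np.where(x == 1, ll_exposed, ll_unexposed)))


def measurement_loglik_two(
    x1: np.ndarray,
    x2: np.ndarray,
    x: np.ndarray,
    S1: float,
    C1: float,
    S2: float,
    C2: float,
) -> float:
    """Joint log-likelihood of two conditionally independent assessments."""
    return measurement_loglik_one(x1, x, S1, C1) + measurement_loglik_one(
        x2, x, S2, C2
    )


def _beta_logpdf(value: float, shape: tuple[float, float]) -> float:
    return float(beta_dist.logpdf(value, *shape))


def prior_logdensity(
    state: ParameterState, priors: PriorSpec, mode: Mode | str
) -> float:
    """Sum of all prior log-densities present in the given mode.

    Coefficients: mean-zero normals with variance ``beta_var`` (outcome) and
    ``gamma_var`` (exposure).  Random intercepts: N(0, sigma^2) and
    N(0, nu^2) respectively.  sigma and nu: uniform(0, sd_upper), minus
    infinity outside the support.  Each sensitivity/specificity present gets
    its beta prior.
    """
    mode = Mode(mode)
    total = 0.0

    beta_sd = np.sqrt(priors.beta_var)
    total += norm.logpdf(state.beta0, 0.0, beta_sd)
    total += norm.logpdf(state.beta1, 0.0, beta_sd)
    total += norm.logpdf(state.beta, 0.0, beta_sd).sum()

    if state.sigma >= priors.sd_upper:
        return -np.inf
    total += -np.log(priors.sd_upper)
    total += norm.logpdf(state.u, 0.0, state.sigma).sum()

    if mode == Mode.NAIVE:
        return float(total)

    gamma_sd = np.sqrt(priors.gamma_var)
    total += norm.logpdf(state.gamma0, 0.0, gamma_sd)
    total += norm.logpdf(state.gamma, 0.0, gamma_sd).sum()
    if state.nu >= priors.sd_upper:
        return -np.inf
    total += -np.log(priors.sd_upper)
    total += norm.logpdf(state.v, 0.0, state.nu).sum()

    total += _beta_logpdf(state.S1, priors.s1_shape)
    total += _beta_logpdf(state.C1, priors.c1_shape)
    if mode == Mode.TWO_TEST:
        # Identifiability convention: each test is better than chance
        # (S + C > 1).  Without it the two-test likelihood is invariant
        # under relabeling the latent exposure, which mirrors (S, C) to
        # (1-C, 1-S), and flat priors leave the posterior bimodal.
        if state.S1 + state.C1 <= 1.0 or state.S2 + state.C2 <= 1.0:
            return -np.inf
        total += _beta_logpdf(state.S2, priors.s2_shape)
        total += _beta_logpdf(state.C2, priors.c2_shape)
    return float(total)


def joint_log_posterior(
    data: Dataset, state: ParameterState, priors: PriorSpec, mode: Mode | str
) -> float:
    """Unnormalized joint log posterior of the full model.

    In naive mode the first assessment is treated as the true exposure and
    only the outcome model and its priors contribute.  In one_test/two_test
    modes the current latent exposure ``state.x_latent`` enters the outcome
    and exposure models, and the measurement model ties it to the observed
    assessments.
    """
    mode = Mode(mode)
    lp = prior_logdensity(state, priors, mode)
    if not np.isfinite(lp):
        return -np.inf
    if mode == Mode.NAIVE:
        return lp + outcome_loglik(data, state, data.x1)

    x = state.x_latent
    if x is None:
        raise InvalidParameterError(f"{mode.value} mode requires state.x_latent")
    lp += outcome_loglik(data, state, x)
    lp += exposure_loglik(data, state, x)
    if mode == Mode.ONE_TEST:
        lp += measurement_loglik_one(data.x1, x, state.S1, state.C1)
    else:
        lp += measurement_loglik_two(
            data.x1, data.x2, x, state.S1, state.C1, state.S2, state.C2
        )
    return float(lp)


def latent_x_probability(
    data: Dataset, state: ParameterState, mode: Mode | str
) -> np.ndarray:
    """P(x_ij = 1 | everything else) for every subject, vectorized.

    Two-point Bayes: with A proportional to pi * Poisson(y; r*lambda(x=1)) *
    f(assessments | x=1) and B the x = 0 analogue, returns A / (A + B),
    computed stably on the log scale.
    """
    mode = Mode(mode)
    if mode == Mode.NAIVE:
        raise InvalidParameterError("naive mode has no latent exposure")
    eta_exp = exposure_linpred(data, state)
    eta0 = outcome_linpred(data, state, np.zeros(data.n_subjects))
    # log A - log B collapses to a single per-subject logit
    delta = (
        data.y * state.beta1
        - data.r * np.exp(eta0) * np.expm1(state.beta1)
        + eta_exp
    )
    x1 = data.x1
    delta = delta + x1 * np.log(state.S1 / (1.0 - state.C1)) + (1 - x1) * np.log(
        (1.0 - state.S1) / state.C1
    )
    if mode == Mode.TWO_TEST:
        x2 = data.x2
        delta = delta + x2 * np.log(state.S2 / (1.0 - state.C2)) + (
            1 - x2
        ) * np.log((1.0 - state.S2) / state.C2)
    return expit(delta)
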