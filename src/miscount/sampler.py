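"""Metropolis-within-Gibbs sampler with data augmentation of the latent exposure.

One sweep updates, in order:

1. every latent true-exposure indicator from its exact Bernoulli full
   conditional (two-point Bayes over x in {0, 1});
2. each regression coefficient (beta0, beta1, beta_k; gamma0, gamma_k) by
   scalar random-walk Metropolis on the joint log posterior;
3. the cluster random intercepts u and v, proposed for all clusters at once
   and accepted/rejected cluster-by-cluster (their full conditionals are
   independent given the rest);
4. the random-intercept SDs sigma and nu by random-walk Metropolis on the
   log scale with the log-Jacobian, respecting the uniform upper bound;
5. each sensitivity/specificity by a conjugate beta draw from the
   augmented-data likelihood (e.g. S1 ~ beta(a + #(x=1, x1=1),
   b + #(x=1, x1=0))).

Proposal scales adapt by Robbins-Monro toward 0.44 acceptance during
burn-in only and are frozen afterwards, so the post-burn-in kernel is a
fixed, detailed-balance-preserving composition.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .data import (
    Dataset,
    InvalidParameterError,
    MiscountError,
    Mode,
    ParameterState,
    PriorSpec,
)
from .likelihoods import latent_x_probability

__all__ = [
    "ChainConfig",
    "PosteriorSample",
    "latent_x_full_conditional",
    "gibbs_step",
    "run_chain",
    "summarize",
]

_TARGET_ACCEPT = 0.44


@dataclass
class ChainConfig:
    """MCMC run settings.

    ``n_iter`` counts post-burn-in draws; ``n_burn`` sweeps are discarded
    (and used for proposal adaptation).  ``proposal_scales`` maps block
    names ('beta', 'gamma', 'u', 'v', 'log_sd') to initial random-walk SDs;
    adaptation normally makes the initial values immaterial.
    """

    n_iter: int = 3000
    n_burn: int = 1500
    seed: int = 0
    thin: int = 1
    proposal_scales: dict = field(default_factory=dict)
    adapt: bool = True
    monitor_random_effects: bool = False

    def __post_init__(self) -> None:
        if self.n_iter < 1 or self.n_burn < 1 or self.thin < 1:
            raise ValueError("n_iter, n_burn and thin must all be >= 1")
        for k, s in self.proposal_scales.items():
            if s <= 0:
                raise ValueError(f"proposal scale {k!r} must be > 0")


@dataclass
class PosteriorSample:
    """Retained MCMC draws plus chain metadata."""

    draws: np.ndarray
    names: list[str]
    config: ChainConfig
    acceptance_rates: dict[str, float]
    mode: Mode = Mode.NAIVE

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.draws, columns=self.names)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.draws[:, self.names.index(name)]


def latent_x_full_conditional(
    data: Dataset,
    state: ParameterState,
    mode: Mode | str,
    pi: np.ndarray | None = None,
) -> np.ndarray:
    """Exact P(x_ij = 1 | all else) per subject.

    ``pi`` optionally overrides the exposure-model probability (useful for
    degenerate checks; pi = 1 forces probability 1 whatever the data say).
    """
    mode = Mode(mode)
    if pi is None:
        return latent_x_probability(data, state, mode)
    state = state.copy()
    with np.errstate(divide="ignore"):
        lo = logit(np.broadcast_to(np.asarray(pi, dtype=float), (data.n_subjects,)))
    # fold the override into gamma0 path by direct computation
    eta0 = (
        state.beta0
        + state.u[data.cluster_index]
        + data.z_outcome @ state.beta
    )
    delta = data.y * state.beta1 - data.r * np.exp(eta0) * np.expm1(state.beta1) + lo
    x1 = data.x1
    delta = delta + x1 * np.log(state.S1 / (1 - state.C1)) + (1 - x1) * np.log(
        (1 - state.S1) / state.C1
    )
    if mode == Mode.TWO_TEST:
        x2 = data.x2
        delta = delta + x2 * np.log(state.S2 / (1 - state.C2)) + (1 - x2) * np.log(
            (1 - state.S2) / state.C2
        )
    return expit(delta)


class _AdaptiveScale:
    """Robbins-Monro log-scale adaptation toward a target acceptance rate."""

    def __init__(self, scale: float):
        self.log_scale = math.log(scale)
        self.t = 0

    @property
    def scale(self) -> float:
        return math.exp(self.log_scale)

    def update(self, accept_rate: float) -> None:
        self.t += 1
        self.log_scale += (accept_rate - _TARGET_ACCEPT) / self.t**0.6
        self.log_scale = min(max(self.log_scale, -12.0), 6.0)


class MCMC:
    """Stateful sampler over one dataset.  ``run_chain`` is the public face.

    Caches the outcome linear predictor without the exposure term
    (``eta_base``), the Poisson means ``mu``, and the exposure linear
    predictor ``eta_exp``; every update touches only what it must.
    """

    def __init__(
        self,
        data: Dataset,
        priors: PriorSpec,
        mode: Mode | str,
        config: ChainConfig,
        rng: np.random.Generator | None = None,
        init: ParameterState | None = None,
    ):
        self.mode = Mode(mode)
        priors.validate_for_mode(self.mode)
        if data.x1 is None:
            raise InvalidParameterError("data must carry the x1 assessment")
        if self.mode == Mode.TWO_TEST and data.x2 is None:
            raise InvalidParameterError("two_test mode requires the x2 assessment")
        self.data = data
        self.priors = priors
        self.config = config
        self.rng = rng if rng is not None else np.random.default_rng(config.seed)

        d = data
        self.cl = d.cluster_index
        self.N = d.n_clusters
        self.n = d.n_subjects
        self.p1 = d.z_outcome.shape[1]
        self.q = d.z_exposure.shape[1]
        self.y = d.y.astype(float)
        self.r = d.r
        self.logr = np.log(d.r)
        self.sum_y = float(self.y.sum())
        self.cluster_sum_y = np.bincount(self.cl, weights=self.y, minlength=self.N)
        self.cluster_size = np.bincount(self.cl, minlength=self.N)

        sc = dict(config.proposal_scales)
        self._scales = {
            "beta0": _AdaptiveScale(sc.get("beta", 0.02)),
            "beta1": _AdaptiveScale(sc.get("beta", 0.05)),
            "u": _AdaptiveScale(sc.get("u", 0.05)),
            "log_sigma": _AdaptiveScale(sc.get("log_sd", 0.5)),
        }
        for k in range(self.p1):
            self._scales[f"beta{k + 2}"] = _AdaptiveScale(sc.get("beta", 0.02))
        if self.mode != Mode.NAIVE:
            self._scales["gamma0"] = _AdaptiveScale(sc.get("gamma", 0.1))
            for k in range(self.q):
                self._scales[f"gamma{k + 1}"] = _AdaptiveScale(sc.get("gamma", 0.05))
            self._scales["v"] = _AdaptiveScale(sc.get("v", 0.1))
            self._scales["log_nu"] = _AdaptiveScale(sc.get("log_sd", 0.5))
        self._accept_counts = {k: 0 for k in self._scales}
        self._accept_trials = {k: 0 for k in self._scales}
        self.adapting = bool(config.adapt)

        if init is None:
            init = self.default_init()
        self.set_state(init)

    # ------------------------------------------------------------ state

    def default_init(self) -> ParameterState:
        """Coefficients at 0, SDs at 0.1, S/C at prior means, x at x1."""
        p = self.priors
        kw: dict = dict(
            beta0=0.0,
            beta1=0.0,
            beta=np.zeros(self.p1),
            u=np.zeros(self.N),
            sigma=0.1,
        )
        if self.mode != Mode.NAIVE:
            kw.update(
                gamma0=0.0,
                gamma=np.zeros(self.q),
                v=np.zeros(self.N),
                nu=0.1,
                S1=p.s1_shape[0] / sum(p.s1_shape),
                C1=p.c1_shape[0] / sum(p.c1_shape),
                x_latent=self.data.x1.copy(),
            )
            if self.mode == Mode.TWO_TEST:
                kw.update(
                    S2=p.s2_shape[0] / sum(p.s2_shape),
                    C2=p.c2_shape[0] / sum(p.c2_shape),
                )
        return ParameterState(**kw)

    def set_state(self, state: ParameterState) -> None:
        s = state.copy()
        self.beta0 = s.beta0
        self.beta1 = s.beta1
        self.beta = s.beta
        self.u = s.u
        self.sigma = s.sigma
        self.gamma0 = s.gamma0
        self.gamma = s.gamma
        self.v = s.v
        self.nu = s.nu
        self.S1, self.C1, self.S2, self.C2 = s.S1, s.C1, s.S2, s.C2
        if self.mode == Mode.NAIVE:
            self.x = self.data.x1.astype(float)
        else:
            if s.x_latent is None:
                s.x_latent = self.data.x1.copy()
            self.x = s.x_latent.astype(float)
        self._refresh_caches()

    def get_state(self) -> ParameterState:
        return ParameterState(
            beta0=self.beta0,
            beta1=self.beta1,
            beta=self.beta.copy(),
            u=self.u.copy(),
            sigma=self.sigma,
            gamma0=self.gamma0,
            gamma=None if self.gamma is None else self.gamma.copy(),
            v=None if self.v is None else self.v.copy(),
            nu=self.nu,
            S1=self.S1,
            C1=self.C1,
            S2=self.S2,
            C2=self.C2,
            x_latent=None if self.mode == Mode.NAIVE else self.x.astype(np.int8),
        )

    def _refresh_caches(self) -> None:
        self.eta_base = (
            self.beta0 + self.u[self.cl] + self.data.z_outcome @ self.beta
        )
        self.mu = self.r * np.exp(self.eta_base + self.beta1 * self.x)
        if self.mode != Mode.NAIVE:
            self.eta_exp = (
                self.gamma0 + self.v[self.cl] + self.data.z_exposure @ self.gamma
            )

    def replace_observations(
        self, y: np.ndarray, x1: np.ndarray, x2: np.ndarray | None = None,
        x_latent: np.ndarray | None = None,
    ) -> None:
        """Swap in new observed data (used by joint-distribution tests)."""
        self.y = np.asarray(y, dtype=float)
        self.data.y = np.asarray(y)
        self.data.x1 = np.asarray(x1, dtype=np.int8)
        if x2 is not None:
            self.data.x2 = np.asarray(x2, dtype=np.int8)
        self.sum_y = float(self.y.sum())
        self.cluster_sum_y = np.bincount(self.cl, weights=self.y, minlength=self.N)
        if x_latent is not None:
            self.x = np.asarray(x_latent, dtype=float)
        elif self.mode == Mode.NAIVE:
            self.x = self.data.x1.astype(float)
        self._refresh_caches()

    # ---------------------------------------------------------- updates

    def _check_finite(self, block: str) -> None:
        if not np.isfinite(self.mu).all():
            raise MiscountError(
                f"non-finite Poisson mean encountered while updating {block!r}"
            )

    def _metropolis(self, name: str, logratio_fn, apply_fn) -> None:
        """Scalar random-walk Metropolis step for block ``name``."""
        scale = self._scales[name].scale
        d = scale * self.rng.standard_normal()
        logr = logratio_fn(d)
        accept = math.log(self.rng.random()) < logr
        if accept:
            apply_fn(d)
        self._accept_trials[name] += 1
        self._accept_counts[name] += accept
        if self.adapting:
            self._scales[name].update(float(accept))

    def _update_latent_x(self) -> None:
        y, r = self.y, self.r
        eta0 = self.eta_base
        delta = (
            y * self.beta1
            - r * np.exp(eta0) * math.expm1(self.beta1)
            + self.eta_exp
        )
        x1 = self.data.x1
        delta = delta + np.where(
            x1 == 1,
            math.log(self.S1 / (1.0 - self.C1)),
            math.log((1.0 - self.S1) / self.C1),
        )
        if self.mode == Mode.TWO_TEST:
            x2 = self.data.x2
            delta = delta + np.where(
                x2 == 1,
                math.log(self.S2 / (1.0 - self.C2)),
                math.log((1.0 - self.S2) / self.C2),
            )
        p = expit(delta)
        self.x = (self.rng.random(self.n) < p).astype(float)
        self.mu = r * np.exp(eta0 + self.beta1 * self.x)

    def _update_beta0(self) -> None:
        prior_var = self.priors.beta_var

        def logratio(d):
            ll = d * self.sum_y - math.expm1(d) * self.mu.sum()
            lp = ((self.beta0**2) - (self.beta0 + d) ** 2) / (2 * prior_var)
            return ll + lp

        def apply(d):
            self.beta0 += d
            f = math.exp(d)
            self.eta_base += d
            self.mu *= f

        self._metropolis("beta0", logratio, apply)

    def _update_beta1(self) -> None:
        prior_var = self.priors.beta_var
        mask = self.x == 1.0
        y1 = float(self.y[mask].sum())
        mu1 = float(self.mu[mask].sum())

        def logratio(d):
            ll = d * y1 - math.expm1(d) * mu1
            lp = ((self.beta1**2) - (self.beta1 + d) ** 2) / (2 * prior_var)
            return ll + lp

        def apply(d):
            self.beta1 += d
            self.mu[mask] *= math.exp(d)

        self._metropolis("beta1", logratio, apply)

    def _update_beta_k(self, k: int) -> None:
        prior_var = self.priors.beta_var
        z = self.data.z_outcome[:, k]
        b = self.beta[k]

        def logratio(d):
            mu_new = self.mu * np.exp(d * z)
            ll = d * float(self.y @ z) - (mu_new.sum() - self.mu.sum())
            lp = (b**2 - (b + d) ** 2) / (2 * prior_var)
            return ll + lp

        def apply(d):
            self.beta[k] += d
            f = np.exp(d * z)
            self.eta_base += d * z
            self.mu *= f

        self._metropolis(f"beta{k + 2}", logratio, apply)

    def _update_u(self) -> None:
        scale = self._scales["u"].scale
        du = scale * self.rng.standard_normal(self.N)
        mu_sums = np.bincount(self.cl, weights=self.mu, minlength=self.N)
        ll = du * self.cluster_sum_y - np.expm1(du) * mu_sums
        lp = (self.u**2 - (self.u + du) ** 2) / (2 * self.sigma**2)
        accept = np.log(self.rng.random(self.N)) < ll + lp
        if accept.any():
            self.u = np.where(accept, self.u + du, self.u)
            shift = np.where(accept, du, 0.0)[self.cl]
            self.eta_base += shift
            self.mu *= np.exp(shift)
        rate = float(accept.mean())
        self._accept_trials["u"] += 1
        self._accept_counts["u"] += rate
        if self.adapting:
            self._scales["u"].update(rate)

    def _update_sigma(self) -> None:
        self._update_sd("log_sigma", "sigma", self.u)

    def _update_nu(self) -> None:
        self._update_sd("log_nu", "nu", self.v)

    def _update_sd(self, block: str, attr: str, effects: np.ndarray) -> None:
        cur = getattr(self, attr)
        ss = float(effects @ effects)
        N = effects.shape[0]

        def logratio(d):
            new = cur * math.exp(d)
            if new >= self.priors.sd_upper:
                return -np.inf
            ll = -N * (math.log(new) - math.log(cur)) - ss / 2 * (
                1 / new**2 - 1 / cur**2
            )
            return ll + d  # log-Jacobian of the log-scale walk

        def apply(d):
            setattr(self, attr, cur * math.exp(d))

        self._metropolis(block, logratio, apply)

    def _exposure_ll_vec(self, eta: np.ndarray) -> np.ndarray:
        return self.x * eta - np.logaddexp(0.0, eta)

    def _update_gamma0(self) -> None:
        prior_var = self.priors.gamma_var
        cur_ll = float(self._exposure_ll_vec(self.eta_exp).sum())

        def logratio(d):
            new_ll = float(self._exposure_ll_vec(self.eta_exp + d).sum())
            lp = (self.gamma0**2 - (self.gamma0 + d) ** 2) / (2 * prior_var)
            return new_ll - cur_ll + lp

        def apply(d):
            self.gamma0 += d
            self.eta_exp += d

        self._metropolis("gamma0", logratio, apply)

    def _update_gamma_k(self, k: int) -> None:
        prior_var = self.priors.gamma_var
        z = self.data.z_exposure[:, k]
        g = self.gamma[k]
        cur_ll = float(self._exposure_ll_vec(self.eta_exp).sum())

        def logratio(d):
            new_ll = float(self._exposure_ll_vec(self.eta_exp + d * z).sum())
            lp = (g**2 - (g + d) ** 2) / (2 * prior_var)
            return new_ll - cur_ll + lp

        def apply(d):
            self.gamma[k] += d
            self.eta_exp += d * z

        self._metropolis(f"gamma{k + 1}", logratio, apply)

    def _update_v(self) -> None:
        scale = self._scales["v"].scale
        dv = scale * self.rng.standard_normal(self.N)
        cur = self._exposure_ll_vec(self.eta_exp)
        new = self._exposure_ll_vec(self.eta_exp + dv[self.cl])
        ll = np.bincount(self.cl, weights=new - cur, minlength=self.N)
        lp = (self.v**2 - (self.v + dv) ** 2) / (2 * self.nu**2)
        accept = np.log(self.rng.random(self.N)) < ll + lp
        if accept.any():
            self.v = np.where(accept, self.v + dv, self.v)
            self.eta_exp += np.where(accept, dv, 0.0)[self.cl]
        rate = float(accept.mean())
        self._accept_trials["v"] += 1
        self._accept_counts["v"] += rate
        if self.adapting:
            self._scales["v"].update(rate)

    def _trunc_beta(self, a: float, b: float, lower: float) -> float:
        """Inverse-CDF draw from beta(a, b) truncated to (lower, 1)."""
        from scipy.stats import beta as beta_dist

        f_lo = beta_dist.cdf(lower, a, b) if lower > 0.0 else 0.0
        u = f_lo + self.rng.random() * (1.0 - f_lo)
        return float(beta_dist.ppf(u, a, b))

    def _update_sc(self) -> None:
        """Conjugate beta draws for each sensitivity/specificity.

        In two-test mode the draws are truncated to the better-than-chance
        region S + C > 1 (one coordinate at a time, which is a valid Gibbs
        scan of the truncated joint), implementing the identifiability
        convention that removes the label-switching mirror mode.
        """
        x = self.x
        truncate = self.mode == Mode.TWO_TEST
        exposed = x == 1.0
        tests = [("S1", "C1", self.data.x1, self.priors.s1_shape, self.priors.c1_shape)]
        if self.mode == Mode.TWO_TEST:
            tests.append(
                ("S2", "C2", self.data.x2, self.priors.s2_shape, self.priors.c2_shape)
            )
        for s_name, c_name, assess, s_shape, c_shape in tests:
            pos = assess == 1
            tp = int(np.count_nonzero(exposed & pos))
            fn = int(np.count_nonzero(exposed & ~pos))
            tn = int(np.count_nonzero(~exposed & ~pos))
            fp = int(np.count_nonzero(~exposed & pos))
            if truncate:
                s = self._trunc_beta(
                    s_shape[0] + tp, s_shape[1] + fn, 1.0 - getattr(self, c_name)
                )
                c = self._trunc_beta(c_shape[0] + tn, c_shape[1] + fp, 1.0 - s)
            else:
                s = self.rng.beta(s_shape[0] + tp, s_shape[1] + fn)
                c = self.rng.beta(c_shape[0] + tn, c_shape[1] + fp)
            eps = 1e-12
            setattr(self, s_name, min(max(s, eps), 1 - eps))
            setattr(self, c_name, min(max(c, eps), 1 - eps))

    def sweep(self) -> None:
        """One full Gibbs sweep over every block."""
        if self.mode != Mode.NAIVE:
            self._update_latent_x()
        self._update_beta0()
        self._update_beta1()
        for k in range(self.p1):
            self._update_beta_k(k)
        self._update_u()
        self._update_sigma()
        if self.mode != Mode.NAIVE:
            self._update_gamma0()
            for k in range(self.q):
                self._update_gamma_k(k)
            self._update_v()
            self._update_nu()
            self._update_sc()
        self._check_finite("sweep")

    # ------------------------------------------------------- monitoring

    def monitored_names(self) -> list[str]:
        names = ["beta0", "beta1"]
        names += [f"beta{k + 2}" for k in range(self.p1)]
        names += ["sigma"]
        if self.mode != Mode.NAIVE:
            names += ["gamma0"]
            names += [f"gamma{k + 1}" for k in range(self.q)]
            names += ["nu", "S1", "C1"]
            if self.mode == Mode.TWO_TEST:
                names += ["S2", "C2"]
        if self.config.monitor_random_effects:
            names += [f"u{j + 1}" for j in range(self.N)]
            if self.mode != Mode.NAIVE:
                names += [f"v{j + 1}" for j in range(self.N)]
        return names

    def monitored_values(self) -> np.ndarray:
        vals = [self.beta0, self.beta1, *self.beta, self.sigma]
        if self.mode != Mode.NAIVE:
            vals += [self.gamma0, *self.gamma, self.nu, self.S1, self.C1]
            if self.mode == Mode.TWO_TEST:
                vals += [self.S2, self.C2]
        if self.config.monitor_random_effects:
            vals += list(self.u)
            if self.mode != Mode.NAIVE:
                vals += list(self.v)
        return np.array(vals)

    def acceptance_rates(self) -> dict[str, float]:
        return {
            k: self._accept_counts[k] / max(self._accept_trials[k], 1)
            for k in self._scales
        }


def gibbs_step(
    data: Dataset,
    state: ParameterState,
    priors: PriorSpec,
    mode: Mode | str,
    config: ChainConfig | None = None,
    rng: np.random.Generator | None = None,
) -> ParameterState:
    """One full Gibbs sweep from ``state``; returns the new state.

    Convenience wrapper over the cached sampler for tests and diagnostics;
    ``run_chain`` amortizes the cache setup over the whole chain.
    """
    config = config or ChainConfig(adapt=False)
    mcmc = MCMC(data, priors, mode, config, rng=rng, init=state)
    mcmc.adapting = False
    mcmc.sweep()
    return mcmc.get_state()


def run_chain(
    data: Dataset,
    priors: PriorSpec,
    mode: Mode | str,
    config: ChainConfig,
    init: ParameterState | None = None,
) -> PosteriorSample:
    """Run the full MCMC and return retained post-burn-in draws.

    Deterministic given (data, priors, config.seed).  Proposal-scale
    adaptation runs during burn-in only; acceptance rates are reported for
    the post-burn-in phase.
    """
    mode = Mode(mode)
    mcmc = MCMC(data, priors, mode, config, init=init)
    for _ in range(config.n_burn):
        mcmc.sweep()
    mcmc.adapting = False
    mcmc._accept_counts = {k: 0 for k in mcmc._scales}
    mcmc._accept_trials = {k: 0 for k in mcmc._scales}

    names = mcmc.monitored_names()
    n_keep = config.n_iter // config.thin
    draws = np.empty((n_keep, len(names)))
    kept = 0
    for it in range(config.n_iter):
        mcmc.sweep()
        if (it + 1) % config.thin == 0 and kept < n_keep:
            draws[kept] = mcmc.monitored_values()
            kept += 1
    sample = PosteriorSample(
        draws=draws[:kept],
        names=names,
        config=config,
        acceptance_rates=mcmc.acceptance_rates(),
        mode=mode,
    )
    if mode == Mode.ONE_TEST:
        crossed = sample["S1"] + sample["C1"] < 1.0
        if crossed.any():
            warnings.warn(
                f"{int(crossed.sum())} of {kept} draws have S1 + C1 < 1: "
                "posterior mass is crossing the label-switching boundary; "
                "the informative S/C priors may be too weak to identify "
                "the model",
                stacklevel=2,
            )
    return sample


def summarize(sample: PosteriorSample | np.ndarray, names=None) -> pd.DataFrame:
    """Posterior mean, SD and equal-tailed 95% interval per quantity.

    The interval is the (2.5%, 97.5%) empirical quantile pair (numpy's
    default linear-interpolation quantile rule); SD is the sample SD with
    ddof=1.
    """
    if isinstance(sample, PosteriorSample):
        draws, names = sample.draws, sample.names
    else:
        draws = np.asarray(sample)
        if draws.ndim == 1:
            draws = draws[:, None]
        if names is None:
            names = [f"q{k}" for k in range(draws.shape[1])]
    if draws.shape[0] < 2:
        raise MiscountError("need at least 2 retained draws to summarize")
    q = np.quantile(draws, [0.025, 0.975], axis=0)
    return pd.DataFrame(
        {
            "mean": draws.mean(axis=0),
            "sd": draws.std(axis=0, ddof=1),
            "q2.5": q[0],
            "q97.5": q[1],
        },
        index=pd.Index(names, name="parameter"),
    )
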