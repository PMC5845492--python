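"""Synthetic two-level count data with a misclassified binary exposure.

The generator mirrors the structure the model assumes: cluster random
intercepts for both sub-models, a logistic exposure model, a log-linear
Poisson outcome model, and one or two fallible assessments of the true
exposure with fixed sensitivity/specificity.  Default parameter values are
the simulation-study settings (25 clusters of 200 subjects; exposure model
intercept -1.5 with slopes -0.21, -0.16, 0.19, -0.29; outcome intercept
0.85, exposure effect 0.4, slopes 0.25, -0.2, -0.18, -0.05; random-effect
SDs 0.1; test 1 with S1 = 0.55, C1 = 0.95; test 2 with S2 = 0.7, C2 = 0.8).

The covariates z1..z4 default to independent standard normals; real
applications will have correlated, partly discrete covariates, so this is
the generator's main idealization (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import expit

from .data import Dataset

__all__ = ["SimDesign", "simulate_dataset"]


@dataclass
class SimDesign:
    """Generative settings for one synthetic dataset."""

    N: int = 25
    n_per_cluster: int = 200
    gamma_true: np.ndarray = field(
        default_factory=lambda: np.array([-1.5, -0.21, -0.16, 0.19, -0.29])
    )
    beta_true: np.ndarray = field(
        default_factory=lambda: np.array([0.85, 0.4, 0.25, -0.2, -0.18, -0.05])
    )
    sigma_true: float = 0.1
    nu_true: float = 0.1
    S1: float = 0.55
    C1: float = 0.95
    S2: float | None = 0.7
    C2: float | None = 0.8
    z_distribution: str = "normal"
    seed: int = 0

    def __post_init__(self) -> None:
        self.gamma_true = np.asarray(self.gamma_true, dtype=float)
        self.beta_true = np.asarray(self.beta_true, dtype=float)
        if self.N < 1 or self.n_per_cluster < 1:
            raise ValueError("N and n_per_cluster must be >= 1")
        if self.sigma_true < 0 or self.nu_true < 0:
            raise ValueError("random-effect SDs must be >= 0")
        for name in ("S1", "C1", "S2", "C2"):
            v = getattr(self, name)
            if v is not None and not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.beta_true.shape[0] != self.gamma_true.shape[0] + 1:
            raise ValueError(
                "beta_true must have one more entry (the exposure effect) "
                "than gamma_true"
            )

    @property
    def two_tests(self) -> bool:
        return self.S2 is not None and self.C2 is not None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["gamma_true"] = list(self.gamma_true)
        d["beta_true"] = list(self.beta_true)
        return d


def _draw_z(design: SimDesign, rng: np.random.Generator, n: int, q: int) -> np.ndarray:
    if design.z_distribution == "normal":
        return rng.standard_normal((n, q))
    if design.z_distribution == "uniform":
        return rng.uniform(-np.sqrt(3), np.sqrt(3), size=(n, q))
    if design.z_distribution == "bernoulli":
        return rng.integers(0, 2, size=(n, q)).astype(float)
    raise ValueError(f"unknown z_distribution {design.z_distribution!r}")


def _fallible(
    rng: np.random.Generator, x_true: np.ndarray, S: float, C: float
) -> np.ndarray:
    p_report_1 = np.where(x_true == 1, S, 1.0 - C)
    return (rng.random(x_true.shape[0]) < p_report_1).astype(np.int8)


def simulate_dataset(
    design: SimDesign, rng: np.random.Generator | None = None
) -> Dataset:
    """Draw one dataset from the generative model.

    The true exposure is included (column ``x_true``) so that simulation
    studies can score coverage; model fitting never reads it.
    """
    if rng is None:
        rng = np.random.default_rng(design.seed)
    N, m = design.N, design.n_per_cluster
    n = N * m
    q = design.gamma_true.shape[0] - 1
    cluster = np.repeat(np.arange(1, N + 1), m)
    cl = cluster - 1

    v = rng.normal(0.0, design.nu_true, size=N)
    u = rng.normal(0.0, design.sigma_true, size=N)
    z = _draw_z(design, rng, n, q)

    eta_exp = design.gamma_true[0] + v[cl] + z @ design.gamma_true[1:]
    x_true = (rng.random(n) < expit(eta_exp)).astype(np.int8)

    eta_out = (
        design.beta_true[0]
        + u[cl]
        + design.beta_true[1] * x_true
        + z @ design.beta_true[2:]
    )
    y = rng.poisson(np.exp(eta_out))

    x1 = _fallible(rng, x_true, design.S1, design.C1)
    x2 = (
        _fallible(rng, x_true, design.S2, design.C2) if design.two_tests else None
    )
    return Dataset(
        y=y,
        cluster=cluster,
        z_outcome=z,
        z_exposure=z,
        x1=x1,
        x2=x2,
        x_true=x_true,
    )


def true_values(design: SimDesign) -> dict[str, float]:
    """Map monitored-parameter names to their generating values."""
    truths = {
        "beta0": design.beta_true[0],
        "beta1": design.beta_true[1],
        "sigma": design.sigma_true,
        "gamma0": design.gamma_true[0],
        "nu": design.nu_true,
        "S1": design.S1,
        "C1": design.C1,
    }
    for k, b in enumerate(design.beta_true[2:]):
        truths[f"beta{k + 2}"] = b
    for k, g in enumerate(design.gamma_true[1:]):
        truths[f"gamma{k + 1}"] = g
    if design.two_tests:
        truths["S2"] = design.S2
        truths["C2"] = design.C2
    return truths
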