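"""Core data containers: subject-level dataset, parameter state, priors.

The model operates on two-level data: subjects i = 1..n nested in clusters
j = 1..N.  Each subject carries a Poisson count outcome ``y`` with a known
offset ``r``, error-free covariates ``z``, and one or two fallible binary
assessments ``x1``/``x2`` of an unobserved true binary exposure.  Cluster
labels are re-indexed internally to 0..N-1; the original labels are kept so
outputs can be mapped back.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd


class Mode(str, Enum):
    """Which measurement model (if any) is attached to the outcome model.

    ``NAIVE`` treats the first fallible assessment as the true exposure and
    fits only the Poisson outcome model.  ``ONE_TEST`` and ``TWO_TEST`` fit
    the joint outcome + exposure + measurement model with the true exposure
    as a latent variable.
    """

    NAIVE = "naive"
    ONE_TEST = "one_test"
    TWO_TEST = "two_test"


class MiscountError(Exception):
    """Base class for structured errors raised by this package."""


class DimensionError(MiscountError):
    """Shape mismatch between data and a coefficient vector."""


class InvalidParameterError(MiscountError):
    """A parameter lies outside its support."""


def _as_binary(name: str, a: np.ndarray) -> np.ndarray:
    a = np.asarray(a)
    if not np.isin(a, (0, 1)).all():
        raise ValueError(f"{name} must contain only 0/1 values")
    return a.astype(np.int8)


@dataclass
class Dataset:
    """Subject-level records for a two-level count model.

    Parameters
    ----------
    y : array of nonnegative integer counts, one per subject.
    cluster : integer cluster labels (any contiguous-after-reindex set).
    z_outcome : (n, p-1) covariate matrix entering the outcome model.
    z_exposure : (n, q) covariate matrix entering the exposure model.
        May be the same array as ``z_outcome``.
    r : positive offsets (exposure time / size); defaults to 1.
    x1, x2 : fallible binary assessments (``x2`` optional).
    x_true : true exposure, available only for simulated data.
    """

    y: np.ndarray
    cluster: np.ndarray
    z_outcome: np.ndarray
    z_exposure: np.ndarray
    r: np.ndarray | None = None
    x1: np.ndarray | None = None
    x2: np.ndarray | None = None
    x_true: np.ndarray | None = None
    cluster_labels: np.ndarray = field(init=False)
    cluster_index: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y)
        if self.y.ndim != 1:
            raise ValueError("y must be one-dimensional")
        if not np.issubdtype(self.y.dtype, np.integer):
            yf = np.asarray(self.y, dtype=float)
            if not np.allclose(yf, np.round(yf)):
                raise ValueError("y must be integer counts")
            self.y = yf.astype(np.int64)
        if (self.y < 0).any():
            raise ValueError("y must be nonnegative")
        n = self.y.shape[0]

        if self.r is None:
            self.r = np.ones(n)
        self.r = np.asarray(self.r, dtype=float)
        if (self.r <= 0).any():
            raise ValueError("offset r must be strictly positive")

        self.z_outcome = np.atleast_2d(np.asarray(self.z_outcome, dtype=float))
        self.z_exposure = np.atleast_2d(np.asarray(self.z_exposure, dtype=float))
        if self.z_outcome.shape[0] != n or self.z_exposure.shape[0] != n:
            raise DimensionError(
                f"covariate matrices must have {n} rows, got "
                f"z_outcome {self.z_outcome.shape[0]}, "
                f"z_exposure {self.z_exposure.shape[0]}"
            )

        cluster = np.asarray(self.cluster)
        labels, index = np.unique(cluster, return_inverse=True)
        self.cluster_labels = labels
        self.cluster_index = index.astype(np.int64)

        for name in ("x1", "x2", "x_true"):
            v = getattr(self, name)
            if v is not None:
                v = _as_binary(name, v)
                if v.shape[0] != n:
                    raise DimensionError(f"{name} must have length {n}")
                setattr(self, name, v)

        for name in ("y", "r", "z_outcome", "z_exposure", "x1", "x2", "x_true"):
            v = getattr(self, name)
            if v is not None and not np.isfinite(np.asarray(v, dtype=float)).all():
                raise ValueError(f"missing or non-finite values in {name}")

    @property
    def n_subjects(self) -> int:
        return self.y.shape[0]

    @property
    def n_clusters(self) -> int:
        return self.cluster_labels.shape[0]

    # ---------------------------------------------------------------- I/O

    _STANDARD_COLUMNS = ("y", "r", "cluster", "x1", "x2", "x_true")

    def to_frame(self) -> pd.DataFrame:
        """Flatten to a tidy DataFrame with columns y, r, cluster, z*, x*."""
        out = {"y": self.y, "r": self.r,
               "cluster": self.cluster_labels[self.cluster_index]}
        shared = self.z_exposure is self.z_outcome or (
            self.z_exposure.shape == self.z_outcome.shape
            and np.array_equal(self.z_exposure, self.z_outcome)
        )
        for k in range(self.z_exposure.shape[1]):
            out[f"z{k + 1}"] = self.z_exposure[:, k]
        if not shared:
            for k in range(self.z_outcome.shape[1]):
                out[f"zo{k + 1}"] = self.z_outcome[:, k]
        for name in ("x1", "x2", "x_true"):
            v = getattr(self, name)
            if v is not None:
                out[name] = v
        return pd.DataFrame(out)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        *,
        y: str = "y",
        cluster: str = "cluster",
        z_outcome: Sequence[str] | None = None,
        z_exposure: Sequence[str] | None = None,
        r: str | None = "r",
        x1: str | None = "x1",
        x2: str | None = "x2",
        x_true: str | None = "x_true",
    ) -> "Dataset":
        """Build a :class:`Dataset` from a tidy DataFrame.

        Column names are configurable; ``z_outcome``/``z_exposure`` default
        to all columns named ``z<k>`` (shared by both models).  Missing
        values anywhere in the used columns are an error, never dropped.
        """
        if z_exposure is None:
            z_exposure = sorted(
                (c for c in df.columns if c.startswith("z") and c[1:].isdigit()),
                key=lambda c: int(c[1:]),
            )
        if z_outcome is None:
            zo = sorted(
                (c for c in df.columns if c.startswith("zo") and c[2:].isdigit()),
                key=lambda c: int(c[2:]),
            )
            z_outcome = zo if zo else z_exposure

        def col(name, required):
            if name is None:
                return None
            if name not in df.columns:
                if required:
                    raise KeyError(f"required column {name!r} not in data")
                return None
            v = df[name]
            if v.isna().any():
                raise ValueError(f"missing values in column {name!r}")
            return v.to_numpy()

        used = [y, cluster, *z_outcome, *z_exposure]
        for c in used:
            if c not in df.columns:
                raise KeyError(f"required column {c!r} not in data")
            if df[c].isna().any():
                raise ValueError(f"missing values in column {c!r}")

        same = list(z_outcome) == list(z_exposure)
        ze = df[list(z_exposure)].to_numpy(dtype=float)
        zo_arr = ze if same else df[list(z_outcome)].to_numpy(dtype=float)
        return cls(
            y=df[y].to_numpy(),
            cluster=df[cluster].to_numpy(),
            z_outcome=zo_arr,
            z_exposure=ze,
            r=col(r, required=False),
            x1=col(x1, required=False),
            x2=col(x2, required=False),
            x_true=col(x_true, required=False),
        )

    @classmethod
    def read_csv(cls, path, **kwargs) -> "Dataset":
        return cls.from_frame(pd.read_csv(path), **kwargs)


@dataclass
class PriorSpec:
    """Hyperparameters of every prior in the joint model.

    Regression coefficients get mean-zero normal priors parameterized by
    VARIANCE (not precision, unlike BUGS dialects): ``gamma_var`` for all
    logistic exposure-model coefficients and ``beta_var`` for all Poisson
    outcome-model coefficients.  The random-intercept standard deviations
    sigma and nu get uniform(0, ``sd_upper``) priors.  Each sensitivity and
    specificity gets a beta prior with the given ``(a, b)`` shapes.
    """

    gamma_var: float = 10.0
    beta_var: float = 100.0
    sd_upper: float = 3.0
    s1_shape: tuple[float, float] = (1.0, 1.0)
    c1_shape: tuple[float, float] = (1.0, 1.0)
    s2_shape: tuple[float, float] = (1.0, 1.0)
    c2_shape: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        for name in ("gamma_var", "beta_var", "sd_upper"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")
        for name in ("s1_shape", "c1_shape", "s2_shape", "c2_shape"):
            a, b = getattr(self, name)
            if a <= 0 or b <= 0:
                raise InvalidParameterError(f"{name} shapes must be > 0")

    def validate_for_mode(self, mode: Mode) -> None:
        """One-test fits are unidentifiable under flat S/C priors.

        With a single fallible assessment the likelihood cannot separate
        (S, C) from the exposure prevalence, so informative beta shapes for
        S1 and C1 are required; beta(1, 1) is refused.
        """
        if mode == Mode.ONE_TEST:
            if self.s1_shape == (1.0, 1.0) or self.c1_shape == (1.0, 1.0):
                raise InvalidParameterError(
                    "one_test mode requires informative beta priors for S1 and "
                    "C1; flat beta(1, 1) shapes leave the model unidentifiable"
                )


@dataclass
class ParameterState:
    """One full configuration of the model unknowns.

    Outcome model: ``log lambda = beta0 + u[j] + beta1 * x + z_outcome @ beta``
    with u_j ~ N(0, sigma^2).  Exposure model:
    ``logit pi = gamma0 + v[j] + z_exposure @ gamma`` with v_j ~ N(0, nu^2).
    ``S1/C1`` (and ``S2/C2``) are the sensitivities/specificities of the
    fallible assessments; ``x_latent`` is the current imputation of the true
    exposure.  Fields not used by a mode are ``None``.
    """

    beta0: float
    beta1: float
    beta: np.ndarray
    u: np.ndarray
    sigma: float
    gamma0: float | None = None
    gamma: np.ndarray | None = None
    v: np.ndarray | None = None
    nu: float | None = None
    S1: float | None = None
    C1: float | None = None
    S2: float | None = None
    C2: float | None = None
    x_latent: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        if self.sigma <= 0:
            raise InvalidParameterError("sigma must be > 0")
        if self.gamma is not None:
            self.gamma = np.asarray(self.gamma, dtype=float)
        if self.v is not None:
            self.v = np.asarray(self.v, dtype=float)
        if self.nu is not None and self.nu <= 0:
            raise InvalidParameterError("nu must be > 0")
        for name in ("S1", "C1", "S2", "C2"):
            val = getattr(self, name)
            if val is not None and not 0.0 < val < 1.0:
                raise InvalidParameterError(f"{name} must lie in (0, 1)")
        if self.x_latent is not None:
            self.x_latent = _as_binary("x_latent", self.x_latent)

    def copy(self) -> "ParameterState":
        new = replace(self)
        for name in ("beta", "u", "gamma", "v", "x_latent"):
            val = getattr(new, name)
            if val is not None:
                setattr(new, name, val.copy())
        return new
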