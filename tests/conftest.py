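import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from miscount import Dataset, ParameterState

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_dataset(rng):
    """Hand-rolled 20-subject, 3-cluster dataset with both assessments."""
    n, q = 20, 2
    cluster = np.repeat([1, 2, 3], [7, 7, 6])
    z = rng.standard_normal((n, q))
    return Dataset(
        y=rng.poisson(2.0, n),
        cluster=cluster,
        z_outcome=z,
        z_exposure=z,
        r=rng.uniform(0.5, 2.0, n),
        x1=rng.integers(0, 2, n),
        x2=rng.integers(0, 2, n),
        x_true=rng.integers(0, 2, n),
    )


@pytest.fixture
def small_state(small_dataset, rng):
    n = small_dataset.n_subjects
    N = small_dataset.n_clusters
    return ParameterState(
        beta0=0.3,
        beta1=0.4,
        beta=np.array([0.25, -0.2]),
        u=rng.normal(0, 0.1, N),
        sigma=0.15,
        gamma0=-1.0,
        gamma=np.array([-0.2, 0.1]),
        v=rng.normal(0, 0.1, N),
        nu=0.12,
        S1=0.6,
        C1=0.9,
        S2=0.7,
        C2=0.8,
        x_latent=rng.integers(0, 2, n),
    )
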