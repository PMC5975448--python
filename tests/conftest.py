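import numpy as np
import pytest

from survscreen import SimulationSpec, SurvivalDataset, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20260901)


@pytest.fixture
def tiny_dataset():
    """Six samples, all deaths, one covariate; small enough to hand-check."""
    return SurvivalDataset(
        expression=np.array([[0.5], [-0.2], [0.3], [-0.7], [0.1], [0.4]]),
        time=np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0]),
        event=np.ones(6, dtype=int),
        feature_ids=("g1",),
        sample_ids=tuple("abcdef"),
    )


@pytest.fixture(scope="session")
def sim50():
    """One default synthetic cohort (n=50, p=40, 10% censoring)."""
    return simulate_dataset(SimulationSpec(n=50, seed=11))


def random_survival_dataset(rng, n=30, p=2, censor_prob=0.25):
    """Continuous-time random dataset (tie-free almost surely)."""
    X = rng.standard_normal((n, p))
    t = rng.exponential(1.0, n) + 1e-3
    e = (rng.uniform(size=n) > censor_prob).astype(int)
    if e.sum() < max(2, p + 1):  # make sure fits are identifiable
        e[rng.choice(n, size=max(2, p + 1), replace=False)] = 1
    return SurvivalDataset(X, t, e)
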