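import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from wfdms import SimulationConfig, sample_reads, simulate_wf
from wfdms.frequencies import FrequencyTrajectory

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def two_allele_traj() -> FrequencyTrajectory:
    """One site, wild type A vs mutant G, mutant frequency 0.1 -> 0.2."""
    return FrequencyTrajectory(
        replicate_id="rep1",
        times=np.array([0.0, 1.0]),
        sites=[1],
        alleles={1: ["A", "G"]},
        wildtype={1: "A"},
        z={1: np.array([[0.9, 0.8], [0.1, 0.2]])},
        depth={1: np.array([100.0, 100.0])},
        counts={1: np.array([[90.0, 80.0], [10.0, 20.0]])},
    )


@pytest.fixture(scope="session")
def small_dataset():
    """A small sampled simulation shared across read-only tests."""
    config = SimulationConfig(
        n_sites=3, alleles_per_site=3, population_size=2000, rounds=3,
        depth=5000, dispersion=np.inf, replicates=2, seed=11,
    )
    return sample_reads(simulate_wf(config))


def random_trajectory(rng: np.random.Generator, n_alleles: int, n_intervals: int):
    """Valid random single-site trajectory (Dirichlet frequencies)."""
    z = rng.dirichlet(np.ones(n_alleles), size=n_intervals + 1).T
    alleles = [f"a{i}" for i in range(n_alleles)]
    return FrequencyTrajectory(
        replicate_id="r", times=np.arange(n_intervals + 1, dtype=float),
        sites=[1], alleles={1: alleles}, wildtype={1: "a0"},
        z={1: z}, depth={1: np.full(n_intervals + 1, 1000.0)},
    )
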