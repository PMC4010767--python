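import numpy as np
import pytest

from slickmap.sim import BreedConfig, CrossDesign, SimulationConfig, simulate_cohort


def small_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A fast two-carrier/two-control cohort for unit tests (seconds, not minutes)."""
    kw = dict(
        seed=seed,
        n_snps=400,
        chrom_length_bp=4_000_000,
        generations=8,
        pop_size=40,
        breeds=[
            BreedConfig("CA", n_samples=14, carrier=True, n_founder_haplotypes=40),
            BreedConfig("CB", n_samples=10, carrier=True, n_founder_haplotypes=40),
            BreedConfig("NA", n_samples=12, n_founder_haplotypes=40),
            BreedConfig("NB", n_samples=12, n_founder_haplotypes=40),
        ],
        cross_designs=[
            CrossDesign("CA", "NA", n_backcross_generations=2, n_samples=4, name="CX")
        ],
    )
    kw.update(overrides)
    return SimulationConfig(**kw)


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(small_config(1))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
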