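import numpy as np
import pytest

from pansv import simulate


def small_config(**overrides) -> simulate.SimulationConfig:
    """A reduced cohort that keeps every stage exercised but fast."""
    defaults = dict(
        seed=11,
        chrom_lengths=(400_000, 300_000),
        mechanism_counts={"VNTR": 4, "NAHR": 4, "STEI": 4, "MTEI": 3, "NHR": 4},
        n_samples=50,
        n_snps=900,
        n_callset_samples=4,
        sweep=simulate.SweepSpec(start=100_000, end=130_000, strength=0.95),
        introgression=simulate.IntrogressionSpec(start=250_000, end=280_000),
    )
    defaults.update(overrides)
    return simulate.SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort() -> simulate.SimulatedCohort:
    return simulate.simulate_cohort(small_config())


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(123)
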