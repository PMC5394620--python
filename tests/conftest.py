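import pytest

from itckit.synthetic import (
    SimulationConfig,
    make_reference,
    make_truth,
    simulate_callsets,
)


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    return SimulationConfig(
        genome_length=60_000,
        n_snv=200,
        n_indel=25,
        purities=(1.0, 0.1, 0.01),
        fp_rate_per_mb=400.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def reference(small_cfg):
    return make_reference(small_cfg)


@pytest.fixture(scope="session")
def truth_fixture(small_cfg, reference):
    return make_truth(reference, small_cfg)


@pytest.fixture(scope="session")
def sim_pure(small_cfg, reference, truth_fixture):
    """Simulated call quartet at purity 1.0."""
    return simulate_callsets(reference, truth_fixture, 1.0, small_cfg, purity_index=0)
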