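import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from retrosite.core_io import InsertSizeModel, RunConfig
from retrosite.mp_simulator import SimulationConfig, simulate_insertion_replicate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_sim():
    """One small simulated replicate at full prevalence (200 kbp reference),
    shared across tests that only inspect its reads/pairs/truth."""
    config = SimulationConfig(
        reference_length=200_000,
        insert_length=8000,
        prevalence=1.0,
        physical_coverage=20.0,
        substitution_error_rate=0.0,
        seed=777,
    )
    reference, carrier, truth, sim = simulate_insertion_replicate(config)
    return {
        "config": config,
        "reference": reference,
        "carrier": carrier,
        "truth": truth,
        "sim": sim,
    }


@pytest.fixture(scope="session")
def null_sim():
    """Insertion-free simulation: reads drawn from the reference only."""
    from retrosite.mp_simulator import CarrierGenome, generate_mate_pairs, make_reference

    config = SimulationConfig(
        reference_length=200_000,
        prevalence=0.0,
        physical_coverage=20.0,
        substitution_error_rate=0.0,
        seed=4242,
    )
    reference = make_reference(config.reference_length, 99)
    carrier = CarrierGenome.identity(reference)
    sim = generate_mate_pairs(reference, carrier, config)
    return {"config": config, "reference": reference, "sim": sim}


@pytest.fixture
def default_config():
    return RunConfig()


@pytest.fixture
def insert_model():
    return InsertSizeModel()
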