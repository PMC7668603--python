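import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from exomir.synthetic_data import (SimulationDesign, generate_genome,
                                   generate_spikeins, plant_annotations,
                                   simulate_experiment, simulate_libraries)

settings.register_profile(
    "suite", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def toy_genome():
    """Small two-chromosome genome with repeat cassettes."""
    genome, repeats = generate_genome(seed=42, chrom_lengths=(12_000, 8_000),
                                      n_repeat_families=4, repeat_copies=4)
    return genome, repeats


@pytest.fixture(scope="session")
def clean_experiment():
    """Zero-jitter, zero-error, adapter-free simulation: the end-to-end
    oracle regime where the quantifier must recover truth exactly."""
    design = SimulationDesign(n_samples_per_group=2, timepoints=("E16",),
                              depth_per_sample=12_000,
                              jitter_probs={0: 1.0}, error_rate=0.0,
                              adapter_seq=None, seed=7)
    return simulate_experiment(design)


@pytest.fixture(scope="session")
def messy_experiment():
    """Default-style simulation with jitter, errors and adapters."""
    design = SimulationDesign(n_samples_per_group=2, timepoints=("E16",),
                              depth_per_sample=6_000, seed=13)
    return simulate_experiment(design)


@pytest.fixture(scope="session")
def default_run():
    """Full default design at reduced depth, for DE/cluster level tests."""
    design = SimulationDesign(depth_per_sample=8_000, seed=5)
    return simulate_experiment(design)
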