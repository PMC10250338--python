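import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from minicirc.classify import ClassifierConfig
from minicirc.pipeline import classify_read_set
from minicirc.synthetic import (
    SimulationParams,
    build_species_model,
    cds_references,
    constant_references,
    default_config,
    generate_minicircles,
    simulate_reads,
)


@pytest.fixture(scope="session")
def model():
    return build_species_model(default_config())


@pytest.fixture(scope="session")
def circles(model):
    return generate_minicircles(model, 1)


@pytest.fixture(scope="session")
def cds_refs(circles):
    return cds_references(circles)


@pytest.fixture(scope="session")
def constant_refs(circles):
    return constant_references(circles)


@pytest.fixture(scope="session")
def clean_sim(circles):
    """Error-free mixed read set with generous concatemer fractions."""
    params = SimulationParams(
        n_reads=120,
        fraction_homo=0.10,
        fraction_hetero=0.10,
        fraction_background=0.05,
        seed=5,
    )
    return simulate_reads(circles, params)


@pytest.fixture(scope="session")
def noisy_sim(circles):
    """5% substitutions + 2% indels, mixed categories."""
    params = SimulationParams(
        n_reads=150,
        sub_rate=0.05,
        indel_rate=0.02,
        fraction_homo=0.06,
        fraction_hetero=0.06,
        fraction_background=0.05,
        seed=11,
    )
    return simulate_reads(circles, params)


@pytest.fixture(scope="session")
def clean_classified(clean_sim, cds_refs, constant_refs):
    reads, truth = clean_sim
    hits, classifications = classify_read_set(
        reads, cds_refs, constant_refs, ClassifierConfig()
    )
    return reads, truth, hits, classifications


@pytest.fixture(scope="session")
def noisy_classified(noisy_sim, cds_refs, constant_refs):
    reads, truth = noisy_sim
    hits, classifications = classify_read_set(
        reads, cds_refs, constant_refs, ClassifierConfig()
    )
    return reads, truth, hits, classifications
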