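import numpy as np
import pytest

from contactsol import (
    EdgeScheme,
    ModelConfig,
    SyntheticProteinSpec,
    build_dataset,
    generate_cohort,
    generate_synthetic_protein,
    init_parameters,
)


@pytest.fixture(scope="session")
def spec():
    return SyntheticProteinSpec(length_range=(20, 40), seed=7)


@pytest.fixture(scope="session")
def protein(spec):
    return generate_synthetic_protein(spec, 0)


@pytest.fixture(scope="session")
def small_cohort(spec):
    return generate_cohort(12, spec, start_seed=0)


@pytest.fixture(scope="session")
def small_dataset(small_cohort):
    dataset, scaler = build_dataset(small_cohort, EdgeScheme())
    return dataset


@pytest.fixture(scope="session")
def tiny_config():
    """A small architecture that keeps per-test training fast."""
    return ModelConfig(input_dim=91, gcn_dims=(16, 8), attention_heads=2,
                       attention_hidden=8)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_symmetric_map(rng, L):
    """Random valid contact-probability matrix (symmetric, zero diagonal)."""
    P = rng.uniform(0, 1, size=(L, L))
    P = np.triu(P, 1)
    P = P + P.T
    return P
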