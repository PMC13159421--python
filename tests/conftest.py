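import numpy as np
import pytest

from gatorst import (RunConfig, SyntheticSpec, build_knn_graph,
                     generate_dataset, train)


@pytest.fixture(scope="session")
def separable_fixture():
    """600 spots, 4 planted horizontal-band domains, strong separation:
    the reference synthetic dataset for end-to-end recovery checks."""
    spec = SyntheticSpec(
        n_spots=600, n_genes=60, n_domains=4,
        effect_size=3.0, noise_sd=1.0, seed=7,
    )
    dataset, planted_means = generate_dataset(spec)
    graph = build_knn_graph(dataset.coordinates, 6)
    return dataset, graph, planted_means


@pytest.fixture(scope="session")
def trained_result(separable_fixture):
    """One full training run on the separable fixture, shared across tests."""
    dataset, graph, _ = separable_fixture
    return train(dataset, graph, RunConfig(seed=0))


@pytest.fixture
def tiny_dataset():
    spec = SyntheticSpec(
        n_spots=40, n_genes=8, n_domains=3, effect_size=2.0,
        noise_sd=0.5, dropout_rate=0.0, seed=11,
    )
    dataset, _ = generate_dataset(spec)
    return dataset


@pytest.fixture
def rng():
    return np.random.default_rng(0)
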