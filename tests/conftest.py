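import numpy as np
import pytest

import mixedstock as ms


@pytest.fixture
def small_rookeries():
    # two rookeries fixed for disjoint haplotypes
    return ms.HaplotypeCountTable(
        ("R1", "R2"), ("A", "B"), np.array([[50, 0], [0, 50]]), ms.SiteKind.ROOKERY
    )


@pytest.fixture
def small_mixed():
    return ms.HaplotypeCountTable(
        ("MS1",), ("A", "B"), np.array([[60, 40]]), ms.SiteKind.MIXED_STOCK
    )


@pytest.fixture
def small_dataset(small_rookeries, small_mixed):
    sizes = ms.SourceSizeTable(("R1", "R2"), np.array([100.0, 300.0]), "test")
    dist = ms.EffectiveDistanceMatrix(("MS1",), ("R1", "R2"), np.array([[1000.0, 2000.0]]))
    return ms.MSADataset.assemble(small_rookeries, small_mixed, sizes, dist)


@pytest.fixture(scope="session")
def synthetic_example():
    from mixedstock.datasets import synthetic_example

    return synthetic_example()


@pytest.fixture(scope="session")
def quick_fit(synthetic_example):
    """One moderate fit of the synthetic example, shared across tests."""
    dataset, truth = synthetic_example
    samples, result = ms.fit(dataset, ms.ModelConfig(n_iter=3000, n_burnin=1500, seed=17))
    return dataset, truth, samples, result
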