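import numpy as np
import pytest

from mdfldrr import DrugCatalog, FeatureMatrix, InteractionMatrix, generate


@pytest.fixture(scope="session")
def small_ds():
    """Noise-free planted dataset small enough for per-test fits."""
    return generate(n=30, m=2, dims=(25, 20), rank=4, density=0.1, noise=0.0, seed=5)


@pytest.fixture(scope="session")
def tiny_catalog():
    return DrugCatalog(("A", "B", "C", "D"))


def random_instance(seed, n=8, m=2, dims=(6, 7), density=0.3):
    """Random catalog-aligned (Hs, J) pair for solver oracles."""
    rng = np.random.default_rng(seed)
    catalog = DrugCatalog(tuple(f"D{i}" for i in range(n)))
    Hs = [
        FeatureMatrix(
            f"f{k}",
            tuple(f"f{k}_{j}" for j in range(ni)),
            (rng.random((n, ni)) < 0.4).astype(float),
            catalog,
        )
        for k, ni in enumerate(dims)
    ]
    iu, ju = np.triu_indices(n, k=1)
    edges = rng.random(iu.size) < density
    J = np.zeros((n, n))
    J[iu[edges], ju[edges]] = 1.0
    J += J.T
    if J.sum() == 0:  # ensure trainable network
        J[0, 1] = J[1, 0] = 1.0
    return Hs, InteractionMatrix(J, catalog)
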