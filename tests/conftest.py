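import numpy as np
import pytest

from dtikit.core_io import DDINetwork, EntityRegistry, SimilarityMatrix
from dtikit.synthetic import SyntheticConfig, generate


def random_graph(rng, n: int, p: float = 0.4) -> DDINetwork:
    ids = tuple(f"d{i}" for i in range(n))
    reg = EntityRegistry(ids)
    pairs = [
        (ids[i], ids[j]) for i in range(n) for j in range(i + 1, n) if rng.random() < p
    ]
    return DDINetwork.from_pairs(reg, pairs)


def random_psd_matrix(rng, n: int) -> SimilarityMatrix:
    a = rng.normal(size=(n, n))
    k = a @ a.T / n
    return SimilarityMatrix(EntityRegistry(tuple(f"e{i}" for i in range(n))), k)


def permute_drug_labels(dti, seed: int):
    """Reassign interaction profiles to drugs at random (label-shuffle control)."""
    from dtikit.core_io import InteractionTable

    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(dti.drugs))
    mapping = {dti.drugs.ids[i]: dti.drugs.ids[perm[i]] for i in range(len(dti.drugs))}
    pairs = frozenset((mapping[d], p) for d, p in dti.pairs)
    return InteractionTable(dti.drugs, dti.proteins, pairs)


@pytest.fixture(scope="session")
def signal_dataset():
    """Module-structured dataset at the default 'signal' conditions."""
    return generate(SyntheticConfig(seed=20260920))


@pytest.fixture(scope="session")
def small_dataset():
    return generate(SyntheticConfig(n_drugs=40, n_proteins=16, n_modules=4, seed=5))
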