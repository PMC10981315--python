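import numpy as np
import pytest

from daecfr import (
    AssociationMatrix,
    Catalog,
    FixtureSpec,
    SimilarityMatrix,
    generate_dataset,
    load_config,
)


@pytest.fixture
def toy_assoc():
    """2x2 identity association matrix."""
    return AssociationMatrix(
        np.eye(2, dtype=np.int8), Catalog(["m1", "m2"]), Catalog(["d1", "d2"])
    )


@pytest.fixture(scope="session")
def small_planted():
    """Small planted dataset + fast config for pipeline-level unit tests."""
    spec = FixtureSpec(n_m=80, n_d=60, n_blocks=4, density=0.06, seed=3)
    A, fm, tree_map, heldout = generate_dataset(spec)
    FM = SimilarityMatrix(fm, A.mirnas, kind="FM")
    config = load_config(
        seed=3,
        k_clusters=5,
        per_cluster=max(1, round(A.n_associations / 5)),
        folds=3,
        epochs=12,
        kmeans_n_init=2,
    )
    return A, FM, tree_map, heldout, config


def random_toy_forest(rng: np.random.Generator):
    """Random small hierarchy: <= 8 diseases, tree-number depth <= 4.

    Tokens are drawn from a small pool so prefixes collide and DAGs overlap.
    """
    from daecfr import TreeNumberMap

    n = int(rng.integers(2, 9))
    catalog = Catalog([f"d{k}" for k in range(n)])
    pool = [f"T{k}" for k in range(4)]
    entries = {}
    for k in range(n):
        if rng.random() < 0.15:  # some diseases have no tree numbers
            continue
        numbers = set()
        for _ in range(int(rng.integers(1, 3))):
            depth = int(rng.integers(1, 5))
            numbers.add(".".join(rng.choice(pool) for _ in range(depth)))
        entries[f"d{k}"] = numbers
    return catalog, TreeNumberMap(entries)
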