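import random

import pytest

from chronograft import fixtures
from chronograft.trees import Chronogram, Tree, parse_newick


@pytest.fixture(scope="session")
def small_example():
    """(db, taxonomy, query, target) for the bundled six-species example."""
    return fixtures.small_example_db()


@pytest.fixture(scope="session")
def canonical_db(small_example):
    db, taxonomy, _query, _target = small_example
    return db.canonicalized(taxonomy)


def random_ultrametric(seed: int, n_tips: int, labels=None) -> Chronogram:
    if labels is None:
        labels = [f"t{i:02d}" for i in range(n_tips)]
    return fixtures.random_chronogram(labels, seed=seed)


def random_tree(seed: int, n_tips: int) -> Tree:
    """A random (not necessarily ultrametric) binary tree with random
    branch lengths, for round-trip and structural tests."""
    rng = random.Random(seed)
    parts = [f"t{i:02d}" for i in range(n_tips)]
    while len(parts) > 1:
        i, j = sorted(rng.sample(range(len(parts)), 2), reverse=True)
        a, b = parts.pop(i), parts.pop(j)
        la, lb = rng.uniform(0.1, 5.0), rng.uniform(0.1, 5.0)
        parts.append(f"({a}:{la:.4f},{b}:{lb:.4f})")
    return parse_newick(parts[0] + ";")
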