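import random

import pytest

from tfcover import HittingSetInstance, ProteinDnaGraph


def random_instance(rnd: random.Random, max_m=14, max_n=8, max_t=3):
    """Sample a small feasible hitting-set instance (for oracle checks)."""
    m = rnd.randint(2, max_m)
    n = rnd.randint(1, max_n)
    t = rnd.randint(1, min(max_t, m))
    elements = tuple(f"e{i:02d}" for i in range(m))
    weights = {e: rnd.uniform(0.05, 5.0) for e in elements}
    family = tuple(
        frozenset(rnd.sample(elements, rnd.randint(t, min(m, t + 4))))
        for _ in range(n)
    )
    return HittingSetInstance(elements, weights, family, t)


@pytest.fixture
def toy_graph():
    """Two TFs, two genes: g1 bound by A and B, g2 by A only."""
    return ProteinDnaGraph({
        ("A", "g1"): 0.5,
        ("B", "g1"): 0.5,
        ("A", "g2"): 0.5,
    })


@pytest.fixture
def shared_target_graph():
    """Three TFs co-binding two genes, plus asymmetric extras."""
    return ProteinDnaGraph({
        ("A", "g1"): 1.0, ("A", "g2"): 1.0, ("A", "g3"): 1.0,
        ("B", "g1"): 1.0, ("B", "g2"): 1.0,
        ("C", "g1"): 1.0, ("C", "g2"): 1.0,
    })
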