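import numpy as np
import pytest

from topspread import Network, fixture


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def cycle5():
    return fixture("cycle", 5)


@pytest.fixture
def complete4():
    return fixture("complete", 4)


@pytest.fixture
def path4():
    return fixture("path", 4)


def random_digraph(n: int, p: float, seed: int) -> Network:
    """Random simple digraph over string labels (not necessarily connected)."""
    rng = np.random.default_rng(seed)
    labels = [f"v{i:03d}" for i in range(n)]
    edges = [
        (labels[i], labels[j])
        for i in range(n)
        for j in range(n)
        if i != j and rng.random() < p
    ]
    return Network(edges, nodes=labels)


def random_scc(n: int, p: float, seed: int) -> Network:
    """Random digraph guaranteed strongly connected by a ring backbone."""
    rng = np.random.default_rng(seed)
    labels = [f"v{i:03d}" for i in range(n)]
    edges = [(labels[i], labels[(i + 1) % n]) for i in range(n)]
    edges += [
        (labels[i], labels[j])
        for i in range(n)
        for j in range(n)
        if i != j and rng.random() < p
    ]
    return Network(edges, nodes=labels)
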