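import numpy as np
import pytest

from inflanet.estimate import NetworkModel


def make_network(weights: np.ndarray, names: list[str] | None = None, n: int = 100) -> NetworkModel:
    """NetworkModel wrapper around a hand-written weight matrix."""
    w = np.asarray(weights, dtype=float)
    p = w.shape[0]
    names = names or [f"n{i + 1}" for i in range(p)]
    return NetworkModel(
        weights=w,
        node_names=names,
        selected_lambda=0.1,
        ebic_gamma=0.0,
        path_lambdas=np.array([0.1]),
        path_ebics=np.array([0.0]),
        n=n,
        p=p,
    )


@pytest.fixture
def two_clique_net():
    """Two positive 4-cliques with no edges between them."""
    p = 8
    w = np.zeros((p, p))
    for block in (range(0, 4), range(4, 8)):
        for i in block:
            for j in block:
                if i != j:
                    w[i, j] = 1.0
    return make_network(w)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
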