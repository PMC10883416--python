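import numpy as np
import pytest

from bigatae.alignment import BipartiteGraph
from bigatae.io import preprocess_pair
from bigatae.synthetic import SynthConfig, generate_slice_pair


@pytest.fixture(scope="session")
def default_pair():
    """Synthetic consecutive-slice pair at generator defaults, seed 0."""
    return generate_slice_pair(SynthConfig(seed=0))


@pytest.fixture(scope="session")
def preprocessed_pair(default_pair):
    target, adjacent = default_pair
    return preprocess_pair(target, adjacent)


def random_bipartite_instance(rng, n_u, n_v, d, edge_p=0.5, ensure_nonempty=True):
    """Random expression matrices plus a random bipartite graph."""
    E_u = rng.random((n_u, d)) * 2.0
    E_v = rng.random((n_v, d)) * 2.0
    mask = rng.random((n_u, n_v)) < edge_p
    if ensure_nonempty and not mask.any():
        mask[0, 0] = True
    edges = frozenset((int(i), int(j)) for i, j in zip(*np.nonzero(mask)))
    return E_u, E_v, BipartiteGraph(n_u=n_u, n_v=n_v, edges=edges)


def full_bipartite_graph(n_u, n_v):
    return BipartiteGraph(
        n_u=n_u, n_v=n_v,
        edges=frozenset((i, j) for i in range(n_u) for j in range(n_v)),
    )
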