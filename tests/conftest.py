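import numpy as np
import pytest

import freqlink as fl


@pytest.fixture()
def k2():
    """Single pseudogene-miRNA edge."""
    return fl.BipartiteGraph(["p"], ["m"], {(0, 0)})


@pytest.fixture()
def path3():
    """Path p1 - m1 - p2 (global node order: p1, p2, m1)."""
    return fl.BipartiteGraph(["p1", "p2"], ["m1"], {(0, 0), (1, 0)})


@pytest.fixture()
def toy4():
    """The 4-node toy: edges (p1,m1), (p1,m2), (p2,m2)."""
    return fl.BipartiteGraph(["p1", "p2"], ["m1", "m2"], {(0, 0), (0, 1), (1, 1)})


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_bigraph(rng, n_p=4, n_m=4, p_edge=0.5, ensure_edge=True):
    """Small random bipartite graph for oracle comparisons."""
    edges = {(i, j) for i in range(n_p) for j in range(n_m)
             if rng.random() < p_edge}
    if ensure_edge and not edges:
        edges = {(int(rng.integers(n_p)), int(rng.integers(n_m)))}
    p_ids = [f"p{i}" for i in range(n_p)]
    m_ids = [f"m{j}" for j in range(n_m)]
    return fl.BipartiteGraph(p_ids, m_ids, edges)


@pytest.fixture(scope="session")
def planted():
    """Default planted synthetic graph plus its latent score matrix."""
    spec = fl.SyntheticSpec()
    graph, scores = fl.planted_bipartite(spec)
    return spec, graph, scores


@pytest.fixture(scope="session")
def planted_features(planted):
    spec, graph, _ = planted
    seqs = {**fl.random_sequences(graph.pseudogene_ids,
                                  spec.pseudogene_length_range, seed=1),
            **fl.random_sequences(graph.mirna_ids,
                                  spec.mirna_length_range, seed=2)}
    return fl.featurize_nodes(graph, seqs, k=3)
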