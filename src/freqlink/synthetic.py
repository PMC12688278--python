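"""Synthetic bipartite association graphs with planted low-rank structure.

The generator draws rank-r latent factors for each side, thresholds the
sigmoid of their inner products at the quantile matching the requested
edge density, and then flips each cell independently with a small noise
probability.  Link-prediction signal therefore lives purely in the graph
topology (the latent score matrix is returned as a recoverability
oracle); node sequences are uniform random RNA and carry no planted
signal — they exercise the featurization plumbing, not the learning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph_io import BipartiteGraph

__all__ = ["SyntheticSpec", "planted_bipartite", "random_sequences"]


@dataclass
class SyntheticSpec:
    """Desk-scale generator settings (defaults train in seconds)."""

    n_pseudogenes: int = 50
    n_mirnas: int = 30
    latent_rank: int = 2
    edge_density: float = 0.10
    noise: float = 0.05
    pseudogene_length_range: tuple[int, int] = (100, 300)
    mirna_length_range: tuple[int, int] = (19, 25)   # typical mature miRNA lengths
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.edge_density < 1.0):
            raise ValueError("edge_density must lie in (0, 1)")
        if self.latent_rank > min(self.n_pseudogenes, self.n_mirnas):
            raise ValueError("latent_rank exceeds the smaller side")
        if not (0.0 <= self.noise < 0.5):
            raise ValueError("noise must lie in [0, 0.5)")


def planted_bipartite(spec: SyntheticSpec) -> tuple[BipartiteGraph, np.ndarray]:
    """Bipartite graph with planted rank-r structure plus flip noise.

    Returns the graph and the latent score matrix S (n_pseudogenes x
    n_mirnas); higher S[i, j] means edge (i, j) is more likely before
    noise.  Deterministic for a given spec.seed.
    """
    rng = np.random.default_rng(spec.seed)
    r = spec.latent_rank
    U = rng.normal(0.0, 1.0 / np.sqrt(r), (spec.n_pseudogenes, r))
    V = rng.normal(0.0, 1.0 / np.sqrt(r), (spec.n_mirnas, r))
    S = U @ V.T
    probs = 1.0 / (1.0 + np.exp(-S))
    thr = np.quantile(probs, 1.0 - spec.edge_density)
    adj = probs > thr
    if spec.noise > 0:
        flip = rng.random(adj.shape) < spec.noise
        adj = adj ^ flip
    edges = {(int(i), int(j)) for i, j in zip(*np.nonzero(adj))}
    if not edges:
        raise ValueError("spec produced zero edges")
    width_p = len(str(spec.n_pseudogenes))
    width_m = len(str(spec.n_mirnas))
    p_ids = [f"PG{i:0{width_p}d}" for i in range(spec.n_pseudogenes)]
    m_ids = [f"MIR{j:0{width_m}d}" for j in range(spec.n_mirnas)]
    return BipartiteGraph(p_ids, m_ids, edges), S


def random_sequences(ids, length_range: tuple[int, int],
                     alphabet: str = "ACGU", seed: int = 0) -> dict[str, str]:
    """Uniform i.i.d. sequences, one per id; deterministic per seed."""
    lo, hi = length_range
    if lo < 1 or hi < lo:
        raise ValueError("invalid length range")
    rng = np.random.default_rng(seed)
    letters = np.array(list(alphabet))
    out = {}
    for name in ids:
        n = int(rng.integers(lo, hi + 1))
        out[name] = "".join(letters[rng.integers(0, len(letters), n)])
    return out
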