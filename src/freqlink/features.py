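"""k-mer frequency featurization of pseudogene and miRNA sequences.

Each node is represented by the normalized frequency vector of its
length-k substrings over the RNA alphabet {A, C, G, U} in lexicographic
order, giving a 4^k-dimensional vector (64 for the default k=3).  T is
mapped to U before counting so DNA-recorded pseudogene sequences and RNA
miRNA sequences land in the same space; windows containing any other
character (e.g. N) are skipped and the denominator counts valid windows
only, so every row with at least one valid window sums to one regardless
of sequence length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np
from Bio import SeqIO

__all__ = ["FeatureMatrix", "kmer_vector", "featurize_nodes", "read_fasta",
           "write_fasta", "kmer_order"]

_ALPHABET = "ACGU"


def kmer_order(k: int) -> list[str]:
    """All k-mers over {A,C,G,U} in lexicographic order."""
    return ["".join(t) for t in product(_ALPHABET, repeat=k)]


@dataclass
class FeatureMatrix:
    """Node-by-4^k matrix of k-mer frequencies, rows in graph node order."""

    values: np.ndarray
    k: int

    def __post_init__(self):
        if self.values.shape[1] != 4 ** self.k:
            raise ValueError(f"dimension must be 4^k = {4 ** self.k}")

    @property
    def dimension(self) -> int:
        return self.values.shape[1]


def kmer_vector(sequence: str, k: int = 3) -> np.ndarray:
    """Frequency vector of the k-mers of `sequence` over {A,C,G,U}.

    Raises if the sequence is shorter than k; returns an all-zero vector
    (with a warning) when every window contains an ambiguous character.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    seq = sequence.upper().replace("T", "U")
    if len(seq) < k:
        raise ValueError(f"sequence shorter than k ({len(seq)} < {k})")
    index = {km: i for i, km in enumerate(kmer_order(k))}
    counts = np.zeros(4 ** k)
    valid = 0
    for i in range(len(seq) - k + 1):
        window = seq[i:i + k]
        j = index.get(window)
        if j is not None:
            counts[j] += 1
            valid += 1
    if valid == 0:
        warnings.warn("no valid k-mer window (all windows ambiguous); zero vector",
                      stacklevel=2)
        return counts
    return counts / valid


def featurize_nodes(graph, sequences: dict[str, str], k: int = 3,
                    allow_missing: bool = False) -> tuple[FeatureMatrix, FeatureMatrix]:
    """k-mer feature matrices for both sides of a bipartite graph.

    Row order follows the graph's node order, never the mapping order.
    Nodes without a sequence get the uniform vector 1/4^k when
    `allow_missing` is set, otherwise the missing ids are reported.
    """
    dim = 4 ** k
    uniform = np.full(dim, 1.0 / dim)

    def build(ids):
        missing = [i for i in ids if i not in sequences]
        if missing and not allow_missing:
            raise KeyError(f"missing sequences for: {', '.join(missing[:10])}"
                           + ("..." if len(missing) > 10 else ""))
        rows = [kmer_vector(sequences[i], k) if i in sequences else uniform.copy()
                for i in ids]
        return FeatureMatrix(np.vstack(rows), k)

    return build(graph.pseudogene_ids), build(graph.mirna_ids)


def read_fasta(path) -> dict[str, str]:
    """id -> sequence map from a FASTA file (first record wins per id)."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out.setdefault(rec.id, str(rec.seq))
    return out


def write_fasta(sequences: dict[str, str], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n{seq}\n")
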