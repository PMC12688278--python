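"""Bipartite association graphs: I/O, negative sampling and CV folds.

The association network is a bipartite graph between pseudogenes and
miRNAs.  Node indexing is fixed once per graph: identifiers are sorted
lexicographically within each side, the pseudogene block comes first, so
the adjacency matrix (and everything downstream) is reproducible for a
given edge list.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["BipartiteGraph", "LabeledPairs", "read_edge_list", "write_edge_list",
           "sample_negatives", "make_folds", "export_pairs"]


@dataclass
class BipartiteGraph:
    """Undirected bipartite graph between pseudogenes and miRNAs.

    Edges are stored as ``(pseudogene_index, mirna_index)`` pairs of
    side-local indices.  Global node indices run over the pseudogene block
    first (``0 .. n_pseudogenes-1``) then the miRNA block.
    """

    pseudogene_ids: list[str]
    mirna_ids: list[str]
    edges: set[tuple[int, int]] = field(default_factory=set)

    def __post_init__(self):
        if len(set(self.pseudogene_ids)) != len(self.pseudogene_ids):
            raise ValueError("duplicate pseudogene identifiers")
        if len(set(self.mirna_ids)) != len(self.mirna_ids):
            raise ValueError("duplicate miRNA identifiers")
        n, a = len(self.pseudogene_ids), len(self.mirna_ids)
        for p, m in self.edges:
            if not (0 <= p < n and 0 <= m < a):
                raise ValueError(f"edge ({p},{m}) out of range")

    # -- sizes ---------------------------------------------------------------
    @property
    def n_pseudogenes(self) -> int:
        return len(self.pseudogene_ids)

    @property
    def n_mirnas(self) -> int:
        return len(self.mirna_ids)

    @property
    def n_nodes(self) -> int:
        return self.n_pseudogenes + self.n_mirnas

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    # -- index conversions ---------------------------------------------------
    def global_index(self, side: str, i: int) -> int:
        """Global node index of side-local index `i` (`side` in {'p','m'})."""
        return i if side == "p" else self.n_pseudogenes + i

    def pair_to_global(self, pair: tuple[int, int]) -> tuple[int, int]:
        p, m = pair
        return p, self.n_pseudogenes + m

    def is_mirna_node(self, g: int) -> bool:
        return g >= self.n_pseudogenes

    # -- matrices ------------------------------------------------------------
    @property
    def adjacency(self) -> np.ndarray:
        """Symmetric 0/1 adjacency over all nodes, pseudogene block first."""
        n = self.n_nodes
        A = np.zeros((n, n))
        for p, m in self.edges:
            g = self.n_pseudogenes + m
            A[p, g] = A[g, p] = 1.0
        return A

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    def neighbors_of_pseudogene(self, p: int) -> set[int]:
        return {m for (pp, m) in self.edges if pp == p}

    def neighbors_of_mirna(self, m: int) -> set[int]:
        return {p for (p, mm) in self.edges if mm == m}

    def validate(self) -> None:
        """Check bipartiteness invariants (adjacency symmetry, zero diagonal)."""
        A = self.adjacency
        if not np.array_equal(A, A.T):
            raise AssertionError("adjacency not symmetric")
        if np.any(np.diag(A) != 0):
            raise AssertionError("nonzero diagonal")
        n = self.n_pseudogenes
        if np.any(A[:n, :n]) or np.any(A[n:, n:]):
            raise AssertionError("within-side edge: graph not bipartite")

    def without_edges(self, drop: set[tuple[int, int]]) -> "BipartiteGraph":
        """Copy of the graph with the given (p, m) edges removed."""
        return BipartiteGraph(list(self.pseudogene_ids), list(self.mirna_ids),
                              self.edges - set(drop))


@dataclass
class LabeledPairs:
    """Candidate (pseudogene, miRNA) pairs with 0/1 labels and CV folds."""

    pairs: np.ndarray          # (n, 2) side-local indices
    labels: np.ndarray         # (n,) in {0, 1}
    fold: np.ndarray | None = None   # (n,) in [0, k_folds) once assigned

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, mask: np.ndarray) -> "LabeledPairs":
        return LabeledPairs(self.pairs[mask], self.labels[mask],
                            None if self.fold is None else self.fold[mask])


def _parse_rows(path) -> list[tuple[str, str]]:
    rows = []
    with open(path, newline="", encoding="utf-8") as fh:
        text = fh.read()
    if not text.strip():
        raise ValueError(f"{path}: no associations (empty file)")
    delim = "\t" if "\t" in text.splitlines()[0] else ","
    for ln, row in enumerate(csv.reader(text.splitlines(), delimiter=delim), start=1):
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        if len(row) < 2:
            raise ValueError(f"{path}: line {ln}: expected >=2 fields, got {len(row)}")
        a, b = row[0].strip(), row[1].strip()
        if ln == 1 and a.lower() in {"pseudogene", "pseudogene_id"}:
            continue  # optional header
        rows.append((a, b))
    if not rows:
        raise ValueError(f"{path}: no associations")
    return rows


def read_edge_list(path) -> BipartiteGraph:
    """Read a two-column pseudogene/miRNA association table (TSV or CSV).

    Duplicate rows are deduplicated (with a logged count); identifiers are
    sorted lexicographically to fix the node index order.
    """
    rows = _parse_rows(path)
    uniq = sorted(set(rows))
    if len(uniq) < len(rows):
        logger.info("deduplicated %d duplicate association rows", len(rows) - len(uniq))
    p_ids = sorted({p for p, _ in uniq})
    m_ids = sorted({m for _, m in uniq})
    p_idx = {x: i for i, x in enumerate(p_ids)}
    m_idx = {x: i for i, x in enumerate(m_ids)}
    edges = {(p_idx[p], m_idx[m]) for p, m in uniq}
    logger.info("read %d pseudogenes, %d miRNAs, %d associations",
                len(p_ids), len(m_ids), len(edges))
    return BipartiteGraph(p_ids, m_ids, edges)


def write_edge_list(graph: BipartiteGraph, path) -> None:
    """Write the deduplicated edge set as a TSV with a header."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("pseudogene\tmirna\n")
        for p, m in sorted(graph.edges):
            fh.write(f"{graph.pseudogene_ids[p]}\t{graph.mirna_ids[m]}\n")


def sample_negatives(graph: BipartiteGraph, ratio: float = 1.0,
                     seed: int = 0) -> LabeledPairs:
    """All positive edges plus ``floor(ratio * n_edges)`` uniform non-edges.

    Negatives are drawn uniformly without replacement from the set of
    unobserved (pseudogene, miRNA) pairs; deterministic for a given seed.
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    n_neg = int(ratio * graph.n_edges)
    all_pairs = graph.n_pseudogenes * graph.n_mirnas
    n_non_edges = all_pairs - graph.n_edges
    if n_neg > n_non_edges:
        raise ValueError(
            f"insufficient non-edges: need {n_neg}, graph has {n_non_edges}")
    pos = sorted(graph.edges)
    edge_flat = {p * graph.n_mirnas + m for p, m in graph.edges}
    non_edges = np.array(sorted(set(range(all_pairs)) - edge_flat))
    rng = np.random.default_rng(seed)
    chosen = rng.choice(non_edges, size=n_neg, replace=False)
    neg = [(int(f) // graph.n_mirnas, int(f) % graph.n_mirnas) for f in chosen]
    pairs = np.array(pos + neg, dtype=np.intp).reshape(-1, 2)
    labels = np.concatenate([np.ones(len(pos), dtype=np.intp),
                             np.zeros(n_neg, dtype=np.intp)])
    return LabeledPairs(pairs, labels)


def make_folds(pairs: LabeledPairs, k_folds: int = 5, seed: int = 0) -> LabeledPairs:
    """Assign stratified CV folds, splitting positives and negatives separately.

    Each class is shuffled and split into `k_folds` near-equal blocks, so
    every fold preserves the global positive:negative ratio within rounding.
    """
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    if len(pairs) == 0:
        raise ValueError("no pairs to fold")
    n_pos = int(pairs.labels.sum())
    if k_folds > n_pos:
        raise ValueError(f"k_folds={k_folds} exceeds number of positives ({n_pos})")
    rng = np.random.default_rng(seed)
    fold = np.empty(len(pairs), dtype=np.intp)
    for label in (1, 0):
        idx = np.flatnonzero(pairs.labels == label)
        if idx.size == 0:
            continue
        rng.shuffle(idx)
        for f, block in enumerate(np.array_split(idx, k_folds)):
            fold[block] = f
    return LabeledPairs(pairs.pairs, pairs.labels, fold)


def export_pairs(graph: BipartiteGraph, pairs: LabeledPairs, path,
                 scores: np.ndarray | None = None) -> None:
    """Write pairs as TSV: pseudogene, mirna, label, fold, score."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("pseudogene\tmirna\tlabel\tfold\tscore\n")
        for i, ((p, m), y) in enumerate(zip(pairs.pairs, pairs.labels)):
            f = "" if pairs.fold is None else int(pairs.fold[i])
            s = "" if scores is None else f"{scores[i]:.6f}"
            fh.write(f"{graph.pseudogene_ids[p]}\t{graph.mirna_ids[m]}\t{int(y)}\t{f}\t{s}\n")
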