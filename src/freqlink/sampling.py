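"""Local and global graph views around a candidate pseudogene-miRNA pair.

The local view is the enclosing subgraph: starting from the candidate
pair, both sides are expanded alternately for k rounds (each round uses
the node sets as they stood at its start), the subgraph is induced, and
the candidate edge itself is removed so a positive pair can never leak
its own label into the structure it is scored from.  The global view is
the random-walk-with-restart (RWR) proximity profile of the pseudogene:
the fixed point of rho = c * A D^{-1} rho + (1 - c) e.  In a bipartite
graph every node at an odd hop from a pseudogene is a miRNA, so the top
scoring miRNAs form the natural global neighbourhood; the two views are
merged (node and edge union) before encoding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph_io import BipartiteGraph

__all__ = ["SampledGraph", "enclosing_subgraph", "local_subgraph",
           "subgraph_rounds", "rwr", "rwr_graph", "merge_graphs",
           "export_sampled"]


@dataclass
class SampledGraph:
    """A sampled view of a parent bipartite graph.

    Nodes are *global* parent indices (pseudogene block first); edges are
    (pseudogene_global, mirna_global) pairs.  `center_pair` records the
    candidate pair the sample was built around, in global indices.
    """

    kind: str                                   # enclosing | auxiliary | rwr | merged
    parent: BipartiteGraph
    nodes: frozenset[int]
    edges: frozenset[tuple[int, int]]
    center_pair: tuple[int, int] | None = None
    hop_k: int | None = None
    restart_c: float | None = None
    rwr_scores: np.ndarray | None = None

    def __post_init__(self):
        for u, v in self.edges:
            if u not in self.nodes or v not in self.nodes:
                raise ValueError("edge endpoint outside node subset")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def node_order(self) -> np.ndarray:
        """Sorted global indices; the row order used by adjacency()."""
        return np.array(sorted(self.nodes), dtype=np.intp)

    def adjacency(self) -> np.ndarray:
        order = self.node_order()
        pos = {g: i for i, g in enumerate(order)}
        A = np.zeros((len(order), len(order)))
        for u, v in self.edges:
            A[pos[u], pos[v]] = A[pos[v], pos[u]] = 1.0
        return A


def _neighbors(graph: BipartiteGraph):
    """Adjacency lists in global indices."""
    nbr: dict[int, set[int]] = {g: set() for g in range(graph.n_nodes)}
    for p, m in graph.edges:
        gm = graph.n_pseudogenes + m
        nbr[p].add(gm)
        nbr[gm].add(p)
    return nbr


def _induce(graph: BipartiteGraph, nodes: set[int]) -> frozenset[tuple[int, int]]:
    edges = set()
    for p, m in graph.edges:
        gm = graph.n_pseudogenes + m
        if p in nodes and gm in nodes:
            edges.add((p, gm))
    return frozenset(edges)


def enclosing_subgraph(graph: BipartiteGraph, pair: tuple[int, int], k: int,
                       kind: str = "enclosing") -> SampledGraph:
    """k-round enclosing subgraph around a (pseudogene, miRNA) pair.

    `pair` is in side-local indices; it need not be an edge.  Each round
    adds the miRNA neighbours of the current pseudogene set and the
    pseudogene neighbours of the current miRNA set, both computed from the
    sets as they stood at the start of the round.  The candidate edge is
    removed from the induced subgraph if present.
    """
    p, m = pair
    if not (0 <= p < graph.n_pseudogenes):
        raise IndexError(f"pseudogene index {p} out of range")
    if not (0 <= m < graph.n_mirnas):
        raise IndexError(f"miRNA index {m} out of range")
    if k < 0:
        raise ValueError("k must be >= 0")
    gp, gm = graph.pair_to_global(pair)
    nbr = _neighbors(graph)
    P, M = {gp}, {gm}
    for _ in range(k):
        m_new = set().union(*(nbr[x] for x in P)) - M
        p_new = set().union(*(nbr[x] for x in M)) - P
        if not m_new and not p_new:
            break  # saturated at the connected component
        P |= p_new
        M |= m_new
    nodes = P | M
    edges = set(_induce(graph, nodes))
    edges.discard((gp, gm))
    return SampledGraph(kind=kind, parent=graph, nodes=frozenset(nodes),
                        edges=frozenset(edges), center_pair=(gp, gm), hop_k=k)


def local_subgraph(graph: BipartiteGraph, pair: tuple[int, int], k: int) -> SampledGraph:
    """Union of the miRNA-seeded enclosing and pseudogene-seeded auxiliary
    subgraphs around the pair (they coincide under simultaneous expansion,
    so this is the enclosing subgraph; kept as an explicit union)."""
    enc = enclosing_subgraph(graph, pair, k, kind="enclosing")
    aux = enclosing_subgraph(graph, pair, k, kind="auxiliary")
    return SampledGraph(kind="enclosing", parent=graph,
                        nodes=enc.nodes | aux.nodes, edges=enc.edges | aux.edges,
                        center_pair=enc.center_pair, hop_k=k)


def subgraph_rounds(graph: BipartiteGraph) -> int:
    """Nominal expansion-round budget floor(v * e / 2) for a graph with v
    nodes and e edges (expansion is stopped early once it saturates)."""
    return (graph.n_nodes * graph.n_edges) // 2


def rwr(graph: BipartiteGraph, start: int, c: float = 0.5,
        tol: float = 1e-8, max_iter: int = 10_000) -> np.ndarray:
    """Random walk with restart from a global node index.

    Power iteration on rho = c * A D^{-1} rho + (1 - c) e until the L1
    change drops below `tol`.  The result is a probability vector over all
    parent nodes, zero outside the start's connected component.
    """
    if not (0.0 < c < 1.0):
        raise ValueError("restart probability c must lie in (0, 1)")
    n = graph.n_nodes
    if not (0 <= start < n):
        raise IndexError("start node out of range")
    A = graph.adjacency
    deg = A.sum(axis=0)
    if deg[start] == 0:
        raise ValueError("start node is isolated: RWR undefined")
    W = A / np.where(deg > 0, deg, 1.0)[None, :]   # column-stochastic on non-isolated
    e = np.zeros(n)
    e[start] = 1.0
    rho = e.copy()
    for _ in range(max_iter):
        new = c * (W @ rho) + (1.0 - c) * e
        if np.abs(new - rho).sum() < tol:
            return new
        rho = new
    raise RuntimeError("RWR power iteration failed to converge")


def rwr_graph(graph: BipartiteGraph, pseudogene: int, c: float = 0.5,
              top_n: int = 20, tol: float = 1e-8) -> SampledGraph:
    """Global RWR view of a pseudogene: its top-scoring miRNAs plus bridges.

    `pseudogene` is a side-local index.  The walk starts at the pseudogene;
    the `top_n` miRNA-side nodes by stationary probability are retained
    (ties broken by index), together with any pseudogene adjacent to at
    least two retained nodes so length-2 connecting paths survive induction.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    gp = graph.global_index("p", pseudogene)
    rho = rwr(graph, gp, c=c, tol=tol)
    n_p = graph.n_pseudogenes
    m_scores = rho[n_p:]
    candidates = np.flatnonzero(m_scores > 0)
    ranked = candidates[np.lexsort((candidates, -m_scores[candidates]))]
    selected = {n_p + int(g) for g in ranked[:top_n]}
    retained = {gp} | selected
    nbr = _neighbors(graph)
    bridges = {p for p in range(n_p)
               if p != gp and len(nbr[p] & selected) >= 2}
    nodes = retained | bridges
    return SampledGraph(kind="rwr", parent=graph, nodes=frozenset(nodes),
                        edges=_induce(graph, nodes), center_pair=None,
                        restart_c=c, rwr_scores=rho)


def merge_graphs(local: SampledGraph, global_g: SampledGraph) -> SampledGraph:
    """Node/edge union of the local and global views (candidate edge stays
    removed); both must have been sampled from the same parent graph."""
    if local.parent is not global_g.parent:
        raise ValueError("sampled graphs come from different parents")
    nodes = local.nodes | global_g.nodes
    edges = set(local.edges | global_g.edges)
    center = local.center_pair or global_g.center_pair
    if center is not None:
        edges.discard(tuple(center))
    return SampledGraph(kind="merged", parent=local.parent,
                        nodes=frozenset(nodes), edges=frozenset(edges),
                        center_pair=center, hop_k=local.hop_k,
                        restart_c=global_g.restart_c,
                        rwr_scores=global_g.rwr_scores)


def export_sampled(sub: SampledGraph, path) -> None:
    """Edge-list TSV with a comment header recording the sample provenance."""
    g = sub.parent
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# kind={sub.kind} center={sub.center_pair} "
                 f"k={sub.hop_k} c={sub.restart_c}\n")
        for u, v in sorted(sub.edges):
            fh.write(f"{g.pseudogene_ids[u]}\t{g.mirna_ids[v - g.n_pseudogenes]}\n")
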