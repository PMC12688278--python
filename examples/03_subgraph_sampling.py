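"""Local enclosing subgraphs and global RWR views around a candidate pair.

Extracts both views for one (pseudogene, miRNA) candidate on a planted
synthetic graph and merges them into the structure the encoder sees.
The candidate edge itself is always removed, so a known association can
never leak its own label.
"""

import freqlink as fl

graph, _ = fl.planted_bipartite(fl.SyntheticSpec())
pair = next(iter(sorted(graph.edges)))      # a known association
print(f"candidate pair: {graph.pseudogene_ids[pair[0]]} - {graph.mirna_ids[pair[1]]}")

local = fl.local_subgraph(graph, pair, k=2)
print(f"local view (2-round enclosing subgraph): {local.n_nodes} nodes, "
      f"{len(local.edges)} edges; candidate edge removed: "
      f"{local.center_pair not in local.edges}")

glob = fl.rwr_graph(graph, pair[0], c=0.5, top_n=10)
top = sorted(((glob.rwr_scores[g], g) for g in glob.nodes
              if graph.is_mirna_node(g)), reverse=True)[:3]
print(f"global view (RWR, restart 0.5): {glob.n_nodes} nodes; "
      "top miRNAs by stationary probability:")
for score, g in top:
    print(f"  {graph.mirna_ids[g - graph.n_pseudogenes]}: {score:.4f}")

merged = fl.merge_graphs(local, glob)
print(f"merged view fed to the encoder: {merged.n_nodes} nodes, "
      f"{len(merged.edges)} edges")
print(f"nominal round budget floor(v*e/2) = {fl.subgraph_rounds(graph)} "
      "(expansion stops early once the node set saturates)")
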