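"""Molecular-complex detection with the MCODE reimplementation.

Plants a perfect 8-protein complex inside a sparse random interactome and
runs core-clustering vertex weighting plus greedy complex expansion.
Printed: the predicted clusters; the planted complex should surface as the
top-scoring one.
"""

import networkx as nx

from phenonet import find_complexes, postprocess, simulate_interactome

records, truth = simulate_interactome(core=set(), n_shell=150,
                                      background_edge_prob=0.02,
                                      complexes=[(8, 1.0)], seed=42)
graph = nx.Graph()
for rec in records:
    graph.add_edge(rec.node_a, rec.node_b)

clusters = postprocess(graph, find_complexes(graph))
print(f"{graph.number_of_nodes()} proteins, {graph.number_of_edges()} "
      f"interactions, {len(clusters)} predicted complexes")
for i, c in enumerate(clusters[:3], 1):
    print(f"  cluster {i}: score {c.score:.2f}, nodes {sorted(c.nodes)}")

planted = set(truth.true_complexes[0])
top = set(clusters[0].nodes)
print(f"\nplanted complex recovered in top cluster: {planted <= top}")
# Cluster score is density x size of the induced subgraph; a full 8-clique
# scores 8.0, far above anything a p = 0.02 random background produces.
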