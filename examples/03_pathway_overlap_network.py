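"""Pathway-overlap network from shared differentially expressed genes.

Two pathways are connected when they share at least five upregulated or five
downregulated genes (counted on their platform-restricted "S-lists").
Printed: the retained pathway pairs with shared-DEG counts and the partner
profile of the best-connected process pathway.
"""

from phenonet import (GeneSet, GeneSetCatalog, build_overlap_network,
                      partner_profile)

catalog = GeneSetCatalog()
universe = [f"g{i}" for i in range(120)]
tags = ["process", "signaling", "other"]
for i in range(8):
    members = set(universe[i * 12:i * 12 + 40])
    catalog.add(GeneSet(f"PW{i}", f"pathway {i}", members,
                        functional_tag=tags[i % 3]))

up = {f"g{i}" for i in range(0, 120, 2)}
down = {f"g{i}" for i in range(1, 120, 4)}
net = build_overlap_network(catalog, up, down, set(universe), min_shared=5)

print(f"{len(net.nodes)} pathways, {len(net.edges)} overlap edges")
for e in net.edges:
    print(f"  {e.set_a} -- {e.set_b}: {e.n_up} shared up, {e.n_down} shared down")

process_terms = [t for t, a in net.nodes.items() if a["tag"] == "process"]
best = max(process_terms, key=lambda t: len(net.neighbors(t)))
print(f"\npartner profile of {best}:")
for partner, n_up, n_down, tag in partner_profile(best, net):
    print(f"  {partner} ({tag}): {n_up} up, {n_down} down")
# The process pathway overlapping the most signaling pathways is the natural
# seed for a phenotype-specific interaction network.
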