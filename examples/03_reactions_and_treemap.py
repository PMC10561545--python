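"""Encode pairs as reactions, fingerprint them with DRFP, build the tree-map.

Each selected pair becomes a reaction SMILES (smaller molecule as
reactant).  The differential reaction fingerprint hashes the circular
substructures occurring on only one side; pairs representing the same
transformation therefore collapse to nearby DRFP vectors, and the
minimum spanning tree of the DRFP k-NN graph lays related
transformations out as branches of one tree.
"""

from alchemap import all_distance_matrices, drfp_matrix, select_pairs
from alchemap.fingerprints import jaccard_distance
from alchemap.fixtures import FixtureSpec, generate_family
from alchemap.reaction_encoding import drfp
from alchemap.treemap_layout import build_treemap

molset = generate_family(FixtureSpec(2, 5, 4, seed=0))
pairs = select_pairs(all_distance_matrices(molset), profile="focused", k=5, quorum=7)
records, dists = drfp_matrix(pairs, molset)
print(f"{len(records)} reactions encoded; example: {records[0].forward_rxn}")

# the same substituent change on two scaffolds gives nearly the same DRFP
a = drfp("Cc1ccccc1>>CCc1ccccc1")     # methyl -> ethyl on benzene
b = drfp("Cc1ccncc1>>CCc1ccncc1")     # methyl -> ethyl on pyridine
c = drfp("Cc1ccccc1>>OCC(O)CO")       # unrelated transformation
print(f"DRFP distance, same transformation on two scaffolds: "
      f"{jaccard_distance(a, b):.3f}")
print(f"DRFP distance, unrelated transformations:            "
      f"{jaccard_distance(a, c):.3f}")

layout = build_treemap(dists, [r.key for r in records], k=5)
n_nodes = len(layout.coords)
n_comp = len(set(layout.components.values()))
print(f"\ntree-map: {n_nodes} pair nodes, {len(layout.mst_edges)} MST edges, "
      f"{n_comp} component(s)  (edges = nodes - components)")
print("Each node is a molecule PAIR; close nodes are pairs related by "
      "similar structural transformations.")
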