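"""Standardize a small molecule list and compare fingerprint distances.

Reads raw (id, SMILES) tuples, canonicalizes and deduplicates them, then
computes all eight fingerprint distance matrices and prints the distances
between one close analog pair and one unrelated pair.  Jaccard distances
live in [0, 1] natively; Taxicab (MXFP, MQN) distances are min-max
rescaled over the whole set, so they are only comparable within a set.
"""

from alchemap import all_distance_matrices, standardize_set

raw = [
    ("toluene", "Cc1ccccc1"),
    ("toluene_dup", "c1ccccc1C"),       # duplicate structure: dropped
    ("ethylbenzene", "CCc1ccccc1"),
    ("aspirin", "CC(=O)Oc1ccccc1C(=O)O"),
    ("glucose", "OC[C@H]1O[C@@H](O)[C@H](O)[C@@H](O)[C@@H]1O"),
]

molset = standardize_set(raw)
print(f"{len(raw)} inputs -> {len(molset)} unique standardized molecules")
for r in molset:
    print(f"  {r.id:14s} {r.smiles:32s} heavy atoms: {r.heavy_atom_count}")

dms = all_distance_matrices(molset)
print("\ndistance toluene vs ethylbenzene (analogs) and toluene vs glucose:")
for name, dm in dms.items():
    close = dm.get("toluene", "ethylbenzene")
    far = dm.get("toluene", "glucose")
    print(f"  {name:6s} analog {close:.3f}   unrelated {far:.3f}")
print("\nEvery fingerprint sees the analog pair as closer; the absolute "
      "scale differs per fingerprint, which is why selection uses "
      "per-fingerprint thresholds and ranks.")
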