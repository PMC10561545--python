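"""Score atom-mapping confidence distances for the worked drug examples.

amcd = 1 - confidence, averaged over forward and backward reactions.
Low amcd: the pair is related by a simple, usually feasible
transformation (a matched molecular pair).  High amcd: an "alchemical"
transmutation, e.g. a scaffold rearrangement no single reaction could
perform.  The built-in baseline scores the ring-aware maximum common
substructure; an RXNMapper transformer backend can be plugged in when
that package is installed.
"""

from alchemap import classify_pair, compute_amcd, worked_example_set
from alchemap.amcd import McsOverlapBackend
from alchemap.reaction_encoding import ReactionRecord, build_reaction_smiles, drfp

molset = worked_example_set()
backend = McsOverlapBackend()

examples = [
    ("tyrosine", "levodopa", "hydroxylation (matched pair)"),
    ("tetrabenazine", "hydrocodone", "double cyclization (alchemical)"),
    ("afatinib", "osimertinib", "substituent + ring-system changes"),
]
for a, b, label in examples:
    fwd, bwd = build_reaction_smiles(molset.by_id(a), molset.by_id(b))
    rec = compute_amcd(ReactionRecord(a, b, fwd, bwd, drfp(fwd)), backend)
    verdict = classify_pair(rec, cutoff=0.5)
    print(f"{a:14s} -> {b:14s} amcd={rec.amcd:.3f}  {verdict:10s} ({label})")
print("\namcd < 0.5 is called feasible here; the cutoff is a user "
      "parameter, and the two ends of the scale are what separates "
      "matched molecular pairs from scaffold transmutations.")
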