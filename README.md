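# alchemap

Alchemical analysis of molecule sets: map the structural relationships in a
compound collection by treating every similar molecule **pair** as a
(possibly mass-imbalanced) chemical reaction.

Chemical space maps depend on which molecular similarity you pick — and
there are many. `alchemap` sidesteps the choice by selecting pairs that are
similar under **eight fingerprints simultaneously**, then analyzing the
*pairs* with reaction-informatics tools that do not care whether the
"reaction" conserves mass:

1. **Standardize** the input SMILES (canonicalize, kekulize, deduplicate).
2. **Fingerprint** every molecule eight ways — circular substructure
   (ECFP4, ECFP6, MHFP6), atom-pair/shape (AP, MXFP, MAP4) and composition
   (MACCS keys, MQN) — with Jaccard distance d_J for the binary/MinHashed
   fingerprints and min–max rescaled Taxicab distance d_T for MXFP and MQN.
3. **Select pairs** by the union of three criteria: the nearest neighbor
   per fingerprint, membership in ≥7 of the 8 top-20 neighbor lists, and
   per-fingerprint distance thresholds (strict `<`; presets `fda` for a
   diverse set, `focused` for analog series).
4. **Encode each pair as a reaction** `smaller>>larger` (by heavy-atom
   count) and fingerprint it with the **differential reaction fingerprint
   (DRFP)**: the symmetric difference of the circular-substructure shingle
   sets of the two sides, hashed to 2048 bits. Identical transformations on
   different scaffolds land on nearly identical vectors.
5. **Lay out the pair space** as a tree-map: exact k-NN graph in DRFP
   space → minimum spanning tree → deterministic 2-D radial layout
   (GraphML/TSV export).
6. **Score each pair's atom-mapping confidence distance**
   `amcd = 1 − confidence`, averaged over the forward and backward
   reaction. Low amcd ⇒ a feasible transformation (a matched molecular
   pair, e.g. a hydroxylation); high amcd ⇒ an "alchemical" transmutation
   (e.g. a scaffold rearrangement). The built-in baseline backend scores
   the ring-aware maximum-common-substructure overlap; the published
   RXNMapper transformer can be plugged in as an optional backend.

The audience is computational and medicinal chemists who want a single map
of a drug set, an analog series or generative-model output that shows *how*
molecules are related, not just *that* they are similar.

## Worked example

```bash
python examples/04_amcd_feasible_vs_alchemical.py
```

```
tyrosine       -> levodopa       amcd=0.071  feasible   (hydroxylation (matched pair))
tetrabenazine  -> hydrocodone    amcd=0.565  alchemical (double cyclization (alchemical))
afatinib       -> osimertinib    amcd=0.703  alchemical (substituent + ring-system changes)
```

Tyrosine → levodopa differs by one hydroxyl — a classic matched molecular
pair, and the baseline backend finds almost all atoms in common (amcd
0.071). Tetrabenazine and hydrocodone share most of their atoms but relate
only through an exotic double ring formation: no single feasible reaction
connects them, and the ring-aware overlap collapses (amcd 0.565,
"alchemical"). The other examples (`examples/01...03`) walk through
standardization, pair selection with provenance, DRFP clustering of
transformations and the MST tree-map, each printing the numbers it
computes.

A thin CLI wraps the same library:

```bash
alchemap fixtures --scaffolds 2 --substituents 5 --decoys 4 --seed 0 --out mols.csv
alchemap run --set mols.csv --profile focused --out rundir/
```

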