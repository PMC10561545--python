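# Methods

## The model

`alchemap` analyzes a molecule set through its *pairs*. Two ideas carry the
whole pipeline:

1. **Multi-fingerprint consensus.** No single molecular fingerprint defines
   similarity; eight are computed side by side and a pair is kept when it is
   similar under any of three criteria (nearest neighbor, top-k consensus,
   threshold). Each criterion hit is recorded per pair, so downstream users
   can always see *why* a pair exists.
2. **Pairs as reactions.** Writing a pair as `reactant>>product` lets
   reaction-informatics machinery run on it even when no real reaction
   connects the two molecules — the encodings used here (DRFP, atom-mapping
   confidence) are defined on arbitrary, mass-imbalanced transformations.
   The useful signal is exactly the degree to which a pair *fails* to look
   like a feasible reaction.

## Standardization

Input SMILES are parsed with RDKit, reduced to their largest fragment (salt
stripping, logged), kekulized with cleared aromatic flags, and emitted as
canonical kekulized SMILES. Deduplication is on that canonical string, with
stereochemistry preserved as given; the first-seen id wins and input order
is the tie-break. Unparseable or unkekulizable entries are dropped with a
logged reason — set preparation is a filter, not a validator. An input that
yields no valid molecule raises.

## Fingerprints and distances

| name  | type | width | distance |
|-------|------|-------|----------|
| ECFP4 / ECFP6 | circular substructure, binary | 2048 | Jaccard |
| MHFP6 | circular substructure shingles, MinHash | 2048 | Jaccard (MinHash estimate) |
| AP    | hashed atom pairs, binary | 2048 | Jaccard |
| MAP4  | MinHashed atom-pair substructure shingles | 2048 | Jaccard (MinHash estimate) |
| MXFP  | pharmacophore category distance spectra | 217 | Taxicab, rescaled |
| MACCS | substructure keys | 167 | Jaccard |
| MQN   | atom/bond/topology counts | 42 | Taxicab, rescaled |

ECFP, AP, MACCS, MQN and the MHFP6 MinHash come from RDKit. For the MinHash
fingerprints (MHFP6, MAP4) the "Jaccard distance" is the standard MinHash
estimator — the fraction of non-matching hash positions — not set Jaccard
on bit positions. All hashing is seeded (seed 42) so vectors are identical
across runs and platforms.

MXFP and MAP4 have no implementation in the installed stack, so both are
computed here from their published definitions. MAP4 shingles are
`env(a,r)|d|env(b,r)` strings — the canonical SMILES of the two atoms'
circular environments at radii 1 and 2 joined by their topological
distance — MinHashed with the same seeded encoder as MHFP6. MXFP assigns
atoms to seven pharmacophore categories (heavy, heteroatom, H-bond
acceptor, H-bond donor, positive, negative, aromatic) and, per category,
accumulates the pairwise topological distances into 31 Gaussian-smoothed
bins (centers geometric from 1 to 300 bonds, σ = 0.35·center), normalized
per pair count and scaled by 100. The bin constants are this package's
parameterization of the published scheme; they are fixed, documented here,
and recorded with every persisted matrix.

**Taxicab rescaling** is min–max over the set of all off-diagonal pairwise
distances, per fingerprint and per molecule set (each set is analyzed
independently). Consequences worth knowing: rescaled d_T values are only
comparable within one set, and adding a molecule to a set can change all
rescaled d_T entries while Jaccard entries never move (both behaviors are
tested). A set whose pairwise distances are all equal degenerates to all
zeros with a warning.

## Pair selection

Ranked neighbor lists are built per molecule and fingerprint, sorted by
(distance, id) — the id tie-break makes every downstream artifact
reproducible. The three criteria:

- **NN**: for every molecule and every fingerprint, the rank-1 neighbor.
  Not symmetric; both directions can contribute different pairs.
- **Consensus**: candidate *c* is paired with query *q* when *c* occurs in
  *q*'s top-k list for at least `quorum` of the eight fingerprints
  (defaults k=20, quorum=7). Membership is evaluated per directed query
  list and the pair stored unordered; mutuality is not required.
- **Threshold**: distance strictly below a per-fingerprint maximum, any
  fingerprint sufficing. Two presets ship: `fda` (d_J < 0.6 for
  ECFP4/ECFP6/MHFP6, 0.5 for AP, 0.2 for MACCS, 0.8 for MAP4; rescaled
  d_T < 0.1 for MXFP, 0.05 for MQN) for diverse sets and `focused`
  (d_J < 0.2 for ECFP4/ECFP6/MHFP6/AP, 0.0125 for MACCS, 0.3 for MAP4;
  same d_T) for analog series. Taxicab thresholds apply to *rescaled*
  distances.

The final selection is the union with merged provenance, sorted by
(id_a, id_b). Selection is monotone in thresholds, and the NN criterion is
the k=1/quorum=1 special case of consensus — both are property-tested.

## DRFP

For each side of a reaction the shingle set is the canonical SMILES of
every atom's circular environment at radii 0..3 plus every smallest ring as
a whole; fragments within a side are unioned; multiplicity is ignored (set
semantics). The fingerprint sets one bit per shingle in the symmetric
difference of the two sides, hashed by 32-bit FNV-1a mod 2048. Design
points:

- Environments are canonicalized as unrooted fragment SMILES.
- The hash is fixed and process-independent; no randomized hashing.
- `drfp(A>>B) == drfp(B>>A)` by construction; an identity reaction gives
  the all-zero vector (valid, logged); popcount is bounded by the shingle
  difference size (collisions only merge bits).
- The forward direction is `smaller>>larger` by heavy atoms, ties broken by
  lexicographic canonical SMILES.

## Tree-map

Exact k-NN (default k=20) in DRFP space, undirected union of the directed
relations, ties broken by (distance, id). Kruskal MST with a stable edge
order so equal-weight ties resolve identically everywhere. Layout is a
deterministic radial embedding: per component the highest-degree node roots
the tree, children receive angular wedges proportional to subtree size, and
components are placed left-to-right in disjoint bounding boxes.
Disconnected k-NN graphs are *not* artificially bridged — component labels
are exported instead, with an optional global-nearest-edge bridging left to
the caller via the exported graph. The layout has no stochastic step; the
seed parameter exists for interface stability.

## amcd

`amcd = 1 − confidence`, averaged over forward and backward directions;
both directional values are always persisted because the asymmetry can be
substantial. The confidence backend is pluggable:

- **Baseline (`mcs-overlap`)**: heavy atoms in the maximum common
  substructure divided by the heavy atoms of the larger molecule, with
  ring-aware matching (`ringMatchesRingOnly`, `completeRingsOnly`). The
  ring constraints are the discriminative choice: with unconstrained MCS,
  chain atoms pair freely with ring atoms and a scaffold rearrangement like
  tetrabenazine→hydrocodone scores almost as high as a hydroxylation.
  Requiring rings to match as rings makes the baseline reflect what a
  chemist would call the same ring system. MCS timeouts fall back to the
  best-found substructure (logged).
- **Transformer (`rxnmapper`)**: optional; wraps the published RXNMapper
  model when installed. No tests depend on it and the baseline makes no
  claim of reproducing its values.

Classification is `feasible` iff `amcd < cutoff` (strict). No canonical
cutoff exists; it defaults to 0.5 and is logged on every call.

## Synthetic data

`generate_family` emulates what the pipeline is meant to find in real
collections: analog series (a shared scaffold — anilinoquinazoline,
phenylpiperazine amide, indole acetamide or a benzamide chain — decorated
with substituents drawn seeded from a fixed pool of 16) plus structurally
unrelated decoys (sugar, NSAID, alkaloid, steroid, fatty acid, ...).
Ground truth travels in the ids (`fam0_3`, `decoy_1`). What it does *not*
emulate: realistic activity landscapes, stereo-rich macrocycles (the
polymyxin regime), salt forms, or set sizes above a few dozen — so passing
tests demonstrate the machinery's correctness and the relative ordering of
its scores, not performance statistics on real drug collections.
`worked_example_set` packages six literal drug structures whose pairings
span the feasible→alchemical range.

## Problem sizes and determinism

Tests and the acceptance script run on sets of 5–40 molecules and up to a
few hundred pairs — sizes at which exact k-NN and exhaustive oracles
(brute-force selection loops, spanning-tree enumeration on ≤8 nodes,
pre-hash shingle enumeration on ≤10-heavy-atom molecules) are fast and
unambiguous. The library itself is comfortable at the
thousands-of-molecules scale. Every stochastic element (fixture generation,
MinHash) is seeded; repeated runs are byte-identical, which is itself an
acceptance check.

## Known limitations

- The baseline amcd is a structural-overlap score, not a learned reaction
  model; it mirrors the feasible/alchemical dichotomy qualitatively but
  its absolute values have no calibration against transformer confidences.
- MXFP here is a faithful re-parameterization, not a bit-for-bit
  reimplementation of the reference code; distances computed with it are
  internally consistent but not interchangeable with other MXFP builds.
- Min–max rescaled Taxicab distances are set-relative by design.
- The radial layout optimizes readability and determinism, not stress or
  edge-length fidelity; it is a tree drawing, not an embedding of the full
  k-NN graph.
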