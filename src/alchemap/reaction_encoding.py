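"""Pairs as reactions and the differential reaction fingerprint (DRFP).

Each selected molecule pair is written as a reaction SMILES, the smaller
molecule (by heavy atoms) as reactant, and encoded by the DRFP: the set of
canonical circular-substructure shingles (radii 0..3, plus whole smallest
rings) is extracted for each side, and the symmetric difference of the two
shingle sets is hashed to a fixed-width bit vector.  Because only set
differences are encoded, the fingerprint is well-defined even for
mass-imbalanced "alchemical" transmutations — no atom balance is required.

Shingle hashing uses a fixed 32-bit FNV-1a over the UTF-8 shingle string,
so bit vectors are identical across runs and platforms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from scipy.spatial.distance import pdist, squareform

from .chem_io import MoleculeRecord, MoleculeSet
from .pair_selection import SelectedPair

logger = logging.getLogger(__name__)

__all__ = [
    "ReactionRecord",
    "build_reaction_smiles",
    "extract_shingles",
    "drfp",
    "drfp_shingle_diff",
    "drfp_matrix",
]

DRFP_WIDTH = 2048
DRFP_RADIUS = 3

_FNV_OFFSET = 0x811C9DC5
_FNV_PRIME = 0x01000193


def _fnv1a_32(s: str) -> int:
    """Fixed 32-bit FNV-1a string hash (platform-stable, no randomization)."""
    h = _FNV_OFFSET
    for byte in s.encode("utf-8"):
        h ^= byte
        h = (h * _FNV_PRIME) & 0xFFFFFFFF
    return h


@dataclass
class ReactionRecord:
    """Forward/backward reaction SMILES and the DRFP for one pair."""

    id_a: str
    id_b: str
    forward_rxn: str
    backward_rxn: str
    drfp: np.ndarray  # binary vector, width DRFP_WIDTH

    @property
    def key(self) -> tuple[str, str]:
        return (self.id_a, self.id_b)


def build_reaction_smiles(a: MoleculeRecord, b: MoleculeRecord) -> tuple[str, str]:
    """Forward = smaller>>larger by heavy atoms; ties broken by SMILES order."""
    if a.smiles == b.smiles:
        raise ValueError("a pair needs two distinct molecules")
    key_a = (a.heavy_atom_count, a.smiles)
    key_b = (b.heavy_atom_count, b.smiles)
    small, large = (a, b) if key_a <= key_b else (b, a)
    forward = f"{small.smiles}>>{large.smiles}"
    backward = f"{large.smiles}>>{small.smiles}"
    return forward, backward


def extract_shingles(
    smiles: str, max_radius: int = DRFP_RADIUS, include_rings: bool = True
) -> frozenset[str]:
    """Canonical circular-substructure shingles of one molecule.

    For every atom and every radius 0..max_radius the canonical SMILES of
    the circular environment is collected; optionally each smallest ring is
    added as a whole.  Set semantics: multiplicity is ignored.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES {smiles!r}")
    shingles: set[str] = set()
    for atom in mol.GetAtoms():
        i = atom.GetIdx()
        shingles.add(Chem.MolFragmentToSmiles(mol, atomsToUse=[i], canonical=True))
        for radius in range(1, max_radius + 1):
            bond_ids = Chem.FindAtomEnvironmentOfRadiusN(mol, radius, i)
            if not bond_ids:
                break
            atoms = set()
            for b in bond_ids:
                bond = mol.GetBondWithIdx(b)
                atoms.add(bond.GetBeginAtomIdx())
                atoms.add(bond.GetEndAtomIdx())
            shingles.add(
                Chem.MolFragmentToSmiles(
                    mol, atomsToUse=sorted(atoms), bondsToUse=list(bond_ids),
                    canonical=True,
                )
            )
    if include_rings:
        for ring_bonds in mol.GetRingInfo().BondRings():
            atoms = set()
            for b in ring_bonds:
                bond = mol.GetBondWithIdx(b)
                atoms.add(bond.GetBeginAtomIdx())
                atoms.add(bond.GetEndAtomIdx())
            shingles.add(
                Chem.MolFragmentToSmiles(
                    mol, atomsToUse=sorted(atoms), bondsToUse=list(ring_bonds),
                    canonical=True,
                )
            )
    return frozenset(shingles)


def _side_shingles(side: str, max_radius: int, include_rings: bool) -> frozenset[str]:
    out: set[str] = set()
    for frag in side.split("."):
        if frag:
            out |= extract_shingles(frag, max_radius, include_rings)
    return frozenset(out)


def drfp_shingle_diff(
    rxn_smiles: str, max_radius: int = DRFP_RADIUS, include_rings: bool = True
) -> frozenset[str]:
    """The pre-hash symmetric difference of reactant- and product-side shingles."""
    try:
        reactants, products = rxn_smiles.split(">>")
    except ValueError:
        raise ValueError(f"expected 'reactants>>products', got {rxn_smiles!r}")
    left = _side_shingles(reactants, max_radius, include_rings)
    right = _side_shingles(products, max_radius, include_rings)
    return left ^ right


def drfp(
    rxn_smiles: str,
    width: int = DRFP_WIDTH,
    max_radius: int = DRFP_RADIUS,
    include_rings: bool = True,
) -> np.ndarray:
    """Differential reaction fingerprint as a binary vector.

    Shingles occurring on exactly one side of the reaction are hashed to
    bit indices mod ``width``.  An identity reaction gives an all-zero
    vector (valid, logged).
    """
    diff = drfp_shingle_diff(rxn_smiles, max_radius, include_rings)
    vec = np.zeros(width, dtype=np.uint8)
    if not diff:
        logger.warning("empty symmetric difference for %r: all-zero DRFP", rxn_smiles)
        return vec
    for shingle in diff:
        vec[_fnv1a_32(shingle) % width] = 1
    return vec


def drfp_matrix(
    pairs: list[SelectedPair],
    mols: MoleculeSet,
    width: int = DRFP_WIDTH,
    max_radius: int = DRFP_RADIUS,
) -> tuple[list[ReactionRecord], np.ndarray]:
    """Encode every pair; return records plus pairwise Jaccard DRFP distances.

    Records are in the deterministic (id_a, id_b) order of ``pairs``; the
    distance matrix rows follow that order.
    """
    by_id = {r.id: r for r in mols}
    records: list[ReactionRecord] = []
    for p in sorted(pairs, key=lambda p: p.key):
        try:
            a, b = by_id[p.id_a], by_id[p.id_b]
        except KeyError as e:
            raise KeyError(f"pair references unknown molecule id {e.args[0]!r}") from None
        fwd, bwd = build_reaction_smiles(a, b)
        records.append(ReactionRecord(p.id_a, p.id_b, fwd, bwd,
                                      drfp(fwd, width=width, max_radius=max_radius)))
    vecs = np.vstack([r.drfp for r in records]).astype(bool)
    if len(records) == 1:
        dists = np.zeros((1, 1))
    else:
        dists = squareform(pdist(vecs, metric="jaccard"))
        np.fill_diagonal(dists, 0.0)
    return records, dists
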