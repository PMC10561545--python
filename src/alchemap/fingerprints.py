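"""The eight molecular fingerprints and their pairwise distance matrices.

Circular-substructure fingerprints (ECFP4, ECFP6, MHFP6), pharmacophore /
atom-pair fingerprints (AP, MXFP, MAP4) and composition fingerprints
(MACCS keys, MQN) are computed per molecule; distances are Jaccard for the
binary and MinHashed fingerprints and min-max rescaled Taxicab (L1) for the
count fingerprints MXFP and MQN.

ECFP4/6, AP, MACCS, MQN and the MHFP6 MinHash come from RDKit.  MXFP and
MAP4 are computed here from their published definitions: MXFP as a 217-value
vector of Gaussian-smoothed topological atom-pair distance distributions over
seven pharmacophore categories, MAP4 as MinHashed atom-pair shingles
``env(a, r)|d|env(b, r)`` with radii 1..2.  All hashing is seeded so vectors
are stable across runs and platforms.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem import MACCSkeys, rdFingerprintGenerator, rdMHFPFingerprint, rdmolops
from rdkit.Chem import rdMolDescriptors
from scipy.spatial.distance import pdist, squareform

from .chem_io import MoleculeSet

logger = logging.getLogger(__name__)

__all__ = [
    "FingerprintSpec",
    "DistanceMatrix",
    "FINGERPRINT_NAMES",
    "get_spec",
    "compute_fingerprint",
    "jaccard_distance",
    "minhash_distance",
    "taxicab_distance_matrix",
    "distance_matrix",
    "all_distance_matrices",
    "save_distance_matrix",
    "load_distance_matrix",
]

MINHASH_SEED = 42  # fixed so MHFP6 / MAP4 vectors are reproducible
_MHFP_ENCODER = rdMHFPFingerprint.MHFPEncoder(2048, MINHASH_SEED)


@dataclass(frozen=True)
class FingerprintSpec:
    """Name, representation, width and distance metric of one fingerprint."""

    name: str
    representation: str  # "binary" | "count"
    width: int
    metric: str  # "jaccard" | "taxicab"
    minhash: bool = False  # MinHash vectors compare by position mismatch


_SPECS = {
    "ECFP4": FingerprintSpec("ECFP4", "binary", 2048, "jaccard"),
    "ECFP6": FingerprintSpec("ECFP6", "binary", 2048, "jaccard"),
    "MHFP6": FingerprintSpec("MHFP6", "binary", 2048, "jaccard", minhash=True),
    "AP": FingerprintSpec("AP", "binary", 2048, "jaccard"),
    "MXFP": FingerprintSpec("MXFP", "count", 217, "taxicab"),
    "MAP4": FingerprintSpec("MAP4", "binary", 2048, "jaccard", minhash=True),
    "MACCS": FingerprintSpec("MACCS", "binary", 167, "jaccard"),
    "MQN": FingerprintSpec("MQN", "count", 42, "taxicab"),
}

FINGERPRINT_NAMES = tuple(_SPECS)


def get_spec(name: str) -> FingerprintSpec:
    try:
        return _SPECS[name]
    except KeyError:
        raise ValueError(f"unsupported fingerprint {name!r}; choose from {FINGERPRINT_NAMES}")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances for one fingerprint over one set."""

    fingerprint: str
    ids: list[str]
    values: np.ndarray  # (n, n) float, zero diagonal
    metric: str
    rescaled: bool = False

    @property
    def n(self) -> int:
        return len(self.ids)

    def get(self, id_a: str, id_b: str) -> float:
        i, j = self.ids.index(id_a), self.ids.index(id_b)
        return float(self.values[i, j])


# ---------------------------------------------------------------------------
# per-fingerprint vector computation

def _bitvect_to_numpy(bv, width: int) -> np.ndarray:
    arr = np.zeros(width, dtype=np.uint8)
    arr[list(bv.GetOnBits())] = 1
    return arr


def _morgan(mols, radius: int) -> np.ndarray:
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=2048)
    return np.vstack([_bitvect_to_numpy(gen.GetFingerprint(m), 2048) for m in mols])


def _atom_pair(mols) -> np.ndarray:
    gen = rdFingerprintGenerator.GetAtomPairGenerator(fpSize=2048)
    return np.vstack([_bitvect_to_numpy(gen.GetFingerprint(m), 2048) for m in mols])


def _maccs(mols) -> np.ndarray:
    return np.vstack([_bitvect_to_numpy(MACCSkeys.GenMACCSKeys(m), 167) for m in mols])


def _mqn(mols) -> np.ndarray:
    return np.vstack([np.asarray(rdMolDescriptors.MQNs_(m), dtype=np.int64) for m in mols])


def _mhfp6(mols) -> np.ndarray:
    return np.vstack([
        np.asarray(_MHFP_ENCODER.EncodeMol(m, radius=3, rings=True), dtype=np.uint32)
        for m in mols
    ])


def _env_smiles(mol: Chem.Mol, atom_idx: int, radius: int) -> str:
    """Canonical SMILES of the circular environment of one atom."""
    if radius == 0:
        return Chem.MolFragmentToSmiles(mol, atomsToUse=[atom_idx], canonical=True)
    bond_ids = Chem.FindAtomEnvironmentOfRadiusN(mol, radius, atom_idx)
    if not bond_ids:
        return Chem.MolFragmentToSmiles(mol, atomsToUse=[atom_idx], canonical=True)
    atoms = set()
    for b in bond_ids:
        bond = mol.GetBondWithIdx(b)
        atoms.add(bond.GetBeginAtomIdx())
        atoms.add(bond.GetEndAtomIdx())
    return Chem.MolFragmentToSmiles(
        mol, atomsToUse=sorted(atoms), bondsToUse=list(bond_ids), canonical=True
    )


def _map4_shingles(mol: Chem.Mol, radii=(1, 2)) -> list[str]:
    """Atom-pair substructure shingles: env(a,r) | topological distance | env(b,r)."""
    n = mol.GetNumAtoms()
    if n == 1:
        return [Chem.MolToSmiles(mol)]
    dm = rdmolops.GetDistanceMatrix(mol)
    shingles: set[str] = set()
    for r in radii:
        envs = [_env_smiles(mol, i, r) for i in range(n)]
        for i in range(n):
            for j in range(i + 1, n):
                a, b = sorted((envs[i], envs[j]))
                shingles.add(f"{a}|{int(dm[i, j])}|{b}")
    return sorted(shingles)


def _map4(mols) -> np.ndarray:
    rows = []
    for m in mols:
        sh = _map4_shingles(m)
        rows.append(np.asarray(_MHFP_ENCODER.FromStringArray(sh), dtype=np.uint32))
    return np.vstack(rows)


# MXFP: seven pharmacophore atom categories, each summarised by the
# distribution of pairwise topological distances over Gaussian bins.
_MXFP_CENTERS = np.geomspace(1.0, 300.0, 31)
_MXFP_SIGMAS = 0.35 * _MXFP_CENTERS


def _mxfp_categories(mol: Chem.Mol) -> dict[str, list[int]]:
    cats: dict[str, list[int]] = {
        "heavy": [], "hetero": [], "hba": [], "hbd": [],
        "pos": [], "neg": [], "aromatic": [],
    }
    for atom in mol.GetAtoms():
        i = atom.GetIdx()
        z = atom.GetAtomicNum()
        cats["heavy"].append(i)
        if z not in (6, 1):
            cats["hetero"].append(i)
        if z in (7, 8):
            cats["hba"].append(i)
            if atom.GetTotalNumHs() > 0:
                cats["hbd"].append(i)
        if atom.GetFormalCharge() > 0:
            cats["pos"].append(i)
        if atom.GetFormalCharge() < 0:
            cats["neg"].append(i)
        if atom.GetIsAromatic():
            cats["aromatic"].append(i)
    return cats


def _mxfp(mols) -> np.ndarray:
    rows = []
    for mol in mols:
        dm = rdmolops.GetDistanceMatrix(mol)
        cats = _mxfp_categories(mol)
        vec = np.zeros(7 * 31, dtype=np.float64)
        for c, key in enumerate(["heavy", "hetero", "hba", "hbd", "pos", "neg", "aromatic"]):
            idx = cats[key]
            if len(idx) < 2:
                continue
            sub = dm[np.ix_(idx, idx)]
            d = sub[np.triu_indices(len(idx), k=1)]
            # Gaussian-binned, normalized distance distribution scaled to 100
            g = np.exp(-((d[:, None] - _MXFP_CENTERS[None, :]) ** 2)
                       / (2.0 * _MXFP_SIGMAS[None, :] ** 2))
            vec[c * 31:(c + 1) * 31] = 100.0 * g.sum(axis=0) / len(d)
        rows.append(vec)
    return np.vstack(rows)


_COMPUTERS = {
    "ECFP4": lambda mols: _morgan(mols, 2),
    "ECFP6": lambda mols: _morgan(mols, 3),
    "MHFP6": _mhfp6,
    "AP": _atom_pair,
    "MXFP": _mxfp,
    "MAP4": _map4,
    "MACCS": _maccs,
    "MQN": _mqn,
}


def compute_fingerprint(molset: MoleculeSet, name: str) -> np.ndarray:
    """Fingerprint vectors for a set: one row per molecule, in id order."""
    spec = get_spec(name)
    mols = [r.mol() for r in molset]
    vecs = _COMPUTERS[spec.name](mols)
    assert vecs.shape == (len(molset), spec.width)
    return vecs


# ---------------------------------------------------------------------------
# distances

def jaccard_distance(a: np.ndarray, b: np.ndarray) -> float:
    """1 - |a AND b| / |a OR b| on binary vectors; 0 if both all-zero."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"width mismatch: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return 1.0 - np.logical_and(a, b).sum() / union


def minhash_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Jaccard distance estimated from MinHash vectors: mismatch fraction."""
    if a.shape != b.shape:
        raise ValueError(f"width mismatch: {a.shape} vs {b.shape}")
    return float(np.mean(a != b))


def _rescale_offdiag(values: np.ndarray) -> tuple[np.ndarray, bool]:
    n = values.shape[0]
    iu = np.triu_indices(n, k=1)
    off = values[iu]
    lo, hi = off.min(), off.max()
    if hi == lo:
        logger.warning("all pairwise distances equal; min-max rescale degenerates to 0")
        return np.zeros_like(values), True
    out = np.zeros_like(values, dtype=np.float64)
    out[iu] = (off - lo) / (hi - lo)
    return out + out.T, True


def taxicab_distance_matrix(vectors: np.ndarray, ids: list[str],
                            fingerprint: str = "MQN") -> DistanceMatrix:
    """Raw L1 distances for all pairs, min-max rescaled to [0, 1] as a set."""
    if len(ids) < 2:
        raise ValueError("need at least 2 molecules")
    raw = squareform(pdist(np.asarray(vectors, dtype=np.float64), metric="cityblock"))
    values, rescaled = _rescale_offdiag(raw)
    return DistanceMatrix(fingerprint, list(ids), values, "taxicab", rescaled)


def distance_matrix(molset: MoleculeSet, name: str) -> DistanceMatrix:
    """Pairwise distance matrix for one fingerprint over one set."""
    if len(molset) < 2:
        raise ValueError("need at least 2 molecules")
    spec = get_spec(name)
    vecs = compute_fingerprint(molset, name)
    if spec.metric == "taxicab":
        return taxicab_distance_matrix(vecs, molset.ids, spec.name)
    if spec.minhash:
        values = squareform(pdist(vecs, metric=lambda a, b: np.mean(a != b)))
    else:
        values = squareform(pdist(vecs.astype(bool), metric="jaccard"))
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(spec.name, molset.ids, values, "jaccard", rescaled=False)


def all_distance_matrices(molset: MoleculeSet) -> dict[str, DistanceMatrix]:
    """All eight distance matrices, keyed by fingerprint name."""
    return {name: distance_matrix(molset, name) for name in FINGERPRINT_NAMES}


# ---------------------------------------------------------------------------
# persistence: dense TSV + JSON sidecar

def save_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    path = Path(path)
    np.savetxt(path, dm.values, delimiter="\t", fmt="%.10g")
    sidecar = {
        "fingerprint": dm.fingerprint,
        "metric": dm.metric,
        "rescaled": dm.rescaled,
        "ids": dm.ids,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def load_distance_matrix(path: str | Path) -> DistanceMatrix:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    values = np.loadtxt(path, delimiter="\t", ndmin=2)
    return DistanceMatrix(meta["fingerprint"], meta["ids"], values,
                          meta["metric"], meta["rescaled"])
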