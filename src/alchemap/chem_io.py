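"""Reading, standardizing and writing molecule sets.

Input SMILES are canonicalized and kekulized, duplicates (by canonical
SMILES, stereochemistry preserved) are collapsed to the first-seen id,
multi-fragment entries are reduced to their largest fragment, and
unparseable entries are dropped with a logged reason.  The resulting
:class:`MoleculeSet` is the common currency of the whole pipeline.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

__all__ = [
    "MoleculeRecord",
    "MoleculeSet",
    "StandardizationError",
    "standardize_set",
    "canonical_kekulized_smiles",
    "compute_fsp3",
    "read_molecule_file",
    "write_molecule_file",
]


class StandardizationError(ValueError):
    """Raised when an input set yields no valid molecule."""


@dataclass(frozen=True)
class MoleculeRecord:
    """One standardized molecule.

    Attributes
    ----------
    id : str
        Opaque identifier, unique within a set.
    smiles : str
        Canonical kekulized SMILES.
    heavy_atom_count : int
        Number of non-hydrogen atoms; the ordering key used when a pair
        is written as a reaction.
    activity : float, optional
        Numeric activity (e.g. pIC50) if supplied.
    fsp3 : float, optional
        Fraction of sp3 carbons, populated by :func:`compute_fsp3`.
    """

    id: str
    smiles: str
    heavy_atom_count: int
    activity: float | None = None
    fsp3: float | None = None

    def mol(self) -> Chem.Mol:
        m = Chem.MolFromSmiles(self.smiles)
        if m is None:  # pragma: no cover - invariant of construction
            raise ValueError(f"stored SMILES no longer parses: {self.smiles!r}")
        return m


@dataclass
class MoleculeSet:
    """An ordered, deduplicated collection of molecules.

    Records are kept sorted by id so every downstream stage sees a
    stable, deterministic order.
    """

    records: list[MoleculeRecord] = field(default_factory=list)
    name: str = "molecules"

    def __post_init__(self) -> None:
        self.records = sorted(self.records, key=lambda r: r.id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[MoleculeRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> MoleculeRecord:
        return self.records[i]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def by_id(self, mol_id: str) -> MoleculeRecord:
        for r in self.records:
            if r.id == mol_id:
                return r
        raise KeyError(mol_id)


def _largest_fragment(mol: Chem.Mol) -> Chem.Mol:
    """Keep the largest fragment by heavy-atom count (salt stripping)."""
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) == 1:
        return mol
    return max(frags, key=lambda f: (f.GetNumHeavyAtoms(), Chem.MolToSmiles(f)))


def canonical_kekulized_smiles(smiles: str) -> str | None:
    """Canonical kekulized SMILES of ``smiles``, or None if it fails.

    Stereochemistry is preserved as given.  Multi-fragment inputs are
    reduced to the largest fragment before canonicalization.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    if len(Chem.GetMolFrags(mol)) > 1:
        logger.warning("multi-fragment SMILES %r: keeping largest fragment", smiles)
        mol = _largest_fragment(mol)
        Chem.SanitizeMol(mol)
    try:
        Chem.Kekulize(mol, clearAromaticFlags=True)
        return Chem.MolToSmiles(mol, kekuleSmiles=True)
    except Chem.KekulizeException:
        return None


def standardize_set(
    raw: Sequence[tuple[str, str]] | Iterable[tuple[str, str]],
    name: str = "molecules",
    activities: dict[str, float] | None = None,
) -> MoleculeSet:
    """Canonicalize, kekulize and deduplicate a list of (id, SMILES).

    Duplicate canonical structures collapse to the first-seen id;
    unparseable or unkekulizable entries are dropped with a warning.

    Raises
    ------
    StandardizationError
        If the input is empty or no entry yields a valid molecule.
    """
    raw = list(raw)
    if not raw:
        raise StandardizationError("empty input: no molecules to standardize")

    seen_smiles: dict[str, str] = {}
    seen_ids: set[str] = set()
    records: list[MoleculeRecord] = []
    failures: list[tuple[str, str]] = []
    for mol_id, smi in raw:
        mol_id = str(mol_id)
        canon = canonical_kekulized_smiles(smi)
        if canon is None:
            failures.append((mol_id, smi))
            logger.warning("dropping %s: unparseable/unkekulizable SMILES %r", mol_id, smi)
            continue
        if canon in seen_smiles:
            logger.info("duplicate structure %s == %s; keeping first", mol_id, seen_smiles[canon])
            continue
        if mol_id in seen_ids:
            raise StandardizationError(f"duplicate id {mol_id!r} with distinct structures")
        seen_smiles[canon] = mol_id
        seen_ids.add(mol_id)
        mol = Chem.MolFromSmiles(canon)
        records.append(
            MoleculeRecord(
                id=mol_id,
                smiles=canon,
                heavy_atom_count=mol.GetNumHeavyAtoms(),
                activity=None if activities is None else activities.get(mol_id),
            )
        )
    if not records:
        raise StandardizationError(
            "no valid molecules; failures: "
            + "; ".join(f"{i}:{s!r}" for i, s in failures)
        )
    return MoleculeSet(records=records, name=name)


def compute_fsp3(record: MoleculeRecord | str) -> float:
    """Fraction of sp3-hybridized carbons among all carbons (0 if no C)."""
    smiles = record.smiles if isinstance(record, MoleculeRecord) else record
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES {smiles!r}")
    carbons = [a for a in mol.GetAtoms() if a.GetAtomicNum() == 6]
    if not carbons:
        return 0.0
    sp3 = sum(1 for a in carbons if a.GetHybridization() == Chem.HybridizationType.SP3)
    return sp3 / len(carbons)


def annotate_fsp3(molset: MoleculeSet) -> MoleculeSet:
    """Return a copy of the set with the fsp3 field populated."""
    return MoleculeSet(
        records=[replace(r, fsp3=compute_fsp3(r)) for r in molset],
        name=molset.name,
    )


# ---------------------------------------------------------------------------
# file I/O

def read_molecule_file(
    path: str | Path,
    format: str | None = None,
    id_column: str = "id",
    smiles_column: str = "smiles",
    activity_column: str = "activity",
    name: str | None = None,
) -> MoleculeSet:
    """Read a .smi (``SMILES [id]`` per line) or .csv molecule file.

    The format is inferred from the suffix when not given.  CSV files
    must contain the id and smiles columns (names configurable); an
    activity column is optional.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or ("csv" if path.suffix.lower() == ".csv" else "smi")
    name = name or path.stem

    raw: list[tuple[str, str]] = []
    activities: dict[str, float] = {}
    if fmt == "smi":
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            smi = parts[0]
            mol_id = parts[1] if len(parts) > 1 else f"mol{lineno}"
            raw.append((mol_id, smi))
    elif fmt == "csv":
        with path.open(newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or id_column not in reader.fieldnames \
                    or smiles_column not in reader.fieldnames:
                raise ValueError(
                    f"{path}: csv must have {id_column!r} and {smiles_column!r} columns; "
                    f"found {reader.fieldnames}"
                )
            for lineno, row in enumerate(reader, start=2):
                mol_id, smi = row[id_column], row[smiles_column]
                if not smi:
                    raise ValueError(f"{path}:{lineno}: empty SMILES field")
                raw.append((mol_id, smi))
                act = row.get(activity_column)
                if act not in (None, ""):
                    activities[mol_id] = float(act)
    else:
        raise ValueError(f"unknown format {fmt!r} (expected 'smi' or 'csv')")
    return standardize_set(raw, name=name, activities=activities or None)


def write_molecule_file(molset: MoleculeSet, path: str | Path) -> None:
    """Write a set as CSV (id, smiles, heavy_atom_count, activity, fsp3)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "smiles", "heavy_atom_count", "activity", "fsp3"])
        for r in molset:
            writer.writerow([
                r.id,
                r.smiles,
                r.heavy_atom_count,
                "" if r.activity is None else repr(r.activity),
                "" if r.fsp3 is None else repr(r.fsp3),
            ])
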