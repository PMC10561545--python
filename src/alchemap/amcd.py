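"""Atom-mapping confidence distance (amcd) and feasible/alchemical calls.

A confidence backend maps a reaction SMILES to a confidence score in
[0, 1] (and optionally an atom-mapped reaction SMILES).  The amcd of a pair
is ``1 - confidence``, averaged over the forward and backward reaction
directions.  Low amcd marks pairs related by a simple, usually feasible
transformation (matched molecular pairs); high amcd marks "alchemical"
transmutations such as scaffold hops.

Two backends are provided: a built-in baseline scoring the maximum-common-
substructure overlap of the two molecules (runs everywhere, deterministic),
and an optional transformer backend wrapping the published RXNMapper model
when that package is installed.  Both directional values are always kept —
the forward/backward difference can be substantial.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Protocol

from rdkit import Chem
from rdkit.Chem import rdFMCS

from .reaction_encoding import ReactionRecord

logger = logging.getLogger(__name__)

__all__ = [
    "AmcdRecord",
    "ConfidenceBackend",
    "McsOverlapBackend",
    "RxnMapperBackend",
    "compute_amcd",
    "mcs_overlap_confidence",
    "classify_pair",
]

DEFAULT_CUTOFF = 0.5


@dataclass
class AmcdRecord:
    """Confidence scores and the averaged amcd for one pair."""

    id_a: str
    id_b: str
    conf_fwd: float
    conf_bwd: float
    backend: str
    mapped_fwd: str | None = None
    mapped_bwd: str | None = None
    incomplete: bool = False

    @property
    def amcd_fwd(self) -> float:
        return 1.0 - self.conf_fwd

    @property
    def amcd_bwd(self) -> float:
        return 1.0 - self.conf_bwd

    @property
    def amcd(self) -> float | None:
        if self.incomplete:
            return None
        return (self.amcd_fwd + self.amcd_bwd) / 2.0


class ConfidenceBackend(Protocol):
    """Contract: reaction SMILES -> (confidence in [0,1], mapped SMILES or None)."""

    name: str

    def __call__(self, rxn_smiles: str) -> tuple[float, str | None]: ...


def mcs_overlap_confidence(rxn_smiles: str, timeout: int = 10) -> float:
    """Baseline confidence: MCS heavy atoms / heavy atoms of the larger side.

    Identical molecules score 1.  If the MCS search hits its timeout the
    best substructure found so far is used (flagged in the log).
    """
    try:
        reactant_s, product_s = rxn_smiles.split(">>")
    except ValueError:
        raise ValueError(f"expected 'reactant>>product', got {rxn_smiles!r}")
    r = Chem.MolFromSmiles(reactant_s)
    p = Chem.MolFromSmiles(product_s)
    if r is None or p is None:
        raise ValueError(f"invalid reaction SMILES {rxn_smiles!r}")
    larger = max(r.GetNumHeavyAtoms(), p.GetNumHeavyAtoms())
    if larger == 0:
        return 1.0
    if Chem.MolToSmiles(r) == Chem.MolToSmiles(p):
        return 1.0
    # ring-aware matching: ring atoms only pair with ring atoms and rings
    # must match completely, so scaffold rearrangements score low even when
    # most atoms could be paired topologically
    res = rdFMCS.FindMCS([r, p], timeout=timeout,
                         ringMatchesRingOnly=True, completeRingsOnly=True)
    if res.canceled:
        logger.warning("MCS timeout for %r: using best-found substructure", rxn_smiles)
    common = res.numAtoms
    if common <= 0:
        # a single shared element is still a 1-atom common substructure
        elems_r = {a.GetAtomicNum() for a in r.GetAtoms()}
        elems_p = {a.GetAtomicNum() for a in p.GetAtoms()}
        common = 1 if elems_r & elems_p else 0
    return common / larger


class McsOverlapBackend:
    """Built-in baseline backend; deterministic, dependency-free."""

    name = "mcs-overlap"

    def __init__(self, timeout: int = 10):
        self.timeout = timeout

    def __call__(self, rxn_smiles: str) -> tuple[float, str | None]:
        return mcs_overlap_confidence(rxn_smiles, timeout=self.timeout), None


class RxnMapperBackend:
    """Optional transformer backend wrapping the published RXNMapper model."""

    name = "rxnmapper"

    def __init__(self):
        try:
            from rxnmapper import RXNMapper  # type: ignore
        except ImportError as e:  # pragma: no cover - optional dependency
            raise ImportError(
                "the rxnmapper package is not installed; "
                "install alchemap[rxnmapper] or use McsOverlapBackend"
            ) from e
        self._mapper = RXNMapper()

    def __call__(self, rxn_smiles: str) -> tuple[float, str | None]:  # pragma: no cover
        out = self._mapper.get_attention_guided_atom_maps([rxn_smiles])[0]
        return float(out["confidence"]), out["mapped_rxn"]


def compute_amcd(record: ReactionRecord,
                 backend: ConfidenceBackend | Callable | None = None) -> AmcdRecord:
    """Score forward and backward reactions and average the distances.

    A backend failure on either direction yields a record flagged
    incomplete with amcd absent.
    """
    backend = backend or McsOverlapBackend()
    name = getattr(backend, "name", "custom")
    conf_fwd = conf_bwd = 0.0
    mapped_fwd = mapped_bwd = None
    incomplete = False
    try:
        conf_fwd, mapped_fwd = backend(record.forward_rxn)
        conf_bwd, mapped_bwd = backend(record.backward_rxn)
    except Exception as e:
        logger.error("backend %s failed on pair (%s, %s): %s",
                     name, record.id_a, record.id_b, e)
        incomplete = True
    for c in (conf_fwd, conf_bwd):
        if not 0.0 <= c <= 1.0:
            raise ValueError(f"backend {name} returned confidence {c} outside [0, 1]")
    return AmcdRecord(record.id_a, record.id_b, conf_fwd, conf_bwd,
                      backend=name, mapped_fwd=mapped_fwd, mapped_bwd=mapped_bwd,
                      incomplete=incomplete)


def classify_pair(record: AmcdRecord, cutoff: float = DEFAULT_CUTOFF) -> str:
    """"feasible" iff amcd < cutoff (strict), else "alchemical".

    The cutoff is a user parameter with no canonical value; it is logged
    with every call so classifications are traceable.
    """
    if record.amcd is None:
        raise ValueError("amcd absent (incomplete record); cannot classify")
    logger.info("classify (%s, %s): amcd=%.4f cutoff=%.4f",
                record.id_a, record.id_b, record.amcd, cutoff)
    return "feasible" if record.amcd < cutoff else "alchemical"
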