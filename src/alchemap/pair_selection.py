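"""Similar-pair selection under three simultaneous criteria.

For a set of n molecules and eight fingerprint distance matrices, a pair is
selected when (1) one molecule is the other's nearest neighbor under any
fingerprint, (2) one appears in the other's top-k neighbor lists for at
least `quorum` of the eight fingerprints (defaults k=20, quorum=7), or
(3) the pair's distance falls below a per-fingerprint maximum in any
fingerprint.  Provenance of every criterion hit is kept per pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .chem_io import MoleculeSet
from .fingerprints import FINGERPRINT_NAMES, DistanceMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "RankTable",
    "SelectedPair",
    "ThresholdProfile",
    "THRESHOLD_PROFILES",
    "rank_neighbors",
    "select_nn_pairs",
    "select_consensus_pairs",
    "select_threshold_pairs",
    "select_pairs",
    "count_possible_pairs",
    "pairs_to_frame",
]


@dataclass
class RankTable:
    """Per-molecule neighbor lists sorted by ascending distance, ties by id."""

    fingerprint: str
    ranking: dict[str, list[str]]  # query id -> n-1 neighbor ids


@dataclass
class SelectedPair:
    """One unordered selected pair with per-criterion provenance."""

    id_a: str
    id_b: str
    nn_of: set[str] = field(default_factory=set)          # fingerprints with an NN hit
    consensus_top20: bool = False
    threshold_hit: set[str] = field(default_factory=set)  # fingerprints under threshold
    distances: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.id_a == self.id_b:
            raise ValueError("a pair needs two distinct molecules")
        if self.id_a > self.id_b:
            self.id_a, self.id_b = self.id_b, self.id_a

    @property
    def key(self) -> tuple[str, str]:
        return (self.id_a, self.id_b)

    def merge(self, other: "SelectedPair") -> None:
        assert self.key == other.key
        self.nn_of |= other.nn_of
        self.consensus_top20 |= other.consensus_top20
        self.threshold_hit |= other.threshold_hit
        self.distances.update(other.distances)


@dataclass(frozen=True)
class ThresholdProfile:
    """Per-fingerprint maximum distance (strict <) for threshold selection."""

    name: str
    thresholds: tuple[tuple[str, float], ...]

    def __getitem__(self, fp: str) -> float:
        return dict(self.thresholds)[fp]

    def as_dict(self) -> dict[str, float]:
        return dict(self.thresholds)


# Per-set threshold presets: "fda" for a diverse set, "focused" for analog
# series; taxicab thresholds apply to min-max rescaled distances.
THRESHOLD_PROFILES = {
    "fda": ThresholdProfile("fda", (
        ("ECFP4", 0.6), ("ECFP6", 0.6), ("MHFP6", 0.6), ("AP", 0.5),
        ("MACCS", 0.2), ("MAP4", 0.8), ("MXFP", 0.1), ("MQN", 0.05),
    )),
    "focused": ThresholdProfile("focused", (
        ("ECFP4", 0.2), ("ECFP6", 0.2), ("MHFP6", 0.2), ("AP", 0.2),
        ("MACCS", 0.0125), ("MAP4", 0.3), ("MXFP", 0.1), ("MQN", 0.05),
    )),
}


def count_possible_pairs(n: int) -> int:
    """Number of unordered pairs among n molecules: n(n-1)/2."""
    if n < 0:
        raise ValueError("n must be non-negative")
    return n * (n - 1) // 2


def rank_neighbors(dm: DistanceMatrix) -> RankTable:
    """Each molecule's full neighbor list, ascending distance, ties by id."""
    if dm.n < 2:
        raise ValueError("need at least 2 molecules to rank")
    ranking: dict[str, list[str]] = {}
    for i, q in enumerate(dm.ids):
        others = [(float(dm.values[i, j]), dm.ids[j]) for j in range(dm.n) if j != i]
        others.sort()  # (distance, id) lexicographic = deterministic tiebreak
        ranking[q] = [mol_id for _, mol_id in others]
    return RankTable(dm.fingerprint, ranking)


def _get_or_add(pairs: dict[tuple[str, str], SelectedPair], a: str, b: str) -> SelectedPair:
    p = SelectedPair(a, b)
    return pairs.setdefault(p.key, p)


def select_nn_pairs(tables: dict[str, RankTable]) -> list[SelectedPair]:
    """For each molecule and each fingerprint, select (molecule, rank-1 NN)."""
    pairs: dict[tuple[str, str], SelectedPair] = {}
    for fp, table in tables.items():
        for q, ranked in table.ranking.items():
            p = _get_or_add(pairs, q, ranked[0])
            p.nn_of.add(fp)
    return sorted(pairs.values(), key=lambda p: p.key)


def select_consensus_pairs(
    tables: dict[str, RankTable], k: int = 20, quorum: int = 7
) -> list[SelectedPair]:
    """Pairs where a candidate sits in a query's top-k for >= quorum fingerprints.

    Membership is per directed query list; the pair is stored unordered.
    """
    n_fp = len(tables)
    if not 1 <= quorum <= n_fp:
        raise ValueError(f"quorum must be in 1..{n_fp}")
    queries = next(iter(tables.values())).ranking.keys()
    pairs: dict[tuple[str, str], SelectedPair] = {}
    for q in queries:
        counts: dict[str, int] = {}
        for table in tables.values():
            for c in table.ranking[q][:k]:
                counts[c] = counts.get(c, 0) + 1
        for c, cnt in counts.items():
            if cnt >= quorum:
                p = _get_or_add(pairs, q, c)
                p.consensus_top20 = True
    return sorted(pairs.values(), key=lambda p: p.key)


def select_threshold_pairs(
    dms: dict[str, DistanceMatrix], profile: ThresholdProfile
) -> list[SelectedPair]:
    """Pairs with distance strictly below the profile's per-fingerprint maximum."""
    pairs: dict[tuple[str, str], SelectedPair] = {}
    for fp, dm in dms.items():
        t = profile[fp]
        for i in range(dm.n):
            for j in range(i + 1, dm.n):
                if dm.values[i, j] < t:
                    p = _get_or_add(pairs, dm.ids[i], dm.ids[j])
                    p.threshold_hit.add(fp)
    return sorted(pairs.values(), key=lambda p: p.key)


def _attach_distances(pairs: list[SelectedPair], dms: dict[str, DistanceMatrix]) -> None:
    index = {mol_id: i for i, mol_id in enumerate(next(iter(dms.values())).ids)}
    for p in pairs:
        i, j = index[p.id_a], index[p.id_b]
        p.distances = {fp: float(dm.values[i, j]) for fp, dm in dms.items()}


def select_pairs(
    dms: dict[str, DistanceMatrix],
    profile: ThresholdProfile | str = "fda",
    k: int = 20,
    quorum: int = 7,
) -> list[SelectedPair]:
    """Union of the NN, top-k consensus and threshold criteria with provenance.

    Returns pairs sorted by (id_a, id_b); each carries its eight distances.
    """
    if isinstance(profile, str):
        profile = THRESHOLD_PROFILES[profile]
    tables = {fp: rank_neighbors(dm) for fp, dm in dms.items()}
    merged: dict[tuple[str, str], SelectedPair] = {}
    for selection in (
        select_nn_pairs(tables),
        select_consensus_pairs(tables, k=k, quorum=quorum),
        select_threshold_pairs(dms, profile),
    ):
        for p in selection:
            if p.key in merged:
                merged[p.key].merge(p)
            else:
                merged[p.key] = p
    pairs = sorted(merged.values(), key=lambda p: p.key)
    if not pairs:
        logger.warning("no pairs selected")
    _attach_distances(pairs, dms)
    return pairs


def participation_counts(pairs: list[SelectedPair]) -> dict[str, int]:
    """How many selected pairs each molecule takes part in."""
    counts: dict[str, int] = {}
    for p in pairs:
        counts[p.id_a] = counts.get(p.id_a, 0) + 1
        counts[p.id_b] = counts.get(p.id_b, 0) + 1
    return counts


def pairs_to_frame(pairs: list[SelectedPair]) -> pd.DataFrame:
    """Flat table: ids, eight distances, 17 provenance flags."""
    rows = []
    for p in pairs:
        row: dict[str, object] = {"id_a": p.id_a, "id_b": p.id_b}
        for fp in FINGERPRINT_NAMES:
            row[f"d_{fp}"] = p.distances.get(fp)
        for fp in FINGERPRINT_NAMES:
            row[f"nn_{fp}"] = fp in p.nn_of
        row["consensus_top20"] = p.consensus_top20
        for fp in FINGERPRINT_NAMES:
            row[f"thr_{fp}"] = fp in p.threshold_hit
        rows.append(row)
    return pd.DataFrame(rows)
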