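"""End-to-end convenience driver: molecules in, pair map + tables out."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .amcd import AmcdRecord, ConfidenceBackend, McsOverlapBackend, compute_amcd, DEFAULT_CUTOFF
from .chem_io import MoleculeSet
from .fingerprints import DistanceMatrix, all_distance_matrices
from .pair_selection import SelectedPair, participation_counts, select_pairs
from .reaction_encoding import ReactionRecord, drfp_matrix
from .report import pair_property_table, selection_stats
from .treemap_layout import TreeLayout, build_treemap

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    molset: MoleculeSet
    distance_matrices: dict[str, DistanceMatrix]
    pairs: list[SelectedPair]
    reactions: list[ReactionRecord]
    drfp_distances: np.ndarray
    layout: TreeLayout | None
    amcd_records: list[AmcdRecord]
    table: pd.DataFrame
    stats: dict


def run_pipeline(
    molset: MoleculeSet,
    profile: str = "fda",
    k: int = 20,
    quorum: int = 7,
    knn_k: int = 20,
    cutoff: float = DEFAULT_CUTOFF,
    backend: ConfidenceBackend | None = None,
    seed: int = 0,
) -> PipelineResult:
    """Run selection, reaction encoding, tree-map layout, amcd and reporting.

    ``profile`` picks the per-fingerprint threshold preset ("fda" for a
    diverse set, "focused" for analog series); ``k``/``quorum`` control the
    top-k consensus criterion; ``knn_k`` the pair-space k-NN graph;
    ``cutoff`` the feasible/alchemical boundary.
    """
    dms = all_distance_matrices(molset)
    pairs = select_pairs(dms, profile=profile, k=k, quorum=quorum)
    if not pairs:
        return PipelineResult(molset, dms, [], [], np.zeros((0, 0)), None, [],
                              pd.DataFrame(), selection_stats(0, len(molset)))
    reactions, drfp_dists = drfp_matrix(pairs, molset)
    layout = None
    if len(reactions) >= 2:
        layout = build_treemap(drfp_dists, [r.key for r in reactions],
                               k=knn_k, seed=seed)
    backend = backend or McsOverlapBackend()
    amcd_records = [compute_amcd(r, backend) for r in reactions]
    table = pair_property_table(pairs, molset, reactions, amcd_records,
                                layout, cutoff=cutoff)
    stats = selection_stats(len(pairs), len(molset), participation_counts(pairs))
    return PipelineResult(molset, dms, pairs, reactions, drfp_dists,
                          layout, amcd_records, table, stats)
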