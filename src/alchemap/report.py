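"""Summary artifacts: distributions, correlation heat-map data, pair tables.

All functions here are pure functions of persisted stage outputs, so
re-running a report without recomputation reproduces identical files.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .amcd import AmcdRecord, classify_pair, DEFAULT_CUTOFF
from .chem_io import MoleculeSet, compute_fsp3
from .fingerprints import FINGERPRINT_NAMES
from .pair_selection import SelectedPair, count_possible_pairs
from .reaction_encoding import ReactionRecord
from .treemap_layout import TreeLayout

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationMatrix",
    "distance_distributions",
    "correlation_matrix",
    "selection_stats",
    "pair_property_table",
]


@dataclass
class CorrelationMatrix:
    """Symmetric r-squared matrix over fingerprint distances (+ amcd)."""

    labels: list[str]
    values: np.ndarray  # r^2, diagonal 1, NaN where a column has no variance

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def distance_distributions(
    all_pairs: pd.DataFrame, selected_pairs: pd.DataFrame
) -> pd.DataFrame:
    """Per-fingerprint quantile summaries of all-pairs vs selected-pairs distances.

    Returns one row per (fingerprint, population) with quantiles and an
    enrichment column: whether the selected median is <= the all-pairs
    median (selection should enrich high-similarity, i.e. low-distance,
    pairs).
    """
    qs = [0.0, 0.25, 0.5, 0.75, 1.0]
    rows = []
    cols = [c for c in all_pairs.columns if c.startswith("d_") or c == "amcd"]
    for col in cols:
        for pop, df in (("all", all_pairs), ("selected", selected_pairs)):
            if col not in df.columns or df[col].dropna().empty:
                continue
            series = df[col].dropna()
            row = {"fingerprint": col, "population": pop, "n": len(series)}
            for q in qs:
                row[f"q{int(q * 100)}"] = float(series.quantile(q))
            rows.append(row)
    out = pd.DataFrame(rows)
    enrich = {}
    for col in cols:
        sub = out[out.fingerprint == col]
        med = dict(zip(sub.population, sub.q50))
        if "all" in med and "selected" in med:
            enrich[col] = med["selected"] <= med["all"]
    out["selected_enriched_similar"] = out.fingerprint.map(enrich)
    return out


def correlation_matrix(pair_table: pd.DataFrame,
                       columns: list[str] | None = None,
                       method: str = "pearson") -> CorrelationMatrix:
    """Squared correlation (r^2) between distance columns across selected pairs.

    Zero-variance columns give NaN entries with a warning.  Spearman is
    available as an alternative flavor.
    """
    if columns is None:
        columns = [f"d_{fp}" for fp in FINGERPRINT_NAMES if f"d_{fp}" in pair_table]
        if "amcd" in pair_table.columns:
            columns = columns + ["amcd"]
    sub = pair_table[columns].astype(float)
    if len(sub) < 3:
        raise ValueError("need at least 3 selected pairs for correlations")
    for col in columns:
        if sub[col].nunique() <= 1:
            warnings.warn(f"column {col} has zero variance; correlations undefined")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        r = sub.corr(method=method)
    values = (r ** 2).to_numpy()
    np.fill_diagonal(values, np.where(sub.nunique() > 1, 1.0, np.nan))
    return CorrelationMatrix(labels=columns, values=values)


def selection_stats(n_selected: int, n_molecules: int,
                    participation: dict[str, int] | None = None) -> dict:
    """Counts, possible pairs and the selected percentage (2 decimals, half-even)."""
    possible = count_possible_pairs(n_molecules)
    pct = 0.0 if possible == 0 else round(100.0 * n_selected / possible, 2)
    stats = {
        "n_molecules": n_molecules,
        "n_selected": n_selected,
        "n_possible": possible,
        "percent_selected": pct,
    }
    if participation:
        counts = list(participation.values())
        stats["participation_min"] = min(counts)
        stats["participation_max"] = max(counts)
    return stats


def pair_property_table(
    pairs: list[SelectedPair],
    mols: MoleculeSet,
    reactions: list[ReactionRecord] | None = None,
    amcd_records: list[AmcdRecord] | None = None,
    layout: TreeLayout | None = None,
    cutoff: float = DEFAULT_CUTOFF,
) -> pd.DataFrame:
    """One row per selected pair joining every computed property.

    Missing upstream stages simply leave their columns out; a stage passed
    with unresolvable keys raises naming the stage.
    """
    from .pair_selection import pairs_to_frame

    table = pairs_to_frame(pairs)
    by_id = {r.id: r for r in mols}
    missing = [i for p in pairs for i in (p.id_a, p.id_b) if i not in by_id]
    if missing:
        raise KeyError(f"molecule stage: unknown ids {sorted(set(missing))}")

    table["mean_fsp3"] = [
        (compute_fsp3(by_id[p.id_a]) + compute_fsp3(by_id[p.id_b])) / 2 for p in pairs
    ]
    acts = {p.key: (by_id[p.id_a].activity, by_id[p.id_b].activity) for p in pairs}
    table["activity_diff"] = [
        abs(a - b) if a is not None and b is not None else np.nan
        for a, b in (acts[p.key] for p in pairs)
    ]

    if reactions is not None:
        rx = {r.key: r for r in reactions}
        try:
            table["forward_rxn"] = [rx[p.key].forward_rxn for p in pairs]
            table["drfp_popcount"] = [int(rx[p.key].drfp.sum()) for p in pairs]
        except KeyError as e:
            raise KeyError(f"reaction stage: missing pair {e.args[0]!r}") from None
    if amcd_records is not None:
        am = {(r.id_a, r.id_b): r for r in amcd_records}
        try:
            recs = [am[p.key] for p in pairs]
        except KeyError as e:
            raise KeyError(f"amcd stage: missing pair {e.args[0]!r}") from None
        table["conf_fwd"] = [r.conf_fwd for r in recs]
        table["conf_bwd"] = [r.conf_bwd for r in recs]
        table["amcd"] = [r.amcd for r in recs]
        table["class"] = [
            classify_pair(r, cutoff) if r.amcd is not None else "unscored" for r in recs
        ]
    if layout is not None:
        try:
            coords = [layout.coords[p.key] for p in pairs]
        except KeyError as e:
            raise KeyError(f"layout stage: missing pair {e.args[0]!r}") from None
        table["x"] = [c[0] for c in coords]
        table["y"] = [c[1] for c in coords]
        table["component"] = [layout.components[p.key] for p in pairs]
    return table.sort_values(["id_a", "id_b"]).reset_index(drop=True)
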