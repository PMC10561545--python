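"""Ranking, the three selection criteria and their brute-force oracles."""

import numpy as np
import pytest

from alchemap.fingerprints import FINGERPRINT_NAMES, DistanceMatrix
from alchemap.pair_selection import (
    THRESHOLD_PROFILES,
    ThresholdProfile,
    count_possible_pairs,
    pairs_to_frame,
    participation_counts,
    rank_neighbors,
    select_consensus_pairs,
    select_nn_pairs,
    select_pairs,
    select_threshold_pairs,
)


def _dm(values, ids, fingerprint="ECFP4"):
    return DistanceMatrix(fingerprint, ids, np.asarray(values, dtype=float), "jaccard")


def _uniform_dms(values, ids):
    """The same matrix under all eight fingerprint names."""
    return {fp: _dm(values, ids, fp) for fp in FINGERPRINT_NAMES}


class TestRankNeighbors:
    def test_ascending_sort(self):
        dm = _dm([[0, 0.2, 0.1], [0.2, 0, 0.3], [0.1, 0.3, 0]], ["q", "b", "c"])
        assert rank_neighbors(dm).ranking["q"] == ["c", "b"]

    def test_tie_broken_by_id(self):
        dm = _dm([[0, 0.3, 0.3], [0.3, 0, 0.1], [0.3, 0.1, 0]], ["q", "b", "c"])
        assert rank_neighbors(dm).ranking["q"] == ["b", "c"]

    def test_matches_sort_oracle(self, family_dms):
        dm = family_dms["ECFP4"]
        table = rank_neighbors(dm)
        for i, q in enumerate(dm.ids):
            expected = sorted(
                (j for j in range(dm.n) if j != i),
                key=lambda j: (dm.values[i, j], dm.ids[j]),
            )
            assert table.ranking[q] == [dm.ids[j] for j in expected]


class TestNnPairs:
    def test_two_molecules_single_pair_all_flags(self):
        dms = _uniform_dms([[0, 0.4], [0.4, 0]], ["a", "b"])
        tables = {fp: rank_neighbors(dm) for fp, dm in dms.items()}
        pairs = select_nn_pairs(tables)
        assert len(pairs) == 1
        assert pairs[0].nn_of == set(FINGERPRINT_NAMES)

    def test_nn_not_symmetric(self):
        # a's NN is b; b's NN is c; c's NN is b
        values = [[0, 0.1, 0.5], [0.1, 0, 0.05], [0.5, 0.05, 0]]
        tables = {"ECFP4": rank_neighbors(_dm(values, ["a", "b", "c"]))}
        keys = {p.key for p in select_nn_pairs(tables)}
        assert keys == {("a", "b"), ("b", "c")}

    def test_argmin_oracle(self, family_dms):
        tables = {fp: rank_neighbors(dm) for fp, dm in family_dms.items()}
        got = {p.key: p.nn_of for p in select_nn_pairs(tables)}
        expected: dict = {}
        for fp, dm in family_dms.items():
            for i, q in enumerate(dm.ids):
                j = min((j for j in range(dm.n) if j != i),
                        key=lambda j: (dm.values[i, j], dm.ids[j]))
                key = tuple(sorted((q, dm.ids[j])))
                expected.setdefault(key, set()).add(fp)
        assert got == expected


class TestConsensusPairs:
    def _tables_with_candidate_in_n_lists(self, n_lists):
        # 4 molecules; candidate "c" placed in q's top-1 for n_lists fingerprints
        ids = ["q", "b", "c", "d"]
        tables = {}
        for idx, fp in enumerate(FINGERPRINT_NAMES):
            near, far = (0.1, 0.2) if idx < n_lists else (0.2, 0.1)
            values = np.full((4, 4), 0.9)
            np.fill_diagonal(values, 0)
            values[0, 2] = values[2, 0] = near
            values[0, 1] = values[1, 0] = far
            # keep d as c's own nearest neighbor so only q's directed
            # lists decide whether (q, c) reaches the quorum
            values[2, 3] = values[3, 2] = 0.05
            tables[fp] = rank_neighbors(_dm(values, ids, fp))
        return tables

    def test_candidate_in_all_lists_selected(self):
        pairs = select_consensus_pairs(self._tables_with_candidate_in_n_lists(8), k=1)
        assert ("c", "q") in {p.key for p in pairs}

    def test_below_quorum_not_selected(self):
        pairs = select_consensus_pairs(
            self._tables_with_candidate_in_n_lists(6), k=1, quorum=7
        )
        assert ("c", "q") not in {p.key for p in pairs}

    def test_membership_count_oracle(self, family_dms):
        k, quorum = 3, 7
        tables = {fp: rank_neighbors(dm) for fp, dm in family_dms.items()}
        got = {p.key for p in select_consensus_pairs(tables, k=k, quorum=quorum)}
        expected = set()
        ids = next(iter(family_dms.values())).ids
        for q in ids:
            for c in ids:
                if c == q:
                    continue
                hits = sum(c in t.ranking[q][:k] for t in tables.values())
                if hits >= quorum:
                    expected.add(tuple(sorted((q, c))))
        assert got == expected

    def test_planted_near_duplicate_selected(self, family_set, family_dms):
        # one-substituent analogs on the same scaffold should reach consensus
        tables = {fp: rank_neighbors(dm) for fp, dm in family_dms.items()}
        pairs = {p.key for p in select_consensus_pairs(tables, k=5, quorum=7)}
        fam0 = [i for i in family_set.ids if i.startswith("fam0")]
        assert any(tuple(sorted((a, b))) in pairs
                   for a in fam0 for b in fam0 if a < b)

    def test_invalid_quorum_raises(self, family_dms):
        tables = {fp: rank_neighbors(dm) for fp, dm in family_dms.items()}
        with pytest.raises(ValueError):
            select_consensus_pairs(tables, quorum=9)


class TestThresholdPairs:
    def test_strict_inequality_at_boundary(self):
        values = [[0, 0.6], [0.6, 0]]
        dms = {"ECFP4": _dm(values, ["a", "b"])}
        profile = THRESHOLD_PROFILES["fda"]
        assert select_threshold_pairs(dms, profile) == []

    def test_zero_distance_pair_selected(self):
        dms = {"MACCS": _dm([[0, 0.0], [0.0, 0]], ["a", "b"], "MACCS")}
        pairs = select_threshold_pairs(dms, THRESHOLD_PROFILES["fda"])
        assert pairs[0].threshold_hit == {"MACCS"}

    def test_double_loop_oracle(self, family_dms):
        profile = THRESHOLD_PROFILES["focused"]
        got = {p.key: p.threshold_hit for p in select_threshold_pairs(family_dms, profile)}
        expected: dict = {}
        for fp, dm in family_dms.items():
            for i in range(dm.n):
                for j in range(i + 1, dm.n):
                    if dm.values[i, j] < profile[fp]:
                        key = tuple(sorted((dm.ids[i], dm.ids[j])))
                        expected.setdefault(key, set()).add(fp)
        assert got == expected

    def test_monotone_in_thresholds(self, family_dms):
        lo = THRESHOLD_PROFILES["focused"]
        hi = ThresholdProfile("hi", tuple((fp, min(1.0, t * 2)) for fp, t in lo.thresholds))
        selected_lo = {p.key for p in select_threshold_pairs(family_dms, lo)}
        selected_hi = {p.key for p in select_threshold_pairs(family_dms, hi)}
        assert selected_lo <= selected_hi


class TestSelectPairs:
    def test_two_molecule_full_provenance(self):
        dms = _uniform_dms([[0, 0.01], [0.01, 0]], ["a", "b"])
        pairs = select_pairs(dms, profile="fda", k=1, quorum=8)
        assert len(pairs) == 1
        p = pairs[0]
        assert p.nn_of == set(FINGERPRINT_NAMES)
        assert p.consensus_top20
        assert len(p.threshold_hit) > 0
        assert set(p.distances) == set(FINGERPRINT_NAMES)

    def test_disjoint_criteria_both_present(self):
        # (a,b) close only under ECFP4 threshold; NN pairs exist regardless
        ids = ["a", "b", "c", "d"]
        base = np.full((4, 4), 0.9)
        np.fill_diagonal(base, 0)
        dms = {fp: _dm(base.copy(), ids, fp) for fp in FINGERPRINT_NAMES}
        dms["ECFP4"].values[0, 1] = dms["ECFP4"].values[1, 0] = 0.1
        pairs = select_pairs(dms, profile="fda", k=1, quorum=8)
        by_key = {p.key: p for p in pairs}
        assert "ECFP4" in by_key[("a", "b")].threshold_hit
        assert any(p.nn_of and not p.threshold_hit for p in pairs)

    def test_rerun_byte_identical(self, family_dms):
        t1 = pairs_to_frame(select_pairs(family_dms, profile="focused")).to_csv()
        t2 = pairs_to_frame(select_pairs(family_dms, profile="focused")).to_csv()
        assert t1 == t2

    def test_bounds_and_membership(self, family_set, family_dms):
        pairs = select_pairs(family_dms, profile="focused")
        assert len(pairs) <= count_possible_pairs(len(family_set))
        ids = set(family_set.ids)
        assert all(p.id_a in ids and p.id_b in ids for p in pairs)
        counts = participation_counts(pairs)
        assert all(c >= 1 for c in counts.values())

    def test_nn_is_special_case_of_consensus(self, family_dms):
        tables = {fp: rank_neighbors(dm) for fp, dm in family_dms.items()}
        nn_keys = {p.key for p in select_nn_pairs(tables)}
        consensus_keys = {p.key for p in select_consensus_pairs(tables, k=1, quorum=1)}
        assert nn_keys == consensus_keys


class TestCountPossiblePairs:
    @pytest.mark.parametrize("n,expected", [
        (1213, 735078), (1500, 1124250), (274, 37401), (1, 0), (0, 0), (2, 1),
    ])
    def test_values(self, n, expected):
        assert count_possible_pairs(n) == expected

    def test_negative_raises(self):
        with pytest.raises(ValueError):
            count_possible_pairs(-1)
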