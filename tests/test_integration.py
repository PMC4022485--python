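import numpy as np
import pytest

from allomap.coevolution import CoevolutionResult
from allomap.integration import (
    ConsensusPair,
    ConsensusPairTable,
    annotate_contacts,
    classify_pair,
    consensus_pairs,
    count_interdomain_pairs,
    cumulative_propensity,
    interdomain_submatrix,
    top_pairs,
)
from allomap.structure import Residue, StructureModel

from conftest import toy_model


def result_from(matrix, residue_ids, method="MIp"):
    """Score matrix whose columns map 1:1 onto the given residue ids."""
    return CoevolutionResult(method, np.asarray(matrix, float), np.asarray(residue_ids))


def random_result(L, residue_ids, seed, method="MIp"):
    rng = np.random.default_rng(seed)
    s = rng.random((L, L))
    return result_from((s + s.T) / 2, residue_ids, method)


class TestPairSpace:
    def test_dnak_default_pair_count(self):
        assert count_interdomain_pairs() == 82_256

    def test_toy_split(self):
        assert count_interdomain_pairs((1, 3), (4, 5)) == 6


class TestSubmatrix:
    def test_entries_match_full_matrix(self):
        res = random_result(5, [1, 2, 3, 4, 5], seed=0)
        sub = interdomain_submatrix(res, (1, 3), (4, 5))
        assert sub.matrix.shape == (3, 2)
        for ai, ra in enumerate(sub.row_ids):
            for bi, rb in enumerate(sub.col_ids):
                assert sub.matrix[ai, bi] == res.scores[ra - 1, rb - 1]

    def test_unmapped_residues_are_nan(self):
        res = random_result(3, [1, 2, 5], seed=1)
        sub = interdomain_submatrix(res, (1, 2), (4, 6))
        assert np.isnan(sub.matrix[:, 0]).all()  # residue 4 not mapped
        assert np.isfinite(sub.matrix[:, 1]).all()  # residue 5 mapped

    def test_empty_group_rejected(self):
        res = random_result(3, [1, 2, 3], seed=2)
        with pytest.raises(ValueError):
            interdomain_submatrix(res, [], (1, 3))

    def test_no_mapped_columns_rejected(self):
        res = random_result(3, [100, 101, 102], seed=3)
        with pytest.raises(ValueError, match="no mapped"):
            interdomain_submatrix(res, (1, 5), (6, 10))


class TestTopPairs:
    def test_dnak_fraction_gives_fifty(self):
        res = random_result(100, list(range(1, 101)), seed=4)
        sub = interdomain_submatrix(res, (1, 50), (51, 100))
        sub_full = sub
        # ceil(0.0006 * 82256) on the DnaK-sized space
        import math

        assert math.ceil(0.0006 * 82_256) == 50
        # on this 2500-pair toy space: ceil(1.5) = 2
        assert len(top_pairs(sub_full, fraction=0.0006)) == 2

    def test_toy_two_largest(self):
        res = result_from(
            [
                [np.nan, 0, 0, 9, 1],
                [0, np.nan, 0, 2, 8],
                [0, 0, np.nan, 3, 4],
                [9, 2, 3, np.nan, 0],
                [1, 8, 4, 0, np.nan],
            ],
            [1, 2, 3, 4, 5],
        )
        sub = interdomain_submatrix(res, (1, 3), (4, 5))
        top = top_pairs(sub, k_override=2)
        assert top == [(1, 4, 9.0), (2, 5, 8.0)]

    def test_all_equal_scores_flagged_degenerate(self):
        res = result_from(np.ones((4, 4)), [1, 2, 3, 4])
        sub = interdomain_submatrix(res, (1, 2), (3, 4))
        with pytest.warns(UserWarning, match="degenerate"):
            top = top_pairs(sub, k_override=2)
        assert top[0][:2] == (1, 3)  # tie broken by residue ids

    def test_k_clamped_with_warning(self):
        res = random_result(4, [1, 2, 3, 4], seed=5)
        sub = interdomain_submatrix(res, (1, 2), (3, 4))
        with pytest.warns(UserWarning, match="clamp"):
            top = top_pairs(sub, k_override=10, exclude_adjacent=False)
        assert len(top) == 4

    def test_adjacent_pairs_excluded(self):
        res = random_result(4, [1, 2, 3, 4], seed=6)
        sub = interdomain_submatrix(res, (1, 2), (3, 4))
        top = top_pairs(sub, k_override=4)
        assert (2, 3) not in {(a, b) for a, b, _ in top}


class TestConsensus:
    def test_identical_matrices_consensus_is_common_topk(self):
        r1 = random_result(10, list(range(1, 11)), seed=7, method="MIp")
        r2 = result_from(r1.scores, r1.column_map, method="DI")
        tab = consensus_pairs([r1, r2], (1, 5), (6, 10), k_override=3)
        tops = top_pairs(interdomain_submatrix(r1, (1, 5), (6, 10)), k_override=3)
        assert tab.pair_set() == {(a, b) for a, b, _ in tops}
        assert all(p.n_support == 2 for p in tab.pairs)

    def test_disjoint_top_lists_empty_consensus(self):
        base = np.zeros((6, 6))
        m1, m2 = base.copy(), base.copy()
        m1[0, 3] = m1[3, 0] = 5.0
        m2[1, 4] = m2[4, 1] = 5.0
        r1 = result_from(m1, [1, 2, 3, 4, 5, 6], "MIp")
        r2 = result_from(m2, [1, 2, 3, 4, 5, 6], "DI")
        tab = consensus_pairs([r1, r2], (1, 3), (4, 6), k_override=1)
        assert len(tab) == 0

    def test_fewer_than_two_methods_rejected(self):
        r1 = random_result(6, list(range(1, 7)), seed=8)
        with pytest.raises(ValueError, match="2 methods"):
            consensus_pairs([r1], (1, 3), (4, 6))

    def test_monotone_shrinkage_in_min_methods(self):
        ids = list(range(1, 13))
        results = [
            random_result(12, ids, seed=s, method=m)
            for s, m in enumerate(["MIp", "OMES", "DI"])
        ]
        tables = {
            k: consensus_pairs(results, (1, 6), (7, 12), k_override=8, min_methods=k)
            for k in (1, 2, 3)
        }
        assert tables[1].pair_set() >= tables[2].pair_set() >= tables[3].pair_set()

    def test_invariant_to_result_order(self):
        ids = list(range(1, 13))
        results = [
            random_result(12, ids, seed=s, method=m)
            for s, m in enumerate(["MIp", "OMES", "DI"])
        ]
        t1 = consensus_pairs(results, (1, 6), (7, 12), k_override=8)
        t2 = consensus_pairs(results[::-1], (1, 6), (7, 12), k_override=8)
        assert [(p.residue_a, p.residue_b) for p in t1.pairs] == [
            (p.residue_a, p.residue_b) for p in t2.pairs
        ]


class TestPropensity:
    def test_two_by_two_hand_values(self):
        res = result_from(
            [
                [np.nan, 0, 1, 2],
                [0, np.nan, 3, 4],
                [1, 3, np.nan, 0],
                [2, 4, 0, np.nan],
            ],
            [1, 2, 3, 4],
        )
        sub = interdomain_submatrix(res, (1, 2), (3, 4))
        np.testing.assert_allclose(cumulative_propensity(sub, "rows").values, [3, 7])
        np.testing.assert_allclose(cumulative_propensity(sub, "cols").values, [4, 6])

    def test_zero_matrix_zero_profile(self):
        res = result_from(np.zeros((4, 4)), [1, 2, 3, 4])
        sub = interdomain_submatrix(res, (1, 2), (3, 4))
        np.testing.assert_allclose(cumulative_propensity(sub, "rows").values, 0)

    def test_matches_brute_force_over_full_matrix(self):
        res = random_result(12, list(range(1, 13)), seed=10)
        sub = interdomain_submatrix(res, (1, 6), (7, 12))
        prof = cumulative_propensity(sub, "rows")
        for ai, ra in enumerate(prof.residue_ids):
            expected = sum(res.scores[ra - 1, rb - 1] for rb in range(7, 13))
            assert prof.values[ai] == pytest.approx(expected)


class TestClassifyPair:
    @pytest.fixture
    def structure_with_heavy_atoms(self):
        def res(rid, ca, heavy):
            return Residue(rid, "A", "A", ca, tuple(map(tuple, heavy)))

        return StructureModel(
            [
                res(1, (0, 0, 0), [(0, 0, 0), (1.5, 0, 0)]),
                res(2, (6, 0, 0), [(6, 0, 0), (4.0, 0, 0)]),  # heavy-min 2.5
                res(3, (40, 0, 0), [(40, 0, 0)]),
                res(4, (10, 0, 0), [(10, 0, 0)]),
            ]
        )

    def test_contact(self, structure_with_heavy_atoms):
        cls, dist = classify_pair(structure_with_heavy_atoms, (1, 2))
        assert cls == "contact"
        assert dist == pytest.approx(6.0)

    def test_distant(self, structure_with_heavy_atoms):
        cls, _ = classify_pair(structure_with_heavy_atoms, (1, 3))
        assert cls == "distant"

    def test_neighboring_no_contact(self, structure_with_heavy_atoms):
        cls, _ = classify_pair(structure_with_heavy_atoms, (1, 4))
        assert cls == "neighboring_no_contact"

    def test_unresolved(self, structure_with_heavy_atoms):
        cls, dist = classify_pair(structure_with_heavy_atoms, (1, 99))
        assert cls == "unresolved"
        assert np.isnan(dist)

    def test_annotate_contacts_fills_classes(self, structure_with_heavy_atoms):
        table = ConsensusPairTable(
            [ConsensusPair(1, 2, frozenset({"MIp", "DI"}), {"MIp": 1, "DI": 2})],
            min_methods=2,
            k_per_method=5,
            methods=["DI", "MIp"],
        )
        out = annotate_contacts(table, structure_with_heavy_atoms)
        assert out.pairs[0].contact_class == "contact"
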