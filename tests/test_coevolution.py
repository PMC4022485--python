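import numpy as np
import pytest

from allomap.coevolution import (
    BACKGROUND_FREQS,
    CoevolutionResult,
    apc_correct,
    direct_information,
    mip,
    mutual_information,
    omes,
    psicov_score,
    sca,
)
from allomap.msa import AlignmentSet, GAP_STATE, encode, frequencies, shannon_entropy
from allomap.synthetic import make_coupled_msa, null_msa


def aln(*rows):
    return AlignmentSet([f"s{i}" for i in range(len(rows))], np.array([encode(r) for r in rows]))


def brute_force_pair_stats(msa, i, j):
    """Direct enumeration oracle: gap-excluded joint table of columns i, j."""
    joint = np.zeros((20, 20))
    for s in range(msa.n_sequences):
        a, b = msa.matrix[s, i], msa.matrix[s, j]
        if a != GAP_STATE and b != GAP_STATE:
            joint[a, b] += 1
    n_valid = joint.sum()
    p = joint / n_valid
    pa, pb = p.sum(axis=1), p.sum(axis=0)
    mi = 0.0
    om = 0.0
    for a in range(20):
        for b in range(20):
            exp = pa[a] * pb[b]
            if p[a, b] > 0:
                mi += p[a, b] * np.log(p[a, b] / exp)
            om += (joint[a, b] - n_valid * exp) ** 2 / n_valid
    return mi, om


@pytest.fixture(scope="module")
def random_fixture():
    rng = np.random.default_rng(42)
    letters = "ACDEFGHIKL-"
    rows = ["".join(rng.choice(list(letters), 10)) for _ in range(6)]
    return aln(*rows)


class TestMutualInformation:
    def test_perfect_two_state_coupling_ln2(self):
        m = aln("AD", "AD", "CE", "CE")
        assert mutual_information(frequencies(m)).scores[0, 1] == pytest.approx(np.log(2))

    def test_exact_independence_zero(self):
        m = aln("AD", "AE", "CD", "CE")
        assert mutual_information(frequencies(m)).scores[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_bounded_by_column_entropies(self, random_fixture):
        # the information bound holds against entropies taken on the same
        # jointly non-gap sequence subset the MI is computed from
        mi = mutual_information(frequencies(random_fixture)).scores
        for i in range(10):
            for j in range(i + 1, 10):
                if not np.isfinite(mi[i, j]):
                    continue
                joint = np.zeros((20, 20))
                for s in range(random_fixture.n_sequences):
                    a, b = random_fixture.matrix[s, i], random_fixture.matrix[s, j]
                    if a != GAP_STATE and b != GAP_STATE:
                        joint[a, b] += 1
                p = joint / joint.sum()
                pa, pb = p.sum(axis=1), p.sum(axis=0)
                h_i = -np.sum(pa[pa > 0] * np.log(pa[pa > 0]))
                h_j = -np.sum(pb[pb > 0] * np.log(pb[pb > 0]))
                assert mi[i, j] <= min(h_i, h_j) + 1e-10

    def test_matches_brute_force_enumeration(self, random_fixture):
        mi = mutual_information(frequencies(random_fixture)).scores
        for i in range(10):
            for j in range(i + 1, 10):
                ref, _ = brute_force_pair_stats(random_fixture, i, j)
                assert mi[i, j] == pytest.approx(ref, abs=1e-10)


class TestApc:
    def test_two_columns_degenerate_to_zero(self):
        res = CoevolutionResult("MI", np.array([[np.nan, 1.0], [1.0, np.nan]]), np.array([1, 2]))
        with pytest.warns(UserWarning, match="degenerate"):
            out = apc_correct(res)
        np.testing.assert_array_equal(np.nan_to_num(out.scores), 0.0)

    def test_constant_matrix_corrected_to_zero(self):
        s = np.full((5, 5), 2.0)
        out = apc_correct(CoevolutionResult("MI", s, np.arange(5)))
        off = ~np.eye(5, dtype=bool)
        np.testing.assert_allclose(out.scores[off], 0.0, atol=1e-12)

    def test_three_by_three_hand_arithmetic(self):
        # S = [[., 2, 1], [2, ., 1], [1, 1, .]]
        # row means (1.5, 1.5, 1), grand mean 4/3
        # S'(1,2) = 2 - 1.5*1.5/(4/3) = 2 - 27/16 = 5/16
        # S'(1,3) = 1 - 1.5*1.0/(4/3) = 1 - 9/8  = -1/8
        s = np.array([[np.nan, 2, 1], [2, np.nan, 1], [1, 1, np.nan]])
        out = apc_correct(CoevolutionResult("MI", s, np.arange(3)))
        assert out.scores[0, 1] == pytest.approx(5 / 16)
        assert out.scores[0, 2] == pytest.approx(-1 / 8)
        assert out.scores[1, 2] == pytest.approx(-1 / 8)

    def test_mip_cross_checked_against_direct_formula(self, random_fixture):
        raw = mutual_information(frequencies(random_fixture)).scores
        corrected = mip(random_fixture).scores
        row = np.nanmean(raw, axis=1)
        grand = np.nanmean(raw)
        for i in range(10):
            for j in range(i + 1, 10):
                expected = raw[i, j] - row[i] * row[j] / grand
                assert corrected[i, j] == pytest.approx(expected, abs=1e-10)


class TestOmes:
    def test_independent_columns_zero(self):
        assert omes(aln("AD", "AE", "CD", "CE")).scores[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_coupled_two_state_hand_value(self):
        # 2x2 table: obs (2,0;0,2), exp all 1 -> sum (1+1+1+1)/4 = 1
        assert omes(aln("AD", "AD", "CE", "CE")).scores[0, 1] == pytest.approx(1.0)

    def test_gap_reduces_valid_count_hand_value(self):
        # valid rows: (A,D),(A,D),(C,E); n=3
        # obs AD=2 exp 4/3; CE=1 exp 1/3; AE exp 2/3; CD exp 2/3
        m = aln("AD", "AD", "CE", "-E")
        expected = ((2 - 4 / 3) ** 2 + (1 - 1 / 3) ** 2 + 2 * (2 / 3) ** 2) / 3
        assert m.matrix[3, 0] == GAP_STATE
        assert omes(m).scores[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_matches_brute_force_enumeration(self, random_fixture):
        scores = omes(random_fixture).scores
        for i in range(10):
            for j in range(i + 1, 10):
                _, ref = brute_force_pair_stats(random_fixture, i, j)
                assert scores[i, j] == pytest.approx(ref, abs=1e-10)


class TestSca:
    def test_fully_conserved_pair_zero(self):
        assert sca(aln("AD", "AD", "AD", "AD")).scores[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_duplicated_column_maximal_in_row(self):
        m = aln("ADA", "ADA", "CEC", "CEC", "ADA", "CEC")
        s = sca(m).scores
        assert s[0, 2] == np.nanmax(s[0])

    def test_matches_direct_enumeration(self):
        rng = np.random.default_rng(3)
        rows = ["".join(rng.choice(list("ACDEFG"), 5)) for _ in range(8)]
        m = aln(*rows)
        s = sca(m).scores
        # independent re-evaluation with explicit loops
        n, L = m.n_sequences, m.n_columns
        lam = 0.03
        q = BACKGROUND_FREQS
        raw = np.zeros((L, 20))
        for i in range(L):
            for a in range(20):
                raw[i, a] = np.mean(m.matrix[:, i] == a)
        f1 = (1 - lam) * raw + lam * q  # regularised, for the weights only
        phi = np.abs(np.log(f1 * (1 - q) / ((1 - f1) * q)))
        for i in range(L):
            for j in range(i + 1, L):
                acc = 0.0
                for a in range(20):
                    for b in range(20):
                        fij = np.mean((m.matrix[:, i] == a) & (m.matrix[:, j] == b))
                        cov = fij - raw[i, a] * raw[j, b]
                        acc += (phi[i, a] * phi[j, b] * cov) ** 2
                assert s[i, j] == pytest.approx(np.sqrt(acc), abs=1e-10)


class TestDirectInformation:
    def test_symmetric_and_non_negative(self):
        msa = null_msa(L=8, N=200, seed=0)
        di = direct_information(msa).scores
        off = ~np.eye(8, dtype=bool)
        np.testing.assert_allclose(di[off], di.T[off], atol=1e-10)
        assert (di[off] >= 0).all()

    def test_planted_pair_is_largest(self):
        truth = make_coupled_msa(L=12, N=1500, planted=[((2, 9), 0.9)], seed=4)
        di = direct_information(truth.msa).scores
        assert np.unravel_index(np.nanargmax(di), di.shape) in {(2, 9), (9, 2)}

    def test_null_couplings_small_relative_to_planted(self):
        # finite-sample null DI is O(1/N), far below a planted coupling
        null = direct_information(null_msa(L=10, N=500, seed=1)).scores
        truth = make_coupled_msa(L=10, N=500, planted=[((1, 7), 0.9)], seed=1)
        planted = direct_information(truth.msa).scores[1, 7]
        assert np.nanmax(null) < 0.25 * planted

    def test_insufficient_pseudocount_errors(self):
        msa = null_msa(L=6, N=30, seed=2)
        with pytest.raises(np.linalg.LinAlgError, match="pseudocount"):
            direct_information(msa, pseudocount_frac=0.0)


class TestPsicov:
    def test_strong_penalty_kills_off_diagonal(self):
        msa = null_msa(L=10, N=400, seed=3)
        res = psicov_score(msa, lasso_rho=0.5, apply_apc=False)
        assert np.nanmax(res.scores) < 1e-6

    def test_planted_pair_top_ranked(self):
        truth = make_coupled_msa(L=20, N=1000, planted=[((3, 15), 0.9)], seed=5)
        res = psicov_score(truth.msa)
        assert np.unravel_index(np.nanargmax(res.scores), res.scores.shape) in {(3, 15), (15, 3)}

    def test_symmetry(self):
        res = psicov_score(null_msa(L=8, N=300, seed=6))
        off = ~np.eye(8, dtype=bool)
        np.testing.assert_allclose(res.scores[off], res.scores.T[off], atol=1e-10)


class TestSharedInvariances:
    @pytest.mark.parametrize("method", [mip, omes, sca, direct_information])
    def test_invariant_under_sequence_reordering(self, method):
        rng = np.random.default_rng(9)
        rows = ["".join(rng.choice(list("ACDEFGHIK"), 6)) for _ in range(12)]
        m1 = aln(*rows)
        perm = rng.permutation(12)
        m2 = aln(*[rows[i] for i in perm])
        np.testing.assert_allclose(
            method(m1).scores, method(m2).scores, atol=1e-10, equal_nan=True
        )

    @pytest.mark.parametrize("method", [mip, omes])
    def test_invariant_under_consistent_residue_relabeling(self, method):
        rows = ["ADAF", "ADCF", "CEAG", "CECG", "ADAG", "CECF"]
        m1 = aln(*rows)
        # swap A<->C consistently within column 0
        swapped = [("C" if r[0] == "A" else "A") + r[1:] for r in rows]
        m2 = aln(*swapped)
        np.testing.assert_allclose(
            method(m1).scores, method(m2).scores, atol=1e-10, equal_nan=True
        )

    def test_separation_null_vs_planted(self):
        """Each scorer's extreme null score sits far below planted-pair scores."""
        planted_cols = [((1, 16), 0.9), ((4, 12), 0.9), ((7, 19), 0.9)]
        truth = make_coupled_msa(L=24, N=1000, planted=planted_cols, seed=11)
        methods = {"MIp": mip, "OMES": omes, "SCA": sca, "DI": direct_information}
        for name, fn in methods.items():
            planted_scores = [
                fn(truth.msa).scores[a, b] for (a, b), _ in planted_cols
            ]
            null_tops = [
                np.nanmax(fn(null_msa(L=24, N=1000, seed=s)).scores)
                for s in range(5)
            ]
            assert np.mean(null_tops) < np.percentile(planted_scores, 5), name
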