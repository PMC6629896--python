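import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cvcoupling import (
    InsufficientDataError,
    PairingError,
    ParameterError,
    family_distribution,
    family_of,
    joint_word_distribution,
    shannon_entropy,
    symbolize,
)
from cvcoupling.symbolic import FAMILIES, _FAMILY_WORDS

floats = st.floats(min_value=-1e6, max_value=1e6, allow_nan=False)


class TestSymbolize:
    def test_ternary_example_with_5ms_threshold(self):
        s = symbolize([800, 810, 807, 797], "ternary", threshold=5)
        assert s.symbols.tolist() == [2, 1, 0]

    def test_constant_series(self):
        assert symbolize(np.full(10, 5.0), "ternary", 1.0).symbols.tolist() == [1] * 9
        assert symbolize(np.full(10, 5.0), "binary").symbols.tolist() == [0] * 9

    @given(st.lists(floats, min_size=2, max_size=40))
    def test_binary_matches_sign_oracle(self, values):
        s = symbolize(values, "binary")
        oracle = [1 if b - a > 0 else 0 for a, b in zip(values, values[1:])]
        assert s.symbols.tolist() == oracle

    @given(st.lists(floats, min_size=2, max_size=30))
    def test_equilibrium_count_monotone_in_threshold(self, values):
        counts = [np.sum(symbolize(values, "ternary", l).symbols == 1)
                  for l in (0.0, 1.0, 10.0, 1e5)]
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_errors(self):
        with pytest.raises(InsufficientDataError):
            symbolize([1.0], "binary")
        with pytest.raises(ParameterError):
            symbolize([1.0, 2.0], "ternary", threshold=-1)


class TestJointWords:
    def test_ternary_matrix_is_27x27(self, rng):
        s1 = symbolize(rng.standard_normal(200), "ternary", 0.5)
        s2 = symbolize(rng.standard_normal(200), "ternary", 0.5)
        m = joint_word_distribution(s1, s2)
        assert m.probs.shape == (27, 27)
        assert m.probs.size == 729
        assert m.counts.sum() == len(s1) - 2
        assert abs(m.probs.sum() - 1.0) < 1e-12

    def test_binary_matrix_is_8x8(self, rng):
        s1 = symbolize(rng.standard_normal(100), "binary")
        s2 = symbolize(rng.standard_normal(100), "binary")
        assert joint_word_distribution(s1, s2).probs.shape == (8, 8)

    def test_single_word_pair(self):
        s = symbolize([1.0, 2.0, 3.0, 4.0], "binary")  # 3 symbols -> one word
        m = joint_word_distribution(s, s)
        assert m.counts.sum() == 1
        assert m.probs.max() == 1.0

    def test_pairing_errors(self, rng):
        b = symbolize(rng.standard_normal(50), "binary")
        t = symbolize(rng.standard_normal(50), "ternary", 0.5)
        with pytest.raises(PairingError):
            joint_word_distribution(b, t)
        short = symbolize(rng.standard_normal(20), "binary")
        with pytest.raises(PairingError):
            joint_word_distribution(b, short)

    def test_swapping_sequences_transposes(self, rng):
        s1 = symbolize(rng.standard_normal(150), "ternary", 0.5)
        s2 = symbolize(rng.standard_normal(150), "ternary", 0.5)
        m12 = joint_word_distribution(s1, s2)
        m21 = joint_word_distribution(s2, s1)
        np.testing.assert_array_equal(m12.counts, m21.counts.T)


class TestFamilies:
    def test_known_words(self):
        assert family_of("000") == "E0"
        assert family_of("111") == "E1"
        assert family_of("222") == "E2"
        assert family_of("202") == "LA1"
        assert family_of("120") == "P"
        assert family_of("021") == "V"
        assert family_of("122") == "LU1"
        assert family_of("011") == "LD1"

    def test_exhaustive_partition(self):
        """Each of the 27 ternary words belongs to exactly one family."""
        words = [f"{a}{b}{c}" for a in "012" for b in "012" for c in "012"]
        assignment = {w: family_of(w) for w in words}
        sizes = sorted(list(assignment.values()).count(f) for f in FAMILIES)
        assert sizes == [1, 1, 1, 2, 3, 3, 8, 8]
        assert len(assignment) == 27
        # membership agrees with the published family lists
        for fam, members in _FAMILY_WORDS.items():
            for w in members:
                assert assignment[w] == fam

    def test_invalid_word(self):
        with pytest.raises(ParameterError):
            family_of("03")


class TestFamilyDistribution:
    def _word_matrix(self, prob_map):
        from cvcoupling.symbolic import JointWordMatrix
        probs = np.zeros((27, 27))
        idx = lambda w: int(w, 3)
        for (w1, w2), p in prob_map.items():
            probs[idx(w1), idx(w2)] = p
        return JointWordMatrix(counts=(probs * 1000).astype(int), probs=probs,
                               word_length=3, alphabet_size=3)

    def test_point_mass(self):
        fam = family_distribution(self._word_matrix({("000", "111"): 1.0}))
        assert fam.probs[FAMILIES.index("E0"), FAMILIES.index("E1")] == 1.0
        assert fam.entropy == 0.0

    def test_uniform_over_family_cells_entropy_6_bits(self):
        reps = {f: _w[0] for f, _w in _FAMILY_WORDS.items()}
        prob_map = {(reps[f1], reps[f2]): 1 / 64 for f1 in FAMILIES for f2 in FAMILIES}
        fam = family_distribution(self._word_matrix(prob_map))
        np.testing.assert_allclose(fam.probs, 1 / 64)
        assert fam.entropy == pytest.approx(6.0)

    def test_regroup_matches_brute_force(self, rng):
        s1 = symbolize(rng.standard_normal(500), "ternary", 0.4)
        s2 = symbolize(rng.standard_normal(500), "ternary", 0.4)
        m = joint_word_distribution(s1, s2)
        fam = family_distribution(m)
        # independent recount: plain loops over all 729 word pairs
        oracle = np.zeros((8, 8))
        words = [f"{a}{b}{c}" for a in "012" for b in "012" for c in "012"]
        for i, w1 in enumerate(words):
            for j, w2 in enumerate(words):
                oracle[FAMILIES.index(family_of(w1)), FAMILIES.index(family_of(w2))] += m.probs[i, j]
        np.testing.assert_allclose(fam.probs, oracle, atol=1e-15)
        np.testing.assert_allclose(fam.marginals_ch1, fam.probs.sum(axis=1))
        np.testing.assert_allclose(fam.marginals_ch2, fam.probs.sum(axis=0))
        assert abs(fam.probs.sum() - 1.0) < 1e-12

    def test_entropy_conventions(self):
        assert shannon_entropy([0.5, 0.5, 0.0]) == pytest.approx(1.0)
        assert shannon_entropy([1.0]) == 0.0
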