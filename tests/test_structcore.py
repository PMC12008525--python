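"""Label modification, symmetrization, decoding, and the validity auditor."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mccfold.errors import ContractError, ValidityError
from mccfold.formats import PairMap, pairs_to_matrix
from mccfold.structcore import (audit_validity, decode, decode_reference,
                                modify_label, row_argmax_binarize,
                                sharp_loop_mask, strip_diagonal, symmetrize)

from conftest import random_pairmap


class TestModifyLabel:
    def test_zero_matrix_becomes_identity(self):
        assert np.array_equal(modify_label(np.zeros((5, 5), dtype=np.int8)), np.eye(5))

    def test_single_pair_is_involution(self):
        S = pairs_to_matrix(PairMap(5, frozenset({frozenset({0, 4})})))
        lab = modify_label(S)
        expected = np.zeros((5, 5))
        expected[0, 4] = expected[4, 0] = expected[1, 1] = expected[2, 2] = expected[3, 3] = 1
        assert np.array_equal(lab, expected)

    def test_random_structures_give_symmetric_permutations(self, rng):
        for _ in range(100):
            L = int(rng.integers(8, 40))
            lab = modify_label(pairs_to_matrix(random_pairmap(L, rng)))
            assert np.array_equal(lab, lab.T)
            assert np.array_equal(lab.sum(axis=0), np.ones(L))
            assert np.array_equal(lab.sum(axis=1), np.ones(L))

    def test_lossless_off_diagonal(self, rng):
        S = pairs_to_matrix(random_pairmap(30, rng))
        assert np.array_equal(strip_diagonal(modify_label(S)), S)

    def test_invalid_input_rejected(self):
        S = np.zeros((6, 6), dtype=np.int8)
        S[0, 5] = 1  # asymmetric
        with pytest.raises(ValidityError):
            modify_label(S)


class TestSymmetrize:
    def test_average_with_transpose(self):
        assert np.array_equal(symmetrize(np.array([[0.0, 2.0], [4.0, 0.0]])),
                              [[0.0, 3.0], [3.0, 0.0]])

    def test_idempotent_and_identity_on_symmetric(self, rng):
        M = rng.normal(size=(7, 7))
        Mh = symmetrize(M)
        assert np.array_equal(Mh, Mh.T)
        assert np.allclose(symmetrize(Mh), Mh)

    def test_nonsquare_rejected(self):
        with pytest.raises(ContractError):
            symmetrize(np.zeros((3, 4)))


class TestRowArgmax:
    def test_max_position(self):
        assert np.array_equal(row_argmax_binarize(np.array([[0.1, 0.7, 0.2]] * 3))[0],
                              [0, 1, 0])

    def test_tie_breaks_to_lowest_index(self):
        P = row_argmax_binarize(np.array([[0.5, 0.5, 0.1]] * 3))
        assert np.array_equal(P[0], [1, 0, 0])

    def test_every_row_sums_to_one(self, rng):
        P = row_argmax_binarize(rng.normal(size=(20, 20)))
        assert np.array_equal(P.sum(axis=1), np.ones(20))


class TestSharpLoopMask:
    def test_small_sizes(self):
        Z5 = sharp_loop_mask(5)
        assert Z5.sum() == 2 and Z5[0, 4] == Z5[4, 0] == 1
        assert sharp_loop_mask(4).sum() == 0
        assert np.all(np.diag(sharp_loop_mask(10)) == 0)


class TestDecode:
    def _scores_for(self, pm: PairMap) -> np.ndarray:
        """Perfect scores: the modified label plus tiny noise-free bias."""
        return modify_label(pairs_to_matrix(pm)).astype(float)

    def test_mutual_peak_yields_pair(self):
        M = self._scores_for(PairMap(10, frozenset({frozenset({0, 9})})))
        P = decode(M)
        assert P[0, 9] == P[9, 0] == 1 and P.sum() == 2

    def test_non_mutual_peaks_cancel(self):
        # symmetric scores where row 5 selects column 2 but row 2 selects
        # column 7: the one-sided (5, 2) entry must not survive decoding
        M = np.zeros((12, 12))
        M[1, 5] = M[5, 1] = 3.0
        M[5, 2] = M[2, 5] = 5.0
        M[2, 7] = M[7, 2] = 6.0
        P = decode(M)
        assert P[5, 2] == 0 and P[2, 5] == 0 and P[1, 5] == 0
        assert P[2, 7] == 1 and P[7, 2] == 1

    def test_close_mutual_peak_removed_by_mask(self):
        M = np.full((8, 8), -1.0)
        M[2, 5] = M[5, 2] = 5.0  # |2-5| = 3 < 4
        assert decode(M)[2, 5] == 0

    def test_perfect_scores_decode_to_themselves(self, rng):
        for _ in range(50):
            pm = random_pairmap(int(rng.integers(10, 40)), rng)
            P = decode(self._scores_for(pm))
            assert np.array_equal(P, pairs_to_matrix(pm))

    def test_validity_on_random_scores(self, rng):
        for _ in range(200):
            L = int(rng.integers(8, 65))
            P = decode(rng.normal(size=(L, L)))
            assert not [v for v in audit_validity(P) if v.is_error]

    def test_matches_reference_decoder(self, rng):
        for _ in range(200):
            L = int(rng.integers(8, 33))
            M = rng.normal(size=(L, L))
            assert np.array_equal(decode(M), decode_reference(M))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1), st.integers(8, 48))
    def test_validity_property(self, seed, L):
        M = np.random.default_rng(seed).normal(size=(L, L))
        assert not [v for v in audit_validity(decode(M)) if v.is_error]


class TestAudit:
    def test_decode_output_is_clean(self, rng):
        assert audit_validity(decode(rng.normal(size=(20, 20)))) == []

    def test_asymmetry_detected(self):
        S = np.zeros((8, 8), dtype=np.int8)
        S[1, 5] = 1
        assert any(v.constraint == "symmetry" and v.indices == (1, 5)
                   for v in audit_validity(S))

    def test_row_multiplicity_detected(self):
        S = np.zeros((10, 10), dtype=np.int8)
        S[0, 4] = S[4, 0] = S[0, 8] = S[8, 0] = 1
        assert any(v.constraint == "row-multiplicity" and v.indices == (0,)
                   for v in audit_validity(S))

    def test_sharp_loop_detected(self):
        S = np.zeros((8, 8), dtype=np.int8)
        S[1, 3] = S[3, 1] = 1
        assert any(v.constraint == "sharp-loop" for v in audit_validity(S))

    def test_non_canonical_is_informational_only(self):
        S = np.zeros((10, 10), dtype=np.int8)
        S[0, 9] = S[9, 0] = 1
        findings = audit_validity(S, bases="AAAAAAAAAA")  # A-A is not canonical
        assert findings and all(not v.is_error for v in findings)
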