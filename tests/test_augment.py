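"""Augmentation operator contracts: edits confined to unpaired bases, pair
conservation, exact length arithmetic, label validity, and the length gate."""

import numpy as np
import pytest

from mccfold.augment import (AugmentConfig, add_noise, augment_dataset,
                             insert_bases, remove_bases, unpaired_indices)
from mccfold.errors import ContractError
from mccfold.fixtures import make_hairpin, make_two_stem
from mccfold.formats import PairMap, matrix_to_pairs, pairs_to_matrix
from mccfold.structcore import audit_validity

from conftest import random_pairmap, random_sequence


def _sample(rng, L=30):
    pm = random_pairmap(L, rng)
    return random_sequence(L, rng), pairs_to_matrix(pm)


def _paired_positions(S):
    return np.nonzero(S.sum(axis=1) > 0)[0]


class TestUnpairedIndices:
    def test_single_pair(self):
        S = pairs_to_matrix(PairMap(10, frozenset({frozenset({0, 9})})))
        assert list(unpaired_indices(S)) == list(range(1, 9))

    def test_zero_matrix(self):
        assert list(unpaired_indices(np.zeros((6, 6)))) == list(range(6))

    def test_valid_nonempty_structure_has_at_least_three_unpaired(self, rng):
        """The sharp-loop rule forces >= 3 unpaired bases inside the
        innermost pair of any stem, so B is never empty for paired samples."""
        for _ in range(50):
            pm = random_pairmap(int(rng.integers(10, 40)), rng)
            if pm.pairs:
                assert len(unpaired_indices(pairs_to_matrix(pm))) >= 3


class TestAddNoise:
    def test_zero_rate_identity(self, rng):
        seq, S = _sample(rng)
        out_seq, out_S = add_noise((seq, S), 0.0, rng)
        assert out_seq.bases == seq.bases and np.array_equal(out_S, S)

    def test_exact_count_and_sites(self, rng):
        seq, S = make_hairpin(1, 8, rng)  # L = 10, pair {0, 9}, |B| = 8
        out_seq, out_S = add_noise((seq, S), 0.10, rng)  # round(0.8) = 1
        diffs = [k for k in range(10) if out_seq.bases[k] != seq.bases[k]]
        assert len(diffs) == 1 and diffs[0] in range(1, 9)
        assert np.array_equal(out_S, S)  # structure bit-identical

    def test_paired_bases_never_touched(self, rng):
        for _ in range(200):
            seq, S = _sample(rng)
            out_seq, _ = add_noise((seq, S), 0.5, rng)
            for i in _paired_positions(S):
                assert out_seq.bases[i] == seq.bases[i]

    def test_mutated_base_differs(self, rng):
        seq, S = make_hairpin(1, 8, rng)
        out_seq, _ = add_noise((seq, S), 1.0, rng)
        for k in unpaired_indices(S):
            assert out_seq.bases[k] != seq.bases[k]


class TestRemoveBases:
    def test_index_shift(self, rng):
        # L = 12, single pair {0, 11}; deleting an interior unpaired base
        # shifts the pair to {0, 10}
        seq, S = make_hairpin(1, 10, rng)
        out_seq, out_S = remove_bases((seq, S), p2=1 / 10 - 1e-9, p1=0.0, rng=rng)
        assert out_seq.length == 11
        assert matrix_to_pairs(out_S).as_tuples() == [(0, 10)]

    def test_pair_count_conserved(self, rng):
        for _ in range(100):
            seq, S = _sample(rng)
            _, out_S = remove_bases((seq, S), 0.2, 0.1, rng)
            assert out_S.sum() == S.sum()
            assert not [v for v in audit_validity(out_S) if v.is_error]

    def test_length_arithmetic(self, rng):
        seq, S = _sample(rng, L=40)
        B = len(unpaired_indices(S))
        k = int(np.floor(0.25 * B + 0.5))
        out_seq, out_S = remove_bases((seq, S), 0.25, 0.0, rng)
        assert out_seq.length == 40 - k == out_S.shape[0]

    def test_sharp_loop_deletion_resampled(self, rng):
        # stem 2, loop exactly 3: loop bases cannot be deleted, but the
        # structure also has no other unpaired bases -> count 0 or error
        seq, S = make_two_stem((2, 2), (3, 3), 6, rng)
        # only linker deletions are legal; request one deletion
        out_seq, out_S = remove_bases((seq, S), p2=0.09, p1=0.0, rng=rng)
        assert out_seq.length == seq.length - 1
        pairs_before = matrix_to_pairs(S).as_tuples()
        assert len(matrix_to_pairs(out_S).as_tuples()) == len(pairs_before)
        assert not [v for v in audit_validity(out_S) if v.is_error]

    def test_infeasible_deletion_errors(self, rng):
        seq, S = make_hairpin(2, 3, rng)  # B = the 3-base loop, untouchable
        with pytest.raises(ContractError, match="sharp loop"):
            remove_bases((seq, S), p2=0.5, p1=0.0, rng=rng)


class TestInsertBases:
    def test_index_shift(self, rng):
        seq, S = make_hairpin(1, 8, rng)  # L = 10, pair {0, 9}
        out_seq, out_S = insert_bases((seq, S), p3=0.1, p1=0.0, rng=rng)
        assert out_seq.length == 11
        (pair,) = matrix_to_pairs(out_S).as_tuples()
        assert pair[1] - pair[0] >= 9  # separation can only grow

    def test_pair_count_and_validity(self, rng):
        for _ in range(100):
            seq, S = _sample(rng)
            out_seq, out_S = insert_bases((seq, S), 0.15, 0.1, rng)
            assert out_S.sum() == S.sum()
            assert out_seq.length == seq.length + int(np.floor(0.15 * seq.length + 0.5))
            assert not [v for v in audit_validity(out_S) if v.is_error]

    def test_zero_rate(self, rng):
        seq, S = _sample(rng)
        out_seq, out_S = insert_bases((seq, S), 0.0, 0.0, rng)
        assert out_seq.bases == seq.bases and np.array_equal(out_S, S)


class TestAugmentDataset:
    def _long_sample(self, rng):
        return make_hairpin(80, 40, rng, name="long")  # L = 200

    def test_gated_sample_yields_six(self, rng):
        sample = self._long_sample(rng)
        out = augment_dataset([sample], AugmentConfig(seed=1))
        assert len(out) == 1 + 6
        ids = [s.identifier for s, _ in out[1:]]
        assert all("|" in i for i in ids)
        assert {i.split("|")[1] for i in ids} == {"noise", "remove", "insert"}

    def test_short_sample_not_augmented(self, rng):
        sample = make_hairpin(20, 10, rng)  # L = 50
        out = augment_dataset([sample], AugmentConfig(seed=1))
        assert len(out) == 1

    def test_deterministic_given_seed(self, rng):
        sample = self._long_sample(rng)
        a = augment_dataset([sample], AugmentConfig(seed=7))
        b = augment_dataset([sample], AugmentConfig(seed=7))
        assert all(x[0].bases == y[0].bases and np.array_equal(x[1], y[1])
                   for x, y in zip(a, b))

    def test_all_outputs_valid(self, rng):
        out = augment_dataset([self._long_sample(rng)], AugmentConfig(seed=3))
        for _, S in out:
            assert not [v for v in audit_validity(S) if v.is_error]
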