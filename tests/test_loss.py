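"""Row softmax and the weighted average cross-entropy, including the
worked 5x5 example, degenerate-|D| fallbacks, and the rows-vs-columns
training equivalence."""

import math

import numpy as np
import pytest

from mccfold.errors import ContractError
from mccfold.formats import PairMap, pairs_to_matrix
from mccfold.loss import (column_weighted_cross_entropy, loss_from_scores,
                          row_softmax, weighted_cross_entropy,
                          weighted_cross_entropy_reference)
from mccfold.structcore import modify_label, symmetrize

from conftest import random_pairmap


class TestRowSoftmax:
    def test_uniform_on_zero_rows(self):
        assert np.allclose(row_softmax(np.zeros((5, 5))), 0.2)

    def test_stable_under_large_values(self):
        out = row_softmax(np.array([[1000.0, 0.0, 0.0]]))
        assert np.isfinite(out).all() and out[0, 0] == pytest.approx(1.0)

    def test_rows_sum_to_one(self, rng):
        out = row_softmax(rng.normal(size=(4, 16, 16)) * 10)
        assert np.allclose(out.sum(axis=-1), 1.0, atol=1e-6)

    def test_nonfinite_rejected(self):
        with pytest.raises(ContractError):
            row_softmax(np.array([[np.inf, 0.0]]))


def _label_single_pair_L5() -> np.ndarray:
    return modify_label(pairs_to_matrix(PairMap(5, frozenset({frozenset({0, 4})}))))


class TestWeightedCrossEntropy:
    def test_worked_example(self):
        """Uniform 5x5 distribution vs label with one pair {0, 4}:
        2 paired rows at ln 5, |D| = 3 unpaired rows weighted by 2/3."""
        Pr = np.full((5, 5), 0.2)
        value = weighted_cross_entropy(Pr, _label_single_pair_L5())
        assert value == pytest.approx(0.8 * math.log(5), abs=1e-9)
        assert value == pytest.approx(
            weighted_cross_entropy_reference(Pr, _label_single_pair_L5()), abs=1e-12
        )

    def test_perfect_prediction_is_zero(self):
        lab = _label_single_pair_L5()
        assert weighted_cross_entropy(lab.astype(float), lab) == pytest.approx(0.0)

    def test_all_unpaired_falls_back_to_mean(self):
        lab = np.eye(5)
        value = weighted_cross_entropy(np.full((5, 5), 0.2), lab)
        assert value == pytest.approx(math.log(5), abs=1e-9)

    def test_no_unpaired_plain_average(self):
        # fully paired 8-row label (permutation without fixed points)
        lab = np.zeros((8, 8))
        for i, j in [(0, 4), (1, 5), (2, 6), (3, 7)]:
            lab[i, j] = lab[j, i] = 1
        value = weighted_cross_entropy(np.full((8, 8), 0.125), lab)
        assert value == pytest.approx(math.log(8), abs=1e-9)

    def test_half_unpaired_reduces_to_plain_mean(self, rng):
        """When |D| = n/2 the weight is 1 and the loss is the plain mean."""
        lab = np.zeros((8, 8))
        lab[0, 4] = lab[4, 0] = lab[1, 5] = lab[5, 1] = 1
        for i in (2, 3, 6, 7):
            lab[i, i] = 1
        Pr = row_softmax(rng.normal(size=(8, 8)))
        cls = lab.argmax(axis=1)
        plain = float(np.mean([-math.log(Pr[i, cls[i]]) for i in range(8)]))
        assert weighted_cross_entropy(Pr, lab) == pytest.approx(plain, abs=1e-9)

    def test_matches_scalar_oracle_on_random_batches(self, rng):
        for _ in range(20):
            L = int(rng.integers(8, 24))
            labs, Prs = [], []
            for _b in range(3):
                labs.append(modify_label(pairs_to_matrix(random_pairmap(L, rng))))
                Prs.append(row_softmax(rng.normal(size=(L, L))))
            got = weighted_cross_entropy(np.stack(Prs), np.stack(labs))
            want = weighted_cross_entropy_reference(np.stack(Prs), np.stack(labs))
            assert got == pytest.approx(want, abs=1e-10)

    def test_padding_excluded(self, rng):
        """A padded batch of one sequence equals the unpadded single loss."""
        L, Lp = 10, 16
        lab_small = modify_label(pairs_to_matrix(random_pairmap(L, rng)))
        M = rng.normal(size=(L, L))
        single = weighted_cross_entropy(row_softmax(M), lab_small)
        M_pad = np.zeros((Lp, Lp))
        M_pad[:L, :L] = M
        lab_pad = np.zeros((Lp, Lp))
        lab_pad[:L, :L] = lab_small
        pad_mask = np.arange(Lp) < L
        # softmax must run over the real columns only
        Pr_pad = np.zeros((Lp, Lp))
        Pr_pad[:L, :L] = row_softmax(M)
        padded = weighted_cross_entropy(Pr_pad, lab_pad, pad_mask)
        assert padded == pytest.approx(single, abs=1e-9)

    def test_sample_order_invariance(self, rng):
        """The loss depends on the multiset of sub-samples, not their order
        in the batch."""
        labs = [modify_label(pairs_to_matrix(random_pairmap(12, rng))) for _ in range(3)]
        Prs = [row_softmax(rng.normal(size=(12, 12))) for _ in range(3)]
        fwd = weighted_cross_entropy(np.stack(Prs), np.stack(labs))
        rev = weighted_cross_entropy(np.stack(Prs[::-1]), np.stack(labs[::-1]))
        assert rev == pytest.approx(fwd, abs=1e-12)


class TestRowColumnEquivalence:
    def test_row_loss_equals_column_loss_on_symmetric_scores(self, rng):
        """Training on rows of symmetric scores is equivalent to training on
        columns of the transposed scores: the losses agree to 1e-9."""
        for _ in range(50):
            L = int(rng.integers(8, 32))
            Mhat = symmetrize(rng.normal(size=(L, L)))
            lab = modify_label(pairs_to_matrix(random_pairmap(L, rng)))
            row_loss = loss_from_scores(Mhat, lab)
            col_loss = column_weighted_cross_entropy(Mhat.T, lab)
            assert col_loss == pytest.approx(row_loss, abs=1e-9)
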