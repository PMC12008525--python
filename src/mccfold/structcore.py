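"""Core matrix operations: label modification, symmetrization, decoding, and
the validity auditor.

The central idea: instead of L x L independent binary classifications, treat
each row of the contact matrix as one L-class classification. Unpaired bases
get a '1' on the diagonal of the label ("pairs with itself"), making every
label row one-hot — the modified label is a symmetric permutation matrix.
At inference time the decoder takes a row-wise argmax, keeps only mutually
agreeing entries via the Hadamard product with the transpose, and applies
the sharp-loop mask; the result is valid by construction, with no iterative
post-processing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ContractError, ValidityError
from .formats import MIN_SEPARATION

#: Watson-Crick plus wobble pairings, used only for informational reporting.
CANONICAL_PAIRS = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")}


@dataclass(frozen=True)
class Violation:
    """One constraint violation found by :func:`audit_validity`.

    ``is_error`` is False for informational findings (non-canonical pairings),
    which never invalidate a structure: pairing chemistry is deliberately not
    enforced — non-canonical pairs occur in real structures and enforcement
    is left to the learned model.
    """

    constraint: str
    indices: tuple
    detail: str = ""
    is_error: bool = True

    def __str__(self) -> str:
        tag = "" if self.is_error else " [info]"
        return f"{self.constraint} at {self.indices}{tag}{': ' + self.detail if self.detail else ''}"


def _require_square(M: np.ndarray, name: str = "matrix") -> np.ndarray:
    M = np.asarray(M)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ContractError(f"{name} must be square 2-D, got shape {M.shape}")
    return M


def audit_validity(S: np.ndarray, bases: str | None = None) -> list[Violation]:
    """Audit a binary matrix against the structure-validity constraints.

    Checks, in order: binary entries; symmetry; at most one '1' per row and
    per column; no entries with ``|i - j| < 4`` (which subsumes a zero
    diagonal). When ``bases`` is given, pairs outside the canonical+wobble
    set are additionally reported as informational (``is_error=False``).

    Returns an empty list iff the matrix is a valid structure.
    """
    S = _require_square(S)
    out: list[Violation] = []

    nonbinary = np.argwhere((S != 0) & (S != 1))
    for i, j in nonbinary[:10]:
        out.append(Violation("binary", (int(i), int(j)), f"entry {S[i, j]!r}"))
    if len(nonbinary):
        return out  # remaining checks assume 0/1 entries

    asym = np.argwhere(S != S.T)
    for i, j in asym[:10]:
        if i < j:
            out.append(Violation("symmetry", (int(i), int(j))))

    row_sums = S.sum(axis=1)
    for i in np.nonzero(row_sums > 1)[0]:
        out.append(Violation("row-multiplicity", (int(i),), f"row sum {int(row_sums[i])}"))
    col_sums = S.sum(axis=0)
    for j in np.nonzero(col_sums > 1)[0]:
        out.append(Violation("column-multiplicity", (int(j),), f"column sum {int(col_sums[j])}"))

    L = S.shape[0]
    ii, jj = np.nonzero(S)
    for i, j in zip(ii, jj):
        if abs(int(i) - int(j)) < MIN_SEPARATION and i <= j:
            out.append(Violation("sharp-loop", (int(i), int(j)), f"|i-j| = {abs(int(i) - int(j))} < {MIN_SEPARATION}"))

    if bases is not None:
        if len(bases) != L:
            raise ContractError(f"bases length {len(bases)} != matrix size {L}")
        for i, j in zip(ii, jj):
            if i < j and (bases[i], bases[j]) not in CANONICAL_PAIRS:
                out.append(Violation(
                    "non-canonical-pairing", (int(i), int(j)),
                    f"{bases[i]}-{bases[j]}", is_error=False,
                ))
    return out


def _require_valid(S: np.ndarray) -> np.ndarray:
    S = _require_square(S, "structure matrix")
    violations = [v for v in audit_validity(S) if v.is_error]
    if violations:
        raise ValidityError("; ".join(str(v) for v in violations))
    return S


def modify_label(S: np.ndarray) -> np.ndarray:
    """Fill the diagonal entries of zero rows with '1's.

    Off-diagonal entries are copied from S; diagonal entry i becomes
    ``1 - sum(S[i, :])``, i.e. 1 exactly when base i is unpaired. The result
    is a symmetric permutation matrix (an involution), so every row and
    column is a one-hot classification label.
    """
    S = _require_valid(S)
    Shat = S.astype(np.int8).copy()
    np.fill_diagonal(Shat, 1 - S.sum(axis=1))
    return Shat


def strip_diagonal(Shat: np.ndarray) -> np.ndarray:
    """Inverse of :func:`modify_label`: drop the diagonal fill."""
    S = np.asarray(Shat).copy()
    np.fill_diagonal(S, 0)
    return S


def symmetrize(M: np.ndarray) -> np.ndarray:
    """Average a score matrix with its transpose: ``(M + M^T) / 2``."""
    M = _require_square(M, "score matrix")
    return (M + M.T) / 2.0


def row_argmax_binarize(Mhat: np.ndarray) -> np.ndarray:
    """Set the largest value of each row to 1 and all others to 0.

    Ties break to the lowest column index, so the operation is deterministic.
    The result has exactly one '1' per row but no column guarantee.
    """
    Mhat = _require_square(Mhat, "score matrix")
    P = np.zeros_like(Mhat, dtype=np.int8)
    P[np.arange(Mhat.shape[0]), np.argmax(Mhat, axis=1)] = 1
    return P


def sharp_loop_mask(L: int) -> np.ndarray:
    """The L x L mask Z with ``Z[i, j] = 0`` iff ``|i - j| < 4``.

    Zeroing the band around the diagonal removes sterically impossible sharp
    loops and, because the diagonal itself is in the band, converts
    "pairs with itself" argmax rows into unpaired predictions.
    """
    if L < 1:
        raise ContractError(f"L must be positive, got {L}")
    idx = np.arange(L)
    return (np.abs(idx[:, None] - idx[None, :]) >= MIN_SEPARATION).astype(np.int8)


def decode(Mhat: np.ndarray) -> np.ndarray:
    """Decode a real score matrix into a guaranteed-valid binary prediction.

    ``P = R ⊙ R^T ⊙ Z`` where R is the row-argmax binarization of the
    symmetrized scores and Z the sharp-loop mask. Each row of R has exactly
    one '1', so the Hadamard product with the transpose keeps an entry only
    when rows i and j select each other — at most one '1' survives per row
    and column, and the product is symmetric. Z then removes near-diagonal
    entries. No iterative post-processing is involved.

    Accepts raw (possibly asymmetric) model output; symmetrization is applied
    internally when needed.
    """
    Mhat = _require_square(Mhat, "score matrix")
    if not np.array_equal(Mhat, Mhat.T):
        Mhat = symmetrize(Mhat)
    R = row_argmax_binarize(Mhat)
    return (R * R.T * sharp_loop_mask(Mhat.shape[0])).astype(np.int8)


def decode_reference(Mhat: np.ndarray) -> np.ndarray:
    """Independent per-entry reference decoder (explicit loops).

    Used only as a cross-check oracle for :func:`decode`; intentionally
    written without shared code or vectorization.
    """
    Mhat = np.asarray(Mhat, dtype=float)
    L = Mhat.shape[0]
    A = [[(Mhat[i][j] + Mhat[j][i]) / 2.0 for j in range(L)] for i in range(L)]
    argmax = []
    for i in range(L):
        best, best_j = A[i][0], 0
        for j in range(1, L):
            if A[i][j] > best:
                best, best_j = A[i][j], j
        argmax.append(best_j)
    P = np.zeros((L, L), dtype=np.int8)
    for i in range(L):
        j = argmax[i]
        if argmax[j] == i and abs(i - j) >= MIN_SEPARATION:
            P[i][j] = 1
    return P
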