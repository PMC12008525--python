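"""Row-wise softmax and the weighted average cross-entropy objective.

Each row of the (symmetrized) score matrix together with the matching row of
the modified label forms one *sub-sample*: an L-class classification whose
target is the partner index (or the base's own index if unpaired). Because
unpaired bases usually dominate, the unpaired sub-samples are down-weighted
by ``(n - |D|) / |D|``, where D is the set of unpaired sub-samples and n the
number of non-padded sub-samples in the batch:

    loss = (1/n) * ( sum_{i not in D} l_i + (n - |D|)/|D| * sum_{i in D} l_i )

Degenerate cases (the formula is undefined at |D| = 0 and collapses to 0 at
|D| = n) fall back to the plain mean; both fallbacks are logged.
"""

from __future__ import annotations

import logging

import numpy as np

from .errors import ContractError

logger = logging.getLogger(__name__)


def row_softmax(Mhat: np.ndarray) -> np.ndarray:
    """Numerically stable softmax over the last axis (rows of the matrix)."""
    Mhat = np.asarray(Mhat, dtype=float)
    if not np.all(np.isfinite(Mhat)):
        raise ContractError("score matrix contains non-finite entries")
    shifted = Mhat - Mhat.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def _row_log_probs(Pr: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """-log probability each row assigns to its labeled class."""
    cls = np.argmax(labels, axis=-1)
    picked = np.take_along_axis(Pr, cls[..., None], axis=-1)[..., 0]
    return -np.log(np.clip(picked, 1e-300, None))


def weighted_cross_entropy(
    Pr_batch: np.ndarray,
    labels: np.ndarray,
    pad_mask: np.ndarray | None = None,
) -> float:
    """The weighted average cross-entropy over a batch of row distributions.

    Parameters
    ----------
    Pr_batch : (b, L, L) or (L, L) array
        Row-stochastic probability matrices (each row sums to 1).
    labels : same shape
        Modified labels: each non-padded row one-hot; a '1' on the diagonal
        marks an unpaired base (membership in D).
    pad_mask : (b, L) or (L,) boolean array, optional
        True at real positions. Padded rows are excluded from both sums and
        from the sub-sample count n.
    """
    Pr = np.asarray(Pr_batch, dtype=float)
    lab = np.asarray(labels)
    if Pr.shape != lab.shape:
        raise ContractError(f"shape mismatch: {Pr.shape} vs {lab.shape}")
    if Pr.ndim == 2:
        Pr, lab = Pr[None], lab[None]
        pad_mask = None if pad_mask is None else np.asarray(pad_mask)[None]
    b, L, _ = Pr.shape
    if pad_mask is None:
        pad_mask = np.ones((b, L), dtype=bool)
    pad_mask = np.asarray(pad_mask, dtype=bool)

    losses = _row_log_probs(Pr, lab)            # (b, L)
    diag = np.arange(L)
    unpaired = lab[:, diag, diag] == 1          # (b, L): D membership

    real = pad_mask
    n = int(real.sum())
    if n == 0:
        raise ContractError("all rows are padded")
    d = int((unpaired & real).sum())
    sum_paired = float(losses[real & ~unpaired].sum())
    sum_unpaired = float(losses[real & unpaired].sum())

    if d == 0:
        logger.info("weighted_cross_entropy: |D| = 0; using plain mean of paired terms")
        return sum_paired / n
    if d == n:
        logger.info("weighted_cross_entropy: |D| = n; falling back to unweighted mean")
        return sum_unpaired / n
    return (sum_paired + (n - d) / d * sum_unpaired) / n


def weighted_cross_entropy_reference(
    Pr_batch: np.ndarray,
    labels: np.ndarray,
    pad_mask: np.ndarray | None = None,
) -> float:
    """Scalar-loop oracle for :func:`weighted_cross_entropy` (cross-check only)."""
    import math

    Pr = np.asarray(Pr_batch, dtype=float)
    lab = np.asarray(labels)
    if Pr.ndim == 2:
        Pr, lab = Pr[None], lab[None]
        pad_mask = None if pad_mask is None else np.asarray(pad_mask)[None]
    b, L, _ = Pr.shape
    paired_terms, unpaired_terms = [], []
    for s in range(b):
        for i in range(L):
            if pad_mask is not None and not pad_mask[s][i]:
                continue
            cls = max(range(L), key=lambda j: lab[s][i][j])
            li = -math.log(Pr[s][i][cls])
            (unpaired_terms if cls == i else paired_terms).append(li)
    n = len(paired_terms) + len(unpaired_terms)
    d = len(unpaired_terms)
    if d == 0:
        return sum(paired_terms) / n
    if d == n:
        return sum(unpaired_terms) / n
    return (sum(paired_terms) + (n - d) / d * sum(unpaired_terms)) / n


def column_weighted_cross_entropy(
    Mhat_batch: np.ndarray,
    labels: np.ndarray,
    pad_mask: np.ndarray | None = None,
) -> float:
    """The column-labeled counterpart: softmax over columns of the scores,
    cross-entropy against label columns.

    For symmetric scores and symmetric labels this equals the row-labeled
    loss on the same matrices — training on rows or on columns is
    equivalent, which is why only rows are used.
    """
    M = np.asarray(Mhat_batch, dtype=float)
    lab = np.asarray(labels)
    if M.ndim == 2:
        M, lab = M[None], lab[None]
        pad_mask = None if pad_mask is None else np.asarray(pad_mask)[None]
    Pr_cols = row_softmax(np.swapaxes(M, -1, -2))
    return weighted_cross_entropy(Pr_cols, np.swapaxes(lab, -1, -2), pad_mask)


def loss_from_scores(
    Mhat_batch: np.ndarray,
    labels: np.ndarray,
    pad_mask: np.ndarray | None = None,
) -> float:
    """Convenience: row softmax then weighted cross-entropy, from raw scores."""
    return weighted_cross_entropy(row_softmax(Mhat_batch), labels, pad_mask)
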