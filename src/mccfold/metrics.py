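"""Confusion counting over candidate pair positions and the evaluation
scores: precision, recall, F1, and INF (interaction network fidelity).

The candidate-position universe is the set of unordered index pairs (i, j)
with j - i >= 4 — positions where a base pair is sterically possible. Each
base pair is counted once (upper triangle), so TP+FP+TN+FN =
(L-4)(L-3)/2 for L >= 4. F1 is insensitive to this choice of universe; INF
(computed identically to the Matthews correlation coefficient) is not, and
counting over feasible positions only avoids inflating TN with entries that
are structurally forced to zero in both matrices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ContractError
from .formats import MIN_SEPARATION

#: Default length bins: the short/long split at 150 used for reporting.
DEFAULT_BINS = ((50, 150), (150, 500))


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def candidate_positions(L: int) -> int:
    """Number of sterically feasible unordered pair positions."""
    return (L - MIN_SEPARATION) * (L - MIN_SEPARATION + 1) // 2 if L > MIN_SEPARATION else 0


def confusion_counts(pred: np.ndarray, ref: np.ndarray) -> ConfusionCounts:
    """TP/FP/TN/FN over upper-triangle positions with j - i >= 4."""
    P, R = np.asarray(pred), np.asarray(ref)
    if P.shape != R.shape or P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ContractError(f"shape mismatch: {P.shape} vs {R.shape}")
    L = P.shape[0]
    ii, jj = np.triu_indices(L, k=MIN_SEPARATION)
    p, r = P[ii, jj].astype(bool), R[ii, jj].astype(bool)
    return ConfusionCounts(
        tp=int(np.sum(p & r)),
        fp=int(np.sum(p & ~r)),
        tn=int(np.sum(~p & ~r)),
        fn=int(np.sum(~p & r)),
    )


def precision_recall_f1(c: ConfusionCounts) -> tuple[float, float, float]:
    """P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2PR/(P+R).

    Conventions: if TP = FP = FN = 0 the two structures agree on having no
    pairs and P = R = F1 = 1; otherwise any 0/0 term is 0.
    """
    if c.tp == 0 and c.fp == 0 and c.fn == 0:
        return 1.0, 1.0, 1.0
    p = c.tp / (c.tp + c.fp) if c.tp + c.fp else 0.0
    r = c.tp / (c.tp + c.fn) if c.tp + c.fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f1


def inf_score(c: ConfusionCounts) -> float:
    """INF = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).

    Computed identically to the Matthews correlation coefficient; a zero
    factor in the denominator yields 0 by the standard MCC convention.
    """
    denom = (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    if denom == 0:
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)


def score_sample(pred: np.ndarray, ref: np.ndarray) -> dict[str, float]:
    """Per-sample P, R, F1 and INF in one call."""
    c = confusion_counts(pred, ref)
    p, r, f1 = precision_recall_f1(c)
    return {"precision": p, "recall": r, "f1": f1, "inf": inf_score(c)}


def f1_from_pair_sets(pred: np.ndarray, ref: np.ndarray) -> float:
    """Independent F1 via set intersection of upper-triangle pair tuples
    (cross-check oracle for the confusion-count route)."""
    pp = {tuple(x) for x in np.argwhere(np.triu(np.asarray(pred)))}
    rr = {tuple(x) for x in np.argwhere(np.triu(np.asarray(ref)))}
    if not pp and not rr:
        return 1.0
    if not pp or not rr:
        return 0.0
    inter = len(pp & rr)
    p, r = inter / len(pp), inter / len(rr)
    return 2 * p * r / (p + r) if p + r else 0.0


def _length_bin(L: int, bins) -> str | None:
    for lo, hi in bins:
        if lo < L <= hi:
            return f"{lo}<L<={hi}"
    return None


def stratified_report(
    samples: list[dict],
    bins=DEFAULT_BINS,
    fine_width: int | None = 100,
    by_family: bool = True,
) -> pd.DataFrame:
    """Macro-averaged (per-sample mean +/- sd) scores per group.

    ``samples`` are dicts with keys ``length``, ``precision``, ``recall``,
    ``f1``, ``inf`` and optionally ``family``. Groups: overall, each coarse
    length bin, width-``fine_width`` bins, and each family tag when present.
    Empty groups are simply absent from the table.
    """
    if not samples:
        raise ContractError("no samples to report")
    df = pd.DataFrame(samples)
    groups: list[tuple[str, pd.DataFrame]] = [("overall", df)]
    for lo, hi in bins:
        sub = df[(df["length"] > lo) & (df["length"] <= hi)]
        if len(sub):
            groups.append((f"{lo}<L<={hi}", sub))
    if fine_width:
        lo = (int(df["length"].min()) - 1) // fine_width * fine_width
        while lo < df["length"].max():
            sub = df[(df["length"] > lo) & (df["length"] <= lo + fine_width)]
            if len(sub):
                groups.append((f"len({lo},{lo + fine_width}]", sub))
            lo += fine_width
    if by_family and "family" in df.columns:
        for fam, sub in df.groupby("family"):
            groups.append((f"family:{fam}", sub))

    rows = []
    for name, sub in groups:
        row = {"group": name, "n": len(sub)}
        for col in ("precision", "recall", "f1", "inf"):
            row[f"{col}_mean"] = float(sub[col].mean())
            row[f"{col}_sd"] = float(sub[col].std(ddof=0))
        rows.append(row)
    return pd.DataFrame(rows)
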