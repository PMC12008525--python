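"""Data augmentation for labeled RNA samples: adding noise, removing, and
inserting — always restricted to bases that form no base pairs.

Large random edits would change the true structure unpredictably, so each
operator makes small edits confined to unpaired bases, and the label is
transformed mechanically: noise keeps S unchanged, removal deletes the
corresponding rows/columns, insertion adds zero rows/columns. Selection
counts use round-half-up of ``p * |B|`` (or ``p * L`` for insertion) so the
expected edit count tracks the configured percentage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ContractError, ValidityError
from .formats import ALPHABET, MIN_SEPARATION, RnaSequence
from .structcore import audit_validity

Sample = tuple[RnaSequence, np.ndarray]


@dataclass(frozen=True)
class AugmentConfig:
    """Augmentation settings; the default percentages are 10% each and two
    repetitions per gated sample (2 x 3 operators = 6 augmented samples),
    with the length gate admitting only longer samples (150 < L <= 500)."""

    p_noise: float = 0.10
    p_remove: float = 0.10
    p_insert: float = 0.10
    repetitions: int = 2
    min_len: int = 150
    max_len: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_noise", "p_remove", "p_insert"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ContractError(f"{name} must be in [0, 1], got {v}")
        if self.repetitions < 0:
            raise ContractError("repetitions must be >= 0")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _validate(sample: Sample) -> tuple[RnaSequence, np.ndarray]:
    seq, S = sample
    S = np.asarray(S)
    if S.shape != (seq.length, seq.length):
        raise ContractError(f"structure shape {S.shape} != L={seq.length}")
    bad = [v for v in audit_validity(S) if v.is_error]
    if bad:
        raise ValidityError(str(bad[0]))
    return seq, S


def unpaired_indices(S: np.ndarray) -> np.ndarray:
    """Sorted indices of bases whose structure-matrix row is all zero."""
    return np.nonzero(np.asarray(S).sum(axis=1) == 0)[0]


def add_noise(sample: Sample, p1: float, rng: np.random.Generator) -> Sample:
    """Mutate round(p1 * |B|) unpaired bases, each to a different base chosen
    uniformly from the 3 alternatives. The structure is unchanged."""
    seq, S = _validate(sample)
    B = unpaired_indices(S)
    k = _round_half_up(p1 * len(B))
    if k == 0:
        return RnaSequence(seq.identifier, seq.bases), S.copy()
    sites = rng.choice(B, size=k, replace=False)
    bases = list(seq.bases)
    for i in sites:
        alternatives = [b for b in ALPHABET if b != bases[i]]
        bases[i] = alternatives[rng.integers(0, 3)]
    return RnaSequence(seq.identifier, "".join(bases)), S.copy()


def _pairs_after_deletion(S: np.ndarray, removed: set[int]) -> list[tuple[int, int]]:
    """Surviving pair coordinates after deleting the given indices."""
    keep = [i for i in range(S.shape[0]) if i not in removed]
    new_index = {old: new for new, old in enumerate(keep)}
    ii, jj = np.nonzero(np.triu(S))
    return [(new_index[int(i)], new_index[int(j)]) for i, j in zip(ii, jj)]


def remove_bases(sample: Sample, p2: float, p1: float,
                 rng: np.random.Generator, max_attempts: int = 1000) -> Sample:
    """Delete round(p2 * |B|) unpaired bases, shift the structure, then add
    noise at rate p1 over the new unpaired set.

    A candidate deletion that would squeeze a surviving pair below the
    minimum separation (e.g. shrinking a hairpin loop under 3 bases) is
    resampled; if the target count is infeasible a :class:`ContractError`
    is raised after ``max_attempts`` draws.
    """
    seq, S = _validate(sample)
    B = list(unpaired_indices(S))
    k = _round_half_up(p2 * len(B))
    removed: set[int] = set()
    pool = list(B)
    attempts = 0
    while len(removed) < k:
        if not pool or attempts >= max_attempts:
            raise ContractError(
                f"cannot delete {k} unpaired bases without creating a sharp loop"
            )
        attempts += 1
        cand = pool[rng.integers(0, len(pool))]
        trial = removed | {int(cand)}
        if all(j - i >= MIN_SEPARATION for i, j in _pairs_after_deletion(S, trial)):
            removed = trial
            pool.remove(cand)
    keep = [i for i in range(seq.length) if i not in removed]
    new_bases = "".join(seq.bases[i] for i in keep)
    new_S = S[np.ix_(keep, keep)]
    return add_noise((RnaSequence(seq.identifier, new_bases), new_S), p1, rng)


def insert_bases(sample: Sample, p3: float, p1: float,
                 rng: np.random.Generator) -> Sample:
    """Insert round(p3 * L) random bases at distinct inter-base gaps, insert
    zero rows/columns into the structure, then add noise at rate p1."""
    seq, S = _validate(sample)
    L = seq.length
    k = _round_half_up(p3 * L)
    if k == 0:
        return add_noise(sample, p1, rng)
    gaps = rng.choice(L + 1, size=k, replace=False)  # gap g inserts before base g
    bases = list(seq.bases)
    new_L = L + k
    new_S = np.zeros((new_L, new_L), dtype=S.dtype)
    # old index i lands at i + (number of chosen gaps <= i)
    shift = np.searchsorted(np.sort(gaps), np.arange(L), side="right")
    dest = np.arange(L) + shift
    new_S[np.ix_(dest, dest)] = S
    out = [None] * new_L
    for i, d in enumerate(dest):
        out[d] = bases[i]
    for g in range(new_L):
        if out[g] is None:
            out[g] = ALPHABET[rng.integers(0, 4)]
    return add_noise((RnaSequence(seq.identifier, "".join(out)), new_S), p1, rng)


def augment_dataset(samples: list[Sample], cfg: AugmentConfig) -> list[Sample]:
    """Apply all three operators ``cfg.repetitions`` times to every sample
    passing the length gate, appending the augmented samples to the
    originals. Augmented identifiers record operator, repetition and seed.
    """
    rng = np.random.default_rng(cfg.seed)
    out = list(samples)
    ops = (("noise", lambda s, r: add_noise(s, cfg.p_noise, r)),
           ("remove", lambda s, r: remove_bases(s, cfg.p_remove, cfg.p_noise, r)),
           ("insert", lambda s, r: insert_bases(s, cfg.p_insert, cfg.p_noise, r)))
    for seq, S in samples:
        if not (cfg.min_len < seq.length <= cfg.max_len):
            continue
        for rep in range(cfg.repetitions):
            for op_name, op in ops:
                new_seq, new_S = op((seq, S), rng)
                tagged = RnaSequence(
                    f"{seq.identifier}|{op_name}|rep{rep}|seed{cfg.seed}", new_seq.bases
                )
                out.append((tagged, new_S))
    return out
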