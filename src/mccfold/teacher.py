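"""Knowledge merge: random sequence synthesis, teacher folding, and the
same-prediction-ratio statistic.

A deep model trained only on real families generalizes poorly to unseen
families. Knowledge merge sidesteps this by synthesizing random sequences
over a length range [L1, L2], labeling each with the prediction of a
classical folding method (the *teacher*), and using those sequence-prediction
pairs as supplementary training samples. The teacher's knowledge is treated
abstractly as a deterministic mapping from sequences to valid structures;
any folding program satisfying that contract can serve.

The built-in teacher is a base-pair-maximization dynamic program
(Nussinov-style) over canonical + wobble pairs with the sharp-loop minimum
separation, so its labels are valid by construction. An adapter for external
folders (LinearFold, RNAstructure, CONTRAfold, ...) is provided for users
who have one installed.
"""

from __future__ import annotations

import shlex
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np

from .errors import ContractError, TeacherError, ValidityError
from .formats import (ALPHABET, MIN_SEPARATION, PairMap, RnaSequence,
                      pairs_to_matrix, parse_dotbracket, read_ct)
from .structcore import audit_validity

#: Pairings the built-in teacher may form (canonical + wobble).
ALLOWED_PAIRS = frozenset(
    {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")}
)


@dataclass(frozen=True)
class SynthesisConfig:
    """Random-synthesis settings.

    Defaults mirror the study conditions: lengths uniform on [50, 500] and
    30,000 synthesized samples. Desk-scale runs pass smaller values.
    """

    min_len: int = 50
    max_len: int = 500
    n: int = 30_000
    seed: int = 0
    teacher: str = "builtin"

    def __post_init__(self) -> None:
        if not (1 <= self.min_len <= self.max_len):
            raise ContractError(f"need 1 <= L1 <= L2, got [{self.min_len}, {self.max_len}]")
        if self.n < 1:
            raise ContractError("n must be positive")


def synthesize_sequence(min_len: int, max_len: int, rng: np.random.Generator,
                        name: str = "synthetic") -> RnaSequence:
    """One random sequence: length uniform on [min_len, max_len], bases
    i.i.d. uniform over {A, U, C, G}."""
    if not (1 <= min_len <= max_len):
        raise ContractError(f"invalid length bounds [{min_len}, {max_len}]")
    L = int(rng.integers(min_len, max_len + 1))
    return RnaSequence(name, "".join(ALPHABET[k] for k in rng.integers(0, 4, size=L)))


# ---------------------------------------------------------------------------
# Built-in dynamic-programming teacher
# ---------------------------------------------------------------------------


def nussinov_fold(seq: RnaSequence, min_sep: int = MIN_SEPARATION,
                  allowed_pairs: frozenset = ALLOWED_PAIRS) -> np.ndarray:
    """Maximum-cardinality non-crossing folding by dynamic programming.

    ``N[i][j]`` is the maximum number of allowed, non-crossing pairs in the
    subsequence [i, j] subject to ``j - i >= min_sep`` for each pair.
    Traceback is deterministic: the pairing branch is preferred over leaving
    base i unpaired, and among pairing partners the smallest index wins, so
    the same sequence always maps to the same structure.
    """
    b = seq.bases
    L = len(b)
    enc = np.frombuffer(b.encode(), dtype=np.uint8)
    allow = np.zeros((256, 256), dtype=bool)
    for x, y in allowed_pairs:
        allow[ord(x), ord(y)] = True
    can_pair = allow[enc[:, None], enc[None, :]]  # (L, L)

    N = np.zeros((L + 1, L + 1), dtype=np.int64)
    # choice[i][j]: -1 = leave i unpaired, else the partner k of i
    choice = np.full((L + 1, L + 1), -1, dtype=np.int64)
    # Anti-diagonal vectorization: for each span, sweep the partner offset d
    # (ascending, strict improvement) so the smallest partner index wins ties.
    for span in range(min_sep, L):
        ii = np.arange(L - span)
        best_pair = np.full(L - span, -1, dtype=np.int64)
        pick = np.full(L - span, -1, dtype=np.int64)
        for d in range(min_sep, span + 1):
            cand = 1 + N[ii + 1, ii + d - 1] + N[ii + d + 1, ii + span]
            ok = can_pair[ii, ii + d] & (cand > best_pair)
            best_pair = np.where(ok, cand, best_pair)
            pick = np.where(ok, ii + d, pick)
        skip = N[ii + 1, ii + span]
        take = (pick != -1) & (best_pair >= skip)  # prefer pairing on ties
        N[ii, ii + span] = np.where(take, best_pair, skip)
        choice[ii, ii + span] = np.where(take, pick, -1)
    pairs = set()
    stack = [(0, L - 1)]
    while stack:
        i, j = stack.pop()
        if j - i < min_sep:
            continue
        k = choice[i, j]
        if k == -1:
            stack.append((i + 1, j))
        else:
            pairs.add((i, int(k)))
            stack.append((i + 1, int(k) - 1))
            stack.append((int(k) + 1, j))
    pm = PairMap(L, frozenset(frozenset(p) for p in pairs))
    return pairs_to_matrix(pm)


def enumerate_structures(seq: RnaSequence, min_sep: int = MIN_SEPARATION,
                         allowed_pairs: frozenset = ALLOWED_PAIRS):
    """Exhaustively enumerate all non-crossing valid structures (pair sets).

    Exponential; usable only for short sequences (L <= ~16). This is the
    independent oracle for :func:`nussinov_fold`'s optimality.
    """
    b = seq.bases
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def structs(i: int, j: int) -> tuple[frozenset, ...]:
        if j - i < min_sep:
            return (frozenset(),)
        out = set(structs(i + 1, j))  # i unpaired
        for k in range(i + min_sep, j + 1):
            if (b[i], b[k]) in allowed_pairs:
                for left in structs(i + 1, k - 1):
                    for right in structs(k + 1, j):
                        out.add(left | right | {(i, k)})
        return tuple(out)

    return structs(0, len(b) - 1)


# ---------------------------------------------------------------------------
# Teacher contract and adapters
# ---------------------------------------------------------------------------

TeacherKnowledge = Callable[[RnaSequence], np.ndarray]


def _check_label(seq: RnaSequence, S: np.ndarray) -> np.ndarray:
    if S.shape != (seq.length, seq.length):
        raise TeacherError(
            f"teacher output shape {S.shape} does not match L={seq.length}"
        )
    bad = [v for v in audit_validity(S) if v.is_error]
    if bad:
        raise TeacherError("teacher output invalid: " + "; ".join(map(str, bad)))
    return S


def builtin_teacher(seq: RnaSequence) -> np.ndarray:
    """The built-in DP folder wrapped as a TeacherKnowledge mapping."""
    return _check_label(seq, nussinov_fold(seq))


def external_teacher(command_template: str) -> TeacherKnowledge:
    """Wrap an external folding executable as a TeacherKnowledge mapping.

    ``command_template`` contains ``{fasta}`` (replaced by a temporary FASTA
    path); the command must print a dot-bracket structure (optionally with
    sequence/header lines) or a CT file path on stdout. Any failure raises
    :class:`TeacherError` with the captured output. Never required by the
    test suite.
    """

    def fold(seq: RnaSequence) -> np.ndarray:
        with tempfile.TemporaryDirectory() as tmp:
            fa = Path(tmp) / "in.fa"
            fa.write_text(f">{seq.identifier}\n{seq.bases}\n")
            cmd = command_template.format(fasta=fa)
            try:
                proc = subprocess.run(
                    shlex.split(cmd), capture_output=True, text=True, timeout=300
                )
            except (OSError, subprocess.TimeoutExpired) as exc:
                raise TeacherError(f"teacher command failed: {cmd}: {exc}") from exc
            if proc.returncode != 0:
                raise TeacherError(
                    f"teacher exited {proc.returncode}: {proc.stderr.strip()[:500]}"
                )
            return _check_label(seq, _parse_teacher_output(seq, proc.stdout))

    return fold


def _parse_teacher_output(seq: RnaSequence, out: str) -> np.ndarray:
    text = out.strip()
    if not text:
        raise TeacherError("teacher produced no output")
    if text.endswith(".ct") and Path(text).exists():
        _, pm = read_ct(text)
        return pairs_to_matrix(pm)
    # find a structure line of the right length made of dots/brackets
    for line in text.splitlines():
        line = line.strip().split()[0] if line.strip() else ""
        if len(line) == seq.length and set(line) <= set(".()[]{}<>"):
            try:
                _, pm = parse_dotbracket(f"{seq.bases}\n{line}")
            except Exception as exc:
                raise TeacherError(f"unparseable dot-bracket {line!r}: {exc}") from exc
            return pairs_to_matrix(pm)
    raise TeacherError(
        f"no dot-bracket line of length {seq.length} in teacher output: {text[:200]!r}"
    )


def generate_teacher_set(
    cfg: SynthesisConfig, teacher: TeacherKnowledge | None = None
) -> list[tuple[RnaSequence, np.ndarray]]:
    """Synthesize ``cfg.n`` random sequences and label each with the teacher.

    Reproducible from ``cfg.seed``; every label is validity-audited. Teacher
    failures abort with the failing sequence named.
    """
    teacher = teacher or builtin_teacher
    rng = np.random.default_rng(cfg.seed)
    out = []
    for k in range(cfg.n):
        seq = synthesize_sequence(cfg.min_len, cfg.max_len, rng, name=f"synthetic_{k}")
        try:
            S = teacher(seq)
        except TeacherError as exc:
            raise TeacherError(f"teacher failed on {seq.identifier}: {exc}") from exc
        out.append((seq, _check_label(seq, S)))
    return out


def same_prediction_ratio(pred_a: np.ndarray, pred_b: np.ndarray) -> float:
    """Fraction of bases whose predicted partner (or 'unpaired') agrees.

    Each base's prediction is its partner index, or 'unpaired' when its row
    is all zero; the ratio counts bases with identical predictions in both
    matrices, over all L bases.
    """
    A, B = np.asarray(pred_a), np.asarray(pred_b)
    if A.shape != B.shape or A.ndim != 2:
        raise ContractError(f"shape mismatch: {A.shape} vs {B.shape}")
    for name, M in (("first", A), ("second", B)):
        bad = [v for v in audit_validity(M) if v.is_error]
        if bad:
            raise ValidityError(f"{name} prediction invalid: {bad[0]}")
    pa = np.where(A.sum(axis=1) > 0, A.argmax(axis=1), -1)
    pb = np.where(B.sum(axis=1) > 0, B.argmax(axis=1), -1)
    return float(np.mean(pa == pb))
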