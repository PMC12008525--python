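"""Sequence and structure interchange: FASTA, CT, dot-bracket, and the
pair-list / contact-matrix duality.

An RNA secondary structure is represented two ways:

* :class:`PairMap` — a set of unordered 0-based index pairs ``{i, j}``, each
  index in at most one pair, with the steric minimum separation
  ``|i - j| >= MIN_SEPARATION`` (a hairpin loop needs at least 3 unpaired
  bases between the arms of a stem).
* :class:`StructureMatrix` (see :mod:`mccfold.structcore` for the validity
  auditor) — the equivalent L x L binary contact matrix ``S`` with
  ``S[i, j] = 1`` iff bases i and j pair.

Indexing is 0-based everywhere in memory; the 1-based convention of the CT
format exists only at the file boundary.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

from .errors import ContractError, FormatError, ValidityError

#: Minimum sequence separation of a base pair: |i - j| >= 4 (no sharp loops).
MIN_SEPARATION = 4

#: The RNA alphabet. FASTA input is normalized (T->U, lowercase->uppercase)
#: before validation.
ALPHABET = "AUCG"

_BRACKET_FAMILIES = [("(", ")"), ("[", "]"), ("{", "}"), ("<", ">")]


@dataclass(frozen=True)
class RnaSequence:
    """An RNA sequence: an identifier and a string over {A, U, C, G}."""

    identifier: str
    bases: str

    def __post_init__(self) -> None:
        bad = set(self.bases) - set(ALPHABET)
        if bad:
            raise FormatError(
                f"sequence {self.identifier!r} contains non-AUCG characters "
                f"after normalization: {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.bases)

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class PairMap:
    """A secondary structure as a set of unordered 0-based index pairs.

    Pseudoknots (crossing pairs) are representable; the constraints are only
    that each index pairs at most once, partners are at least
    :data:`MIN_SEPARATION` apart, and indices lie in ``[0, length)``.
    """

    length: int
    pairs: frozenset[frozenset[int]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValidityError(f"length must be positive, got {self.length}")
        object.__setattr__(
            self, "pairs", frozenset(frozenset(p) for p in self.pairs)
        )
        seen: set[int] = set()
        for pair in self.pairs:
            if len(pair) != 2:
                raise ValidityError(f"pair {set(pair)} is not two distinct indices")
            i, j = sorted(pair)
            if i < 0 or j >= self.length:
                raise ValidityError(f"pair ({i}, {j}) out of range [0, {self.length})")
            if j - i < MIN_SEPARATION:
                raise ValidityError(
                    f"pair ({i}, {j}) violates minimum separation {MIN_SEPARATION}"
                )
            if i in seen or j in seen:
                raise ValidityError(f"index appears in more than one pair: ({i}, {j})")
            seen.update((i, j))

    def partner_array(self) -> np.ndarray:
        """Partner index per base, -1 for unpaired."""
        partner = np.full(self.length, -1, dtype=np.int64)
        for pair in self.pairs:
            i, j = sorted(pair)
            partner[i], partner[j] = j, i
        return partner

    def as_tuples(self) -> list[tuple[int, int]]:
        """Sorted (i, j) tuples with i < j."""
        return sorted(tuple(sorted(p)) for p in self.pairs)


def _normalize_bases(raw: str, identifier: str) -> str:
    bases = raw.strip().upper().replace("T", "U")
    bad = set(bases) - set(ALPHABET)
    if bad:
        raise FormatError(
            f"record {identifier!r}: non-AUCGT characters {sorted(bad)}"
        )
    return bases


def read_fasta(path) -> list[RnaSequence]:
    """Read a (multi-record) FASTA file into :class:`RnaSequence` objects.

    Lowercase letters are uppercased and T is mapped to U before validation,
    so DNA-alphabet FASTA is accepted. Any other character is a
    :class:`FormatError` naming the offending record.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(RnaSequence(rec.id, _normalize_bases(str(rec.seq), rec.id)))
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(seqs: list[RnaSequence], path) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.identifier}\n{s.bases}\n")


# ---------------------------------------------------------------------------
# CT (connectivity table)
#
# Dialect: first line is a header whose first token is L (extra tokens are
# treated as a free-text title); then L lines of 6 whitespace-separated
# columns: index, base, prev, next, partner (0 = unpaired), index. 1-based.
# ---------------------------------------------------------------------------


def read_ct(path) -> tuple[RnaSequence, PairMap]:
    """Read a 6-column CT file; returns the sequence and its 0-based pairs.

    Raises :class:`FormatError` with a line number for asymmetric partner
    columns, out-of-range partners, or malformed rows.
    """
    with open(path) as fh:
        lines = [ln for ln in fh.read().splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty CT file")
    header = lines[0].split()
    try:
        length = int(header[0])
    except (ValueError, IndexError):
        raise FormatError(f"{path}: CT header must start with the length") from None
    title = " ".join(header[1:]) or "structure"
    if len(lines) - 1 < length:
        raise FormatError(f"{path}: header says {length} bases, found {len(lines) - 1} rows")

    bases = []
    partner = np.zeros(length, dtype=np.int64)
    for k in range(length):
        lineno = k + 2
        cols = lines[k + 1].split()
        if len(cols) < 6:
            raise FormatError(f"{path}:{lineno}: expected 6 columns, got {len(cols)}")
        idx, base, pj = int(cols[0]), cols[1], int(cols[4])
        if idx != k + 1:
            raise FormatError(f"{path}:{lineno}: index {idx}, expected {k + 1}")
        if pj < 0 or pj > length:
            raise FormatError(f"{path}:{lineno}: partner {pj} out of range")
        bases.append(base)
        partner[k] = pj

    # symmetry of the partner column, reported at the later line
    for k in range(length):
        pj = partner[k]
        if pj != 0 and partner[pj - 1] != k + 1:
            bad = max(k, pj - 1) + 2
            raise FormatError(
                f"{path}:{bad}: partner columns disagree "
                f"(base {k + 1} -> {pj}, base {pj} -> {partner[pj - 1]})"
            )

    seq = RnaSequence(title.split()[0] if title else "structure",
                      _normalize_bases("".join(bases), title))
    pairs = frozenset(
        frozenset((k, int(partner[k]) - 1)) for k in range(length) if partner[k] > k + 1
    )
    try:
        pm = PairMap(length, pairs)
    except ValidityError as exc:
        raise FormatError(f"{path}: invalid structure: {exc}") from exc
    return seq, pm


def write_ct(seq: RnaSequence, pm: PairMap, path) -> None:
    """Write a 6-column CT file. Inverse of :func:`read_ct`."""
    if pm.length != seq.length:
        raise ContractError(
            f"length mismatch: sequence {seq.length}, structure {pm.length}"
        )
    partner = pm.partner_array()
    with open(path, "w") as fh:
        fh.write(f"{seq.length} {seq.identifier}\n")
        for k, base in enumerate(seq.bases):
            fh.write(
                f"{k + 1} {base} {k} {k + 2} {int(partner[k]) + 1} {k + 1}\n"
            )


# ---------------------------------------------------------------------------
# pair list <-> contact matrix
# ---------------------------------------------------------------------------


def pairs_to_matrix(pm: PairMap) -> np.ndarray:
    """The L x L binary contact matrix of a pair map."""
    S = np.zeros((pm.length, pm.length), dtype=np.int8)
    for pair in pm.pairs:
        i, j = sorted(pair)
        S[i, j] = S[j, i] = 1
    return S


def matrix_to_pairs(S: np.ndarray) -> PairMap:
    """Inverse of :func:`pairs_to_matrix`; validates the matrix first."""
    from .structcore import audit_validity  # cycle-free: structcore imports nothing here

    violations = [v for v in audit_validity(S) if v.is_error]
    if violations:
        raise ValidityError(
            "matrix violates structure constraints: "
            + "; ".join(str(v) for v in violations)
        )
    ii, jj = np.nonzero(np.triu(S))
    return PairMap(S.shape[0], frozenset(frozenset((int(i), int(j))) for i, j in zip(ii, jj)))


# ---------------------------------------------------------------------------
# dot-bracket with pseudoknot tiers
# ---------------------------------------------------------------------------


def _crossing(a: tuple[int, int], b: tuple[int, int]) -> bool:
    (i, j), (k, l) = a, b
    return (i < k < j < l) or (k < i < l < j)


def _max_noncrossing_subset(pairs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """A maximum-cardinality non-crossing subset of disjoint pairs.

    Nussinov-style interval DP restricted to the given pair set, with a
    deterministic traceback (prefer pairing, then the leftmost partner), so
    tier decomposition is reproducible.
    """
    if not pairs:
        return []
    L = max(j for _, j in pairs) + 1
    partner = {}
    for i, j in pairs:
        partner[i] = j
    N = np.zeros((L + 1, L + 1), dtype=np.int64)
    for span in range(1, L):
        for i in range(L - span):
            j = i + span
            best = N[i + 1, j]
            k = partner.get(i)
            if k is not None and i < k <= j:
                best = max(best, 1 + N[i + 1, k - 1] + N[k + 1, j])
            N[i, j] = best
    out: list[tuple[int, int]] = []
    stack = [(0, L - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j:
            continue
        k = partner.get(i)
        if k is not None and i < k <= j and N[i, j] == 1 + N[i + 1, k - 1] + N[k + 1, j]:
            out.append((i, k))
            stack.append((i + 1, k - 1))
            stack.append((k + 1, j))
        else:
            stack.append((i + 1, j))
    return out


def write_dotbracket(seq: RnaSequence, pm: PairMap) -> str:
    """Render a structure as dot-bracket text, one bracket family per
    pseudoknot tier (greedy decomposition: repeatedly extract a maximum
    non-crossing subset).

    Raises :class:`FormatError` when more than four mutually crossing tiers
    would be needed; such structures fall back to CT.
    """
    if pm.length != seq.length:
        raise ContractError("sequence and structure lengths differ")
    remaining = pm.as_tuples()
    symbols = ["."] * pm.length
    tier = 0
    while remaining:
        if tier >= len(_BRACKET_FAMILIES):
            raise FormatError(
                "structure needs more than 4 pseudoknot tiers; use CT instead"
            )
        subset = _max_noncrossing_subset(remaining)
        op, cl = _BRACKET_FAMILIES[tier]
        for i, j in subset:
            symbols[i], symbols[j] = op, cl
        chosen = set(subset)
        remaining = [p for p in remaining if p not in chosen]
        tier += 1
    return f">{seq.identifier}\n{seq.bases}\n{''.join(symbols)}\n"


def parse_dotbracket(text: str) -> tuple[RnaSequence, PairMap]:
    """Parse dot-bracket text (all four bracket families) back to a pair map.

    Accepts the three-line form emitted by :func:`write_dotbracket` or a bare
    two-line sequence/structure pair.
    """
    lines = [ln.strip() for ln in io.StringIO(text) if ln.strip()]
    if not lines:
        raise FormatError("empty dot-bracket text")
    if lines[0].startswith(">"):
        ident, lines = lines[0][1:].strip() or "structure", lines[1:]
    else:
        ident = "structure"
    if len(lines) != 2:
        raise FormatError("expected a sequence line and a structure line")
    bases, struct = lines
    if len(bases) != len(struct):
        raise FormatError(
            f"sequence length {len(bases)} != structure length {len(struct)}"
        )
    opens = {op: [] for op, _ in _BRACKET_FAMILIES}
    closer_of = {cl: op for op, cl in _BRACKET_FAMILIES}
    pairs = set()
    for k, ch in enumerate(struct):
        if ch == ".":
            continue
        if ch in opens:
            opens[ch].append(k)
        elif ch in closer_of:
            stack = opens[closer_of[ch]]
            if not stack:
                raise FormatError(f"unmatched {ch!r} at position {k}")
            pairs.add(frozenset((stack.pop(), k)))
        else:
            raise FormatError(f"unknown structure character {ch!r} at position {k}")
    for op, stack in opens.items():
        if stack:
            raise FormatError(f"unmatched {op!r} at position {stack[-1]}")
    seq = RnaSequence(ident, _normalize_bases(bases, ident))
    return seq, PairMap(len(bases), frozenset(pairs))
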