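"""Deterministic synthetic RNA samples with known valid structures.

Hairpins, two-stem structures and H-type pseudoknot toys, generated with
complementary stem bases (AU/UA/CG/GC/GU/UG drawn uniformly) so that the
pairing signal is learnable by a small model, the way real stems obey
pairing chemistry. Loop and linker bases are uniform over {A, U, C, G}.
Loops are at least 3 bases so the innermost pair of every stem satisfies
the minimum-separation rule.

These generators exist so every other module is testable without any
downloaded dataset; they do not emulate thermodynamic ensembles or
family-specific base composition.
"""

from __future__ import annotations

import numpy as np

from .errors import ContractError
from .formats import ALPHABET, PairMap, RnaSequence, pairs_to_matrix
from .structcore import audit_validity

#: Complementary stem pairs (canonical + wobble), drawn uniformly.
STEM_PAIRS = [("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")]


def _random_bases(n: int, rng: np.random.Generator) -> list[str]:
    return [ALPHABET[k] for k in rng.integers(0, 4, size=n)]


def _build(name: str, slots: list[str | None], pairs: set[tuple[int, int]],
           rng: np.random.Generator) -> tuple[RnaSequence, np.ndarray]:
    """Fill unpaired slots with random bases, paired slots with complements."""
    bases = list(slots)
    for i, j in pairs:
        bi, bj = STEM_PAIRS[rng.integers(0, len(STEM_PAIRS))]
        bases[i], bases[j] = bi, bj
    for k, b in enumerate(bases):
        if b is None:
            bases[k] = _random_bases(1, rng)[0]
    seq = RnaSequence(name, "".join(bases))
    pm = PairMap(len(bases), frozenset(frozenset(p) for p in pairs))
    S = pairs_to_matrix(pm)
    assert not [v for v in audit_validity(S) if v.is_error]
    return seq, S


def make_hairpin(stem: int, loop: int, rng: np.random.Generator,
                 name: str = "hairpin") -> tuple[RnaSequence, np.ndarray]:
    """A single stem-loop: L = 2*stem + loop, pairs {i, L-1-i} for i < stem.

    ``loop`` must be >= 3 so the innermost pair has separation >= 4.
    """
    if loop < 3:
        raise ContractError(f"loop must be >= 3 (got {loop}): sharp-loop rule")
    if stem < 1:
        raise ContractError(f"stem must be >= 1 (got {stem})")
    L = 2 * stem + loop
    pairs = {(i, L - 1 - i) for i in range(stem)}
    return _build(name, [None] * L, pairs, rng)


def make_two_stem(stems: tuple[int, int], loops: tuple[int, int], linker: int,
                  rng: np.random.Generator, name: str = "two_stem") -> tuple[RnaSequence, np.ndarray]:
    """Two sequential hairpins joined by a linker."""
    (s1, s2), (l1, l2) = stems, loops
    if min(l1, l2) < 3:
        raise ContractError("loops must be >= 3")
    off = 2 * s1 + l1 + linker
    L = off + 2 * s2 + l2
    pairs = {(i, 2 * s1 + l1 - 1 - i) for i in range(s1)}
    pairs |= {(off + i, L - 1 - i - (0)) for i in range(s2)}
    return _build(name, [None] * L, pairs, rng)


def make_pseudoknot(s1: int, s2: int, loops: tuple[int, int, int],
                    rng: np.random.Generator, name: str = "pseudoknot") -> tuple[RnaSequence, np.ndarray]:
    """An H-type pseudoknot: two stems whose pairs cross.

    Layout: A (s1) | g1 | B (s2) | g2 | A' (s1) | g3 | B' (s2), where A pairs
    with A' and B pairs with B' in the usual nested (reversed) orientation.
    Geometry must keep every pair separation >= 4.
    """
    g1, g2, g3 = loops
    a0 = 0
    b0 = s1 + g1
    a1 = b0 + s2 + g2              # start of A'
    b1 = a1 + s1 + g3              # start of B'
    L = b1 + s2
    pairs = {(a0 + i, a1 + s1 - 1 - i) for i in range(s1)}
    pairs |= {(b0 + i, b1 + s2 - 1 - i) for i in range(s2)}
    if any(abs(i - j) < 4 for i, j in pairs):
        raise ContractError("pseudoknot geometry violates minimum separation; widen the loops")
    seq, S = _build(name, [None] * L, pairs, rng)
    return seq, S


def has_crossing(pm: PairMap) -> bool:
    """True iff some two pairs cross (i < k < j < l)."""
    ts = pm.as_tuples()
    return any(
        (a[0] < b[0] < a[1] < b[1]) or (b[0] < a[0] < b[1] < a[1])
        for x, a in enumerate(ts) for b in ts[x + 1:]
    )


def make_dataset(
    n: int,
    rng: np.random.Generator,
    motif: str = "hairpin",
    stem_range: tuple[int, int] = (3, 10),
    loop_range: tuple[int, int] = (3, 10),
) -> list[tuple[RnaSequence, np.ndarray]]:
    """A reproducible list of labeled samples.

    ``motif`` is one of ``hairpin``, ``two_stem``, ``pseudoknot`` or ``mix``.
    Default geometry keeps L well under 64 so desk-scale models train fast.
    """
    if n < 1:
        raise ContractError("n must be >= 1")
    kinds = ["hairpin", "two_stem", "pseudoknot"] if motif == "mix" else [motif]
    out = []
    for k in range(n):
        kind = kinds[k % len(kinds)]
        s = int(rng.integers(stem_range[0], stem_range[1] + 1))
        l = int(rng.integers(loop_range[0], loop_range[1] + 1))
        if kind == "hairpin":
            out.append(make_hairpin(s, l, rng, name=f"hairpin_{k}"))
        elif kind == "two_stem":
            s2 = int(rng.integers(stem_range[0], stem_range[1] + 1))
            out.append(make_two_stem((s, s2), (l, max(3, l - 1)),
                                     int(rng.integers(1, 5)), rng, name=f"two_stem_{k}"))
        elif kind == "pseudoknot":
            out.append(make_pseudoknot(max(2, s // 2), max(2, s // 2),
                                       (l, max(4, l), l), rng, name=f"pseudoknot_{k}"))
        else:
            raise ContractError(f"unknown motif {motif!r}")
    return out
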