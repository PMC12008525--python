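import numpy as np
import pytest

from mccfold.formats import MIN_SEPARATION, PairMap, RnaSequence


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_pairmap(L: int, rng: np.random.Generator, allow_crossing: bool = True) -> PairMap:
    """A random valid pair map: a non-crossing backbone plus (optionally) up
    to two extra crossing pairs, mimicking realistic pseudoknot complexity."""
    free = list(range(L))
    pairs: set[tuple[int, int]] = set()

    def crosses_existing(i: int, j: int) -> bool:
        return any(a < i < b < j or i < a < j < b for a, b in pairs)

    for _ in range(int(rng.integers(0, max(2, L // 2)))):
        if len(free) < 2:
            break
        i, j = sorted(rng.choice(free, size=2, replace=False))
        if j - i < MIN_SEPARATION or crosses_existing(i, j):
            continue
        pairs.add((int(i), int(j)))
        free.remove(i)
        free.remove(j)
    if allow_crossing:
        for _ in range(int(rng.integers(0, 3))):
            if len(free) < 2:
                break
            i, j = sorted(rng.choice(free, size=2, replace=False))
            if j - i < MIN_SEPARATION:
                continue
            pairs.add((int(i), int(j)))
            free.remove(i)
            free.remove(j)
    return PairMap(L, frozenset(frozenset(p) for p in pairs))


def random_sequence(L: int, rng: np.random.Generator, name: str = "seq") -> RnaSequence:
    return RnaSequence(name, "".join("AUCG"[k] for k in rng.integers(0, 4, size=L)))
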