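"""The diagonal-filled label and the weighted cross-entropy.

A 5-base toy with one pair {0, 4}: the label transform puts a '1' on the
diagonal of every unpaired base, making each row a one-hot L-class target.
Against a uniform prediction, the paired rows contribute ln 5 each and the
three unpaired rows are down-weighted by (5 - 3)/3.
"""

import math

import numpy as np

from mccfold import modify_label, pairs_to_matrix, weighted_cross_entropy
from mccfold.formats import PairMap

S = pairs_to_matrix(PairMap(5, frozenset({frozenset({0, 4})})))
label = modify_label(S)
print("modified label (a symmetric permutation matrix):")
print(label)

uniform = np.full((5, 5), 0.2)
loss = weighted_cross_entropy(uniform, label)
print(f"weighted cross-entropy vs uniform: {loss:.5f}")
print(f"closed form (4/5) ln 5          : {0.8 * math.log(5):.5f}")
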