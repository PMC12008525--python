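"""The three augmentation operators on a long hairpin.

Noise, removal and insertion each touch only unpaired bases; the structure
label is carried over (noise), row/column-deleted (removal) or zero-row/
column-extended (insertion). A gated sample (150 < L <= 500) with two
repetitions yields six augmented samples.
"""

import numpy as np

from mccfold import AugmentConfig, augment_dataset
from mccfold.fixtures import make_hairpin
from mccfold.formats import matrix_to_pairs

rng = np.random.default_rng(0)
sample = make_hairpin(80, 40, rng, name="long_hairpin")  # L = 200
out = augment_dataset([sample], AugmentConfig(seed=1))

print(f"1 original -> {len(out)} samples")
for seq, S in out:
    n_pairs = len(matrix_to_pairs(S).pairs)
    print(f"  {seq.identifier:40s} L={seq.length:3d} pairs={n_pairs}")
# Lengths shift by round(0.1 * |B|) for removal and round(0.1 * L) for
# insertion; the 80 stem pairs are conserved by every operator.
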