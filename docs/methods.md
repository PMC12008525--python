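# Methods

## Representation and validity constraints

A structure over L bases is an L×L binary contact matrix S (`formats`,
`structcore`). Validity means: binary entries; symmetry; at most one '1'
per row and per column; and no entries with |i − j| < 4 (the sharp-loop
band, which subsumes a zero diagonal). Pairing chemistry (canonical AU/CG
and wobble GU versus non-canonical pairs) is deliberately **not** enforced
anywhere: non-canonical pairs occur in real structures and reference
datasets are noisy, so the auditor reports non-canonical pairings as
informational findings only and the decoder applies no chemistry mask; the
model is left to learn pairing preferences from data. Internally all
indices are 0-based; the CT format's 1-based convention exists only at the
file boundary, so there is a single conversion point.

## Label transform, loss, decoder

`modify_label` copies S off the diagonal and sets Ŝ_ii = 1 − Σ_j S_ij, so
every row (and by symmetry every column) is one-hot: a symmetric
permutation matrix, and each row is the target of one L-class
classification ("sub-sample"). The loss applies a numerically stable
(max-shifted) row softmax and the weighted average cross-entropy with
weight (n − |D|)/|D| on unpaired sub-samples, n being the number of
non-padded sub-samples in the batch and D the unpaired set. Decisions
around the formula's edge cases:

* |D| = 0: the formula is undefined; we use the plain mean of the paired
  terms. |D| = n: the formula collapses to 0; we fall back to the
  unweighted mean. Both fallbacks preserve a training signal and are
  logged.
* D is computed per batch, matching the batch-level form of the objective.
* Padded rows are excluded from both sums **and** from n, and the softmax
  runs over real columns only. This is the only padding convention under
  which a sequence's loss is independent of what it is batched with
  (verified by test).

Training on rows of M̂ or on columns of M̂ᵀ is equivalent — for symmetric
scores and labels the two losses coincide exactly; `column_weighted_cross_entropy`
exists to make that property testable.

The decoder binarizes each row at its maximum (ties break to the lowest
column index — the convention is arbitrary but fixed for reproducibility),
multiplies elementwise with its transpose, and applies the |i − j| ≥ 4
mask. An independent per-entry loop reference (`decode_reference`) is kept
deliberately unvectorized as a cross-check oracle. `decode` accepts raw
asymmetric scores and symmetrizes internally, since symmetrization always
precedes decoding in the method's flow.

## Scoring network

PyTorch-free by design: the network runs on a small reverse-mode autodiff
core (`mccfold.nn`) over numpy — tensors in float32, gradients in float64,
every op gradient-checked against central differences. Architecture
(`model`):

* one-hot embedding (4 → d) plus **two-sided sinusoidal positions**:
  features of the distance from the 5' end and from the 3' end. Stem
  geometry depends on position relative to both ends, and product features
  of two-sided sinusoids expose i+j / i−j relations to the trunk directly;
  with one-sided encodings the end-anchored half would have to be inferred
  through attention, which is slow to learn at desk scale.
* a pre-norm Transformer encoder (configurable layers/heads/FFN width)
  with key-padding masking;
* pairwise grid: concat(h_i, h_j, h_i ⊙ h_j) per cell, the construction of
  the E2Efold/UFold model family;
* a U-Net (configurable depth, channels doubling per level, 3×3
  convolutions, nearest-neighbour upsampling with skip concatenation, 1×1
  head) producing the raw score matrix M.

Padding invariance is exact by construction: sequences are right-padded to
a multiple of 2^depth, attention masks padded keys, and the grid and every
convolution output are multiplied by the (max-pooled) validity mask, so
padded cells are identically zero and a real cell's receptive field sees
the same values regardless of padding extent. The published architecture
this family derives from is not specified in enough public detail to
reproduce exactly; this network is a configurable member of the same
family, and nothing downstream depends on it — decoded predictions are
valid under any scores.

Defaults: `max_len` 512 (covers L ≤ 500); tests and examples use a ~20k
parameter configuration (d = 16, 1 encoder layer, 2 heads, U-Net depth 2,
8 base channels) with Adam at lr 3·10⁻³, batch 16, which reaches F1 ≈ 0.95
on held-out hairpins in 10 epochs / ~30 s on one CPU. All randomness
(initialization, batch order, dropout) is generator-seeded; checkpoints
store weights, config, and optimizer state, so training resumes
bit-identically on one CPU thread.

## Augmentation

Operators act only on B, the set of unpaired bases, because edits to
paired bases would invalidate the carried-over label. Selection counts are
round-half-up of p·|B| (noise, removal) or p·L (insertion), keeping the
expected edit count at the configured percentage; defaults p1 = p2 = p3 =
10%, two repetitions of the three operators per gated sample (six
augmented samples), gate 150 < L ≤ 500 — augmentation targets the
longer-sequence regime where training data is scarce. Choices where the
operator definitions left room:

* "followed by adding noise" in removal/insertion reuses p1 over the
  post-edit unpaired set (the literal operator composition);
* insertion points are the L+1 inter-base gaps, sampled without
  replacement; inserted bases are uniform over all four, mutated bases
  uniform over the three alternatives;
* a deletion that would squeeze a surviving pair below separation 4
  (shrinking a hairpin loop under 3 bases) is resampled among the
  remaining candidates; if the requested count is infeasible the operator
  raises rather than silently under-delivering.

## Knowledge merge and the teacher

Synthesis draws a length uniformly from [L1, L2] (defaults 50 and 500) and
bases i.i.d. uniform; the study-scale sample count default is 30,000. A
teacher is any deterministic mapping from sequences to valid structures.
The built-in teacher is a Nussinov-style maximum-pair dynamic program over
canonical+wobble pairs with minimum separation 4 (labels valid by
construction), anti-diagonal-vectorized with a deterministic traceback
(pairing preferred over skipping, smallest partner index first). It is the
package's own teacher, with an adapter for plugging in external folding
programs via a command template; the test suite never requires one. An
exhaustive enumerator of all non-crossing structures (usable to L ≈ 16)
serves as the optimality oracle.

The same-prediction ratio between two predictions is the fraction of all L
bases whose predicted partner — an index, or "unpaired" — agrees. The
desk-scale knowledge-merge experiment (2,000 teacher-labeled sequences,
L ∈ [20, 60], vs the same architecture trained on hairpins, 200 held-out
random sequences) checks the direction only: the teacher-trained model
tracks the teacher substantially better (≈ 0.39 vs ≈ 0.27 in the
acceptance run). Study-scale ratios require the full training corpus and
are not reproduced here.

## Metrics

Confusion counts run over unordered upper-triangle positions with
j − i ≥ 4 — the sterically feasible candidate set, (L−4)(L−3)/2 positions.
F1 is insensitive to the choice of universe; INF (computed exactly as the
Matthews correlation coefficient) is not, and counting infeasible
positions would inflate TN and hence INF, so the feasible universe is the
conservative choice. Conventions: two empty structures agree perfectly
(P = R = F1 = 1); otherwise 0/0 terms are 0; a zero MCC denominator factor
gives INF = 0. Reporting is macro (per-sample mean ± sd) per group:
overall, the (50, 150] / (150, 500] split, width-100 fine bins, and family
tags when present.

## Synthetic samples

Fixtures generate hairpins, two-stem structures, and H-type pseudoknots
with complementary stems (the six canonical+wobble complements drawn
uniformly) and uniform loop/linker bases — a learnable analogue of real
pairing rules, with no thermodynamic realism, family-specific composition,
non-canonical pairs, or structural noise. Passing the desk-scale learning
checks therefore shows that the training objective, gradients, and decoder
compose correctly, not that the architecture would reach benchmark
accuracy on real families. Loops are ≥ 3 bases so every innermost pair
satisfies the separation rule; default geometry keeps L ≤ 64 so tests run
in seconds.

## Problem sizes

Desk-scale experiment sizes used throughout tests and the acceptance
script: decoder validity over 1,000 matrices (L 8–64); 500 format
round-trips; 500 training / 100 held-out hairpins for learning; 2,000
teacher samples for knowledge merge. These sizes make the full suite run
in a few minutes on a single CPU while leaving each check statistically
unambiguous.

## Known limitations

* The scoring network is a desk-scale approximation; benchmark-level
  within-family accuracy on real datasets is out of scope.
* O(L²) grids and attention bound practical lengths (default cap 512).
* The built-in teacher maximizes pair count, which overpredicts pairs
  relative to thermodynamic folders; knowledge-merge conclusions here are
  directional.
* Dot-bracket output supports at most four crossing tiers (bracket
  families); deeper pseudoknots must use CT.
* No slippage-tolerant (±1) pair credit; no micro-averaged reporting.
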