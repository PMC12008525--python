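"""Knowledge merge: teaching the network a classical folder's behaviour.

Synthesizes random sequences, labels them with the built-in dynamic-
programming folder (the teacher), trains one model on those samples and an
identical model on hairpin fixtures, then compares how closely each tracks
the teacher on held-out random sequences via the same-prediction ratio
(fraction of bases whose predicted partner, or unpaired status, agrees).
Expect the merged model's ratio to be clearly higher — the direction that
matters for cross-family use. Runtime: a few minutes on one CPU.
"""

import numpy as np

from mccfold import (ModelConfig, SynthesisConfig, TrainConfig, build_model,
                     generate_teacher_set, predict, same_prediction_ratio,
                     train)
from mccfold.fixtures import make_dataset

TINY = dict(embed_dim=16, n_layers=1, n_heads=2, ff_dim=32,
            unet_depth=2, base_channels=8, max_len=64)

syn = generate_teacher_set(SynthesisConfig(min_len=20, max_len=60, n=2000, seed=5))
held = generate_teacher_set(SynthesisConfig(min_len=20, max_len=60, n=200, seed=6))

merged = build_model(ModelConfig(**TINY, seed=2))
train(merged, syn, TrainConfig(epochs=3, batch_size=16, lr=3e-3, seed=2))

baseline = build_model(ModelConfig(**TINY, seed=2))
train(baseline, make_dataset(500, np.random.default_rng(0)),
      TrainConfig(epochs=5, batch_size=16, lr=3e-3, seed=2))

seqs = [s for s, _ in held]
for name, net in (("knowledge merge", merged), ("hairpin baseline", baseline)):
    ratio = np.mean([same_prediction_ratio(P, S)
                     for P, (_, S) in zip(predict(net, seqs), held)])
    print(f"{name:17s} mean same-prediction ratio vs teacher: {ratio:.3f}")
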