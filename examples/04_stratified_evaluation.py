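"""Stratified perplexity report and per-layer pruning profile.

Evaluates a hand-made mask (pruning a random 2% of slots) against the
baseline, illustrating the report layout; a trained mask from example 03
plugs in the same way.
"""

import numpy as np

from plmsubnet import (
    CathLevel,
    SuppressionSpec,
    SyntheticSpec,
    Vocabulary,
    build_partition,
    build_toy_model,
    generate_corpus,
    pretrain_toy,
    split_dataset,
)
from plmsubnet.evaluation import stratified_perplexity
from plmsubnet.testbed.pretrain import PretrainConfig

corpus = generate_corpus(SyntheticSpec(n_per_class=40, seed=7))
split = split_dataset(corpus, seed=0)
train = [r for r in corpus if split.assignment[r.id] == "train"]
model = build_toy_model(Vocabulary(), depth=2, width=32, seed=1)
pretrain_toy(model, train, config=PretrainConfig(steps=300, seed=0))

spec = SuppressionSpec(level="sequence", target_label="1", cath_level=CathLevel.CLASS)
partition = build_partition(corpus, spec)

rng = np.random.default_rng(0)
mask = (rng.random(model.num_maskable) > 0.02).astype(float)

report = stratified_perplexity(model, mask, corpus, split, partition, seed=11)
print(report.to_frame().to_string(index=False))
print(f"\nsparsity: {report.sparsity:.2f}%")
print("\nper-layer pruning profile:")
print(report.per_layer.to_string(index=False))

# A random (untargeted) mask perturbs suppression and maintenance classes
# alike — contrast with example 03, where training concentrates the damage
# on the suppressed class.
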