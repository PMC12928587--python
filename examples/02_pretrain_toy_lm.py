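"""Pretrain the toy masked LM and compare against reference predictors.

Uses a reduced corpus and step count so the example runs in about a
minute; the package defaults (SyntheticSpec / PretrainConfig) are larger.
"""

import numpy as np

from plmsubnet import SyntheticSpec, Vocabulary, build_toy_model, generate_corpus, perplexity, pretrain_toy, split_dataset
from plmsubnet.evaluation import evaluation_nlls
from plmsubnet.testbed.pretrain import PretrainConfig, unigram_perplexity

corpus = generate_corpus(SyntheticSpec(n_per_class=60, seed=7))
split = split_dataset(corpus, seed=0)
train = [r for r in corpus if split.assignment[r.id] == "train"]
held = [r for r in corpus if split.assignment[r.id] == "test"]

model = build_toy_model(Vocabulary(), depth=2, width=32, seed=1)


def held_ppl():
    nll = evaluation_nlls(model, held, rate=0.15, seed=5, rounds=2)
    return perplexity(np.concatenate([v for _, v in nll.values()]))


print(f"uniform guessing perplexity : 20.0")
print(f"train-unigram perplexity    : {unigram_perplexity(train, held):.2f}")
print(f"untrained model             : {held_ppl():.2f}")
pretrain_toy(model, train, config=PretrainConfig(steps=400, seed=0))
print(f"after 400 MLM steps         : {held_ppl():.2f}")

# The trained model should sit below both reference lines: beating 20 means
# it learned residue statistics at all, beating the unigram model means it
# exploits sequence context (class composition, motifs, local structure).
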