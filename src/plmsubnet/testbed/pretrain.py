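"""Masked-language-model pretraining of the toy reference model.

Standard BERT-style training: 15% of positions are selected per sequence,
corrupted with the 80/10/10 mask/mutate/keep scheme, and the model is
trained by Adam to minimise the mean NLL of the true residues at the
selected positions (over the 20-amino-acid support).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .._batch import encode_records, pad_batch
from ..annotations import ConfigError, DomainRecord
from ..autodiff import Adam
from ..objectives import apply_plan, make_corruption_plan
from .model import ToyMaskedLM

__all__ = ["PretrainConfig", "pretrain_toy", "unigram_perplexity"]


@dataclass
class PretrainConfig:
    """MLM pretraining defaults: 5000 Adam steps with a two-stage lr decay."""

    steps: int = 5000
    batch_size: int = 16
    lr: float = 3e-3
    lr_decay_points: tuple[float, float] = (0.7, 0.9)  # fractions of steps
    lr_decay_factors: tuple[float, float] = (1.0 / 3.0, 1.0 / 6.0)
    rate: float = 0.15
    action_mix: tuple[float, float, float] = (0.80, 0.10, 0.10)
    seed: int = 0

    def lr_at(self, step: int) -> float:
        frac = step / max(self.steps, 1)
        lr = self.lr
        for point, factor in zip(self.lr_decay_points, self.lr_decay_factors):
            if frac >= point:
                lr = self.lr * factor
        return lr


def pretrain_toy(
    model: ToyMaskedLM,
    corpus: list[DomainRecord],
    steps: int | None = None,
    seed: int | None = None,
    config: PretrainConfig | None = None,
) -> ToyMaskedLM:
    """Train ``model`` in place on ``corpus``; returns the same object.

    Deterministic for fixed seeds.  ``steps`` and ``seed`` override the
    corresponding config fields when given.
    """
    cfg = config or PretrainConfig()
    if steps is not None:
        cfg = PretrainConfig(
            steps=steps, batch_size=cfg.batch_size, lr=cfg.lr,
            rate=cfg.rate, action_mix=cfg.action_mix,
            seed=cfg.seed if seed is None else seed,
        )
    elif seed is not None:
        cfg = PretrainConfig(
            steps=cfg.steps, batch_size=cfg.batch_size, lr=cfg.lr,
            rate=cfg.rate, action_mix=cfg.action_mix, seed=seed,
        )
    if cfg.steps <= 0:
        raise ConfigError(f"steps must be positive, got {cfg.steps}")
    if not corpus:
        raise ConfigError("corpus is empty")

    vocab = model.vocab
    tokens = encode_records(corpus, vocab)
    ids = [r.id for r in corpus]
    rng = np.random.default_rng(cfg.seed)

    model.set_trainable(True)
    opt = Adam(list(model.params.values()), lr=cfg.lr)
    n = len(ids)
    for step in range(cfg.steps):
        opt.lr = cfg.lr_at(step)
        batch_ids = rng.choice(n, size=min(cfg.batch_size, n), replace=False)
        corrupted, rows, cols, targets = [], [], [], []
        for bi, idx in enumerate(batch_ids):
            t = tokens[ids[idx]]
            plan = make_corruption_plan(t.size, cfg.rate, cfg.action_mix, seed=rng)
            corrupted.append(apply_plan(t, plan, vocab))
            scored = plan.positions[t[plan.positions] < vocab.amino_acid_count]
            rows.extend([bi] * scored.size)
            cols.extend(scored.tolist())
            targets.extend(t[scored].tolist())
        if not rows:
            continue
        batch, _ = pad_batch(corrupted, vocab.pad_id)
        logp = model.forward(batch, return_log=True)
        loss = -(logp[np.array(rows), np.array(cols), np.array(targets)].mean())
        opt.zero_grad()
        loss.backward()
        opt.step()
    model.set_trainable(False)
    return model


def unigram_perplexity(train: list[DomainRecord], heldout: list[DomainRecord]) -> float:
    """Perplexity of the train-corpus unigram model on held-out residues.

    A context-free reference: any model that has learned sequence context
    should beat this (and the uniform value of 20).
    """
    from ..annotations import AMINO_ACIDS

    idx = {a: i for i, a in enumerate(AMINO_ACIDS)}
    counts = np.ones(20)  # add-one smoothing
    for r in train:
        for c in r.sequence:
            if c in idx:
                counts[idx[c]] += 1
    p = counts / counts.sum()
    nll = []
    for r in heldout:
        for c in r.sequence:
            if c in idx:
                nll.append(-np.log(p[idx[c]]))
    return float(np.exp(np.mean(nll)))
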