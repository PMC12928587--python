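"""Loss components for subnetwork training, plus the MLM corruption scheme.

Three terms drive the mask:

* **Suppression** — mean KL divergence (nats) between the subnetwork's
  predictive distribution at suppressed tokens and the uniform reference
  over the 20-amino-acid support: a suppressed model should be reduced to
  uniform guessing.
* **Maintenance KL** — mean KL between the subnetwork's and the frozen
  full model's predictive distributions at maintained tokens.
* **Maintenance MLM** — mean negative log-likelihood of the true residue
  at corrupted positions (BERT-style 15% selection; of selected positions
  80% become the mask token, 10% are randomly substituted, 10% kept),
  restricted to maintained residues for residue-level suppression.

All three are oriented so that *minimizing* the weighted sum achieves the
stated goals; aggregation is the arithmetic mean over included positions,
in natural-log units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .annotations import ConfigError
from .autodiff import Tensor, astensor
from .vocab import Vocabulary

__all__ = [
    "EPS",
    "UNIFORM_NLL",
    "LossWeights",
    "CorruptionPlan",
    "make_corruption_plan",
    "apply_plan",
    "suppression_loss",
    "maintenance_kl",
    "mlm_loss",
    "combine",
    "perplexity",
]

#: Floor inside logarithms.
EPS = 1e-9

#: Negative log-likelihood of uniform guessing over the 20 amino acids.
UNIFORM_NLL = float(np.log(20.0))

ACTION_MASK, ACTION_MUTATE, ACTION_KEEP = 0, 1, 2


@dataclass(frozen=True)
class LossWeights:
    """Nonnegative weights (λ1, λ2, λ3) for suppression / maintenance-KL / MLM."""

    suppression: float = 1.0
    maintenance: float = 1.0
    mlm: float = 1.0

    def __post_init__(self):
        vals = (self.suppression, self.maintenance, self.mlm)
        if any(v < 0 for v in vals):
            raise ConfigError(f"loss weights must be nonnegative, got {vals}")
        if all(v == 0 for v in vals):
            raise ConfigError("at least one loss weight must be positive")


@dataclass(frozen=True)
class CorruptionPlan:
    """MLM corruption for one sequence of a given length.

    ``positions`` (M) are the 0-based selected indices; ``actions`` holds a
    per-position code (0 mask, 1 mutate, 2 keep) and ``replacements`` the
    substituted amino-acid index for mutate actions (unused elsewhere).
    """

    length: int
    positions: np.ndarray
    actions: np.ndarray
    replacements: np.ndarray

    @property
    def complement(self) -> np.ndarray:
        """M': the unselected positions."""
        keep = np.ones(self.length, dtype=bool)
        keep[self.positions] = False
        return np.nonzero(keep)[0]


def make_corruption_plan(
    length: int,
    rate: float = 0.15,
    action_mix: tuple[float, float, float] = (0.80, 0.10, 0.10),
    seed: int | np.random.Generator = 0,
) -> CorruptionPlan:
    """Select ~15% of positions i.i.d. and assign 80/10/10 mask/mutate/keep."""
    if not 0.0 < rate < 1.0:
        raise ConfigError(f"corruption rate must be in (0, 1), got {rate}")
    if abs(sum(action_mix) - 1.0) > 1e-9 or min(action_mix) < 0:
        raise ConfigError(f"action mix must be a distribution, got {action_mix}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    selected = np.nonzero(rng.random(length) < rate)[0]
    actions = rng.choice(3, size=selected.size, p=action_mix)
    replacements = rng.integers(0, 20, size=selected.size)
    return CorruptionPlan(
        length=length,
        positions=selected.astype(np.intp),
        actions=actions.astype(np.intp),
        replacements=replacements.astype(np.intp),
    )


def apply_plan(tokens: np.ndarray, plan: CorruptionPlan, vocab: Vocabulary) -> np.ndarray:
    """Return a corrupted copy of ``tokens`` according to the plan."""
    if plan.length != len(tokens):
        raise ConfigError("plan length does not match token sequence")
    out = np.array(tokens, copy=True)
    pos, act = plan.positions, plan.actions
    out[pos[act == ACTION_MASK]] = vocab.mask_id
    out[pos[act == ACTION_MUTATE]] = plan.replacements[act == ACTION_MUTATE]
    return out


def _check_normalized(p: np.ndarray) -> None:
    sums = p.sum(axis=-1)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        raise ConfigError(
            f"distributions not normalized (max |sum-1| = {np.abs(sums - 1).max():.2e})"
        )


def suppression_loss(probs, support: int = 20) -> Tensor:
    """Mean KL(p ‖ uniform) in nats over the included positions.

    ``probs`` has shape (N, support): the subnetwork's predictive
    distributions gathered at the suppressed tokens (all positions of a
    suppressed sequence, or the J* positions for residue-level work).
    """
    p = astensor(probs)
    if p.shape[-1] != support:
        raise ConfigError(f"expected support {support}, got {p.shape[-1]}")
    _check_normalized(p.data)
    # KL(p||u) = sum p log p + log support
    ent = (p * (p + EPS).log()).sum(axis=-1)
    return ent.mean() + float(np.log(support))


def maintenance_kl(probs_subnet, probs_baseline) -> Tensor:
    """Mean KL(p_subnet ‖ p_baseline) in nats; the baseline carries no gradient."""
    p = astensor(probs_subnet)
    q = astensor(probs_baseline).detach()
    if p.shape != q.shape:
        raise ConfigError(f"shape mismatch {p.shape} vs {q.shape}")
    _check_normalized(p.data)
    _check_normalized(q.data)
    kl = (p * ((p + EPS).log() - np.log(q.data + EPS))).sum(axis=-1)
    return kl.mean()


def mlm_loss(
    probs,
    true_tokens: np.ndarray,
    plan: CorruptionPlan,
    suppressed_positions: np.ndarray | None = None,
) -> Tensor:
    """Mean NLL of the true residue at the scored corruption positions.

    Scored set: M for sequence-level work; M ∩ J' (selected positions on
    maintained residues) when ``suppressed_positions`` (J*) is given.  An
    empty scored set returns 0 with a warning.
    """
    p = astensor(probs)
    true_tokens = np.asarray(true_tokens)
    if plan.positions.size and plan.positions.max() >= p.shape[0]:
        raise ConfigError("plan position out of range for the given distributions")
    scored = plan.positions
    if suppressed_positions is not None:
        scored = np.setdiff1d(scored, suppressed_positions, assume_unique=False)
    scored = scored[true_tokens[scored] < p.shape[-1]] if scored.size else scored
    if scored.size == 0:
        warnings.warn("empty scored set for MLM loss; returning 0", stacklevel=2)
        return Tensor(0.0)
    gathered = p[scored, true_tokens[scored]]
    return -((gathered + EPS).log().mean())


def combine(losses, weights: LossWeights) -> Tensor:
    """Weighted sum λ1·L_supp + λ2·L_maint + λ3·L_mlm."""
    ls, lm, lmlm = (astensor(x) for x in losses)
    return (
        weights.suppression * ls + weights.maintenance * lm + weights.mlm * lmlm
    )


def perplexity(nlls) -> float:
    """exp(mean per-position NLL in nats); 20 for uniform guessing, 1 if perfect."""
    nlls = np.asarray(nlls, dtype=float)
    if nlls.size == 0:
        raise ConfigError("perplexity of an empty NLL collection is undefined")
    return float(np.exp(nlls.mean()))
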