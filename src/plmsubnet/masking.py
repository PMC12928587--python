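"""Differentiable binary weight masks.

A mask is parameterised by one logit per maskable slot.  During training a
stochastic score is drawn through a Gumbel-sigmoid transform,

    s_i = sigmoid( -(1/tau) * [ l_i + log(U/(1-U)) ] ),   U ~ Uniform(0,1),

and binarized with a straight-through estimator: the forward value is the
strict indicator 1(s_i > T) while gradients pass through s unchanged.  The
sign convention follows the score definition above: a *larger* logit gives
a *lower* score, i.e. drives the slot toward pruning.  At evaluation time
the mask is the deterministic, noise-free binarization of
``sigmoid(-l/tau)`` against T.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .annotations import ConfigError
from .autodiff import Tensor

logger = logging.getLogger(__name__)

__all__ = [
    "MaskState",
    "sample_scores",
    "binarize",
    "sparsity",
    "apply_mask",
    "MaskedModel",
    "save_mask",
    "load_mask",
]

_NOISE_EPS = 1e-6


def _expit(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(x, dtype=np.float64)))


@dataclass
class MaskState:
    """Learnable mask over K maskable slots: logits plus (tau, T, noise seed)."""

    logits: np.ndarray
    tau: float = 0.5
    threshold: float = 0.5
    noise_seed: int = 0

    def __post_init__(self):
        self.logits = np.asarray(self.logits, dtype=np.float64)
        if self.tau <= 0:
            raise ConfigError(f"temperature must be positive, got {self.tau}")
        if not 0.0 < self.threshold < 1.0:
            raise ConfigError(f"threshold must be in (0,1), got {self.threshold}")

    @classmethod
    def initialize(
        cls, k: int, logit_init: float = -5.0, tau: float = 0.5,
        threshold: float = 0.5, noise_seed: int = 0,
    ) -> "MaskState":
        """All-logits-equal start; the default -5 keeps essentially every slot."""
        return cls(np.full(k, logit_init), tau=tau, threshold=threshold, noise_seed=noise_seed)

    @property
    def k(self) -> int:
        return self.logits.size

    def scores(self) -> np.ndarray:
        """Noise-free evaluation scores sigmoid(-l/tau)."""
        return _expit(-self.logits / self.tau)

    def mask(self) -> np.ndarray:
        """The deterministic binary mask 1(scores > T), as floats."""
        return (self.scores() > self.threshold).astype(np.float64)

    def sparsity(self) -> float:
        return sparsity(self.mask())


def sample_scores(logits, tau: float, noise) -> "Tensor | np.ndarray":
    """Gumbel-sigmoid scores; accepts a Tensor (differentiable) or an array.

    ``noise`` is the uniform draw U in (0,1), one value per slot; values at
    the boundary are clamped to (1e-6, 1-1e-6) and logged.
    """
    if tau <= 0:
        raise ConfigError(f"temperature must be positive, got {tau}")
    noise = np.asarray(noise, dtype=np.float64)
    if np.any(noise <= 0.0) or np.any(noise >= 1.0):
        logger.warning("uniform noise at {0,1} clamped to (eps, 1-eps)")
        noise = np.clip(noise, _NOISE_EPS, 1.0 - _NOISE_EPS)
    gumbel = np.log(noise / (1.0 - noise))
    if isinstance(logits, Tensor):
        return ((logits + gumbel) * (-1.0 / tau)).sigmoid()
    return _expit(-(np.asarray(logits, dtype=np.float64) + gumbel) / tau)


def binarize(scores, threshold: float):
    """Strict indicator 1(s > T); Tensors get the straight-through gradient."""
    if isinstance(scores, Tensor):
        hard = (scores.data > threshold).astype(np.float64)
        # m = [1(s>T) - s]_detach + s : forward is hard, gradient is identity
        return scores + Tensor(hard - scores.data)
    return (np.asarray(scores, dtype=np.float64) > threshold).astype(np.float64)


def sparsity(mask) -> float:
    """Percentage of zero entries in a binary mask."""
    m = mask.data if isinstance(mask, Tensor) else np.asarray(mask, dtype=np.float64)
    if m.size == 0:
        raise ConfigError("sparsity of an empty mask is undefined")
    return float(100.0 * np.count_nonzero(m == 0.0) / m.size)


class MaskedModel:
    """A view of ``model`` whose forward multiplies maskable weights by ``m``.

    The underlying stored weights are never modified.
    """

    def __init__(self, model, m):
        m_arr = m.data if isinstance(m, Tensor) else np.asarray(m, dtype=np.float64)
        if m_arr.shape != (model.num_maskable,):
            raise ConfigError(
                f"mask length {m_arr.shape} does not match K={model.num_maskable}"
            )
        self.model = model
        self.m = m

    def forward(self, tokens, return_log: bool = False):
        return self.model.forward(tokens, mask=self.m, return_log=return_log)


def apply_mask(model, m) -> MaskedModel:
    """Bind a flat binary mask to a model; see :class:`MaskedModel`."""
    return MaskedModel(model, m)


def save_mask(state: MaskState, model, path: str | Path) -> None:
    """Persist logits, (tau, T, seed), the binary mask and the manifest fingerprint."""
    meta = {
        "tau": state.tau,
        "threshold": state.threshold,
        "noise_seed": state.noise_seed,
        "fingerprint": model.manifest_fingerprint(),
        "k": state.k,
    }
    np.savez(path, meta=json.dumps(meta), logits=state.logits, mask=state.mask())


def load_mask(path: str | Path, model=None) -> MaskState:
    """Load a mask checkpoint; verifies the manifest fingerprint if a model is given."""
    try:
        with np.load(path, allow_pickle=False) as zf:
            meta = json.loads(str(zf["meta"]))
            logits = np.array(zf["logits"])
    except Exception as exc:  # truncated / corrupt archive
        raise ConfigError(f"cannot read mask checkpoint {path}: {exc}") from exc
    if logits.size != meta.get("k"):
        raise ConfigError(f"mask checkpoint {path} is inconsistent (truncated?)")
    if model is not None and model.manifest_fingerprint() != meta["fingerprint"]:
        raise ConfigError(
            "mask checkpoint manifest fingerprint does not match the model"
        )
    return MaskState(
        logits,
        tau=float(meta["tau"]),
        threshold=float(meta["threshold"]),
        noise_seed=int(meta["noise_seed"]),
    )
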