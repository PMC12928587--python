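"""A small bidirectional transformer masked LM implementing the model contract.

The model exposes:

* ``forward(tokens, mask=None)`` — per-position predictive distributions
  over the 20 amino acids (special tokens are never predicted; the softmax
  support is the amino-acid alphabet).  With a binary mask ``m`` of length
  ``K``, each maskable weight is multiplied elementwise by its slot of
  ``m`` during the forward pass; stored weights are never modified, and a
  forward with an all-ones mask is bit-identical to a forward with none.
* ``maskable_index`` — the ordered manifest of maskable parameter slots.
  Masking covers exactly the attention and feed-forward projection weight
  matrices of each block; embeddings, biases and normalization parameters
  are deliberately absent from the manifest.

Everything runs on the package's numpy autodiff engine, so both the
pretraining of this model and the mask-logit training differentiate
through the same forward code.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np

from ..annotations import ConfigError
from ..autodiff import Tensor, gelu, log_softmax, softmax
from ..vocab import MASK_TOKEN, Vocabulary

__all__ = ["ManifestEntry", "ToyMaskedLM", "build_toy_model", "save_model", "load_model"]

_MASKABLE_MODULES = ("attn.wq", "attn.wk", "attn.wv", "attn.wo", "ffn.w1", "ffn.w2")


@dataclass(frozen=True)
class ManifestEntry:
    """One maskable weight tensor: its layer, module name and flat slot range."""

    layer: int
    module: str
    shape: tuple[int, int]
    offset: int

    @property
    def size(self) -> int:
        return int(np.prod(self.shape))


class ToyMaskedLM:
    def __init__(
        self,
        vocab: Vocabulary,
        depth: int = 2,
        width: int = 32,
        n_heads: int = 4,
        max_len: int = 128,
        seed: int = 0,
    ):
        if depth <= 0 or width <= 0:
            raise ConfigError("depth and width must be positive")
        if width % n_heads != 0:
            raise ConfigError(f"width {width} not divisible by n_heads {n_heads}")
        if MASK_TOKEN not in vocab.tokens:
            raise ConfigError("vocabulary lacks the MASK token")
        self.vocab = vocab
        self.depth = depth
        self.width = width
        self.n_heads = n_heads
        self.max_len = max_len
        self.seed = seed
        self.params: dict[str, Tensor] = {}
        self._init_params(np.random.default_rng(seed))
        self._build_manifest()

    # -- parameters ----------------------------------------------------
    def _init_params(self, rng) -> None:
        d, v = self.width, self.vocab.size
        scale = d**-0.5

        def normal(*shape, s=scale):
            return Tensor(rng.normal(0.0, s, size=shape))

        self.params["embed"] = normal(v, d, s=0.05)
        self.params["pos"] = normal(self.max_len, d, s=0.05)
        for i in range(self.depth):
            p = f"blocks.{i}."
            for name in ("attn.wq", "attn.wk", "attn.wv", "attn.wo"):
                self.params[p + name] = normal(d, d)
            self.params[p + "ffn.w1"] = normal(d, 4 * d)
            self.params[p + "ffn.w2"] = normal(4 * d, d, s=(4 * d) ** -0.5)
            self.params[p + "ffn.b1"] = Tensor(np.zeros(4 * d))
            self.params[p + "ffn.b2"] = Tensor(np.zeros(d))
            for ln in ("ln1", "ln2"):
                self.params[p + ln + ".g"] = Tensor(np.ones(d))
                self.params[p + ln + ".b"] = Tensor(np.zeros(d))
        self.params["final_ln.g"] = Tensor(np.ones(d))
        self.params["final_ln.b"] = Tensor(np.zeros(d))
        self.params["out_bias"] = Tensor(np.zeros(self.vocab.amino_acid_count))

    def _build_manifest(self) -> None:
        entries = []
        offset = 0
        for i in range(self.depth):
            for mod in _MASKABLE_MODULES:
                shape = self.params[f"blocks.{i}.{mod}"].shape
                entries.append(ManifestEntry(i, mod, tuple(shape), offset))
                offset += int(np.prod(shape))
        self.maskable_index: tuple[ManifestEntry, ...] = tuple(entries)
        self.num_maskable = offset
        self._by_name = {
            f"blocks.{e.layer}.{e.module}": e for e in self.maskable_index
        }

    def slot_layers(self) -> np.ndarray:
        """Layer id of every maskable slot, length K."""
        out = np.empty(self.num_maskable, dtype=np.intp)
        for e in self.maskable_index:
            out[e.offset : e.offset + e.size] = e.layer
        return out

    def slot_tags(self) -> Iterator[tuple[int, str, tuple[int, int]]]:
        """(layer, module, within-tensor coordinate) for each slot, in order."""
        for e in self.maskable_index:
            rows, cols = e.shape
            for r in range(rows):
                for c in range(cols):
                    yield (e.layer, e.module, (r, c))

    def manifest_fingerprint(self) -> str:
        text = "\n".join(
            f"{e.layer}:{e.module}:{e.shape}:{e.offset}" for e in self.maskable_index
        )
        return hashlib.sha256(text.encode()).hexdigest()

    def weights_hash(self) -> str:
        h = hashlib.sha256()
        for name in sorted(self.params):
            h.update(name.encode())
            h.update(np.ascontiguousarray(self.params[name].data).tobytes())
        return h.hexdigest()

    def set_trainable(self, flag: bool) -> None:
        for p in self.params.values():
            p.requires_grad = flag
            p.grad = None

    # -- forward -------------------------------------------------------
    def _eff(self, name: str, mask: Tensor | None) -> Tensor:
        w = self.params[name]
        if mask is None:
            return w
        e = self._by_name[name]
        return w * mask[e.offset : e.offset + e.size].reshape(e.shape)

    @staticmethod
    def _layer_norm(x: Tensor, g: Tensor, b: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * (var + 1e-5) ** -0.5 * g + b

    def forward(
        self,
        tokens: np.ndarray,
        mask: Tensor | np.ndarray | None = None,
        return_log: bool = False,
    ) -> Tensor:
        """Predictive distributions over the 20 amino acids, shape (B, L, 20).

        A 1-D ``tokens`` input returns shape (L, 20).  ``mask`` is the flat
        binary (or straight-through) mask over the maskable manifest.
        """
        tokens = np.asarray(tokens, dtype=np.intp)
        squeeze = tokens.ndim == 1
        if squeeze:
            tokens = tokens[None, :]
        B, L = tokens.shape
        if L > self.max_len:
            raise ConfigError(f"sequence length {L} exceeds max_len {self.max_len}")
        if mask is not None:
            if not isinstance(mask, Tensor):
                mask = Tensor(np.asarray(mask, dtype=np.float64))
            if mask.shape != (self.num_maskable,):
                raise ConfigError(
                    f"mask length {mask.shape} != K={self.num_maskable}"
                )

        pad_bias = np.where(tokens == self.vocab.pad_id, -1e9, 0.0)[:, None, None, :]
        x = self.params["embed"][tokens] + self.params["pos"][0:L]
        d, h = self.width, self.n_heads
        dh = d // h
        inv_sqrt = dh**-0.5
        for i in range(self.depth):
            p = f"blocks.{i}."
            xn = self._layer_norm(x, self.params[p + "ln1.g"], self.params[p + "ln1.b"])

            def heads(t: Tensor) -> Tensor:
                return t.reshape(B, L, h, dh).transpose(0, 2, 1, 3)

            q = heads(xn @ self._eff(p + "attn.wq", mask))
            k = heads(xn @ self._eff(p + "attn.wk", mask))
            v = heads(xn @ self._eff(p + "attn.wv", mask))
            scores = (q @ k.transpose(0, 1, 3, 2)) * inv_sqrt + pad_bias
            att = softmax(scores, axis=-1)
            ctx = (att @ v).transpose(0, 2, 1, 3).reshape(B, L, d)
            x = x + ctx @ self._eff(p + "attn.wo", mask)

            xn = self._layer_norm(x, self.params[p + "ln2.g"], self.params[p + "ln2.b"])
            hdn = gelu(xn @ self._eff(p + "ffn.w1", mask) + self.params[p + "ffn.b1"])
            x = x + hdn @ self._eff(p + "ffn.w2", mask) + self.params[p + "ffn.b2"]

        x = self._layer_norm(x, self.params["final_ln.g"], self.params["final_ln.b"])
        aa = self.vocab.amino_acid_count
        head = self.params["embed"][0:aa].transpose(1, 0)
        logits = x @ head + self.params["out_bias"]
        out = log_softmax(logits, axis=-1) if return_log else softmax(logits, axis=-1)
        if squeeze:
            out = out.reshape(L, aa)
        return out


def build_toy_model(
    vocab: Vocabulary,
    depth: int = 2,
    width: int = 32,
    n_heads: int = 4,
    max_len: int = 128,
    seed: int = 0,
) -> ToyMaskedLM:
    """Construct the reference toy masked LM (randomly initialised)."""
    return ToyMaskedLM(vocab, depth=depth, width=width, n_heads=n_heads, max_len=max_len, seed=seed)


def save_model(model: ToyMaskedLM, path: str | Path) -> None:
    """Self-describing checkpoint: hyperparameters, vocabulary, weights, manifest."""
    meta = {
        "depth": model.depth,
        "width": model.width,
        "n_heads": model.n_heads,
        "max_len": model.max_len,
        "seed": model.seed,
        "tokens": list(model.vocab.tokens),
        "fingerprint": model.manifest_fingerprint(),
    }
    arrays = {f"param/{k}": v.data for k, v in model.params.items()}
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_model(path: str | Path) -> ToyMaskedLM:
    with np.load(path, allow_pickle=False) as zf:
        meta = json.loads(str(zf["meta"]))
        model = ToyMaskedLM(
            Vocabulary(tuple(meta["tokens"])),
            depth=meta["depth"],
            width=meta["width"],
            n_heads=meta["n_heads"],
            max_len=meta["max_len"],
            seed=meta["seed"],
        )
        for k in model.params:
            model.params[k].data = np.array(zf[f"param/{k}"])
    if model.manifest_fingerprint() != meta["fingerprint"]:
        raise ConfigError("checkpoint manifest fingerprint mismatch")
    return model
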