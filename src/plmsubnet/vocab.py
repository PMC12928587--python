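"""Token vocabulary shared by the toy model, objectives and evaluation.

The predictive support for every loss and perplexity is the 20 canonical
amino acids; the special tokens (MASK, PAD, UNK) are model inputs only and
are never predicted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotations import AMINO_ACIDS

__all__ = ["Vocabulary", "MASK_TOKEN", "PAD_TOKEN", "UNK_TOKEN"]

MASK_TOKEN = "<mask>"
PAD_TOKEN = "<pad>"
UNK_TOKEN = "<unk>"


@dataclass(frozen=True)
class Vocabulary:
    """20 amino acids followed by the special tokens MASK, PAD, UNK."""

    tokens: tuple[str, ...] = field(
        default=tuple(AMINO_ACIDS) + (MASK_TOKEN, PAD_TOKEN, UNK_TOKEN)
    )

    @property
    def amino_acid_count(self) -> int:
        return 20

    @property
    def size(self) -> int:
        return len(self.tokens)

    @property
    def mask_id(self) -> int:
        return self.tokens.index(MASK_TOKEN)

    @property
    def pad_id(self) -> int:
        return self.tokens.index(PAD_TOKEN)

    @property
    def unk_id(self) -> int:
        return self.tokens.index(UNK_TOKEN)

    def encode(self, sequence: str) -> np.ndarray:
        """Map a sequence to token ids; non-canonical letters become UNK."""
        idx = {t: i for i, t in enumerate(self.tokens)}
        unk = self.unk_id
        return np.array([idx.get(c, unk) for c in sequence], dtype=np.intp)

    def decode(self, ids: np.ndarray) -> str:
        return "".join(self.tokens[i] for i in ids)
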