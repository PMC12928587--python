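"""Internal batching helpers: encoding and padding variable-length sequences."""

from __future__ import annotations

import numpy as np

from .vocab import Vocabulary


def encode_records(records, vocab: Vocabulary) -> dict[str, np.ndarray]:
    return {r.id: vocab.encode(r.sequence) for r in records}


def pad_batch(token_arrays: list[np.ndarray], pad_id: int) -> tuple[np.ndarray, np.ndarray]:
    """Stack ragged token arrays into (B, Lmax) padded with ``pad_id``.

    Returns the padded batch and the original lengths.
    """
    lengths = np.array([t.size for t in token_arrays], dtype=np.intp)
    out = np.full((len(token_arrays), int(lengths.max())), pad_id, dtype=np.intp)
    for i, t in enumerate(token_arrays):
        out[i, : t.size] = t
    return out, lengths
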