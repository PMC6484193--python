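"""Localist slot coding between words and network input/output vectors.

A word occupies four positional slots.  Each slot owns a contiguous block of
units, one unit per alphabet symbol, laid out slot-major: unit ``slot * A +
symbol`` is active iff that slot holds that symbol.  With the default 33
letters and 28 phonemes this gives 132 orthographic input units and 112
phonological output units.  BLANK slots encode as an all-zero block.

Decoding a real-valued phonological output applies a 0.5 readout threshold
per slot block: below threshold the slot reads as BLANK, otherwise as the
argmax phoneme (ties broken by lowest index).
"""

from __future__ import annotations

from typing import List, Tuple

import numpy as np

from .lexicon import BLANK, N_SLOTS, Lexicon, WordItem

#: readout threshold for a slot to be considered non-BLANK
DECODE_THRESHOLD: float = 0.5


def _encode_slots(slots: Tuple[int, ...], alphabet_size: int) -> np.ndarray:
    vec = np.zeros(N_SLOTS * alphabet_size)
    for k, s in enumerate(slots):
        if s == BLANK:
            continue
        if not 0 <= s < alphabet_size:
            raise ValueError(f"slot symbol {s} out of alphabet range [0, {alphabet_size})")
        vec[k * alphabet_size + s] = 1.0
    return vec


def encode_orthography(item: WordItem, n_letters: int) -> np.ndarray:
    """Binary input vector of length ``4 * n_letters`` (132 by default)."""
    return _encode_slots(item.spelling, n_letters)


def encode_phonology(item: WordItem, n_phonemes: int) -> np.ndarray:
    """Binary target vector of length ``4 * n_phonemes`` (112 by default)."""
    return _encode_slots(item.pronunciation, n_phonemes)


def decode_phonology(output: np.ndarray, n_phonemes: int) -> Tuple[int, int, int, int]:
    """Read a pronunciation off a real-valued output vector.

    Per slot block: BLANK if the peak activation is below 0.5, else the
    argmax phoneme (numpy argmax already takes the lowest index on ties).
    """
    output = np.asarray(output)
    if output.ndim != 1 or output.size % n_phonemes != 0:
        raise ValueError("output length must be a multiple of the phoneme alphabet size")
    blocks = output.reshape(-1, n_phonemes)
    slots: List[int] = []
    for block in blocks:
        j = int(np.argmax(block))
        slots.append(BLANK if block[j] < DECODE_THRESHOLD else j)
    return tuple(slots)  # type: ignore[return-value]


def decode_phonology_batch(outputs: np.ndarray, n_phonemes: int) -> np.ndarray:
    """Vectorised decode: (n, 4*A) activations -> (n, 4) slot symbols."""
    outputs = np.asarray(outputs)
    n = outputs.shape[0]
    blocks = outputs.reshape(n, -1, n_phonemes)
    arg = blocks.argmax(axis=2)
    peak = blocks.max(axis=2)
    return np.where(peak < DECODE_THRESHOLD, BLANK, arg)


def encode_lexicon(lexicon: Lexicon) -> Tuple[np.ndarray, np.ndarray]:
    """Stack the whole lexicon into input matrix X and target matrix T,
    row order matching ``lexicon.items``."""
    X = np.stack([encode_orthography(it, lexicon.n_letters) for it in lexicon])
    T = np.stack([encode_phonology(it, lexicon.n_phonemes) for it in lexicon])
    return X, T
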