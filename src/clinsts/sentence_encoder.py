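"""Sentence-level pair representation S.

The snippet pair is jointly encoded in the standard two-segment format
``[CLS] a [SEP] b [SEP]`` and S is the hidden state at the ``[CLS]``
position.  The encoder is a *contract* (:class:`PairEncoder`): any object
with an ``encode_pair`` method and a ``hidden_size`` fits the slot, so a
large pretrained masked-language-model checkpoint can be plugged in where
available.  The shipped implementation is :class:`TinyTransformerEncoder`,
a deterministic 2-layer, 2-head transformer with a word-plus-character
fallback vocabulary built from the training corpus — small enough to train
from scratch on a CPU, with the same interface and truncation semantics a
production encoder would have.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Protocol

import numpy as np

from . import nn

__all__ = ["EncoderConfig", "PairEncoder", "TinyTransformerEncoder", "make_tiny_encoder"]

PAD, UNK, CLS, SEP = 0, 1, 2, 3
_SPECIALS = ("[PAD]", "[UNK]", "[CLS]", "[SEP]")


@dataclass
class EncoderConfig:
    """Encoder hyperparameters.

    ``max_len`` is the maximum joint sequence length (default 380);
    sequences beyond it are truncated pair-wise, trimming the longer
    segment first.  ``checkpoint`` identifies the encoder ("tiny-random"
    for the shipped implementation).
    """

    max_len: int = 380
    hidden: int = 32
    n_layers: int = 2
    n_heads: int = 2
    checkpoint: str = "tiny-random"
    seed: int = 0

    def __post_init__(self):
        if self.max_len < 3:
            raise ValueError("max_len must be >= 3 (two separators + one content position)")
        if self.hidden < 4 or self.hidden % 2:
            raise ValueError("hidden must be even and >= 4")


class PairEncoder(Protocol):
    """Contract for the sentence-level module."""

    hidden_size: int

    def encode_pair(self, a: str, b: str) -> nn.Tensor: ...


def _word_tokenize(text: str) -> list[str]:
    """The encoder's own simple subword scheme: lowercase words, character
    fallback for out-of-vocabulary words (applied at encoding time)."""
    out: list[str] = []
    current: list[str] = []
    for ch in text.lower():
        if ch.isalnum():
            current.append(ch)
        else:
            if current:
                out.append("".join(current))
                current = []
            if not ch.isspace():
                out.append(ch)
    if current:
        out.append("".join(current))
    return out


class _SelfAttentionBlock(nn.Module):
    def __init__(self, hidden: int, n_heads: int, rng: np.random.Generator):
        if hidden % n_heads:
            raise ValueError("hidden must be divisible by n_heads")
        self.n_heads = n_heads
        self.head_dim = hidden // n_heads
        self.q = nn.Linear(hidden, hidden, rng)
        self.k = nn.Linear(hidden, hidden, rng)
        self.v = nn.Linear(hidden, hidden, rng)
        self.out = nn.Linear(hidden, hidden, rng)
        self.ln1 = nn.LayerNorm(hidden)
        self.ffn1 = nn.Linear(hidden, 2 * hidden, rng)
        self.ffn2 = nn.Linear(2 * hidden, hidden, rng)
        self.ln2 = nn.LayerNorm(hidden)

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        length, hidden = x.shape
        heads, hd = self.n_heads, self.head_dim

        def split(t: nn.Tensor) -> nn.Tensor:  # (L,H) -> (heads, L, hd)
            return t.reshape(length, heads, hd).transpose(1, 0, 2)

        q, k, v = split(self.q(x)), split(self.k(x)), split(self.v(x))
        scores = (q @ k.transpose(0, 2, 1)) * (1.0 / np.sqrt(hd))
        attn = scores.softmax(axis=-1) @ v  # (heads, L, hd)
        merged = attn.transpose(1, 0, 2).reshape(length, hidden)
        x = self.ln1(x + self.out(merged))
        x = self.ln2(x + self.ffn2(self.ffn1(x).relu()))
        return x


class TinyTransformerEncoder(nn.Module):
    """Deterministic desk-scale transformer pair encoder."""

    def __init__(self, config: EncoderConfig, vocab: dict[str, int]):
        rng = np.random.default_rng(config.seed)
        self.config = config
        self.vocab = vocab
        self.hidden_size = config.hidden
        self.tok_emb = nn.Embedding(len(vocab), config.hidden, rng)
        self.pos_emb = nn.Embedding(config.max_len, config.hidden, rng)
        self.seg_emb = nn.Embedding(2, config.hidden, rng)
        self.ln = nn.LayerNorm(config.hidden)
        self.blocks = [
            _SelfAttentionBlock(config.hidden, config.n_heads, rng)
            for _ in range(config.n_layers)
        ]

    # -- tokenization ---------------------------------------------------------

    def _piece_ids(self, text: str) -> list[int]:
        ids: list[int] = []
        for word in _word_tokenize(text):
            if word in self.vocab:
                ids.append(self.vocab[word])
            else:
                ids.extend(self.vocab.get(c, UNK) for c in word)
        return ids

    def _build_input(self, a: str, b: str) -> tuple[np.ndarray, np.ndarray]:
        ids_a = self._piece_ids(a)
        ids_b = self._piece_ids(b)
        budget = self.config.max_len - 3  # [CLS] + 2 [SEP]
        while len(ids_a) + len(ids_b) > budget:
            # trim the longer segment first (ties: segment b)
            if len(ids_a) > len(ids_b):
                ids_a.pop()
            else:
                ids_b.pop()
        ids = [CLS] + ids_a + [SEP] + ids_b + [SEP]
        segments = [0] * (len(ids_a) + 2) + [1] * (len(ids_b) + 1)
        return np.array(ids, dtype=np.intp), np.array(segments, dtype=np.intp)

    # -- encoding -------------------------------------------------------------

    def encode_pair(self, a: str, b: str) -> nn.Tensor:
        """S: hidden state at the [CLS] position of the jointly encoded pair."""
        if not a.strip() or not b.strip():
            raise ValueError("both snippets must be non-empty")
        ids, segments = self._build_input(a, b)
        positions = np.arange(len(ids), dtype=np.intp)
        x = self.tok_emb(ids) + self.pos_emb(positions) + self.seg_emb(segments)
        x = self.ln(x)
        for block in self.blocks:
            x = block(x)
        return x.take(np.array([0], dtype=np.intp), axis=0).reshape(self.hidden_size)


def build_vocab(texts: Iterable[str]) -> dict[str, int]:
    """Word + single-character vocabulary covering every character seen."""
    words: set[str] = set()
    chars: set[str] = set()
    for text in texts:
        for w in _word_tokenize(text):
            words.add(w)
            chars.update(w)
    vocab = {s: i for i, s in enumerate(_SPECIALS)}
    for piece in sorted(chars) + sorted(words - chars):
        if piece not in vocab:
            vocab[piece] = len(vocab)
    return vocab


def make_tiny_encoder(
    corpus_texts: Iterable[str],
    seed: int = 0,
    hidden: int = 32,
    max_len: int = 380,
    n_layers: int = 2,
    n_heads: int = 2,
) -> TinyTransformerEncoder:
    """Deterministically initialised tiny encoder with a corpus-built vocabulary."""
    config = EncoderConfig(
        max_len=max_len,
        hidden=hidden,
        n_layers=n_layers,
        n_heads=n_heads,
        checkpoint="tiny-random",
        seed=seed,
    )
    return TinyTransformerEncoder(config, build_vocab(corpus_texts))
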