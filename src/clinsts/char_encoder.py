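"""Character-level representation C of a snippet pair.

Each token is embedded character by character, convolved with a width-3
kernel (symmetric zero-padding by one position, so even 1-character tokens
yield a window) and max-pooled over character positions to a single
``n_filters`` vector.  The pair representation C is the elementwise maximum
over the token vectors of *all* tokens of both snippets, which makes C
invariant to token order and to duplicated tokens.

A single char-CNN is shared between the two snippets.  The character
embedding dimension defaults to 25 and the filter count to 50; neither is
dictated by the similarity model itself, both are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from . import nn
from .data_io import TokenSequence

__all__ = ["CharVocabulary", "CharCNN"]

PAD_INDEX = 0
UNK_INDEX = 1


@dataclass(frozen=True)
class CharVocabulary:
    """Dense character -> index map with reserved padding/unknown slots."""

    index: dict[str, int]

    @classmethod
    def build(cls, texts: Iterable[str]) -> "CharVocabulary":
        chars = sorted({c for t in texts for c in t.lower()})
        return cls(index={c: i + 2 for i, c in enumerate(chars)})

    def __len__(self) -> int:
        return len(self.index) + 2

    def encode(self, token: str) -> np.ndarray:
        return np.array([self.index.get(c, UNK_INDEX) for c in token], dtype=np.intp)

    def to_dict(self) -> dict[str, int]:
        return dict(self.index)

    @classmethod
    def from_dict(cls, d: dict[str, int]) -> "CharVocabulary":
        return cls(index={str(k): int(v) for k, v in d.items()})


class CharCNN(nn.Module):
    """Siamese per-token char convolution with global max pooling."""

    def __init__(
        self,
        vocab: CharVocabulary,
        rng: np.random.Generator,
        embed_dim: int = 25,
        n_filters: int = 50,
        kernel: int = 3,
    ):
        self.vocab = vocab
        self.kernel = kernel
        self.n_filters = n_filters
        self.embed_dim = embed_dim
        self.embedding = nn.Embedding(len(vocab), embed_dim, rng)
        # padding rows stay zero so padded positions contribute nothing
        self.embedding.weight.data[PAD_INDEX] = 0.0
        self.conv_weight = nn.Parameter(
            rng.uniform(
                -np.sqrt(6.0 / (kernel * embed_dim + n_filters)),
                np.sqrt(6.0 / (kernel * embed_dim + n_filters)),
                size=(kernel * embed_dim, n_filters),
            )
        )
        self.conv_bias = nn.Parameter(np.zeros(n_filters))

    def encode_token(self, char_ids: np.ndarray | tuple[int, ...]) -> nn.Tensor:
        """Token vector: conv over character embeddings, max over positions."""
        ids = np.asarray(char_ids, dtype=np.intp)
        if ids.size == 0:
            raise ValueError("cannot encode an empty token")
        pad = self.kernel // 2
        padded = np.concatenate([np.full(pad, PAD_INDEX), ids, np.full(pad, PAD_INDEX)])
        emb = self.embedding(padded)  # (L + 2*pad, E)
        windows = nn.sliding_windows(emb, self.kernel)  # (L, k*E)
        conv = windows @ self.conv_weight + self.conv_bias  # (L, F)
        return conv.max(axis=0)

    def encode_pair(self, tok_a: TokenSequence, tok_b: TokenSequence) -> nn.Tensor:
        """Pair vector C: elementwise max over all token vectors of a and b."""
        if len(tok_a) == 0 or len(tok_b) == 0:
            raise ValueError("both token sequences must be non-empty")
        vecs = [
            self.encode_token(self.vocab.encode(tok))
            for seq in (tok_a, tok_b)
            for tok in seq.tokens
        ]
        return nn.stack(vecs, axis=0).max(axis=0)
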