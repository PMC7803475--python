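"""Entity-level representation I: siamese CNN over entity-type label sequences.

Each snippet's per-token label sequence (nine clinical types + "O") is
embedded with a shared 50-dimensional label table, passed through a shared
wide convolution (kernel 3, 50 filters, tanh) and average-pooled over
positions to one vector per sequence.  The two pooled vectors u_a, u_b are
combined into the pair representation E = [u_a − u_b ; u_a * u_b], the same
difference/product comparison used by the knowledge-graph entity variant,
so the two entity representations are commensurable.

Wide convolution here pads the *label sequence* by replicating its boundary
labels (kernel−1 positions per side) before embedding.  Under replication
padding every window of a constant-label sequence sees identical content,
so the pooled vector of a constant sequence does not depend on its length —
a property zero padding would break.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .entities import ALL_LABELS, LABEL_INDEX

__all__ = ["LabelBCNN"]


class LabelBCNN(nn.Module):
    """Basic bi-CNN (no attention): shared embedding + wide conv + mean pool."""

    def __init__(
        self,
        rng: np.random.Generator,
        embed_dim: int = 50,
        n_filters: int = 50,
        kernel: int = 3,
    ):
        self.embed_dim = embed_dim
        self.n_filters = n_filters
        self.kernel = kernel
        self.embedding = nn.Embedding(len(ALL_LABELS), embed_dim, rng)
        bound = np.sqrt(6.0 / (kernel * embed_dim + n_filters))
        self.conv_weight = nn.Parameter(
            rng.uniform(-bound, bound, size=(kernel * embed_dim, n_filters))
        )
        self.conv_bias = nn.Parameter(np.zeros(n_filters))

    @property
    def output_dim(self) -> int:
        return 2 * self.n_filters

    def _label_ids(self, labels: tuple[str, ...]) -> np.ndarray:
        try:
            ids = [LABEL_INDEX[lab] for lab in labels]
        except KeyError as exc:
            raise ValueError(f"unknown entity label {exc.args[0]!r}") from exc
        return np.asarray(ids, dtype=np.intp)

    def encode_sequence(self, labels: tuple[str, ...]) -> nn.Tensor:
        """Pooled branch vector u for one label sequence."""
        if not labels:
            raise ValueError("label sequence must be non-empty")
        ids = self._label_ids(labels)
        pad = self.kernel - 1
        padded = np.concatenate(
            [np.full(pad, ids[0]), ids, np.full(pad, ids[-1])]
        ).astype(np.intp)
        emb = self.embedding(padded)  # (L + 2(k-1), D)
        windows = nn.sliding_windows(emb, self.kernel)  # (L + k - 1, kD)
        conv = (windows @ self.conv_weight + self.conv_bias).tanh()
        return conv.mean(axis=0)

    def encode_pair(self, es_a: tuple[str, ...], es_b: tuple[str, ...]) -> nn.Tensor:
        """E = [u_a − u_b ; u_a * u_b] with parameters shared between branches."""
        u_a = self.encode_sequence(es_a)
        u_b = self.encode_sequence(es_b)
        return nn.concat([u_a - u_b, u_a * u_b], axis=0)
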