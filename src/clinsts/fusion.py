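"""Fusion of the three representation levels and score regression.

The pair vector is the ordered concatenation f = [S; C; E_I; E_II] of the
enabled components (S is always present; the others are optional, which is
what the ablation study toggles).  A multilayer perceptron — one hidden
tanh layer of width 128 by default, then a linear map to a scalar — regresses
the similarity score; training minimises mean squared error against the
gold scores, and at inference the raw output is clipped to the [0, 5] scale
before reporting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .char_encoder import CharCNN, CharVocabulary
from .data_io import STSPair, TokenSequence, preprocess
from .entities import EntityLexicon, kg_entities, tag
from .entity_bcnn import LabelBCNN
from .kg import KGAggregator, KGEmbeddingTable, pool_entities
from .sentence_encoder import PairEncoder

__all__ = ["PairFeatures", "featurize", "MLPHead", "SimilarityModel", "mse_loss", "fuse"]


@dataclass(frozen=True)
class PairFeatures:
    """Everything the model needs for one pair, computed once up front."""

    pair: STSPair
    tokens_a: TokenSequence
    tokens_b: TokenSequence
    labels_a: tuple[str, ...]
    labels_b: tuple[str, ...]
    kg_ids_a: tuple[str, ...] = ()
    kg_ids_b: tuple[str, ...] = ()


def featurize(pairs: list[STSPair], lexicon: EntityLexicon) -> list[PairFeatures]:
    """Tokenize, tag and map every pair once before training/inference."""
    out = []
    for p in pairs:
        ta, tb = preprocess(p.snippet_a), preprocess(p.snippet_b)
        la, lb = tag(ta, lexicon), tag(tb, lexicon)
        out.append(
            PairFeatures(
                pair=p,
                tokens_a=ta,
                tokens_b=tb,
                labels_a=la,
                labels_b=lb,
                kg_ids_a=tuple(kg_entities(la, ta, lexicon)),
                kg_ids_b=tuple(kg_entities(lb, tb, lexicon)),
            )
        )
    return out


def fuse(components: list[nn.Tensor]) -> nn.Tensor:
    """Ordered concatenation of the enabled representation vectors."""
    if not components:
        raise ValueError("at least one representation (S) must be present")
    if len(components) == 1:
        return components[0]
    return nn.concat(components, axis=0)


def mse_loss(p_scores: list[nn.Tensor], g_scores: list[float]) -> nn.Tensor:
    """Mean of squared prediction errors over a batch."""
    if len(p_scores) != len(g_scores) or not p_scores:
        raise ValueError("p_scores and g_scores must be equal-length and non-empty")
    terms = [(p - float(g)) ** 2 for p, g in zip(p_scores, g_scores)]
    total = terms[0]
    for t in terms[1:]:
        total = total + t
    return total / float(len(terms))


class MLPHead(nn.Module):
    """Wf + b followed by a tanh hidden layer and a linear scalar output."""

    def __init__(self, input_dim: int, rng: np.random.Generator, hidden: int = 128):
        self.input_dim = input_dim
        self.hidden_layer = nn.Linear(input_dim, hidden, rng)
        self.output_layer = nn.Linear(hidden, 1, rng)

    def __call__(self, f: nn.Tensor) -> nn.Tensor:
        if f.shape != (self.input_dim,):
            raise ValueError(f"fused vector has dim {f.shape}, head expects {self.input_dim}")
        return self.output_layer(self.hidden_layer(f).tanh()).reshape(())


@dataclass
class ComponentFlags:
    """Which optional representations participate in f."""

    char: bool = True
    entity_i: bool = True
    entity_ii: bool = True

    def name(self) -> str:
        parts = []
        if self.char:
            parts.append("char")
        if self.entity_i:
            parts.append("entityI")
        if self.entity_ii:
            parts.append("entityII")
        return "+".join(parts) if parts else "sentence-only"


class SimilarityModel(nn.Module):
    """The full multi-level similarity regressor.

    Holds the sentence encoder, the optional character CNN, the optional
    entity-I BCNN, the optional entity-II aggregator over a frozen KG
    embedding table, and the MLP head.  All held sub-modules train jointly;
    the KG table itself stays fixed.
    """

    def __init__(
        self,
        encoder: PairEncoder,
        flags: ComponentFlags,
        rng: np.random.Generator,
        char_vocab: CharVocabulary | None = None,
        kg_table: KGEmbeddingTable | None = None,
        char_embed_dim: int = 25,
        char_filters: int = 50,
        mlp_hidden: int = 128,
        entity_ii_dim: int | None = None,
    ):
        self.encoder = encoder
        self.flags = flags
        self.char_cnn = None
        self.bcnn = None
        self.kg_aggregator = None
        self.kg_table = kg_table
        if flags.char:
            if char_vocab is None:
                raise ValueError("char component enabled but no character vocabulary given")
            self.char_cnn = CharCNN(
                char_vocab, rng, embed_dim=char_embed_dim, n_filters=char_filters
            )
        if flags.entity_i:
            self.bcnn = LabelBCNN(rng)
        if flags.entity_ii:
            if kg_table is None:
                raise ValueError("entity-II component enabled but no KG embedding table given")
            self.kg_aggregator = KGAggregator(kg_table.dim, rng, output_dim=entity_ii_dim)
        dim = encoder.hidden_size
        if self.char_cnn is not None:
            dim += self.char_cnn.n_filters
        if self.bcnn is not None:
            dim += self.bcnn.output_dim
        if self.kg_aggregator is not None:
            dim += self.kg_aggregator.output_dim
        self.fused_dim = dim
        self.head = MLPHead(dim, rng, hidden=mlp_hidden)
        # start predictions at the score-scale midpoint so early inference is
        # not saturated by the [0, 5] clip
        self.head.output_layer.bias.data[:] = 2.5

    def forward(self, feat: PairFeatures) -> nn.Tensor:
        """Raw (unclipped) predicted score for one featurized pair."""
        components = [self.encoder.encode_pair(feat.pair.snippet_a, feat.pair.snippet_b)]
        if self.char_cnn is not None:
            components.append(self.char_cnn.encode_pair(feat.tokens_a, feat.tokens_b))
        if self.bcnn is not None:
            components.append(self.bcnn.encode_pair(feat.labels_a, feat.labels_b))
        if self.kg_aggregator is not None:
            eg_a = pool_entities(list(feat.kg_ids_a), self.kg_table)
            eg_b = pool_entities(list(feat.kg_ids_b), self.kg_table)
            components.append(self.kg_aggregator(eg_a, eg_b))
        return self.head(fuse(components))

    def predict(self, feats: list[PairFeatures]) -> np.ndarray:
        """Inference scores, clipped to the [0, 5] scale."""
        raw = np.array([self.forward(f).item() for f in feats])
        return np.clip(raw, 0.0, 5.0)
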