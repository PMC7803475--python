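"""Training loop, Pearson evaluation, cross-validation and the ablation runner.

Default hyperparameters are the model's standard setting: learning rate
2e-5, 12 epochs, batch size 20, maximum joint sequence length 380.  All of
them are overridable — desk-scale runs with the tiny from-scratch encoder
use a larger learning rate, since 2e-5 is a fine-tuning rate for a large
pretrained encoder.

Training optimises every enabled component jointly with Adam on the MSE
loss and keeps the *last* epoch's parameters as the final model (no
best-epoch selection).  One master seed derives all randomness streams
(parameter init, epoch shuffling), so runs are exactly reproducible on a
single thread.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .char_encoder import CharVocabulary
from .data_io import STSPair
from .entities import EntityLexicon
from .fusion import ComponentFlags, SimilarityModel, featurize, mse_loss
from .kg import KGEmbeddingTable
from .nn import Adam
from .sentence_encoder import make_tiny_encoder

__all__ = [
    "TrainConfig",
    "TrainResult",
    "EvalReport",
    "pearson",
    "train",
    "evaluate",
    "crossvalidate",
    "cv_folds",
    "ablate",
    "ABLATION_CONFIGURATIONS",
    "write_ablation_tsv",
    "score_histogram",
    "HISTOGRAM_BINS",
    "save_manifest",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class TrainConfig:
    """Hyperparameters; defaults are the model's standard setting."""

    learning_rate: float = 2e-5
    epochs: int = 12
    batch_size: int = 20
    max_seq_len: int = 380
    seed: int = 0
    use_char: bool = True
    use_entity_i: bool = True
    use_entity_ii: bool = True
    encoder_hidden: int = 32
    mlp_hidden: int = 128
    char_embed_dim: int = 25
    char_filters: int = 50
    kg_dim: int = 100

    def flags(self) -> ComponentFlags:
        return ComponentFlags(
            char=self.use_char, entity_i=self.use_entity_i, entity_ii=self.use_entity_ii
        )


@dataclass
class TrainResult:
    model: SimilarityModel
    epoch_losses: list[float]
    manifest: dict


@dataclass
class EvalReport:
    """PCC plus per-pair predictions; ablation rows keyed by configuration."""

    pcc: float
    predictions: np.ndarray
    rows: dict[str, float] = field(default_factory=dict)


def pearson(p, g) -> float:
    """Sample Pearson correlation coefficient between two score vectors."""
    p = np.asarray(p, dtype=float)
    g = np.asarray(g, dtype=float)
    if p.shape != g.shape or p.ndim != 1 or len(p) < 2:
        raise ValueError("pearson requires two equal-length vectors of length >= 2")
    if np.ptp(p) == 0:
        raise ValueError("zero variance in predicted scores")
    if np.ptp(g) == 0:
        raise ValueError("zero variance in gold scores")
    return float(stats.pearsonr(p, g).statistic)


def _derive_seed(master: int, stream: str) -> int:
    """Stable per-stream seed derived from the master seed (< 2**31)."""
    h = 2166136261
    for ch in f"{master}:{stream}":
        h = (h ^ ord(ch)) * 16777619 % (1 << 32)
    return h % (1 << 31)


def _build_model(
    corpus: list[STSPair],
    config: TrainConfig,
    kg_table: KGEmbeddingTable | None,
) -> SimilarityModel:
    texts = [t for p in corpus for t in (p.snippet_a, p.snippet_b)]
    encoder = make_tiny_encoder(
        texts,
        seed=_derive_seed(config.seed, "encoder"),
        hidden=config.encoder_hidden,
        max_len=config.max_seq_len,
    )
    rng = np.random.default_rng(_derive_seed(config.seed, "model"))
    char_vocab = CharVocabulary.build(texts) if config.use_char else None
    return SimilarityModel(
        encoder=encoder,
        flags=config.flags(),
        rng=rng,
        char_vocab=char_vocab,
        kg_table=kg_table if config.use_entity_ii else None,
        char_embed_dim=config.char_embed_dim,
        char_filters=config.char_filters,
        mlp_hidden=config.mlp_hidden,
    )


def train(
    corpus: list[STSPair],
    config: TrainConfig,
    lexicon: EntityLexicon | None = None,
    kg_table: KGEmbeddingTable | None = None,
) -> TrainResult:
    """Jointly optimise all enabled components for exactly ``config.epochs``.

    The last epoch's parameters are the final model.  Raises on an empty or
    unlabeled corpus.
    """
    if not corpus:
        raise ValueError("training corpus is empty")
    if any(p.g_score is None for p in corpus):
        raise ValueError("training corpus must be fully labeled")
    if config.use_entity_ii and kg_table is None:
        raise ValueError(
            "entity-II component enabled but no KG embedding table given; "
            "pass kg_table= or set use_entity_ii=False"
        )
    lexicon = lexicon if lexicon is not None else EntityLexicon()
    model = _build_model(corpus, config, kg_table)
    feats = featurize(corpus, lexicon)
    optimizer = Adam(model.parameters(), lr=config.learning_rate)
    shuffle_rng = np.random.default_rng(_derive_seed(config.seed, "shuffle"))

    epoch_losses: list[float] = []
    for _ in range(config.epochs):
        order = shuffle_rng.permutation(len(feats))
        batch_losses: list[float] = []
        for start in range(0, len(order), config.batch_size):
            batch = [feats[i] for i in order[start : start + config.batch_size]]
            preds = [model.forward(f) for f in batch]
            loss = mse_loss(preds, [f.pair.g_score for f in batch])
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            batch_losses.append(loss.item())
        epoch_losses.append(float(np.mean(batch_losses)))

    manifest = {
        "config": asdict(config),
        "n_pairs": len(corpus),
        "epoch_losses": epoch_losses,
        "components": model.flags.name(),
        "fused_dim": model.fused_dim,
    }
    return TrainResult(model=model, epoch_losses=epoch_losses, manifest=manifest)


def evaluate(
    model: SimilarityModel,
    corpus: list[STSPair],
    lexicon: EntityLexicon | None = None,
) -> EvalReport:
    """PCC of the model's clipped predictions against gold scores."""
    if any(p.g_score is None for p in corpus):
        raise ValueError("evaluation corpus must be labeled")
    lexicon = lexicon if lexicon is not None else EntityLexicon()
    feats = featurize(corpus, lexicon)
    preds = model.predict(feats)
    gold = np.array([p.g_score for p in corpus])
    return EvalReport(pcc=pearson(preds, gold), predictions=preds)


def crossvalidate(
    corpus: list[STSPair],
    config: TrainConfig,
    k: int = 5,
    lexicon: EntityLexicon | None = None,
    kg_table: KGEmbeddingTable | None = None,
) -> tuple[list[float], float]:
    """k-fold cross-validation: per-fold PCC and their arithmetic mean.

    Folds come from one seeded shuffle split into k near-equal disjoint
    parts whose union is the corpus.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(corpus) < k:
        raise ValueError(f"corpus of {len(corpus)} pairs cannot form {k} folds")
    rng = np.random.default_rng(_derive_seed(config.seed, "cv"))
    order = rng.permutation(len(corpus))
    folds = np.array_split(order, k)
    pccs: list[float] = []
    for held_out in folds:
        held = set(held_out.tolist())
        train_pairs = [corpus[i] for i in order if i not in held]
        test_pairs = [corpus[i] for i in held_out]
        result = train(train_pairs, config, lexicon=lexicon, kg_table=kg_table)
        pccs.append(evaluate(result.model, test_pairs, lexicon=lexicon).pcc)
    return pccs, float(np.mean(pccs))


def cv_folds(n: int, k: int, seed: int) -> list[np.ndarray]:
    """The index partition used by :func:`crossvalidate` (for inspection)."""
    rng = np.random.default_rng(_derive_seed(seed, "cv"))
    return np.array_split(rng.permutation(n), k)


#: The seven ablation rows: full model with each entity variant (and both),
#: the same three without the character-level component, and sentence-only.
ABLATION_CONFIGURATIONS: list[tuple[str, dict[str, bool]]] = [
    ("entity_I", {"use_char": True, "use_entity_i": True, "use_entity_ii": False}),
    ("entity_II", {"use_char": True, "use_entity_i": False, "use_entity_ii": True}),
    ("entity_I+entity_II", {"use_char": True, "use_entity_i": True, "use_entity_ii": True}),
    ("no_char/entity_I", {"use_char": False, "use_entity_i": True, "use_entity_ii": False}),
    ("no_char/entity_II", {"use_char": False, "use_entity_i": False, "use_entity_ii": True}),
    ("no_entity", {"use_char": True, "use_entity_i": False, "use_entity_ii": False}),
    ("without_both", {"use_char": False, "use_entity_i": False, "use_entity_ii": False}),
]


def ablate(
    corpus_train: list[STSPair],
    corpus_test: list[STSPair],
    base_config: TrainConfig,
    lexicon: EntityLexicon | None = None,
    kg_table: KGEmbeddingTable | None = None,
) -> EvalReport:
    """Train and evaluate the seven component configurations with one seed."""
    rows: dict[str, float] = {}
    preds = None
    for name, overrides in ABLATION_CONFIGURATIONS:
        cfg = TrainConfig(**{**asdict(base_config), **overrides})
        result = train(corpus_train, cfg, lexicon=lexicon, kg_table=kg_table)
        report = evaluate(result.model, corpus_test, lexicon=lexicon)
        rows[name] = report.pcc
        if preds is None:
            preds = report.predictions
    best = max(rows.values())
    return EvalReport(pcc=best, predictions=preds, rows=rows)


def write_ablation_tsv(report: EvalReport, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("configuration\tpcc\n")
        for name, pcc in report.rows.items():
            fh.write(f"{name}\t{pcc:.4f}\n")


#: Unit score intervals: [0,0.5), [0.5,1.5), ..., [3.5,4.5), [4.5,5].
HISTOGRAM_BINS: list[tuple[float, float]] = [
    (0.0, 0.5),
    (0.5, 1.5),
    (1.5, 2.5),
    (2.5, 3.5),
    (3.5, 4.5),
    (4.5, 5.0),
]


def score_histogram(corpus: list[STSPair]) -> np.ndarray:
    """Pair counts per unit score interval (six bins centred on 0..5)."""
    counts = np.zeros(len(HISTOGRAM_BINS), dtype=int)
    for p in corpus:
        if p.g_score is None:
            raise ValueError("score_histogram requires a labeled corpus")
        for i, (lo, hi) in enumerate(HISTOGRAM_BINS):
            if (lo <= p.g_score < hi) or (i == len(HISTOGRAM_BINS) - 1 and p.g_score == hi):
                counts[i] += 1
                break
    return counts


def save_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n", encoding="utf-8")


CHECKPOINT_VERSION = 1


def save_checkpoint(result: TrainResult, path: str | Path) -> None:
    """One archive holding all parameter tensors, config and vocabularies."""
    model = result.model
    meta = {
        "version": CHECKPOINT_VERSION,
        "config": result.manifest["config"],
        "encoder_vocab": model.encoder.vocab,
        "char_vocab": model.char_cnn.vocab.to_dict() if model.char_cnn else None,
        "epoch_losses": result.epoch_losses,
    }
    arrays = {f"param/{k}": v for k, v in model.state_dict().items()}
    if model.kg_table is not None:
        arrays["kg/entity_vecs"] = model.kg_table.entity_vecs
        arrays["kg/relation_vecs"] = model.kg_table.relation_vecs
        meta["kg_entity_ids"] = model.kg_table.entity_ids
        meta["kg_relation_ids"] = model.kg_table.relation_ids
    np.savez(Path(path), __meta__=np.array(json.dumps(meta)), **arrays)


def load_checkpoint(path: str | Path) -> tuple[SimilarityModel, TrainConfig]:
    """Rebuild a model (architecture, vocabularies, weights) from an archive."""
    from .sentence_encoder import EncoderConfig, TinyTransformerEncoder

    with np.load(Path(path), allow_pickle=True) as data:
        meta = json.loads(str(data["__meta__"]))
        if meta["version"] != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['version']}")
        config = TrainConfig(**meta["config"])
        kg_table = None
        if meta.get("kg_entity_ids") is not None and "kg/entity_vecs" in data:
            kg_table = KGEmbeddingTable(
                entity_ids=meta["kg_entity_ids"],
                relation_ids=meta["kg_relation_ids"],
                entity_vecs=data["kg/entity_vecs"],
                relation_vecs=data["kg/relation_vecs"],
            )
        enc_config = EncoderConfig(
            max_len=config.max_seq_len,
            hidden=config.encoder_hidden,
            seed=_derive_seed(config.seed, "encoder"),
        )
        encoder = TinyTransformerEncoder(enc_config, dict(meta["encoder_vocab"]))
        char_vocab = (
            CharVocabulary.from_dict(meta["char_vocab"]) if meta["char_vocab"] else None
        )
        model = SimilarityModel(
            encoder=encoder,
            flags=config.flags(),
            rng=np.random.default_rng(0),
            char_vocab=char_vocab,
            kg_table=kg_table if config.use_entity_ii else None,
            char_embed_dim=config.char_embed_dim,
            char_filters=config.char_filters,
            mlp_hidden=config.mlp_hidden,
        )
        state = {k[len("param/") :]: data[k] for k in data.files if k.startswith("param/")}
        model.load_state_dict(state)
    return model, config
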