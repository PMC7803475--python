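"""Entity-level representation II: translation-based knowledge-graph embeddings.

Entities and relations of a triple store (head, relation, tail — the de
facto benchmark TSV format) are embedded in R^d (d = 100 by default) by
TransE: a true triple should satisfy h + r ≈ t, trained with the margin
ranking loss

    max(0, γ + ‖h + r − t‖ − ‖h′ + r − t′‖)

against corrupted negatives in which the head or the tail (chosen uniformly)
is replaced by a random entity.  Entity vectors are projected to the unit
L2 sphere after every epoch.  Training is plain SGD with hand-derived
gradients; given a seed it is fully deterministic.

For the similarity model the learned table is frozen: each snippet's mapped
entities are average-pooled into eg, and the pair representation is

    E = tanh(W_e [eg_a − eg_b ; eg_a * eg_b] + b_e)

with W_e, b_e trained jointly with the rest of the model.  Snippets with no
mapped entity pool to the zero vector — common in practice, since only a
minority of clinical entities map into the graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import nn

__all__ = [
    "Triple",
    "read_triples",
    "write_triples",
    "KGEmbeddingTable",
    "train_transe",
    "pool_entities",
    "KGAggregator",
]

logger = logging.getLogger(__name__)

_EPS = 1e-12


@dataclass(frozen=True)
class Triple:
    """A (head, relation, tail) edge; all identifiers non-empty strings."""

    head: str
    relation: str
    tail: str

    def __post_init__(self):
        if not (self.head and self.relation and self.tail):
            raise ValueError("triple identifiers must be non-empty")


def read_triples(path: str | Path) -> list[Triple]:
    """Read ``head<TAB>relation<TAB>tail`` per line."""
    triples: list[Triple] = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated fields")
            triples.append(Triple(*fields))
    return triples


def write_triples(triples: list[Triple], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        for t in triples:
            fh.write(f"{t.head}\t{t.relation}\t{t.tail}\n")


class KGEmbeddingTable:
    """Entity and relation vectors of a common dimension d, with lookup."""

    FORMAT_VERSION = 1

    def __init__(
        self,
        entity_ids: list[str],
        relation_ids: list[str],
        entity_vecs: np.ndarray,
        relation_vecs: np.ndarray,
    ):
        self.entity_ids = list(entity_ids)
        self.relation_ids = list(relation_ids)
        self.entity_vecs = np.asarray(entity_vecs, dtype=np.float64)
        self.relation_vecs = np.asarray(relation_vecs, dtype=np.float64)
        self._e_index = {e: i for i, e in enumerate(self.entity_ids)}
        self._r_index = {r: i for i, r in enumerate(self.relation_ids)}

    @property
    def dim(self) -> int:
        return self.entity_vecs.shape[1]

    def __contains__(self, entity_id: str) -> bool:
        return entity_id in self._e_index

    def entity(self, entity_id: str) -> np.ndarray:
        return self.entity_vecs[self._e_index[entity_id]]

    def relation(self, relation_id: str) -> np.ndarray:
        return self.relation_vecs[self._r_index[relation_id]]

    def score(self, triple: Triple) -> float:
        """TransE dissimilarity ‖h + r − t‖ (lower = more plausible)."""
        return float(
            np.linalg.norm(
                self.entity(triple.head) + self.relation(triple.relation) - self.entity(triple.tail)
            )
        )

    # -- serialization: header (ids) + dense matrix, all text-friendly npz ----

    def save(self, path: str | Path) -> None:
        np.savez(
            Path(path),
            format_version=np.array(self.FORMAT_VERSION),
            entity_ids=np.array(self.entity_ids, dtype=object),
            relation_ids=np.array(self.relation_ids, dtype=object),
            entity_vecs=self.entity_vecs,
            relation_vecs=self.relation_vecs,
        )

    @classmethod
    def load(cls, path: str | Path) -> "KGEmbeddingTable":
        with np.load(Path(path), allow_pickle=True) as data:
            version = int(data["format_version"])
            if version != cls.FORMAT_VERSION:
                raise ValueError(f"unsupported embedding table version {version}")
            return cls(
                entity_ids=[str(e) for e in data["entity_ids"]],
                relation_ids=[str(r) for r in data["relation_ids"]],
                entity_vecs=data["entity_vecs"],
                relation_vecs=data["relation_vecs"],
            )


def train_transe(
    triples: list[Triple],
    d: int = 100,
    margin: float = 1.0,
    epochs: int = 200,
    lr: float = 0.01,
    seed: int = 0,
) -> KGEmbeddingTable:
    """Train TransE embeddings on a triple store.

    Uniform negative sampling (head or tail corrupted with equal
    probability), SGD on the margin ranking loss with L2 dissimilarity, and
    unit-norm projection of every entity vector at the end of each epoch.
    """
    if not triples:
        raise ValueError("cannot train on an empty triple set")
    if d < 2:
        raise ValueError("embedding dimension must be >= 2")
    entity_ids = sorted({t.head for t in triples} | {t.tail for t in triples})
    relation_ids = sorted({t.relation for t in triples})
    e_index = {e: i for i, e in enumerate(entity_ids)}
    r_index = {r: i for i, r in enumerate(relation_ids)}
    rng = np.random.default_rng(seed)

    bound = 6.0 / np.sqrt(d)
    E = rng.uniform(-bound, bound, size=(len(entity_ids), d))
    R = rng.uniform(-bound, bound, size=(len(relation_ids), d))
    R /= np.maximum(np.linalg.norm(R, axis=1, keepdims=True), _EPS)
    E /= np.maximum(np.linalg.norm(E, axis=1, keepdims=True), _EPS)

    idx = np.array([(e_index[t.head], r_index[t.relation], e_index[t.tail]) for t in triples])
    n = len(triples)
    n_entities = len(entity_ids)

    for _ in range(epochs):
        order = rng.permutation(n)
        corrupt_head = rng.random(n) < 0.5
        replacements = rng.integers(0, n_entities, size=n)
        for pos, j in enumerate(order):
            h, r, t = idx[j]
            if corrupt_head[pos]:
                h_neg, t_neg = int(replacements[pos]), t
            else:
                h_neg, t_neg = h, int(replacements[pos])
            diff_pos = E[h] + R[r] - E[t]
            diff_neg = E[h_neg] + R[r] - E[t_neg]
            d_pos = np.linalg.norm(diff_pos)
            d_neg = np.linalg.norm(diff_neg)
            if margin + d_pos - d_neg <= 0.0:
                continue
            g_pos = diff_pos / max(d_pos, _EPS)  # ∂‖x‖/∂x = x/‖x‖
            g_neg = diff_neg / max(d_neg, _EPS)
            E[h] -= lr * g_pos
            E[t] += lr * g_pos
            R[r] -= lr * (g_pos - g_neg)
            E[h_neg] += lr * g_neg
            E[t_neg] -= lr * g_neg
        E /= np.maximum(np.linalg.norm(E, axis=1, keepdims=True), _EPS)

    return KGEmbeddingTable(entity_ids, relation_ids, E, R)


def pool_entities(entity_ids: list[str], table: KGEmbeddingTable) -> np.ndarray:
    """Arithmetic mean of the vectors of the listed entities.

    Unknown identifiers are skipped with a logged warning; an empty (or
    fully unknown) list pools to the zero vector of dimension d.
    """
    vecs = []
    for eid in entity_ids:
        if eid in table:
            vecs.append(table.entity(eid))
        else:
            logger.warning("entity %r absent from embedding table; skipped", eid)
    if not vecs:
        return np.zeros(table.dim)
    return np.mean(vecs, axis=0)


class KGAggregator(nn.Module):
    """E = tanh(W_e [eg_a − eg_b ; eg_a * eg_b] + b_e); W_e, b_e trainable."""

    def __init__(self, d: int, rng: np.random.Generator, output_dim: int | None = None):
        self.d = d
        self.output_dim = output_dim if output_dim is not None else d
        self.linear = nn.Linear(2 * d, self.output_dim, rng)

    def __call__(self, eg_a: np.ndarray | nn.Tensor, eg_b: np.ndarray | nn.Tensor) -> nn.Tensor:
        a = nn.Tensor.as_tensor(eg_a)
        b = nn.Tensor.as_tensor(eg_b)
        if a.shape != b.shape or a.shape != (self.d,):
            raise ValueError(
                f"pooled entity vectors must both have dimension {self.d}; "
                f"got {a.shape} and {b.shape}"
            )
        features = nn.concat([a - b, a * b], axis=0)
        return self.linear(features).tanh()
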