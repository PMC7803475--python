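"""Train translation-based embeddings on a toy knowledge graph.

A small triple store (head, relation, tail) is embedded so that
h + r is close to t for true triples; the dissimilarity ||h + r - t||
then ranks plausible edges above corrupted ones.  Snippet-level entity
vectors are average-pooled from the table.
"""

import numpy as np

from clinsts import Triple, pool_entities, train_transe

triples = [
    Triple("zocor", "treats", "hyperlipidemia"),
    Triple("tabufen", "treats", "migraine"),
    Triple("migraine", "is_a", "disorder"),
    Triple("hyperlipidemia", "is_a", "disorder"),
]

table = train_transe(triples, d=16, margin=1.0, epochs=200, lr=0.05, seed=0)

print(f"entities: {table.entity_ids}")
print(f"entity vector norms: {np.linalg.norm(table.entity_vecs, axis=1).round(6)}")

true = triples[0]
corrupt = Triple("zocor", "treats", "migraine")
print(f"score(true  {true.head}-{true.relation}->{true.tail}) = {table.score(true):.3f}")
print(f"score(wrong {corrupt.head}-{corrupt.relation}->{corrupt.tail}) = {table.score(corrupt):.3f}")
# the true triple scores LOWER (= more plausible) than the corruption

eg = pool_entities(["zocor", "hyperlipidemia"], table)
print(f"pooled snippet vector: dim={eg.shape[0]}, norm={np.linalg.norm(eg):.3f}")
print(f"no mapped entities pools to zeros: {pool_entities([], table)[:4]}")
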