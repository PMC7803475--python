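# Methods

## Task and model

Clinical semantic textual similarity: regress a similarity score in [0, 5]
for a pair of clinical text snippets *(a, b)* and evaluate with the Pearson
correlation coefficient. The model fuses three representations of the pair,

    f = [S; C; E],        p = MLP(W f + b),

trained end to end with mean squared error against the gold scores. `E` can
be the entity-type-sequence representation (entity I), the knowledge-graph
representation (entity II), or both concatenated; any subset of {C, E_I,
E_II} can be disabled, which is what the seven-row ablation exercises. At
inference, raw outputs are clipped to [0, 5] before scoring — gold scores
live on that scale and an unclipped regressor can stray outside it early in
training. The output bias is initialised at 2.5 (the scale midpoint) so the
clip is not saturated at initialisation.

## Components and their parameters

**Sentence level (S).** The pair is encoded jointly as
`[CLS] a [SEP] b [SEP]` with token, learned-position and segment embeddings;
`S` is the final hidden state at `[CLS]`. The encoder is a structural
contract (`PairEncoder`); the shipped implementation is a tiny 2-layer,
2-head post-norm transformer (residual + LayerNorm, ReLU feed-forward) with
a word-plus-character-fallback vocabulary built from the training corpus. Joint sequences longer than `max_len` (default 380) are
truncated pair-wise, trimming the longer segment first. The tiny encoder is
trained from scratch together with the rest of the model; a large pretrained
encoder can be substituted behind the same interface, in which case the
2e-5 default learning rate is the appropriate fine-tuning rate.

**Character level (C).** Characters are embedded (dimension 25, padding row
pinned to zero), convolved with kernel 3 (zero-padding 1 per side so even
1-character tokens yield a window), max-pooled over positions to one
50-dimensional vector per token, then max-pooled elementwise over *all*
tokens of both snippets. Global max pooling makes `C` exactly invariant to
token order and duplication and monotone under token addition; these are
asserted as properties. The embedding dimension and filter count are not
dictated by the fusion architecture; 25/50 are conventional char-CNN sizes
and both are configurable.

**Entity level I (E_I).** Token-aligned label sequences over the nine
clinical entity-mention types + `O` are produced by a pluggable tagger; the
shipped dictionary tagger does greedy longest-match, leftmost-first n-gram
lookup against a lexicon (a cTAKES-style clinical tagger can be adapted in
through the token/label file format). Mentions are maximal same-type runs —
the convention that reproduces the worked medication-line example, where two
non-adjacent occurrences of the same drug word are separate mentions. The
label sequences are embedded (10 × 50 table), passed through a shared wide
convolution (kernel 3, 50 filters, tanh) and average-pooled; the branch
vectors combine as `E_I = [u_a − u_b ; u_a ⊙ u_b]`, the same
difference/product comparison used for entity II, chosen so the two entity
variants are commensurable. The wide convolution pads the *label sequence*
by replicating boundary labels (k−1 per side) rather than zero-padding the
embedding: under replication padding every window of a constant sequence
sees identical content, so the pooled vector of a constant-label sequence is
independent of its length — an exactness property zero padding breaks
(the positional average would then depend on L through the edge windows).

**Entity level II (E_II).** TransE embeddings are trained on a triple file:
margin ranking loss `max(0, γ + ‖h+r−t‖ − ‖h′+r−t′‖)` with L2
dissimilarity, uniform corruption of head or tail, plain SGD, and unit-norm
projection of entity vectors after each epoch. Defaults: d = 100, γ = 1.0,
lr = 0.01, 200 epochs — the embedding dimension is the model's standard
setting; the others follow the original translation-embedding recipe and are
configurable because no single set is canonical for small graphs. The table
is **frozen** during similarity training (the model adopts the learned
entity representations as-is); only the aggregation parameters `W_e, b_e`
train with the model. Snippets whose mentions carry no KG identifier pool to
the zero vector — with realistic coverage (~20% of mentions mapping into a
curated graph) empty sets are common and must be well defined.

## Training and evaluation

Adam (no weight decay) on all trainable parameters with a single learning
rate; MSE is the mean over the batch; exactly `epochs` epochs are run and
the **last** epoch's parameters are kept (no best-epoch selection). One
master seed derives independent stream seeds (parameter init, shuffling,
negative sampling) via an FNV-style hash, so single-threaded runs are bit
reproducible. Pearson correlation is computed on clipped predictions —
what a submission file would contain — and raises on zero-variance inputs
naming the degenerate side. Five-fold cross-validation shuffles once with
the derived seed and splits into near-equal disjoint folds.

Defaults (`TrainConfig`): lr 2e-5, 12 epochs, batch 20, max sequence length
380. Desk-scale runs in the tests, examples and ablations use the tiny
encoder with lr 1e-3, hidden sizes 16–32 and corpora of 16–500 pairs: 2e-5
is a fine-tuning rate for a large pretrained encoder and moves a
from-scratch tiny model too slowly to be informative at these sizes. These
problem sizes were chosen once as the smallest at which the behavioural
properties (overfit learnability, ablation ordering) are stable.

## Synthetic data: what it emulates and what it does not

The generator emulates the *statistical structure* of a graded clinical STS
corpus: template-based snippets (medication lines, exam findings, care
plans, visit notes) with entity mentions drawn from a generated lexicon;
the integer similarity level controls the edit applied to derive snippet B
(paraphrase / numeric-detail change / key-entity swap / topic-sharing /
topic-class-only / unrelated), so higher scores share more entity mentions
by construction; gold scores are the level ± uniform jitter ≤ 0.4, keeping
each level inside its own unit histogram bin so bin frequencies estimate
the mixture weights. KG identifiers are assigned to a subset of lexicon
entries chosen by a greedy subset-sum over observed mention counts
(ascending, so the mass spreads over many entities) to make the
*mention-level* coverage rate match the configured fraction (default 0.2);
the triple graph is a seeded spanning chain plus random chords, hence
connected with every mapped entity in at least one triple.

It does **not** emulate real EHR language: no misspellings, abbreviations,
negation scope, section headers, PHI-like strings, or lexical ambiguity.
Passing tests therefore demonstrate that the architecture and training
machinery work and can exploit entity-driven similarity signal — not that
the model reaches any particular accuracy on real clinical text, which
additionally requires a pretrained encoder and a licensed corpus.

## Numerical choices

* All floats are float64; the autograd core (`clinsts.nn`) computes exact
  reverse-mode gradients verified against central finite differences.
* Max-pool ties split the subgradient evenly; softmax is computed with the
  usual max-shift stabilisation.
* TransE distances are guarded with a 1e-12 epsilon before division.
* Tokenizer: the special-symbol set is fixed to `[ ] / , .` exactly; a `.`
  is kept inside a token iff flanked by digits on both sides. Hyphens and
  other punctuation pass through. A closed set is required for the
  tokenizer to be reproducible; idempotence on its own output is asserted.
* Checkpoints are a single `.npz` archive: parameter tensors, a JSON
  metadata block (config, vocabularies, per-epoch losses, format version)
  and, when present, the frozen KG table.

## Known limitations

* The shipped encoder is deliberately tiny; the sentence representation
  carries far less signal than a pretrained clinical language model would.
* The dictionary tagger has no disambiguation: a surface form has one type.
* Entity I sees only *types*, so it cannot distinguish pairs that differ by
  swapping one entity of the same type — exactly the regime where entity II
  (identity-bearing) information helps.
* TransE on toy graphs is trained far past the regime where its
  hyperparameters matter; none of the defaults should be read as tuned for
  large knowledge graphs.
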