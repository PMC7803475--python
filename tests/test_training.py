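"""Training loop, Pearson evaluation, cross-validation and ablation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clinsts.kg import train_transe
from clinsts.training import (
    ABLATION_CONFIGURATIONS,
    HISTOGRAM_BINS,
    TrainConfig,
    crossvalidate,
    cv_folds,
    evaluate,
    load_checkpoint,
    pearson,
    save_checkpoint,
    score_histogram,
    train,
    write_ablation_tsv,
)
from clinsts.data_io import STSPair
from clinsts.synth import GeneratorSpec, generate_corpus

TINY = dict(learning_rate=1e-3, encoder_hidden=16, mlp_hidden=32, use_entity_ii=False)
TINY_KG = dict(learning_rate=1e-3, encoder_hidden=16, mlp_hidden=32)


def test_pearson_closed_form_oracle():
    p = np.array([1.0, 2.0, 3.0])
    g = np.array([1.0, 2.0, 4.0])
    cov = np.mean((p - p.mean()) * (g - g.mean()))
    expected = cov / (p.std() * g.std())
    assert pearson(p, g) == pytest.approx(expected, abs=1e-12)
    assert pearson(p, p) == pytest.approx(1.0)
    assert pearson(p, -p) == pytest.approx(-1.0)


def test_pearson_errors_name_the_degenerate_side():
    with pytest.raises(ValueError, match="predicted"):
        pearson([1.0, 1.0], [0.0, 1.0])
    with pytest.raises(ValueError, match="gold"):
        pearson([0.0, 1.0], [2.0, 2.0])
    with pytest.raises(ValueError):
        pearson([1.0], [1.0])


@given(
    st.lists(st.floats(-100, 100), min_size=3, max_size=20).filter(
        lambda x: max(x) - min(x) > 1e-3
    ),
    st.floats(0.1, 10),
    st.floats(-5, 5),
)
@settings(max_examples=100, deadline=None)
def test_pearson_affine_invariance(x, a, c):
    x = np.asarray(x)
    assert pearson(x, a * x + c) == pytest.approx(1.0, abs=1e-9)
    assert pearson(x, -a * x + c) == pytest.approx(-1.0, abs=1e-9)


def test_default_config_matches_standard_setting():
    cfg = TrainConfig()
    assert cfg.learning_rate == 2e-5
    assert cfg.epochs == 12
    assert cfg.batch_size == 20
    assert cfg.max_seq_len == 380
    assert cfg.kg_dim == 100
    assert cfg.char_embed_dim == 25


def test_training_is_deterministic_and_logs_per_epoch(small_bundle):
    cfg = TrainConfig(epochs=3, seed=7, **TINY)
    r1 = train(small_bundle.pairs, cfg, lexicon=small_bundle.lexicon)
    r2 = train(small_bundle.pairs, cfg, lexicon=small_bundle.lexicon)
    assert len(r1.epoch_losses) == 3
    assert r1.epoch_losses == r2.epoch_losses
    s1, s2 = r1.model.state_dict(), r2.model.state_dict()
    for k in s1:
        np.testing.assert_array_equal(s1[k], s2[k])


def test_twelve_epoch_run_emits_twelve_loss_entries(small_bundle):
    cfg = TrainConfig(epochs=12, seed=1, **TINY)
    result = train(small_bundle.pairs[:4], cfg, lexicon=small_bundle.lexicon)
    assert len(result.epoch_losses) == 12
    assert result.manifest["config"]["epochs"] == 12


def test_loss_decreases_on_small_corpus(small_bundle):
    cfg = TrainConfig(epochs=20, seed=5, **TINY)
    result = train(small_bundle.pairs, cfg, lexicon=small_bundle.lexicon)
    assert result.epoch_losses[-1] < result.epoch_losses[0]


def test_train_rejects_bad_corpora():
    cfg = TrainConfig(**TINY)
    with pytest.raises(ValueError):
        train([], cfg)
    unlabeled = [STSPair(snippet_a="a b", snippet_b="c d")]
    with pytest.raises(ValueError):
        train(unlabeled, cfg)


def test_checkpoint_roundtrip_preserves_predictions(tmp_path, small_bundle):
    table = train_transe(small_bundle.triples, d=6, epochs=10, seed=0)
    cfg = TrainConfig(epochs=2, seed=3, **TINY_KG)
    result = train(small_bundle.pairs, cfg, lexicon=small_bundle.lexicon, kg_table=table)
    report = evaluate(result.model, small_bundle.pairs, lexicon=small_bundle.lexicon)
    path = tmp_path / "ckpt.npz"
    save_checkpoint(result, path)
    model2, cfg2 = load_checkpoint(path)
    report2 = evaluate(model2, small_bundle.pairs, lexicon=small_bundle.lexicon)
    np.testing.assert_array_equal(report.predictions, report2.predictions)
    assert cfg2.epochs == 2


def test_cv_folds_partition_corpus():
    folds = cv_folds(10, 5, seed=0)
    assert [len(f) for f in folds] == [2, 2, 2, 2, 2]
    all_idx = np.concatenate(folds)
    assert sorted(all_idx.tolist()) == list(range(10))
    # same seed -> identical membership
    folds2 = cv_folds(10, 5, seed=0)
    for a, b in zip(folds, folds2):
        np.testing.assert_array_equal(a, b)
    # uneven sizes stay near-equal
    assert [len(f) for f in cv_folds(11, 5, seed=1)] == [3, 2, 2, 2, 2]


def test_crossvalidate_bookkeeping(small_bundle):
    cfg = TrainConfig(epochs=2, seed=2, **TINY)
    pccs, mean = crossvalidate(small_bundle.pairs, cfg, k=2, lexicon=small_bundle.lexicon)
    assert len(pccs) == 2
    assert mean == pytest.approx(np.mean(pccs))
    with pytest.raises(ValueError):
        crossvalidate(small_bundle.pairs, cfg, k=1)
    with pytest.raises(ValueError):
        crossvalidate(small_bundle.pairs[:3], cfg, k=5)


def test_ablation_configuration_table():
    assert len(ABLATION_CONFIGURATIONS) == 7
    names = [n for n, _ in ABLATION_CONFIGURATIONS]
    assert len(set(names)) == 7
    flags = {n: f for n, f in ABLATION_CONFIGURATIONS}
    assert flags["without_both"] == {
        "use_char": False,
        "use_entity_i": False,
        "use_entity_ii": False,
    }
    # exactly one all-entity row enables everything
    assert flags["entity_I+entity_II"] == {
        "use_char": True,
        "use_entity_i": True,
        "use_entity_ii": True,
    }


def test_score_histogram_bins():
    def pair(s):
        return STSPair(snippet_a="a b", snippet_b="c d", g_score=s)

    assert len(HISTOGRAM_BINS) == 6
    counts = score_histogram([pair(2.5)] * 4)
    assert counts.tolist() == [0, 0, 0, 4, 0, 0]
    assert score_histogram([]).tolist() == [0] * 6
    edge = score_histogram([pair(0.0), pair(0.5), pair(5.0), pair(4.5)])
    assert edge.tolist() == [1, 1, 0, 0, 0, 2]
    assert score_histogram([pair(s) for s in (0.2, 1.0, 2.0, 3.0, 4.0, 4.9)]).tolist() == [1] * 6


def test_histogram_recovers_generator_mixture():
    """With levels jittered inside their own unit bins, bin frequencies
    estimate the mixture weights (±3 points at n=2000)."""
    mixture = (0.05, 0.25, 0.1, 0.3, 0.2, 0.1)
    bundle = generate_corpus(GeneratorSpec(n_pairs=2000, score_mixture=mixture, seed=21))
    freqs = score_histogram(bundle.pairs) / 2000
    np.testing.assert_allclose(freqs, mixture, atol=0.03)


def test_ablation_tsv_report(tmp_path):
    from clinsts.training import EvalReport

    report = EvalReport(pcc=0.5, predictions=np.zeros(1), rows={"entity_I": 0.5, "no_entity": 0.4})
    out = tmp_path / "ablation.tsv"
    write_ablation_tsv(report, out)
    lines = out.read_text().splitlines()
    assert lines[0] == "configuration\tpcc"
    assert len(lines) == 3
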