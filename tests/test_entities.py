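"""Dictionary tagging, mention extraction and KG-identifier mapping."""

import pytest

from clinsts.data_io import TokenSequence, preprocess
from clinsts.entities import (
    ALL_LABELS,
    ENTITY_TYPES,
    OUTSIDE,
    DictionaryTagger,
    EntityLexicon,
    kg_coverage,
    kg_entities,
    mentions,
    read_label_file,
    tag,
)
from clinsts.synth import GeneratorSpec, generate_corpus

MED_SENTENCE = "Zocor 40 mg tablet 1 tablet by mouth one time daily."


def test_label_vocabulary_is_closed():
    assert len(ENTITY_TYPES) == 9
    assert len(ALL_LABELS) == 10 and ALL_LABELS[-1] == OUTSIDE


def test_medication_line_worked_example(fig_lexicon):
    """The printed per-token label sequence of the medication-line example."""
    toks = preprocess(MED_SENTENCE)
    labels = tag(toks, fig_lexicon)
    assert labels == (
        "MedicationMention", "O", "O", "MedicationMention", "O",
        "MedicationMention", "O", "AnatomicalSiteMention", "O", "O", "O", "O",
    )
    ms = mentions(labels)
    assert sum(m.entity_type == "MedicationMention" for m in ms) == 3
    assert sum(m.entity_type == "AnatomicalSiteMention" for m in ms) == 1
    assert [m.surface(toks) for m in ms] == ["zocor", "tablet", "tablet", "mouth"]


def test_empty_lexicon_tags_all_outside():
    toks = preprocess("anything at all")
    assert tag(toks, EntityLexicon()) == (OUTSIDE,) * 3
    assert mentions(tag(toks, EntityLexicon())) == []


def greedy_oracle(tokens: tuple[str, ...], entries: dict[tuple[str, ...], str]) -> tuple[str, ...]:
    """Longest-match oracle by explicit enumeration of spans at each position."""
    labels = [OUTSIDE] * len(tokens)
    i = 0
    while i < len(tokens):
        spans = [
            (j, entries[tokens[i:j]])
            for j in range(len(tokens), i, -1)
            if tokens[i:j] in entries
        ]
        if spans:
            j, etype = max(spans, key=lambda s: s[0])
            for k in range(i, j):
                labels[k] = etype
            i = j
        else:
            i += 1
    return tuple(labels)


@pytest.mark.parametrize(
    "tokens,entries",
    [
        (("heart", "attack"), {("heart", "attack"): "DiseaseDisorderMention",
                               ("heart",): "AnatomicalSiteMention"}),
        (("acute", "heart", "attack", "pain"),
         {("heart",): "AnatomicalSiteMention",
          ("heart", "attack"): "DiseaseDisorderMention",
          ("attack", "pain"): "SignSymptomMention",
          ("pain",): "SignSymptomMention"}),
        (("a", "b", "a"), {("a", "b"): "Predicate", ("b", "a"): "ProcedureMention",
                           ("a",): "TemporalInformation"}),
    ],
)
def test_longest_match_against_enumeration_oracle(tokens, entries):
    lex = EntityLexicon((" ".join(k), v, None) for k, v in entries.items())
    seq = TokenSequence(tokens=tokens)
    assert tag(seq, lex) == greedy_oracle(tokens, entries)


def test_overlapping_entries_prefer_longest():
    lex = EntityLexicon(
        [("heart attack", "DiseaseDisorderMention", None), ("heart", "AnatomicalSiteMention", None)]
    )
    seq = TokenSequence(tokens=("heart", "attack"))
    assert tag(seq, lex) == ("DiseaseDisorderMention", "DiseaseDisorderMention")


def test_tag_preserves_length_and_is_deterministic(small_bundle):
    tagger = DictionaryTagger(small_bundle.lexicon)
    for pair in small_bundle.pairs:
        toks = preprocess(pair.snippet_a)
        labels = tagger(toks)
        assert len(labels) == len(toks)
        assert labels == tagger(toks)
        assert len(mentions(labels)) <= len(toks)


def test_mention_runs():
    assert len(mentions(("MedicationMention",) * 2 + (OUTSIDE, "MedicationMention"))) == 2
    runs = mentions(("MedicationMention", "AnatomicalSiteMention"))
    assert [m.entity_type for m in runs] == ["MedicationMention", "AnatomicalSiteMention"]
    assert mentions((OUTSIDE,) * 4) == []


def test_kg_entities_mapping(fig_lexicon):
    toks = preprocess(MED_SENTENCE)
    labels = tag(toks, fig_lexicon)
    # only "zocor" carries an identifier in the fixture lexicon
    assert kg_entities(labels, toks, fig_lexicon) == ["K0001"]

    lex = EntityLexicon([("zocor", "MedicationMention", "E1")])
    toks2 = preprocess("zocor then zocor")
    labels2 = tag(toks2, lex)
    assert kg_entities(labels2, toks2, lex) == ["E1", "E1"]
    assert kg_entities((OUTSIDE, OUTSIDE), TokenSequence(tokens=("x", "y")), lex) == []


def test_kg_entities_resegments_merged_runs():
    lex = EntityLexicon(
        [("zocor", "MedicationMention", "E1"), ("tablet", "MedicationMention", "E2")]
    )
    toks = TokenSequence(tokens=("zocor", "tablet"))
    labels = tag(toks, lex)
    assert mentions(labels) and mentions(labels)[0].end == 2  # merged same-type run
    assert kg_entities(labels, toks, lex) == ["E1", "E2"]


def test_kg_coverage_recovers_generator_rate():
    """Mention-level KG-mapping rate tracks the generator's setting within 2 points."""
    bundle = generate_corpus(GeneratorSpec(n_pairs=300, kg_fraction=0.2, seed=11))
    token_seqs, label_seqs = [], []
    for p in bundle.pairs:
        for snip in (p.snippet_a, p.snippet_b):
            toks = preprocess(snip)
            token_seqs.append(toks)
            label_seqs.append(tag(toks, bundle.lexicon))
    mapped, total = kg_coverage(label_seqs, token_seqs, bundle.lexicon)
    assert total >= 1000
    assert abs(mapped / total - 0.2) <= 0.02


def test_lexicon_tsv_roundtrip(tmp_path, fig_lexicon):
    path = tmp_path / "lex.tsv"
    fig_lexicon.write_tsv(path)
    back = EntityLexicon.read_tsv(path)
    assert back.lookup(("zocor",)) == ("MedicationMention", "K0001")
    assert back.lookup(("mouth",)) == ("AnatomicalSiteMention", None)
    assert len(back) == len(fig_lexicon)


def test_lexicon_is_case_insensitive():
    lex = EntityLexicon([("Zocor", "MedicationMention", None)])
    assert lex.lookup(("zocor",)) is not None
    with pytest.raises(ValueError):
        lex.add("x", "NotAType")


def test_label_file_adapter(tmp_path):
    path = tmp_path / "labels.tsv"
    path.write_text(
        "zocor\tMedicationMention\nby\tO\n\nmouth\tAnatomicalSiteMention\n", encoding="utf-8"
    )
    snippets = read_label_file(path)
    assert snippets == [
        (("zocor", "by"), ("MedicationMention", "O")),
        (("mouth",), ("AnatomicalSiteMention",)),
    ]
    bad = tmp_path / "bad.tsv"
    bad.write_text("tok\tNotALabel\n", encoding="utf-8")
    with pytest.raises(ValueError, match="bad.tsv:1"):
        read_label_file(bad)
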