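"""Corpus I/O and rule-based tokenization."""

import re

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clinsts.data_io import (
    SPECIAL_SYMBOLS,
    STSPair,
    preprocess,
    read_sts_tsv,
    write_predictions,
    write_sts_tsv,
)


def regex_tokenize_oracle(text: str) -> list[str]:
    """Independent tokenizer: regex-based, unlike the character scanner."""
    text = text.lower()
    # protect digit.digit, then split out the special symbols
    protected = re.sub(r"(?<=\d)\.(?=\d)", "\x00", text)
    pieces = re.split(r"([\[\]/,.])|\s+", protected)
    return [p.replace("\x00", ".") for p in pieces if p]


@pytest.mark.parametrize(
    "text,expected",
    [
        (
            "Albuterol [PROVENTIL/VENTOLIN] 90",
            ["albuterol", "[", "proventil", "/", "ventolin", "]", "90"],
        ),
        ("dose 2.5 mg.", ["dose", "2.5", "mg", "."]),
        ("ABC", ["abc"]),
        ("a,b", ["a", ",", "b"]),
        ("x 1-2 puffs", ["x", "1-2", "puffs"]),  # hyphens pass through
        (".5 mg", [".", "5", "mg"]),  # leading dot is not a decimal
        ("v1.2.3", ["v1.2.3"]),
    ],
)
def test_preprocess_examples(text, expected):
    assert list(preprocess(text).tokens) == expected


@given(st.text(min_size=1, max_size=60))
@settings(max_examples=300, deadline=None)
def test_preprocess_matches_regex_oracle(text):
    if not text.strip() or "\x00" in text:  # NUL is the oracle's sentinel
        return
    assert list(preprocess(text).tokens) == regex_tokenize_oracle(text)


@given(st.text(min_size=1, max_size=60))
@settings(max_examples=200, deadline=None)
def test_preprocess_token_invariants(text):
    if not text.strip():
        return
    seq = preprocess(text)
    assert len(seq.tokens) >= 1
    assert len(seq.char_ids) == len(seq.tokens)
    for tok in seq.tokens:
        assert tok == tok.lower() and len(tok) >= 1
        if tok not in SPECIAL_SYMBOLS:
            for sym in "[]/,":
                assert sym not in tok
            for i, c in enumerate(tok):  # any remaining '.' is a decimal point
                if c == ".":
                    assert 0 < i < len(tok) - 1
                    assert tok[i - 1].isdigit() and tok[i + 1].isdigit()
    # idempotence on the joined output
    rejoined = " ".join(seq.tokens)
    assert preprocess(rejoined).tokens == seq.tokens


def test_preprocess_rejects_empty():
    with pytest.raises(ValueError):
        preprocess("   ")


def test_read_sts_tsv_parses_and_validates(tmp_path):
    p = tmp_path / "c.tsv"
    p.write_text("A.\tB.\t5.0\nC x\tD y\t0\nE\tF\t2.5\n", encoding="utf-8")
    pairs = read_sts_tsv(p, labeled=True)
    assert len(pairs) == 3
    assert pairs[0].snippet_a == "A." and pairs[0].g_score == 5.0
    assert [q.g_score for q in pairs] == [5.0, 0.0, 2.5]

    bad = tmp_path / "bad.tsv"
    bad.write_text("A.\tB.\t6.0\n", encoding="utf-8")
    with pytest.raises(ValueError, match="bad.tsv:1"):
        read_sts_tsv(bad, labeled=True)

    malformed = tmp_path / "m.tsv"
    malformed.write_text("only one field\n", encoding="utf-8")
    with pytest.raises(ValueError, match="m.tsv:1"):
        read_sts_tsv(malformed, labeled=True)


def test_unlabeled_read(tmp_path):
    p = tmp_path / "u.tsv"
    p.write_text("A snippet\tB snippet\n", encoding="utf-8")
    (pair,) = read_sts_tsv(p, labeled=False)
    assert pair.g_score is None


def test_pair_validation():
    with pytest.raises(ValueError):
        STSPair(snippet_a=" ", snippet_b="b", g_score=1.0)
    with pytest.raises(ValueError):
        STSPair(snippet_a="a", snippet_b="b", g_score=5.5)


@given(
    st.lists(
        st.tuples(
            st.text(
                alphabet=st.characters(blacklist_characters="\t\n\r", blacklist_categories=("Cs",)),
                min_size=1,
            ).filter(lambda s: s.strip()),
            st.text(
                alphabet=st.characters(blacklist_characters="\t\n\r", blacklist_categories=("Cs",)),
                min_size=1,
            ).filter(lambda s: s.strip()),
            st.floats(min_value=0.0, max_value=5.0, allow_nan=False),
        ),
        min_size=1,
        max_size=10,
    )
)
@settings(max_examples=50, deadline=None)
def test_tsv_roundtrip(tmp_path_factory, rows):
    tmp = tmp_path_factory.mktemp("rt") / "c.tsv"
    pairs = [STSPair(snippet_a=a, snippet_b=b, g_score=s) for a, b, s in rows]
    write_sts_tsv(pairs, tmp)
    back = read_sts_tsv(tmp, labeled=True)
    assert [(p.snippet_a, p.snippet_b, p.g_score) for p in back] == [
        (p.snippet_a, p.snippet_b, p.g_score) for p in pairs
    ]


def test_exemplar_pairs_fixture_smoke(exemplar_path):
    """The six graded exemplar pairs load, cover each score level once, and
    tokenize cleanly (incl. bracketed drug names and slash-separated units)."""
    pairs = read_sts_tsv(exemplar_path, labeled=True)
    assert [p.g_score for p in pairs] == [0.0, 1.0, 2.0, 3.0, 4.0, 5.0]
    for p in pairs:
        for snippet in (p.snippet_a, p.snippet_b):
            toks = preprocess(snippet).tokens
            assert len(toks) >= 5
            assert all(t == t.lower() for t in toks)
    # the bracketed formulation splits into standalone symbols
    toks4 = preprocess(pairs[4].snippet_a).tokens
    assert ("[" in toks4) and ("]" in toks4) and ("/" in toks4)


def test_write_predictions(tmp_path):
    p1 = STSPair(snippet_a="a", snippet_b="b", g_score=1.0)
    p2 = STSPair(snippet_a="c", snippet_b="d", g_score=2.0)
    out = tmp_path / "pred.txt"
    write_predictions([p1, p2], [0.0, 5.0], out)
    assert out.read_text().splitlines() == ["0.0000", "5.0000"]
    write_predictions([], [], out)
    assert out.read_text() == ""
    with pytest.raises(ValueError):
        write_predictions([p1], [1.0, 2.0], out)
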