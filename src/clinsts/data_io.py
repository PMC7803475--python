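"""Corpus I/O and preprocessing for clinical STS pairs.

The corpus format is the challenge-style TSV: one pair per line,
``snippetA<TAB>snippetB<TAB>score`` (score omitted for unlabeled sets),
with gold similarity scores on the 0-5 scale.

Preprocessing lowercases each snippet and tokenizes on whitespace plus a
fixed set of special symbols — ``[``, ``]``, ``/``, ``,``, ``.`` — which are
emitted as standalone tokens, except that a ``.`` flanked by digits on both
sides (a decimal number such as ``2.5``) is kept inside its token.  The
symbol set is fixed and documented so tokenization is reproducible; hyphens
and other punctuation pass through unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "STSPair",
    "TokenSequence",
    "SPECIAL_SYMBOLS",
    "read_sts_tsv",
    "write_sts_tsv",
    "preprocess",
    "write_predictions",
]

SPECIAL_SYMBOLS = frozenset("[]/,.")


@dataclass(frozen=True)
class STSPair:
    """A pair of raw clinical text snippets with an optional gold score."""

    snippet_a: str
    snippet_b: str
    g_score: float | None = None
    pair_id: str = ""

    def __post_init__(self):
        if not self.snippet_a.strip() or not self.snippet_b.strip():
            raise ValueError("snippets must be non-empty after whitespace stripping")
        if self.g_score is not None and not 0.0 <= self.g_score <= 5.0:
            raise ValueError(f"g_score {self.g_score} outside [0, 5]")


@dataclass(frozen=True)
class TokenSequence:
    """Lowercased, rule-tokenized snippet with per-token character codes."""

    tokens: tuple[str, ...]
    char_ids: tuple[tuple[int, ...], ...] = field(repr=False, default=())

    def __post_init__(self):
        if self.char_ids and len(self.char_ids) != len(self.tokens):
            raise ValueError("char_ids must align 1:1 with tokens")

    def __len__(self) -> int:
        return len(self.tokens)


def preprocess(snippet: str) -> TokenSequence:
    """Lowercase and rule-tokenize one snippet.

    Splits on whitespace and on each of ``[ ] / , .`` as standalone tokens;
    a ``.`` with a digit immediately on both sides stays inside its token.

    Raises
    ------
    ValueError
        If the snippet is empty or whitespace-only.
    """
    text = snippet.lower()
    if not text.strip():
        raise ValueError("cannot preprocess an empty snippet")
    tokens: list[str] = []
    current: list[str] = []

    def flush():
        if current:
            tokens.append("".join(current))
            current.clear()

    for i, ch in enumerate(text):
        if ch.isspace():
            flush()
        elif ch in SPECIAL_SYMBOLS:
            if (
                ch == "."
                and i > 0
                and i + 1 < len(text)
                and text[i - 1].isdigit()
                and text[i + 1].isdigit()
            ):
                current.append(ch)
            else:
                flush()
                tokens.append(ch)
        else:
            current.append(ch)
    flush()
    char_ids = tuple(tuple(ord(c) for c in tok) for tok in tokens)
    return TokenSequence(tokens=tuple(tokens), char_ids=char_ids)


def read_sts_tsv(path: str | Path, labeled: bool = True) -> list[STSPair]:
    """Read an STS corpus TSV; one :class:`STSPair` per non-empty line.

    Labeled files have three tab-separated fields (snippet, snippet, score),
    unlabeled files two.  Scores must parse as decimals in [0, 5].
    """
    path = Path(path)
    expected = 3 if labeled else 2
    pairs: list[STSPair] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != expected:
                raise ValueError(
                    f"{path}:{lineno}: expected {expected} tab-separated fields, "
                    f"got {len(fields)}"
                )
            score: float | None = None
            if labeled:
                try:
                    score = float(fields[2])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: malformed score {fields[2]!r}") from exc
            try:
                pairs.append(
                    STSPair(
                        snippet_a=fields[0],
                        snippet_b=fields[1],
                        g_score=score,
                        pair_id=f"{path.name}:{lineno}",
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return pairs


def write_sts_tsv(pairs: Iterable[STSPair], path: str | Path) -> None:
    """Write pairs back to the TSV format (labeled if scores are present)."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        for p in pairs:
            if "\t" in p.snippet_a or "\t" in p.snippet_b:
                raise ValueError("literal tabs are not allowed inside snippets")
            if p.g_score is None:
                fh.write(f"{p.snippet_a}\t{p.snippet_b}\n")
            else:
                fh.write(f"{p.snippet_a}\t{p.snippet_b}\t{p.g_score!r}\n")


def write_predictions(
    pairs: Sequence[STSPair], scores: Sequence[float], path: str | Path
) -> None:
    """Write one predicted score per line, in pair order, fixed 4-decimal format."""
    if len(pairs) != len(scores):
        raise ValueError(f"{len(pairs)} pairs but {len(scores)} scores")
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        for s in scores:
            fh.write(f"{float(s):.4f}\n")
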