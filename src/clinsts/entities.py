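"""Entity-type tagging over token sequences.

The model consumes, for each snippet, a per-token sequence of clinical
entity-type labels drawn from the nine cTAKES mention types plus the
non-entity label ``"O"``.  Production clinical taggers (cTAKES) are Java
systems; here the tagger is a contract — any callable producing a
token-aligned label sequence — and the shipped implementation is a
dictionary tagger: greedy longest-match, leftmost-first, over token n-grams
against a lexicon.  The lexicon optionally maps surface forms to
knowledge-graph entity identifiers, standing in for MeSH dictionary lookup.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Protocol

from .data_io import TokenSequence, preprocess

__all__ = [
    "ENTITY_TYPES",
    "ALL_LABELS",
    "OUTSIDE",
    "Mention",
    "EntityLexicon",
    "Tagger",
    "DictionaryTagger",
    "tag",
    "mentions",
    "kg_entities",
    "kg_coverage",
    "read_label_file",
]

#: The nine clinical entity-mention types produced by cTAKES-style taggers.
ENTITY_TYPES: tuple[str, ...] = (
    "AnatomicalSiteMention",
    "DiseaseDisorderMention",
    "FractionAnnotation",
    "MedicationMention",
    "Predicate",
    "ProcedureMention",
    "RomanNumeralAnnotation",
    "SignSymptomMention",
    "TemporalInformation",
)

OUTSIDE = "O"
ALL_LABELS: tuple[str, ...] = ENTITY_TYPES + (OUTSIDE,)
LABEL_INDEX: dict[str, int] = {lab: i for i, lab in enumerate(ALL_LABELS)}


@dataclass(frozen=True)
class Mention:
    """A maximal run of identically labeled tokens."""

    start: int  # token index, inclusive
    end: int  # token index, exclusive
    entity_type: str

    def surface(self, tokens: TokenSequence) -> str:
        return " ".join(tokens.tokens[self.start : self.end])


class EntityLexicon:
    """Surface string -> (entity type, optional KG entity id); case-insensitive.

    Surface forms are tokenized with the corpus tokenizer at insertion time,
    so multi-token entries match over token n-grams.
    """

    def __init__(self, entries: Iterable[tuple[str, str, str | None]] = ()):
        self._entries: dict[tuple[str, ...], tuple[str, str | None]] = {}
        self.max_ngram = 0
        for surface, etype, kg_id in entries:
            self.add(surface, etype, kg_id)

    def add(self, surface: str, entity_type: str, kg_id: str | None = None) -> None:
        if entity_type not in ENTITY_TYPES:
            raise ValueError(f"unknown entity type {entity_type!r}")
        key = preprocess(surface).tokens
        self._entries[key] = (entity_type, kg_id)
        self.max_ngram = max(self.max_ngram, len(key))

    def lookup(self, token_ngram: tuple[str, ...]) -> tuple[str, str | None] | None:
        return self._entries.get(token_ngram)

    def __len__(self) -> int:
        return len(self._entries)

    def surfaces(self) -> list[tuple[str, ...]]:
        return list(self._entries)

    def kg_mapped_fraction(self) -> float:
        if not self._entries:
            return 0.0
        mapped = sum(1 for _, kg in self._entries.values() if kg is not None)
        return mapped / len(self._entries)

    # -- file format: surface<TAB>entity_type[<TAB>kg_entity_id] -------------

    @classmethod
    def read_tsv(cls, path: str | Path) -> "EntityLexicon":
        lex = cls()
        with Path(path).open("r", encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                fields = line.split("\t")
                if len(fields) not in (2, 3):
                    raise ValueError(f"{path}:{lineno}: expected 2 or 3 fields")
                kg_id = fields[2] if len(fields) == 3 and fields[2] else None
                lex.add(fields[0], fields[1], kg_id)
        return lex

    def write_tsv(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
            for key in sorted(self._entries):
                etype, kg_id = self._entries[key]
                surface = " ".join(key)
                if kg_id is None:
                    fh.write(f"{surface}\t{etype}\n")
                else:
                    fh.write(f"{surface}\t{etype}\t{kg_id}\n")


class Tagger(Protocol):
    """Contract for anything that labels tokens with entity types."""

    def __call__(self, tokens: TokenSequence) -> tuple[str, ...]: ...


def tag(tokens: TokenSequence, lexicon: EntityLexicon) -> tuple[str, ...]:
    """Greedy longest-match, leftmost-first dictionary tagging.

    Every token of a matched mention receives the mention's entity type;
    unmatched tokens get ``"O"``.  The output is aligned 1:1 with ``tokens``.
    An empty lexicon yields all-``"O"``.
    """
    if len(tokens) == 0:
        raise ValueError("cannot tag an empty token sequence")
    n = len(tokens)
    labels = [OUTSIDE] * n
    i = 0
    while i < n:
        matched = False
        for width in range(min(lexicon.max_ngram, n - i), 0, -1):
            hit = lexicon.lookup(tokens.tokens[i : i + width])
            if hit is not None:
                etype, _ = hit
                for j in range(i, i + width):
                    labels[j] = etype
                i += width
                matched = True
                break
        if not matched:
            i += 1
    return tuple(labels)


class DictionaryTagger:
    """The shipped :class:`Tagger` implementation."""

    def __init__(self, lexicon: EntityLexicon):
        self.lexicon = lexicon

    def __call__(self, tokens: TokenSequence) -> tuple[str, ...]:
        return tag(tokens, self.lexicon)


def mentions(labels: tuple[str, ...]) -> list[Mention]:
    """Maximal runs of identical non-``"O"`` labels, in token order."""
    out: list[Mention] = []
    i = 0
    n = len(labels)
    while i < n:
        if labels[i] == OUTSIDE:
            i += 1
            continue
        j = i + 1
        while j < n and labels[j] == labels[i]:
            j += 1
        out.append(Mention(start=i, end=j, entity_type=labels[i]))
        i = j
    return out


def kg_entities(
    labels: tuple[str, ...], tokens: TokenSequence, lexicon: EntityLexicon
) -> list[str]:
    """KG entity identifiers for the mentions of a snippet, in mention order.

    For each mention the full surface is looked up first; if a merged run is
    not itself a lexicon entry, the span is greedily re-segmented and the
    identifiers of its sub-entries are emitted.  Mentions without any KG
    identifier are skipped.
    """
    ids: list[str] = []
    for m in mentions(labels):
        hit = lexicon.lookup(tokens.tokens[m.start : m.end])
        if hit is not None:
            if hit[1] is not None:
                ids.append(hit[1])
            continue
        i = m.start
        while i < m.end:
            for width in range(m.end - i, 0, -1):
                sub = lexicon.lookup(tokens.tokens[i : i + width])
                if sub is not None:
                    if sub[1] is not None:
                        ids.append(sub[1])
                    i += width
                    break
            else:
                i += 1
    return ids


def kg_coverage(
    label_seqs: Iterable[tuple[str, ...]],
    token_seqs: Iterable[TokenSequence],
    lexicon: EntityLexicon,
) -> tuple[int, int]:
    """(mentions with a KG identifier, total mentions) over a corpus side."""
    mapped = 0
    total = 0
    for labels, tokens in zip(label_seqs, token_seqs):
        ms = mentions(labels)
        total += len(ms)
        for m in ms:
            hit = lexicon.lookup(tokens.tokens[m.start : m.end])
            if hit is not None and hit[1] is not None:
                mapped += 1
    return mapped, total


def read_label_file(path: str | Path) -> list[tuple[tuple[str, ...], tuple[str, ...]]]:
    """Adapter for external tagger output.

    Format: ``token<TAB>label`` per line, blank line between snippets.
    Returns a list of (tokens, labels) per snippet.
    """
    snippets: list[tuple[tuple[str, ...], tuple[str, ...]]] = []
    toks: list[str] = []
    labs: list[str] = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                if toks:
                    snippets.append((tuple(toks), tuple(labs)))
                    toks, labs = [], []
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected token<TAB>label")
            if fields[1] not in LABEL_INDEX:
                raise ValueError(f"{path}:{lineno}: unknown label {fields[1]!r}")
            toks.append(fields[0])
            labs.append(fields[1])
    if toks:
        snippets.append((tuple(toks), tuple(labs)))
    return snippets
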