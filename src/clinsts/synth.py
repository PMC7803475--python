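"""Synthetic clinical-style STS corpora, lexicons and knowledge graphs.

Real clinical STS corpora are gated by data-use agreements, so every stage
of the pipeline is exercised on generated data instead.  The generator
emits graded-similarity snippet pairs built from clinical-style templates
(medication lines, exam findings, care instructions, visit notes), an
entity lexicon whose surface forms fill the template slots, and a toy
knowledge graph whose triples relate those entities.

The integer similarity level of a pair controls the edit operations applied
when deriving snippet B from snippet A:

* 5 — paraphrase only: same template, same slots, benign surface variation.
* 4 — one small numeric detail (dose, count) changed.
* 3 — same frame, one key entity slot differs.
* 2 — same topic, different template variant sharing topic words.
* 1 — same topic class only; different frame and slots.
* 0 — unrelated templates from different topic classes.

Higher levels therefore share more entity mentions by construction, which
makes "the model can learn entity-driven similarity" a testable property.
The emitted gold score is the level plus a small uniform jitter (±0.4,
clipped to [0, 5]) so each level stays inside its own unit histogram bin.

A configurable fraction of lexicon entities (default 0.2, mirroring how few
clinical entities typically map into a curated medical graph) receives a KG
identifier; the generated triple graph connects all mapped entities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data_io import STSPair
from .entities import EntityLexicon
from .kg import Triple

__all__ = ["GeneratorSpec", "SynthBundle", "generate_corpus", "generate_kg"]

# Surface-form pools per entity type.  Names are invented (synthetic), with
# clinical-style morphology; they never reproduce a real formulary.
_MEDICATIONS = [
    "zocor", "cardizem", "velofex", "dorapril", "mintrazol", "lexarin",
    "tabufen", "novastat", "quilorax", "femodine", "pentrazine", "ostelex",
]
_SITES = ["mouth", "left knee", "forearm", "abdomen", "lower back", "right ankle"]
_DISEASES = ["atrial fibrillation", "chronic fatigue", "hyperlipidemia", "gastritis",
             "migraine", "osteoarthritis"]
_SYMPTOMS = ["swelling", "edema", "numbness", "dizziness", "wheezing", "dry cough"]
_PROCEDURES = ["physical therapy", "ultrasound", "x-ray", "colonoscopy"]
_TEMPORALS = ["daily", "weekly", "every 4 hours", "twice daily"]
_FREQ_WORDS = {"daily": "one time daily", "weekly": "one time weekly",
               "every 4 hours": "every 4 hours as needed", "twice daily": "two times daily"}


@dataclass
class GeneratorSpec:
    """Controls of the synthetic corpus generator.

    ``score_mixture`` gives the probability of each integer similarity
    level 0..5; ``kg_fraction`` the fraction of lexicon entities that carry
    a KG identifier.
    """

    n_pairs: int = 100
    score_mixture: tuple[float, ...] = (1 / 6,) * 6
    n_medications: int = 12
    kg_fraction: float = 0.2
    score_jitter: float = 0.4
    seed: int = 0

    def __post_init__(self):
        if len(self.score_mixture) != 6:
            raise ValueError("score_mixture must have one weight per level 0..5")
        if abs(sum(self.score_mixture) - 1.0) > 1e-9:
            raise ValueError("score_mixture weights must sum to 1")
        if self.n_pairs <= 0 or self.n_medications <= 0:
            raise ValueError("all counts must be positive")
        if not 0.0 <= self.kg_fraction <= 1.0:
            raise ValueError("kg_fraction must lie in [0, 1]")
        if not 0.0 <= self.score_jitter <= 0.45:
            raise ValueError("score_jitter must lie in [0, 0.45] to keep levels in their bins")
        if self.n_medications > len(_MEDICATIONS):
            raise ValueError(f"at most {len(_MEDICATIONS)} medication surfaces available")


@dataclass
class SynthBundle:
    """Everything one generator run emits."""

    pairs: list[STSPair]
    lexicon: EntityLexicon
    triples: list[Triple]
    kg_id_of: dict[str, str] = field(default_factory=dict)


def _lexicon_entries(spec: GeneratorSpec) -> list[tuple[str, str]]:
    entries: list[tuple[str, str]] = []
    entries += [(m, "MedicationMention") for m in _MEDICATIONS[: spec.n_medications]]
    entries += [(s, "AnatomicalSiteMention") for s in _SITES]
    entries += [(d, "DiseaseDisorderMention") for d in _DISEASES]
    entries += [(s, "SignSymptomMention") for s in _SYMPTOMS]
    entries += [(p, "ProcedureMention") for p in _PROCEDURES]
    entries += [(t, "TemporalInformation") for t in _TEMPORALS]
    return entries


def _assign_kg_ids(
    entries: list[tuple[str, str]],
    mention_counts: dict[str, int],
    spec: GeneratorSpec,
) -> dict[str, str]:
    """Pick the KG-mapped subset so the *mention-level* coverage rate of the
    generated corpus approximates ``spec.kg_fraction``.

    Mention frequencies over lexicon entries are uneven (route words recur in
    every medication line), so a uniformly random entry subset would not hit
    the target rate; a greedy subset-sum over observed counts does.
    """
    if spec.kg_fraction == 0.0:
        return {}
    total = sum(mention_counts.values())
    target = spec.kg_fraction * total
    running = 0.0
    mapped: list[str] = []
    # ascending counts: spreads the target mention mass over many entities
    ordered = sorted(entries, key=lambda e: (mention_counts.get(e[0], 0), e[0]))
    for surface, _ in ordered:
        count = mention_counts.get(surface, 0)
        if running + count <= target:
            mapped.append(surface)
            running += count
    for surface, _ in ordered:  # a graph needs at least two nodes
        if len(mapped) >= 2:
            break
        if surface not in mapped:
            mapped.append(surface)
    return {surface: f"K{i:04d}" for i, surface in enumerate(sorted(mapped))}


@dataclass
class _Frame:
    """A filled template: topic class + slot values + renderers."""

    topic: str
    slots: dict[str, str]


def _sample_frame(topic: str, rng: np.random.Generator, spec: GeneratorSpec) -> _Frame:
    meds = _MEDICATIONS[: spec.n_medications]
    if topic == "medication":
        slots = {
            "med": str(rng.choice(meds)),
            "dose": str(int(rng.choice([10, 20, 40, 80, 90]))),
            "count": str(int(rng.integers(1, 4))),
            "site": str(rng.choice(["mouth"])),
            "freq": str(rng.choice(_TEMPORALS)),
        }
    elif topic == "finding":
        slots = {
            "symptom": str(rng.choice(_SYMPTOMS)),
            "site": str(rng.choice(_SITES)),
            "polarity": str(rng.choice(["no ", ""])),
        }
    elif topic == "plan":
        slots = {
            "disease": str(rng.choice(_DISEASES)),
            "procedure": str(rng.choice(_PROCEDURES)),
        }
    else:  # visit
        slots = {
            "disease": str(rng.choice(_DISEASES)),
            "freq": str(rng.choice(_TEMPORALS)),
        }
    return _Frame(topic=topic, slots=slots)


def _render(frame: _Frame, variant: int) -> str:
    s = frame.slots
    if frame.topic == "medication":
        freq = _FREQ_WORDS[s["freq"]]
        if variant == 0:
            return (
                f"{s['med']} {s['dose']} mg tablet {s['count']} tablet "
                f"by {s['site']} {freq}."
            )
        return (
            f"take {s['count']} tablet of {s['med']} {s['dose']} mg "
            f"by {s['site']} {freq}."
        )
    if frame.topic == "finding":
        if variant == 0:
            return f"there is {s['polarity']}{s['symptom']} present in the {s['site']}."
        return f"{s['polarity']}{s['symptom']} noted in the {s['site']} on exam."
    if frame.topic == "plan":
        if variant == 0:
            return (
                f"i explained the diagnosis and treatment plan for {s['disease']} "
                f"and recommended {s['procedure']}."
            )
        return (
            f"began discussion of diagnosis and treatment of {s['disease']}, "
            f"{s['procedure']} recommended."
        )
    if variant == 0:
        return (
            f"patient was seen for follow up of {s['disease']} and will "
            f"return {s['freq']}."
        )
    return f"follow up visit for {s['disease']}, patient to return {s['freq']}."


_TOPICS = ("medication", "finding", "plan", "visit")

_KEY_SLOT = {"medication": "med", "finding": "symptom", "plan": "disease", "visit": "disease"}


def _perturb_numeric(frame: _Frame, rng: np.random.Generator) -> _Frame:
    slots = dict(frame.slots)
    if frame.topic == "medication":
        which = "dose" if rng.random() < 0.5 else "count"
        old = int(slots[which])
        choices = [10, 20, 40, 80, 90] if which == "dose" else [1, 2, 3]
        new = old
        while new == old:
            new = int(rng.choice(choices))
        slots[which] = str(new)
    else:
        # non-numeric frames: flip a minor qualifier instead
        if frame.topic == "finding":
            slots["polarity"] = "" if slots["polarity"] else "no "
        elif "freq" in slots:
            slots["freq"] = str(rng.choice([t for t in _TEMPORALS if t != slots["freq"]]))
        else:
            slots["procedure"] = str(rng.choice([p for p in _PROCEDURES if p != slots["procedure"]]))
    return _Frame(topic=frame.topic, slots=slots)


def _replace_key_slot(frame: _Frame, rng: np.random.Generator, spec: GeneratorSpec) -> _Frame:
    slots = dict(frame.slots)
    key = _KEY_SLOT[frame.topic]
    pools = {
        "med": _MEDICATIONS[: spec.n_medications],
        "symptom": _SYMPTOMS,
        "disease": _DISEASES,
    }
    pool = [v for v in pools[key] if v != slots[key]]
    slots[key] = str(rng.choice(pool))
    return _Frame(topic=frame.topic, slots=slots)


def _make_pair(level: int, rng: np.random.Generator, spec: GeneratorSpec) -> tuple[str, str]:
    topic = str(rng.choice(_TOPICS))
    frame_a = _sample_frame(topic, rng, spec)
    a = _render(frame_a, variant=0)
    if level == 5:
        b = _render(frame_a, variant=1)
    elif level == 4:
        b = _render(_perturb_numeric(frame_a, rng), variant=0)
    elif level == 3:
        b = _render(_replace_key_slot(frame_a, rng, spec), variant=0)
    elif level == 2:
        # same wording skeleton (shared topic words), all slots resampled
        b = _render(_sample_frame(topic, rng, spec), variant=0)
    elif level == 1:
        # same topic class only: different wording and different slots
        b = _render(_sample_frame(topic, rng, spec), variant=1)
    else:
        other = str(rng.choice([t for t in _TOPICS if t != topic]))
        b = _render(_sample_frame(other, rng, spec), variant=int(rng.integers(0, 2)))
    return a, b


def generate_corpus(spec: GeneratorSpec) -> SynthBundle:
    """Generate a labeled corpus, its lexicon and a toy KG; seed-deterministic."""
    from .data_io import preprocess
    from .entities import mentions as extract_mentions
    from .entities import tag

    rng = np.random.default_rng(spec.seed)
    entries = _lexicon_entries(spec)
    levels = rng.choice(6, size=spec.n_pairs, p=np.asarray(spec.score_mixture))
    pairs: list[STSPair] = []
    for i, level in enumerate(levels):
        a, b = _make_pair(int(level), rng, spec)
        jitter = float(rng.uniform(-spec.score_jitter, spec.score_jitter))
        score = float(np.clip(level + jitter, 0.0, 5.0))
        pairs.append(STSPair(snippet_a=a, snippet_b=b, g_score=round(score, 2), pair_id=f"synth:{i}"))

    # count mention occurrences with a type-only lexicon, then choose which
    # entries carry KG identifiers so the mention-level rate hits the spec
    type_lexicon = EntityLexicon((s, t, None) for s, t in entries)
    mention_counts: dict[str, int] = {}
    for p in pairs:
        for snippet in (p.snippet_a, p.snippet_b):
            toks = preprocess(snippet)
            for m in extract_mentions(tag(toks, type_lexicon)):
                mention_counts[m.surface(toks)] = mention_counts.get(m.surface(toks), 0) + 1
    kg_id_of = _assign_kg_ids(entries, mention_counts, spec)
    lexicon = EntityLexicon((s, t, kg_id_of.get(s)) for s, t in entries)
    triples = generate_kg(lexicon, spec, kg_id_of=kg_id_of, rng=rng) if kg_id_of else []
    return SynthBundle(pairs=pairs, lexicon=lexicon, triples=triples, kg_id_of=kg_id_of)


def generate_kg(
    lexicon: EntityLexicon,
    spec: GeneratorSpec,
    kg_id_of: dict[str, str] | None = None,
    rng: np.random.Generator | None = None,
) -> list[Triple]:
    """Toy knowledge graph over the lexicon's KG-mapped entities.

    Relations come from a small vocabulary (treats, located_in, is_a,
    related_to); a seeded spanning chain guarantees every mapped entity
    appears in at least one triple and the graph is connected.
    """
    if kg_id_of is None:
        kg_id_of = {}
        for key in lexicon.surfaces():
            etype, kg = lexicon.lookup(key)
            if kg is not None:
                kg_id_of[" ".join(key)] = kg
    ids = sorted(set(kg_id_of.values()))
    if len(ids) < 2:
        raise ValueError("need at least 2 KG-mapped entities to build a graph")
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    relations = ["treats", "located_in", "is_a", "related_to"]
    order = [ids[i] for i in rng.permutation(len(ids))]
    triples = [
        Triple(head=order[i], relation=str(rng.choice(relations)), tail=order[i + 1])
        for i in range(len(order) - 1)
    ]
    # extra random edges for density
    n_extra = max(1, len(ids) // 2)
    for _ in range(n_extra):
        h, t = rng.choice(ids, size=2, replace=False)
        triples.append(Triple(head=str(h), relation=str(rng.choice(relations)), tail=str(t)))
    return triples


def write_bundle(bundle: SynthBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write corpus/lexicon/triples in the formats the other modules consume."""
    from .data_io import write_sts_tsv
    from .kg import write_triples

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "corpus": out / "corpus.tsv",
        "lexicon": out / "lexicon.tsv",
        "triples": out / "triples.tsv",
    }
    write_sts_tsv(bundle.pairs, paths["corpus"])
    bundle.lexicon.write_tsv(paths["lexicon"])
    write_triples(bundle.triples, paths["triples"])
    return paths
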