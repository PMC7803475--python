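"""Tokenize a medication line and tag it with a dictionary lexicon.

Builds a three-entry lexicon, preprocesses one snippet with the rule-based
tokenizer (lowercasing; ``[ ] / , .`` split off; decimals kept intact), tags
each token with its clinical entity type, and extracts mentions as maximal
same-type runs.
"""

from clinsts import EntityLexicon, mentions, preprocess, tag

sentence = "Zocor 40 mg tablet 1 tablet by mouth one time daily."
lexicon = EntityLexicon(
    [
        ("zocor", "MedicationMention", "K0001"),
        ("tablet", "MedicationMention", None),
        ("mouth", "AnatomicalSiteMention", None),
    ]
)

tokens = preprocess(sentence)
labels = tag(tokens, lexicon)

print("tokens:", " ".join(tokens.tokens))
print("labels:", " ".join(labels))
for m in mentions(labels):
    print(f"mention: {m.surface(tokens)!r} -> {m.entity_type}")

# The label sequence aligns 1:1 with the tokens; the three medication
# mentions and one anatomical-site mention drive the entity-level
# representations of the similarity model.
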