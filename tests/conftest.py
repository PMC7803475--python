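from pathlib import Path

import numpy as np
import pytest

from clinsts.entities import EntityLexicon
from clinsts.synth import GeneratorSpec, generate_corpus

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def exemplar_path() -> Path:
    """Six graded exemplar snippet pairs, one per score level 0..5."""
    return DATA_DIR / "exemplar_pairs.tsv"


@pytest.fixture(scope="session")
def fig_lexicon() -> EntityLexicon:
    """Fixture lexicon for the medication-line worked example."""
    return EntityLexicon(
        [
            ("zocor", "MedicationMention", "K0001"),
            ("tablet", "MedicationMention", None),
            ("mouth", "AnatomicalSiteMention", None),
        ]
    )


@pytest.fixture(scope="session")
def small_bundle():
    """A 16-pair synthetic bundle shared by the slower model tests."""
    return generate_corpus(GeneratorSpec(n_pairs=16, seed=3))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
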