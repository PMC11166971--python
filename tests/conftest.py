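import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from kiddi.corpus import Corpus, Dialogue, Utterance
from kiddi.knowledge_graph import SSDGraph


@pytest.fixture
def tiny_dialogue() -> Dialogue:
    """Self-report with fever, doctor asks headache, patient agrees."""
    return Dialogue(
        id="d1",
        disease="migraine",
        turns=[
            Utterance("patient", "I have fever.", intent="Symptom", symptoms=["fever"]),
            Utterance("doctor", "Do you also have headache?", symptoms=["headache"]),
            Utterance("patient", "Yes, exactly.", intent="Affirmative", symptoms=[]),
        ],
    )


@pytest.fixture
def tiny_corpus(tiny_dialogue) -> Corpus:
    other = Dialogue(
        id="d2",
        disease="flu",
        turns=[
            Utterance("patient", "I have fever and cough.", intent="Symptom",
                      symptoms=["fever", "cough"]),
        ],
    )
    return Corpus(dialogues=[tiny_dialogue, other])


@pytest.fixture
def toy_kg() -> SSDGraph:
    """Hand-built graph: s1 strongly tied to d1, weakly to d2; s2 to d2."""
    return SSDGraph(
        symptoms=["s1", "s2", "s3"],
        diseases=["d1", "d2"],
        sd_edges={("s1", "d1"): 0.6, ("s1", "d2"): 0.2, ("s2", "d2"): 0.5},
        ss_edges={("s1", "s2"): 1.0, ("s2", "s1"): 1.0},
    )
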