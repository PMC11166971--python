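"""Data model and I/O for annotated diagnosis dialogues.

A corpus is a collection of dyadic doctor-patient conversations. Each
dialogue carries a gold disease label and an ordered list of turns that
strictly alternate between patient and doctor, starting with the patient.
The first patient turn is the *self-report* (the chief complaints the
patient volunteers); later patient turns answer the doctor's symptom
inquiries. Patient turns are annotated with an intent tag:

* ``Symptom`` -- the patient names one or more symptoms in the utterance;
  the ``symptoms`` list holds their canonical names.
* ``Affirmative`` -- the patient agrees with the doctor's question without
  naming the symptom; the ``symptoms`` list is empty and the symptom must
  be recovered from the preceding doctor turn (see
  :mod:`kiddi.distillation`).

A patient turn may also carry no intent (e.g. a denial or small talk);
such turns contribute no symptoms. Doctor turns never carry an intent;
their ``symptoms`` list names the symptom(s) the doctor asks about.

Symptom and disease names are normalized to lowercase with internal
whitespace collapsed, so they behave as discrete slot identifiers.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "Utterance",
    "Dialogue",
    "Corpus",
    "CorpusValidationError",
    "normalize_name",
    "read_corpus",
    "write_corpus",
    "split_corpus",
    "corpus_stats",
]

PATIENT = "patient"
DOCTOR = "doctor"
INTENT_SYMPTOM = "Symptom"
INTENT_AFFIRMATIVE = "Affirmative"

_WS = re.compile(r"\s+")


class CorpusValidationError(ValueError):
    """Raised when a corpus file or object violates the data model."""


def normalize_name(name: str) -> str:
    """Canonicalize a symptom or disease name (lowercase, collapsed spaces)."""
    return _WS.sub(" ", name.strip().lower())


@dataclass
class Utterance:
    speaker: str
    text: str
    intent: str | None = None
    symptoms: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d: dict = {"speaker": self.speaker, "symptoms": list(self.symptoms), "text": self.text}
        if self.intent is not None:
            d["intent"] = self.intent
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Utterance":
        return cls(
            speaker=d["speaker"],
            text=d["text"],
            intent=d.get("intent"),
            symptoms=[normalize_name(s) for s in d.get("symptoms", [])],
        )


@dataclass
class Dialogue:
    id: str
    disease: str
    turns: list[Utterance]

    @property
    def self_report(self) -> Utterance:
        """The first patient utterance (the dialogue's opening turn)."""
        return self.turns[0]

    def patient_turns(self) -> list[Utterance]:
        return [t for t in self.turns if t.speaker == PATIENT]

    def to_dict(self) -> dict:
        return {
            "disease": self.disease,
            "id": self.id,
            "turns": [t.to_dict() for t in self.turns],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Dialogue":
        return cls(
            id=str(d["id"]),
            disease=normalize_name(d["disease"]),
            turns=[Utterance.from_dict(t) for t in d["turns"]],
        )


@dataclass
class Corpus:
    dialogues: list[Dialogue]
    symptom_vocab: list[str] = field(default_factory=list)
    disease_vocab: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.symptom_vocab and not self.disease_vocab:
            self.rebuild_vocabs()

    def rebuild_vocabs(self) -> None:
        """Recompute lexicographically sorted vocabularies from the dialogues."""
        symptoms: set[str] = set()
        diseases: set[str] = set()
        for dlg in self.dialogues:
            diseases.add(dlg.disease)
            for turn in dlg.turns:
                symptoms.update(turn.symptoms)
        self.symptom_vocab = sorted(symptoms)
        self.disease_vocab = sorted(diseases)

    def to_dict(self) -> dict:
        return {"dialogues": [d.to_dict() for d in self.dialogues]}

    @classmethod
    def from_dict(cls, d: dict) -> "Corpus":
        return cls(dialogues=[Dialogue.from_dict(x) for x in d["dialogues"]])


def _fail(dialogue_id: str, message: str) -> None:
    raise CorpusValidationError(f"dialogue {dialogue_id!r}: {message}")


def validate_dialogue(dlg: Dialogue) -> None:
    """Enforce the turn-structure and annotation invariants of one dialogue."""
    if not dlg.turns:
        _fail(dlg.id, "has no turns")
    if not dlg.disease:
        _fail(dlg.id, "empty disease label")
    for i, turn in enumerate(dlg.turns):
        if turn.speaker not in (PATIENT, DOCTOR):
            _fail(dlg.id, f"turn {i}: unknown speaker {turn.speaker!r}")
        expected = PATIENT if i % 2 == 0 else DOCTOR
        if turn.speaker != expected:
            _fail(dlg.id, f"turn {i}: expected {expected} turn (strict alternation, patient first)")
        if turn.speaker == DOCTOR and turn.intent is not None:
            _fail(dlg.id, f"turn {i}: doctor turn carries intent {turn.intent!r}")
        if turn.intent not in (None, INTENT_SYMPTOM, INTENT_AFFIRMATIVE):
            _fail(dlg.id, f"turn {i}: unknown intent {turn.intent!r}")
        if turn.intent == INTENT_SYMPTOM and not turn.symptoms:
            _fail(dlg.id, f"turn {i}: intent=Symptom requires a non-empty symptom list")
        if turn.intent == INTENT_AFFIRMATIVE and turn.symptoms:
            _fail(dlg.id, f"turn {i}: intent=Affirmative must not name symptoms")


def validate_corpus(corpus: Corpus) -> None:
    seen_ids: set[str] = set()
    for dlg in corpus.dialogues:
        if dlg.id in seen_ids:
            _fail(dlg.id, "duplicate dialogue id")
        seen_ids.add(dlg.id)
        validate_dialogue(dlg)
        if dlg.disease not in corpus.disease_vocab:
            _fail(dlg.id, f"disease {dlg.disease!r} missing from disease_vocab")
        for turn in dlg.turns:
            for s in turn.symptoms:
                if s not in corpus.symptom_vocab:
                    _fail(dlg.id, f"symptom {s!r} missing from symptom_vocab")


def read_corpus(path: str | Path) -> Corpus:
    """Read and validate a corpus from its JSON file format."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        try:
            raw = json.load(fh)
        except json.JSONDecodeError as exc:
            raise CorpusValidationError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(raw, dict) or "dialogues" not in raw:
        raise CorpusValidationError(f"{path}: top-level object must contain 'dialogues'")
    try:
        corpus = Corpus.from_dict(raw)
    except (KeyError, TypeError) as exc:
        raise CorpusValidationError(f"{path}: malformed dialogue record ({exc})") from exc
    validate_corpus(corpus)
    return corpus


def write_corpus(corpus: Corpus, path: str | Path) -> None:
    """Write a corpus as UTF-8 JSON with sorted keys (byte-stable)."""
    validate_corpus(corpus)
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(corpus.to_dict(), fh, ensure_ascii=False, sort_keys=True, indent=1)
        fh.write("\n")


def split_corpus(
    corpus: Corpus,
    fractions: tuple[float, float, float] = (0.7, 0.1, 0.2),
    seed: int = 0,
) -> tuple[Corpus, Corpus, Corpus]:
    """Partition dialogues into train/validation/test, stratified by disease.

    Sizes follow ``fractions`` exactly (largest-remainder rounding on the
    total). Stratification uses scikit-learn's stratified splitter and
    degrades gracefully to a plain seeded shuffle when class counts are
    too small to stratify. Deterministic given ``seed``.
    """
    from sklearn.model_selection import train_test_split

    if any(f < 0 for f in fractions):
        raise ValueError(f"fractions must be nonnegative, got {fractions}")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")

    n = len(corpus.dialogues)
    targets = _apportion(n, fractions)
    idx = list(range(n))
    labels = [d.disease for d in corpus.dialogues]

    def _split(indices: list[int], n_second: int, rstate: int) -> tuple[list[int], list[int]]:
        if n_second == 0:
            return list(indices), []
        if n_second == len(indices):
            return [], list(indices)
        sub_labels = [labels[i] for i in indices]
        try:
            first, second = train_test_split(
                indices, test_size=n_second, random_state=rstate, stratify=sub_labels
            )
        except ValueError:
            # singleton classes etc.: fall back to a plain seeded shuffle
            first, second = train_test_split(
                indices, test_size=n_second, random_state=rstate, stratify=None
            )
        return list(first), list(second)

    train_idx, rest = _split(idx, targets[1] + targets[2], seed)
    val_idx, test_idx = _split(rest, targets[2], seed + 1)

    def _sub(ids: list[int]) -> Corpus:
        sub = Corpus(
            dialogues=[corpus.dialogues[i] for i in sorted(ids)],
            symptom_vocab=list(corpus.symptom_vocab),
            disease_vocab=list(corpus.disease_vocab),
        )
        return sub

    return _sub(train_idx), _sub(val_idx), _sub(test_idx)


def _apportion(n: int, fractions: tuple[float, ...]) -> list[int]:
    """Integer split sizes by largest-remainder rounding."""
    ideal = [f * n for f in fractions]
    sizes = [int(x) for x in ideal]
    remainders = sorted(
        range(len(fractions)), key=lambda i: (ideal[i] - sizes[i], -i), reverse=True
    )
    for i in range(n - sum(sizes)):
        sizes[remainders[i % len(fractions)]] += 1
    return sizes


def corpus_stats(corpus: Corpus) -> dict[str, float]:
    """Descriptive statistics: dialogue/utterance counts, length, vocab sizes."""
    n_dialogues = len(corpus.dialogues)
    n_utterances = sum(len(d.turns) for d in corpus.dialogues)
    # dialogue length in turn pairs: one pair = a patient turn plus the
    # doctor reply (a trailing unpaired patient turn counts as a pair)
    pair_counts = [(len(d.turns) + 1) // 2 for d in corpus.dialogues]
    return {
        "n_dialogues": n_dialogues,
        "n_utterances": n_utterances,
        "avg_turn_pairs": (sum(pair_counts) / n_dialogues) if n_dialogues else 0.0,
        "n_diseases": len(corpus.disease_vocab),
        "n_symptoms": len(corpus.symptom_vocab),
    }
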