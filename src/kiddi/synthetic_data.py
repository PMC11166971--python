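"""Synthetic dialogue corpora with planted symptom-disease structure.

The generator emulates the structure of an annotated medical consultation
corpus: each disease has a symptom profile that mixes a few *common*
symptoms shared across diseases (the "cold, cough, and fever" confound:
patients volunteer mostly those) with discriminative disease-specific
symptoms that the doctor must elicit turn by turn. Every dialogue opens
with a patient self-report drawn preferentially from the common symptoms,
followed by doctor inquiries that each name exactly one symptom and
patient replies that either name the symptom (intent ``Symptom``) or
agree without naming it (intent ``Affirmative``).

Because the generator keeps books on exactly which symptoms were planted
in each dialogue, it serves as the ground-truth oracle for symptom
extraction, knowledge-graph counting, and end-to-end recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .corpus import (
    DOCTOR,
    INTENT_AFFIRMATIVE,
    INTENT_SYMPTOM,
    PATIENT,
    Corpus,
    Dialogue,
    Utterance,
)

__all__ = [
    "GeneratorConfig",
    "DiseaseProfile",
    "GenerationTruth",
    "sample_profiles",
    "generate_dialogue",
    "generate_corpus",
    "generate",
]


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic consultation generator.

    Defaults describe the reference study condition: 10 diseases over a
    40-symptom vocabulary, 4 common symptoms shared by every disease,
    2-symptom self-reports drawn from the common pool, partial
    elicitation (the doctor raises each remaining profile symptom with
    probability ``p_elicit``, as consultations cover only part of a
    textbook profile), 600 dialogues.
    """

    n_diseases: int = 10
    n_symptoms: int = 40
    symptoms_per_disease: int = 8
    n_common_symptoms: int = 4
    self_report_symptoms: int = 2
    p_affirmative: float = 0.3
    p_elicit: float = 0.7
    noise_rate: float = 0.05
    p_denial: float = 0.1
    n_dialogues: int = 600
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_diseases", "n_symptoms", "symptoms_per_disease",
                     "self_report_symptoms", "n_dialogues"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_common_symptoms < 0:
            raise ValueError("n_common_symptoms must be >= 0")
        for name in ("p_affirmative", "p_elicit", "noise_rate", "p_denial"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.symptoms_per_disease <= self.n_common_symptoms:
            raise ValueError(
                "symptoms_per_disease must exceed n_common_symptoms so every "
                "disease keeps at least one discriminative symptom"
            )
        if self.symptoms_per_disease > self.n_symptoms:
            raise ValueError("symptoms_per_disease exceeds the symptom vocabulary")
        if self.n_common_symptoms >= self.n_symptoms:
            raise ValueError("common pool must leave room for specific symptoms")
        if self.self_report_symptoms > self.symptoms_per_disease:
            raise ValueError("self_report_symptoms exceeds symptoms_per_disease")


@dataclass
class DiseaseProfile:
    disease: str
    profile_symptoms: list[str]
    common_symptoms: list[str]

    def specific_symptoms(self) -> list[str]:
        common = set(self.common_symptoms)
        return [s for s in self.profile_symptoms if s not in common]


@dataclass
class GenerationTruth:
    """Generator bookkeeping: planted structure for oracle checks."""

    profiles: list[DiseaseProfile]
    symptom_names: list[str]
    disease_names: list[str]
    # per dialogue id: the symptoms the patient actually reported/confirmed
    gold_symptom_sets: dict[str, list[str]] = field(default_factory=dict)

    def profile_for(self, disease: str) -> DiseaseProfile:
        return next(p for p in self.profiles if p.disease == disease)


def _symptom_names(n: int) -> list[str]:
    return [f"symptom {i:03d}" for i in range(n)]


def _disease_names(n: int) -> list[str]:
    return [f"disease {i:02d}" for i in range(n)]


def sample_profiles(config: GeneratorConfig) -> list[DiseaseProfile]:
    """Draw one symptom profile per disease, deterministically in the seed.

    Every profile contains the full common pool plus disease-specific
    symptoms sampled (without replacement, per disease) from the remaining
    vocabulary, so each disease always has at least one discriminative
    symptom.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    symptoms = _symptom_names(config.n_symptoms)
    diseases = _disease_names(config.n_diseases)
    common = symptoms[: config.n_common_symptoms]
    specific_pool = symptoms[config.n_common_symptoms:]
    n_specific = config.symptoms_per_disease - config.n_common_symptoms
    profiles = []
    for d in diseases:
        picked = rng.choice(len(specific_pool), size=n_specific, replace=False)
        specific = sorted(specific_pool[i] for i in picked)
        profiles.append(
            DiseaseProfile(
                disease=d,
                profile_symptoms=list(common) + specific,
                common_symptoms=list(common),
            )
        )
    return profiles


_SR_TEMPLATE = "Hello doctor, lately I have been having {}."
_ASK_TEMPLATE = "I see. Do you also have {}?"
_CONFIRM_TEMPLATE = "Yes, I do have {}."
_AFFIRM_TEXT = "Yes, exactly, that too."
_DENY_TEXT = "No, nothing like that."


def _join_names(names: Iterable[str]) -> str:
    names = list(names)
    if len(names) == 1:
        return names[0]
    return ", ".join(names[:-1]) + " and " + names[-1]


def generate_dialogue(
    profile: DiseaseProfile,
    config: GeneratorConfig,
    rng: np.random.Generator,
    dialogue_id: str = "dlg-0",
    all_symptoms: list[str] | None = None,
) -> Dialogue:
    """Simulate one consultation for ``profile``; see :func:`generate`."""
    dlg, _ = _generate_dialogue(profile, config, rng, dialogue_id, all_symptoms)
    return dlg


def _generate_dialogue(
    profile: DiseaseProfile,
    config: GeneratorConfig,
    rng: np.random.Generator,
    dialogue_id: str,
    all_symptoms: list[str] | None,
) -> tuple[Dialogue, list[str]]:
    if all_symptoms is None:
        all_symptoms = _symptom_names(config.n_symptoms)
    off_profile = sorted(set(all_symptoms) - set(profile.profile_symptoms))

    # self-report: drawn preferentially from the profile's common symptoms
    common = list(profile.common_symptoms)
    specific = profile.specific_symptoms()
    n_sr = config.self_report_symptoms
    sr: list[str] = []
    if common:
        take = min(n_sr, len(common))
        sr.extend(common[i] for i in rng.choice(len(common), size=take, replace=False))
    if len(sr) < n_sr:
        extra = n_sr - len(sr)
        sr.extend(specific[i] for i in rng.choice(len(specific), size=extra, replace=False))
    sr = sorted(sr)

    turns = [
        Utterance(
            speaker=PATIENT,
            text=_SR_TEMPLATE.format(_join_names(sr)),
            intent=INTENT_SYMPTOM,
            symptoms=list(sr),
        )
    ]
    gold = list(sr)

    # the doctor inquires about remaining profile symptoms, one per turn;
    # each is raised with probability p_elicit (consultations cover only
    # part of a textbook profile), with at least one inquiry always made
    remaining = [s for s in profile.profile_symptoms if s not in set(sr)]
    order = rng.permutation(len(remaining))
    asked = [i for i in order if rng.random() < config.p_elicit]
    if not asked and len(order):
        asked = [int(order[0])]
    for i in asked:
        s = remaining[i]
        if off_profile and rng.random() < config.noise_rate:
            s = off_profile[rng.integers(len(off_profile))]
        if config.p_denial > 0 and off_profile and rng.random() < config.p_denial:
            probe = off_profile[rng.integers(len(off_profile))]
            turns.append(Utterance(DOCTOR, _ASK_TEMPLATE.format(probe), symptoms=[probe]))
            turns.append(Utterance(PATIENT, _DENY_TEXT, intent=None, symptoms=[]))
        turns.append(Utterance(DOCTOR, _ASK_TEMPLATE.format(s), symptoms=[s]))
        if rng.random() < config.p_affirmative:
            turns.append(Utterance(PATIENT, _AFFIRM_TEXT, intent=INTENT_AFFIRMATIVE, symptoms=[]))
        else:
            turns.append(Utterance(PATIENT, _CONFIRM_TEMPLATE.format(s),
                                   intent=INTENT_SYMPTOM, symptoms=[s]))
        if s not in gold:
            gold.append(s)

    return Dialogue(id=dialogue_id, disease=profile.disease, turns=turns), gold


def generate(config: GeneratorConfig) -> tuple[Corpus, GenerationTruth]:
    """Generate a corpus plus full generator bookkeeping.

    Dialogues are assigned to diseases round-robin, so per-disease counts
    differ by at most one. Fully deterministic given ``config.seed``.
    """
    profiles = sample_profiles(config)
    rng = np.random.default_rng(config.seed + 1)  # profile stream kept separate
    symptoms = _symptom_names(config.n_symptoms)
    truth = GenerationTruth(
        profiles=profiles,
        symptom_names=symptoms,
        disease_names=[p.disease for p in profiles],
    )
    dialogues = []
    for i in range(config.n_dialogues):
        profile = profiles[i % config.n_diseases]
        dlg, gold = _generate_dialogue(profile, config, rng, f"dlg-{i:05d}", symptoms)
        dialogues.append(dlg)
        truth.gold_symptom_sets[dlg.id] = sorted(gold)
    corpus = Corpus(dialogues=dialogues)
    return corpus, truth


def generate_corpus(config: GeneratorConfig) -> tuple[Corpus, list[DiseaseProfile]]:
    """Generate a corpus and the planted disease profiles."""
    corpus, truth = generate(config)
    return corpus, truth.profiles
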