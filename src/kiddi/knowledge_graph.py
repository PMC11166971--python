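"""Symptom-symptom-disease (S-S-D) knowledge graph with sf-idf weights.

Nodes are symptoms and diseases. A symptom-disease edge exists whenever
the symptom was reported in at least one dialogue labeled with the
disease, weighted by *symptom frequency - inverse disease frequency*:

    e(s, d) = sf(s, d) * idf(s)
    sf(s, d) = n_sd / sum_k n_kd          (share of d's symptom mentions)
    idf(s)   = ln(|D| / #{d : n_sd > 0})  (specificity of s across diseases)

so a symptom tied to few diseases scores much higher than a ubiquitous
one at equal frequency. Symptom-symptom edges are directed and
row-normalized co-occurrence proportions:

    e(s_i, s_j) = n(s_i, s_j) / sum_k n(s_i, s_k).

Counting granularity is one dialogue = one case: a symptom counts at
most once per dialogue (set semantics), and the per-dialogue symptom set
is resolved by the same rule the distillation stage uses (patient
symptom lists plus Affirmative-resolution against the preceding doctor
turn).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .corpus import Corpus

__all__ = [
    "CooccurrenceCounts",
    "SSDGraph",
    "count_cooccurrences",
    "symptom_frequency",
    "inverse_disease_frequency",
    "sd_edge_weight",
    "ss_edge_weight",
    "build_graph",
]


@dataclass
class CooccurrenceCounts:
    symptoms: list[str]
    diseases: list[str]
    n_sd: np.ndarray  # (n_symptoms, n_diseases) dialogue-level counts
    n_ss: np.ndarray  # (n_symptoms, n_symptoms) symmetric, zero diagonal

    def __post_init__(self) -> None:
        self.symptom_index = {s: i for i, s in enumerate(self.symptoms)}
        self.disease_index = {d: i for i, d in enumerate(self.diseases)}

    @property
    def disease_count(self) -> int:
        return len(self.diseases)


def count_cooccurrences(corpus: Corpus) -> CooccurrenceCounts:
    """Dialogue-level symptom/disease and symptom/symptom co-occurrence counts."""
    from .distillation import resolve_gold_symptoms

    symptoms = list(corpus.symptom_vocab)
    diseases = list(corpus.disease_vocab)
    s_idx = {s: i for i, s in enumerate(symptoms)}
    d_idx = {d: i for i, d in enumerate(diseases)}
    n_sd = np.zeros((len(symptoms), len(diseases)), dtype=np.int64)
    n_ss = np.zeros((len(symptoms), len(symptoms)), dtype=np.int64)
    for dlg in corpus.dialogues:
        present = sorted({s_idx[s] for s in resolve_gold_symptoms(dlg) if s in s_idx})
        di = d_idx[dlg.disease]
        for i in present:
            n_sd[i, di] += 1
        for a in range(len(present)):
            for b in range(a + 1, len(present)):
                n_ss[present[a], present[b]] += 1
                n_ss[present[b], present[a]] += 1
    return CooccurrenceCounts(symptoms, diseases, n_sd, n_ss)


def symptom_frequency(counts: CooccurrenceCounts, s: str, d: str) -> float:
    """sf(s, d): share of disease d's symptom-occurrence mass carried by s."""
    si = counts.symptom_index[s]
    di = counts.disease_index[d]
    total = counts.n_sd[:, di].sum()
    if total == 0:
        return 0.0
    return float(counts.n_sd[si, di]) / float(total)


def inverse_disease_frequency(counts: CooccurrenceCounts, s: str) -> float:
    """idf(s) = ln(|D| / number of diseases s occurs with); natural log."""
    si = counts.symptom_index[s]
    linked = int((counts.n_sd[si, :] > 0).sum())
    if linked == 0:
        raise ValueError(f"symptom {s!r} never occurs with any disease; idf undefined")
    return math.log(counts.disease_count / linked)


def sd_edge_weight(counts: CooccurrenceCounts, s: str, d: str) -> float:
    """Symptom-disease edge weight e(s, d) = sf(s, d) * idf(s)."""
    return symptom_frequency(counts, s, d) * inverse_disease_frequency(counts, s)


def ss_edge_weight(counts: CooccurrenceCounts, s_i: str, s_j: str) -> float:
    """Directed symptom-symptom weight: co-occurrence share of s_j among s_i's."""
    a = counts.symptom_index[s_i]
    b = counts.symptom_index[s_j]
    total = counts.n_ss[a, :].sum()
    if total == 0:
        raise ValueError(f"symptom {s_i!r} co-occurs with no other symptom")
    return float(counts.n_ss[a, b]) / float(total)


@dataclass
class SSDGraph:
    """The weighted S-S-D graph, serializable and exportable to networkx."""

    symptoms: list[str]
    diseases: list[str]
    sd_edges: dict[tuple[str, str], float] = field(default_factory=dict)
    ss_edges: dict[tuple[str, str], float] = field(default_factory=dict)

    def diseases_of(self, s: str) -> dict[str, float]:
        return {d: w for (si, d), w in self.sd_edges.items() if si == s}

    def has_symptom(self, s: str) -> bool:
        return s in self._symptom_set

    @property
    def _symptom_set(self) -> set[str]:
        return set(self.symptoms)

    def to_dict(self) -> dict:
        return {
            "symptoms": self.symptoms,
            "diseases": self.diseases,
            "sd_edges": [[s, d, w] for (s, d), w in sorted(self.sd_edges.items())],
            "ss_edges": [[a, b, w] for (a, b), w in sorted(self.ss_edges.items())],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SSDGraph":
        return cls(
            symptoms=list(d["symptoms"]),
            diseases=list(d["diseases"]),
            sd_edges={(s, dd): float(w) for s, dd, w in d["sd_edges"]},
            ss_edges={(a, b): float(w) for a, b, w in d["ss_edges"]},
        )

    def save(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, ensure_ascii=False, sort_keys=True, indent=1)
            fh.write("\n")

    @classmethod
    def load(cls, path: str | Path) -> "SSDGraph":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))

    def to_networkx(self):
        """Directed graph view (symptom->disease and symptom->symptom edges)."""
        import networkx as nx

        g = nx.DiGraph()
        for s in self.symptoms:
            g.add_node(s, kind="symptom")
        for d in self.diseases:
            g.add_node(d, kind="disease")
        for (s, d), w in self.sd_edges.items():
            g.add_edge(s, d, weight=w, kind="sd")
        for (a, b), w in self.ss_edges.items():
            g.add_edge(a, b, weight=w, kind="ss")
        return g

    def write_edge_list(self, path: str | Path) -> None:
        """Tab-separated (source, target, weight, type) for external viewers."""
        with open(path, "w", encoding="utf-8") as fh:
            for (s, d), w in sorted(self.sd_edges.items()):
                fh.write(f"{s}\t{d}\t{w:.10g}\tsd\n")
            for (a, b), w in sorted(self.ss_edges.items()):
                fh.write(f"{a}\t{b}\t{w:.10g}\tss\n")


def build_graph(corpus: Corpus) -> SSDGraph:
    """Build the weighted S-S-D graph from a corpus (deterministic)."""
    counts = count_cooccurrences(corpus)
    graph = SSDGraph(symptoms=list(counts.symptoms), diseases=list(counts.diseases))
    for si, s in enumerate(counts.symptoms):
        if counts.n_sd[si, :].sum() == 0:
            continue  # unobserved symptom: no idf, no edges
        idf = inverse_disease_frequency(counts, s)
        for di, d in enumerate(counts.diseases):
            if counts.n_sd[si, di] > 0:
                graph.sd_edges[(s, d)] = symptom_frequency(counts, s, d) * idf
    for ai, a in enumerate(counts.symptoms):
        row_total = counts.n_ss[ai, :].sum()
        if row_total == 0:
            continue  # isolated symptom: outgoing weights undefined
        for bi, b in enumerate(counts.symptoms):
            if counts.n_ss[ai, bi] > 0:
                graph.ss_edges[(a, b)] = float(counts.n_ss[ai, bi]) / float(row_total)
    return graph
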