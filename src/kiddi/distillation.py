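"""Discourse-aware selective filtering (DSF).

Given a conversation and the S-S-D knowledge graph, this stage

1. resolves the conversation's symptom set from the annotations
   (patient ``Symptom`` turns name symptoms directly; an ``Affirmative``
   turn agrees with the doctor without naming the symptom, so it
   inherits the symptom(s) the doctor asked about in the immediately
   preceding turn),
2. keeps, for each resolved symptom, its top-K associated diseases by
   sf-idf edge weight, and
3. forms the *joint graph*: the filtered symptom/disease subgraph plus a
   single dialog node connected to every symptom node, each node
   carrying a feature vector supplied by the encoder.

Edge weights are consumed only by the top-K ranking; the graph-attention
network downstream operates on topology and node features alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .corpus import DOCTOR, INTENT_AFFIRMATIVE, PATIENT, Dialogue
from .knowledge_graph import SSDGraph

__all__ = [
    "DistillationConfig",
    "JointGraph",
    "resolve_gold_symptoms",
    "extract_symptoms",
    "top_k_diseases",
    "build_joint_graph",
    "build_joint_topology",
]

logger = logging.getLogger(__name__)

DIALOG_NODE = "<dialog>"


@dataclass
class DistillationConfig:
    K: int = 2
    include_ss_edges: bool = True
    symptom_source: str = "gold_annotations"  # or "learned_tagger"

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.symptom_source not in ("gold_annotations", "learned_tagger"):
            raise ValueError(f"unknown symptom_source {self.symptom_source!r}")


def resolve_gold_symptoms(dialogue: Dialogue) -> list[str]:
    """Resolved symptom set of a dialogue, in first-mention order.

    Union of patient-turn symptom lists, plus Affirmative resolution:
    an Affirmative patient turn contributes the symptom(s) named by the
    immediately preceding doctor turn. Duplicates collapse to the first
    mention; denials and unannotated turns contribute nothing.
    """
    seen: dict[str, None] = {}
    for i, turn in enumerate(dialogue.turns):
        if turn.speaker != PATIENT:
            continue
        symptoms = list(turn.symptoms)
        if turn.intent == INTENT_AFFIRMATIVE:
            if i == 0 or dialogue.turns[i - 1].speaker != DOCTOR:
                logger.warning(
                    "dialogue %s: Affirmative turn %d has no preceding doctor turn",
                    dialogue.id, i)
            else:
                symptoms = list(dialogue.turns[i - 1].symptoms)
        for s in symptoms:
            seen.setdefault(s)
    return list(seen)


def extract_symptoms(
    dialogue: Dialogue,
    config: DistillationConfig | None = None,
    tagger: Callable[[Dialogue], list[str]] | None = None,
) -> list[str]:
    """Extract the conversation's symptom mentions (ordered, deduplicated).

    Gold mode applies :func:`resolve_gold_symptoms` to the annotations.
    Learned mode delegates to a user-supplied tagger with the same
    contract (an optional component; none ships with the package).
    """
    config = config or DistillationConfig()
    if config.symptom_source == "learned_tagger":
        if tagger is None:
            raise ValueError("symptom_source='learned_tagger' requires a tagger")
        seen: dict[str, None] = {}
        for s in tagger(dialogue):
            seen.setdefault(s)
        return list(seen)
    return resolve_gold_symptoms(dialogue)


def top_k_diseases(kg: SSDGraph, s: str, K: int) -> list[str]:
    """Diseases linked to ``s``, by descending sf-idf weight, truncated to K.

    Ties break lexicographically by disease name. A symptom absent from
    the graph yields an empty list.
    """
    linked = kg.diseases_of(s)
    if not linked:
        if s not in kg._symptom_set:
            logger.info("symptom %r absent from knowledge graph", s)
        return []
    ranked = sorted(linked.items(), key=lambda kv: (-kv[1], kv[0]))
    return [d for d, _ in ranked[:K]]


@dataclass
class JointGraph:
    """Dialog node + DSF-filtered subgraph, with per-node features.

    Node 0 is always the dialog node; symptom nodes follow in resolution
    order, then disease nodes in order of first retrieval. ``adjacency``
    is undirected (symmetric, zero diagonal); the GAT adds self-loops.
    """

    node_names: list[str]
    node_kinds: list[str]  # "dialog" | "symptom" | "disease"
    adjacency: np.ndarray  # (N, N) bool, symmetric, no self-loops
    features: np.ndarray | None = None  # (N, d1)
    edges: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return len(self.node_names)

    def symptom_names(self) -> list[str]:
        return [n for n, k in zip(self.node_names, self.node_kinds) if k == "symptom"]

    def disease_names(self) -> list[str]:
        return [n for n, k in zip(self.node_names, self.node_kinds) if k == "disease"]


def build_joint_topology(
    kg: SSDGraph,
    symptoms: list[str],
    config: DistillationConfig | None = None,
) -> JointGraph:
    """DSF topology only (no features): the cacheable part of the joint graph."""
    config = config or DistillationConfig()
    present = [s for s in symptoms if s in kg._symptom_set and kg.diseases_of(s)]
    names: list[str] = [DIALOG_NODE]
    kinds: list[str] = ["dialog"]
    index: dict[str, int] = {DIALOG_NODE: 0}
    for s in present:
        index[s] = len(names)
        names.append(s)
        kinds.append("symptom")
    edge_list: list[tuple[str, str, str]] = []
    disease_edges: list[tuple[str, str]] = []
    for s in present:
        for d in top_k_diseases(kg, s, config.K):
            if d not in index:
                index[d] = len(names)
                names.append(d)
                kinds.append("disease")
            disease_edges.append((s, d))
    n = len(names)
    adj = np.zeros((n, n), dtype=bool)

    def connect(a: str, b: str, kind: str) -> None:
        i, j = index[a], index[b]
        adj[i, j] = adj[j, i] = True
        edge_list.append((a, b, kind))

    for s in present:
        connect(DIALOG_NODE, s, "dialog-symptom")
    for s, d in disease_edges:
        connect(s, d, "symptom-disease")
    if config.include_ss_edges:
        present_set = set(present)
        for (a, b), _w in sorted(kg.ss_edges.items()):
            if a in present_set and b in present_set and not adj[index[a], index[b]]:
                connect(a, b, "symptom-symptom")
    return JointGraph(node_names=names, node_kinds=kinds, adjacency=adj, edges=edge_list)


def build_joint_graph(
    kg: SSDGraph,
    symptoms: list[str],
    config: DistillationConfig | None = None,
    dialog_feature: np.ndarray | None = None,
    node_features: Callable[[str, str], np.ndarray] | None = None,
) -> JointGraph:
    """Full joint graph with node features attached.

    ``node_features(name, kind)`` supplies symptom/disease entity
    features; the dialog node takes ``dialog_feature``. When a resolved
    symptom set is empty (or none of its symptoms reach the KG), the
    graph degenerates to the lone dialog node and classification remains
    well defined downstream.
    """
    graph = build_joint_topology(kg, symptoms, config)
    if dialog_feature is not None:
        dialog_feature = np.asarray(dialog_feature, dtype=np.float64)
        d1 = dialog_feature.shape[0]
        feats = np.zeros((graph.n_nodes, d1))
        feats[0] = dialog_feature
        for i in range(1, graph.n_nodes):
            if node_features is None:
                raise ValueError("node_features provider required when features requested")
            vec = np.asarray(node_features(graph.node_names[i], graph.node_kinds[i]))
            if vec.shape != (d1,):
                raise ValueError(
                    f"feature width mismatch for node {graph.node_names[i]!r}: "
                    f"{vec.shape} vs ({d1},)")
            feats[i] = vec
        graph.features = feats
    return graph
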