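"""Independent brute-force oracles used by the test suite.

These deliberately re-derive every quantity with naive nested loops and
literal formula transcription, sharing no code with the package
implementation, so agreement is evidence and not tautology.
"""

from __future__ import annotations

import math

import numpy as np


# -- knowledge-graph oracle ---------------------------------------------


def resolve_symptoms_oracle(dialogue) -> set[str]:
    """Literal annotation-resolution rule, re-derived independently."""
    out: set[str] = set()
    turns = dialogue.turns
    for i, turn in enumerate(turns):
        if turn.speaker != "patient":
            continue
        if turn.intent == "Symptom":
            out.update(turn.symptoms)
        elif turn.intent == "Affirmative":
            if i > 0 and turns[i - 1].speaker == "doctor":
                out.update(turns[i - 1].symptoms)
    return out


def kg_oracle(corpus) -> dict:
    """Nested-loop evaluation of the sf-idf and co-occurrence formulas.

    Returns dicts keyed by names: n_sd, n_ss, sf, idf, sd_weight, ss_weight.
    """
    symptoms = sorted({s for d in corpus.dialogues for t in d.turns for s in t.symptoms})
    diseases = sorted({d.disease for d in corpus.dialogues})
    resolved = {d.id: resolve_symptoms_oracle(d) for d in corpus.dialogues}

    n_sd: dict[tuple[str, str], int] = {}
    for s in symptoms:
        for dis in diseases:
            c = 0
            for dlg in corpus.dialogues:
                if dlg.disease == dis and s in resolved[dlg.id]:
                    c += 1
            n_sd[(s, dis)] = c
    n_ss: dict[tuple[str, str], int] = {}
    for a in symptoms:
        for b in symptoms:
            if a == b:
                n_ss[(a, b)] = 0
                continue
            c = 0
            for dlg in corpus.dialogues:
                if a in resolved[dlg.id] and b in resolved[dlg.id]:
                    c += 1
            n_ss[(a, b)] = c

    sf: dict[tuple[str, str], float] = {}
    for dis in diseases:
        denom = sum(n_sd[(k, dis)] for k in symptoms)
        for s in symptoms:
            sf[(s, dis)] = n_sd[(s, dis)] / denom if denom else 0.0

    idf: dict[str, float] = {}
    for s in symptoms:
        linked = sum(1 for dis in diseases if n_sd[(s, dis)] > 0)
        if linked:
            idf[s] = math.log(len(diseases) / linked)

    sd_weight = {
        (s, dis): sf[(s, dis)] * idf[s]
        for s in idf
        for dis in diseases
        if n_sd[(s, dis)] > 0
    }
    ss_weight: dict[tuple[str, str], float] = {}
    for a in symptoms:
        denom = sum(n_ss[(a, k)] for k in symptoms)
        if denom == 0:
            continue
        for b in symptoms:
            if n_ss[(a, b)] > 0:
                ss_weight[(a, b)] = n_ss[(a, b)] / denom

    return {"symptoms": symptoms, "diseases": diseases, "n_sd": n_sd,
            "n_ss": n_ss, "sf": sf, "idf": idf,
            "sd_weight": sd_weight, "ss_weight": ss_weight}


# -- GAT oracle ---------------------------------------------------------


def leaky(x: np.ndarray | float, slope: float) -> np.ndarray | float:
    return np.where(np.asarray(x) > 0, x, slope * np.asarray(x))


def gat_layer_oracle(adjacency: np.ndarray, features: np.ndarray,
                     heads: list[tuple[np.ndarray, np.ndarray]],
                     slope: float = 0.2) -> np.ndarray:
    """Per-node, per-neighbor transcription of the attention update.

    ``heads`` holds (W, a) with W of shape (head_dim, d1) and a of shape
    (2 * head_dim,). Neighborhoods include self-loops.
    """
    n = features.shape[0]
    nbrs = [
        [j for j in range(n) if adjacency[i, j] or i == j]
        for i in range(n)
    ]
    head_parts = []
    for w, a in heads:
        dh = w.shape[0]
        out = np.zeros((n, dh))
        for i in range(n):
            scores = []
            for j in nbrs[i]:
                cat = np.concatenate([w @ features[i], w @ features[j]])
                scores.append(float(leaky(a @ cat, slope)))
            scores = np.array(scores)
            ex = np.exp(scores - scores.max())
            alphas = ex / ex.sum()
            msg = np.zeros(dh)
            for alpha_ij, j in zip(alphas, nbrs[i]):
                msg += alpha_ij * (w @ features[j])
            out[i] = msg
        head_parts.append(out)
    return np.asarray(leaky(np.concatenate(head_parts, axis=1), slope))


# -- scalar cross-entropy oracle ----------------------------------------


def cross_entropy_oracle(probs: np.ndarray, labels: np.ndarray) -> float:
    total = 0.0
    for i in range(probs.shape[0]):
        for j in range(probs.shape[1]):
            y = 1.0 if j == labels[i] else 0.0
            total -= y * math.log(max(probs[i, j], 1e-12))
    return total
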