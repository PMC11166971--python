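"""Model core: graph attention, attention fusion, disease classifier.

The two-channel architecture encodes the conversation as text (self-
report encoding ``S`` and dialog encoding ``C``) and as structure (the
joint dialog-knowledge graph). A multi-head graph attention network
(GAT) updates joint-graph node features,

    h_i = LeakyReLU( sum_{j in N_i} alpha_ij W_h h_j ),
    alpha_ij = softmax_j( LeakyReLU( a . [W_h h_i || W_h h_j] ) ),

heads concatenated so the width d1 is preserved; mean-pooling all nodes
(dialog node included) yields the graph embedding s. Additive attention
with s as query weighs the two text channels,

    e_i = v . tanh(W1 h_i + W2 s),  alpha = softmax([e1, e2]),
    context = alpha_1 S + alpha_2 C,

and a softmax layer over [s; context] predicts the disease. Training
minimizes categorical cross-entropy.

Conventions where the formulation is silent: self-loops on every node
(so an isolated dialog node has a defined update), LeakyReLU slope 0.2,
dropout on attention coefficients only, epsilon-clamped logs in the
loss, and argmax ties broken by lowest disease index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Adam, Tensor, concat, glorot, masked_softmax, param
from .corpus import Dialogue
from .distillation import DistillationConfig, JointGraph, build_joint_topology, extract_symptoms
from .encoder import (
    EncoderConfig,
    encode_many,
    init_encoder_params,
    serialize_dialogue,
    serialize_self_report,
    tokenize,
    tokens_to_ids,
)
from .knowledge_graph import SSDGraph

__all__ = [
    "ModelConfig",
    "GATParams",
    "gat_layer",
    "mean_pool",
    "additive_attention",
    "classify",
    "cross_entropy_loss",
    "KIDDIModel",
    "ABLATION_MODES",
]

ABLATION_MODES = (
    "full",
    "sre_only",
    "de_only",
    "knowledge_only",
    "sre_linear",
    "de_linear",
    "sre_knowledge",
    "de_knowledge",
)

_GRAPH_MODES = {"full", "knowledge_only", "sre_knowledge", "de_knowledge"}
_LINEAR_MODES = {"sre_linear", "de_linear"}


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    Defaults are the full-scale profile (d2=768, d1=384, d3=64, 2 GAT
    layers with 3 concatenated heads, attention dropout 0.5); tests and
    the desk-scale profile shrink the widths, not the structure.
    """

    d1: int = 384
    d2: int = 768
    d3: int = 64
    n_layers: int = 2
    n_heads: int = 3
    leaky_slope: float = 0.2
    dropout: float = 0.5
    mode: str = "full"

    def __post_init__(self) -> None:
        if self.d1 % self.n_heads != 0:
            raise ValueError("d1 must be divisible by n_heads (heads concatenate)")
        if self.mode not in ABLATION_MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.leaky_slope <= 0:
            raise ValueError("leaky_slope must be > 0")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")

    @property
    def head_dim(self) -> int:
        return self.d1 // self.n_heads

    @property
    def classifier_width(self) -> int:
        if self.mode == "full":
            return self.d1 + self.d2
        if self.mode in ("sre_only", "de_only"):
            return self.d2
        if self.mode == "knowledge_only":
            return self.d1
        return self.d1 + self.d2  # *_linear / *_knowledge concatenations


@dataclass
class GATParams:
    """One GAT layer: per-head weight matrix W (head_dim x d1) and scoring
    vector a (2*head_dim)."""

    heads: list[tuple[Tensor, Tensor]]


def gat_layer(
    adjacency: np.ndarray,
    features: Tensor,
    layer: GATParams,
    slope: float = 0.2,
    dropout: float = 0.0,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> Tensor:
    """One multi-head GAT update over an undirected topology.

    Neighborhoods include a self-loop on every node. Attention for head
    h is the masked softmax of LeakyReLU(a . [W h_i || W h_j]) over j in
    N_i; heads concatenate; the aggregated message passes through a
    final LeakyReLU. During training, dropout is applied to the
    attention coefficients (inverted scaling).
    """
    n = adjacency.shape[0]
    mask = np.asarray(adjacency, dtype=bool) | np.eye(n, dtype=bool)
    head_outputs = []
    for w, a in layer.heads:
        hw = features @ _transpose(w)  # (n, head_dim)
        dh = w.shape[0]
        f = hw @ a[:dh]  # scores for the "self" slot
        g = hw @ a[dh:]  # scores for the "neighbor" slot
        scores = (f.reshape(n, 1) + g.reshape(1, n)).leaky_relu(slope)
        alpha = masked_softmax(scores, mask, axis=1)
        if training and dropout > 0.0:
            if rng is None:
                raise ValueError("training dropout requires an rng")
            keep = (rng.random(size=(n, n)) >= dropout) / (1.0 - dropout)
            alpha = alpha * Tensor(keep)
        head_outputs.append(alpha @ hw)
    stacked = head_outputs[0] if len(head_outputs) == 1 else concat(head_outputs, axis=1)
    return stacked.leaky_relu(slope)


def _transpose(t: Tensor) -> Tensor:
    out = Tensor(t.data.T, parents=(t,))
    out._backward = lambda g: t._accumulate(g.T)
    return out


def mean_pool(features: Tensor) -> Tensor:
    """Graph embedding: arithmetic mean over all nodes (dialog node included)."""
    if features.shape[0] == 0:
        raise ValueError("cannot pool an empty node table")
    return features.mean(axis=0)


def additive_attention(
    s: Tensor, h1: Tensor, h2: Tensor, w1: Tensor, w2: Tensor, v: Tensor
) -> tuple[Tensor, Tensor]:
    """Additive attention over {self-report, dialog} with graph query ``s``.

    Returns the context vector and the attention pair alpha (a length-2
    tensor summing to 1), exposed for diagnostics.
    """
    e1 = v @ (w1 @ h1 + w2 @ s).tanh()
    e2 = v @ (w1 @ h2 + w2 @ s).tanh()
    e = concat([e1.reshape(1), e2.reshape(1)])
    alpha = masked_softmax(e, np.ones(2, dtype=bool), axis=0)
    context = alpha[0] * h1 + alpha[1] * h2
    return context, alpha


def classify(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Softmax disease distribution from the fused feature vector."""
    logits = w @ x + b
    return masked_softmax(logits, np.ones(logits.shape, dtype=bool), axis=0)


def predict_index(probs: np.ndarray) -> int:
    """Argmax prediction; ties break toward the lowest disease index."""
    return int(np.argmax(probs))


def cross_entropy_loss(predicted: Tensor | list[Tensor], labels) -> Tensor:
    """Categorical cross-entropy summed over the batch.

    ``predicted`` holds probability vectors (rows); ``labels`` the true
    class indices. Probabilities are clamped at 1e-12 inside the log.
    """
    if isinstance(predicted, list):
        predicted = concat([p.reshape(1, -1) for p in predicted], axis=0)
    labels = np.asarray(labels, dtype=int)
    rows = np.arange(predicted.shape[0])
    picked = predicted[rows, labels]
    return -(picked.log(clamp=1e-12).sum())


@dataclass
class PreparedExample:
    """Pre-tokenized, pre-filtered view of one dialogue (parameter-free)."""

    dialogue_id: str
    sr_ids: list[int]
    dlg_ids: list[int]
    topology: JointGraph
    entity_id_lists: list[list[int]]  # token ids per non-dialog node name
    label: int | None


class KIDDIModel:
    """The end-to-end diagnosis model with ablation wiring.

    Owns all trainable parameter tables (encoder, GAT, fusion,
    classifier) in a flat named dict, so optimizers and checkpoints see
    one surface. ``mode`` selects the classifier head's input:

    ``full``            GAT graph embedding + attention-fused text
    ``sre_only``        self-report encoding alone
    ``de_only``         dialog encoding alone
    ``knowledge_only``  GAT graph embedding alone
    ``sre_linear``      self-report + unweighted mean of entity features
    ``de_linear``       dialog encoding + unweighted mean of entity features
    ``sre_knowledge``   self-report + GAT graph embedding (no attention)
    ``de_knowledge``    dialog encoding + GAT graph embedding (no attention)
    """

    def __init__(
        self,
        vocab: dict[str, int],
        disease_vocab: list[str],
        kg: SSDGraph,
        model_config: ModelConfig,
        encoder_config: EncoderConfig,
        distill_config: DistillationConfig | None = None,
        seed: int = 0,
    ):
        self.vocab = vocab
        self.disease_vocab = list(disease_vocab)
        self.kg = kg
        self.config = model_config
        self.encoder_config = encoder_config
        self.distill_config = distill_config or DistillationConfig()
        rng = np.random.default_rng(seed)
        cfg = model_config
        self.params: dict[str, Tensor] = init_encoder_params(encoder_config, cfg.d1, rng)
        for layer in range(cfg.n_layers):
            for head in range(cfg.n_heads):
                self.params[f"gat/{layer}/{head}/W"] = param(glorot(rng, cfg.head_dim, cfg.d1))
                self.params[f"gat/{layer}/{head}/a"] = param(
                    rng.normal(0.0, 0.1, size=2 * cfg.head_dim))
        self.params["att/W1"] = param(glorot(rng, cfg.d3, cfg.d2))
        self.params["att/W2"] = param(glorot(rng, cfg.d3, cfg.d1))
        self.params["att/v"] = param(rng.normal(0.0, 0.1, size=cfg.d3))
        n = len(self.disease_vocab)
        self.params["clf/W"] = param(glorot(rng, n, cfg.classifier_width))
        self.params["clf/b"] = param(np.zeros(n))

    # -- data preparation -------------------------------------------------

    def prepare(self, dialogue: Dialogue) -> PreparedExample:
        ec = self.encoder_config
        sr = tokens_to_ids(serialize_self_report(dialogue, ec.max_sequence_length), self.vocab)
        dlg = tokens_to_ids(serialize_dialogue(dialogue, ec.max_sequence_length), self.vocab)
        symptoms = extract_symptoms(dialogue, self.distill_config)
        topology = build_joint_topology(self.kg, symptoms, self.distill_config)
        entity_ids = [
            tokens_to_ids(tokenize(name), self.vocab) for name in topology.node_names[1:]
        ]
        label = (
            self.disease_vocab.index(dialogue.disease)
            if dialogue.disease in self.disease_vocab
            else None
        )
        return PreparedExample(dialogue.id, sr, dlg, topology, entity_ids, label)

    # -- forward ----------------------------------------------------------

    def _gat_params(self, layer: int) -> GATParams:
        cfg = self.config
        return GATParams(
            heads=[
                (self.params[f"gat/{layer}/{h}/W"], self.params[f"gat/{layer}/{h}/a"])
                for h in range(cfg.n_heads)
            ]
        )

    def forward_prepared(
        self,
        prep: PreparedExample,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> tuple[Tensor, np.ndarray | None, Tensor | None]:
        """Run the pipeline on a prepared example.

        Returns (probability vector over diseases, attention pair alpha
        or None for modes without the fusion stage, graph embedding or
        None for text-only modes).
        """
        cfg = self.config
        p = self.params
        mode = cfg.mode
        need_s = mode in ("full", "sre_only", "sre_linear", "sre_knowledge")
        need_c = mode in ("full", "de_only", "de_linear", "de_knowledge") or mode in _GRAPH_MODES
        s_enc = encode_many([prep.sr_ids], p)[0] if need_s else None
        c_enc = encode_many([prep.dlg_ids], p)[0] if need_c else None

        ent_feat: Tensor | None = None
        if (mode in _GRAPH_MODES or mode in _LINEAR_MODES) and prep.entity_id_lists:
            ent_enc = encode_many(prep.entity_id_lists, p)
            ent_feat = ent_enc @ _transpose(p["enc/proj_W"]) + p["enc/proj_b"]

        graph_emb: Tensor | None = None
        if mode in _GRAPH_MODES:
            dialog_feat = p["enc/proj_W"] @ c_enc + p["enc/proj_b"]
            if ent_feat is not None:
                h = concat([dialog_feat.reshape(1, cfg.d1), ent_feat], axis=0)
            else:
                h = dialog_feat.reshape(1, cfg.d1)
            for layer in range(cfg.n_layers):
                h = gat_layer(
                    prep.topology.adjacency, h, self._gat_params(layer),
                    slope=cfg.leaky_slope, dropout=cfg.dropout,
                    training=training, rng=rng)
            graph_emb = mean_pool(h)

        linear_knowledge: Tensor | None = None
        if mode in _LINEAR_MODES:
            linear_knowledge = (
                ent_feat.mean(axis=0) if ent_feat is not None else Tensor(np.zeros(cfg.d1))
            )

        alpha_np: np.ndarray | None = None
        if mode == "full":
            context, alpha = additive_attention(
                graph_emb, s_enc, c_enc, p["att/W1"], p["att/W2"], p["att/v"])
            head_in = concat([graph_emb, context])
            alpha_np = alpha.data.copy()
        elif mode == "sre_only":
            head_in = s_enc
        elif mode == "de_only":
            head_in = c_enc
        elif mode == "knowledge_only":
            head_in = graph_emb
        elif mode == "sre_linear":
            head_in = concat([linear_knowledge, s_enc])
        elif mode == "de_linear":
            head_in = concat([linear_knowledge, c_enc])
        elif mode == "sre_knowledge":
            head_in = concat([graph_emb, s_enc])
        else:  # de_knowledge
            head_in = concat([graph_emb, c_enc])

        probs = classify(head_in, p["clf/W"], p["clf/b"])
        return probs, alpha_np, graph_emb

    def forward(
        self,
        dialogue: Dialogue,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> tuple[Tensor, np.ndarray | None, Tensor | None]:
        return self.forward_prepared(self.prepare(dialogue), training=training, rng=rng)

    def predict(self, dialogue: Dialogue) -> str:
        """Diagnose: the most probable disease for a conversation."""
        probs, _, _ = self.forward(dialogue)
        return self.disease_vocab[predict_index(probs.data)]

    # -- parameter plumbing ----------------------------------------------

    def make_optimizer(self, lr: float = 1e-3) -> Adam:
        return Adam(self.params, lr=lr)

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            if k not in self.params:
                raise KeyError(f"unexpected parameter {k!r}")
            if self.params[k].data.shape != v.shape:
                raise ValueError(f"shape mismatch for {k!r}")
            self.params[k].data = np.array(v, dtype=np.float64)
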