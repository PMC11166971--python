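"""Training loop, evaluation metrics, ablation harness, hierarchical mode.

Training minimizes categorical cross-entropy with Adam over mini-batches
of dialogues; the checkpoint with the best validation accuracy across
epochs is retained. Evaluation reports accuracy, macro-averaged F1,
mean Jaccard similarity between predicted and true label sets (for the
single-label task this equals top-1 accuracy), top-k coverage for
k in {1, 3, 5}, per-class precision/recall and confusion counts.

The ablation harness retrains the same architecture with the classifier
head rewired (self-report only, dialog only, knowledge only, linear vs
graph knowledge infusion, with or without attention fusion) on shared
splits and seeds, so mode contrasts isolate the component under study.
The hierarchical mode stacks a disease-group classifier over per-group
disease classifiers, mirroring the medical-department structure of a
clinic.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import confusion_matrix, f1_score, precision_recall_fscore_support

from .corpus import Corpus, Dialogue, split_corpus
from .distillation import DistillationConfig
from .encoder import EncoderConfig, build_vocab
from .gat_fusion import KIDDIModel, ModelConfig, cross_entropy_loss, predict_index
from .knowledge_graph import SSDGraph, build_graph

__all__ = [
    "TrainConfig",
    "EvalReport",
    "Checkpoint",
    "train",
    "evaluate",
    "run_ablation",
    "train_hierarchical",
    "hierarchical_classify",
    "evaluate_hierarchical",
    "jaccard",
    "topk_hit",
]

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    batch_size: int = 16
    epochs: int = 25
    learning_rate: float = 1e-3
    seed: int = 0
    K: int = 2
    ablation_mode: str = "full"
    hierarchical: bool = False
    group_map: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")


@dataclass
class Checkpoint:
    """Single-file container: parameter tables, vocabularies, configs."""

    state: dict[str, np.ndarray]
    vocab: dict[str, int]
    disease_vocab: list[str]
    model_config: ModelConfig
    encoder_config: EncoderConfig
    distill_config: DistillationConfig
    history: list[dict] = field(default_factory=list)

    def save(self, path: str | Path) -> None:
        meta = {
            "vocab": self.vocab,
            "disease_vocab": self.disease_vocab,
            "model_config": vars(self.model_config),
            "encoder_config": vars(self.encoder_config),
            "distill_config": vars(self.distill_config),
            "history": self.history,
        }
        arrays = {f"param:{k}": v for k, v in self.state.items()}
        np.savez(path, meta=json.dumps(meta, sort_keys=True), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "Checkpoint":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            state = {
                k[len("param:"):]: np.array(data[k])
                for k in data.files
                if k.startswith("param:")
            }
        return cls(
            state=state,
            vocab=meta["vocab"],
            disease_vocab=meta["disease_vocab"],
            model_config=ModelConfig(**meta["model_config"]),
            encoder_config=EncoderConfig(**meta["encoder_config"]),
            distill_config=DistillationConfig(**meta["distill_config"]),
            history=meta["history"],
        )

    def build_model(self, kg: SSDGraph) -> KIDDIModel:
        model = KIDDIModel(
            vocab=self.vocab,
            disease_vocab=self.disease_vocab,
            kg=kg,
            model_config=self.model_config,
            encoder_config=self.encoder_config,
            distill_config=self.distill_config,
            seed=0,
        )
        model.load_state_dict(self.state)
        return model


def _make_model(
    train_corpus: Corpus,
    kg: SSDGraph,
    model_config: ModelConfig,
    encoder_config: EncoderConfig | None,
    train_config: TrainConfig,
) -> KIDDIModel:
    vocab = build_vocab(train_corpus)
    if encoder_config is None:
        encoder_config = EncoderConfig()
    # copy: the caller's config object must not be mutated across runs
    encoder_config = EncoderConfig(**{**vars(encoder_config), "vocab_size": len(vocab)})
    distill = DistillationConfig(K=train_config.K)
    return KIDDIModel(
        vocab=vocab,
        disease_vocab=list(train_corpus.disease_vocab),
        kg=kg,
        model_config=model_config,
        encoder_config=encoder_config,
        distill_config=distill,
        seed=train_config.seed,
    )


def train(
    train_corpus: Corpus,
    val_corpus: Corpus,
    kg: SSDGraph,
    model_config: ModelConfig | None = None,
    encoder_config: EncoderConfig | None = None,
    train_config: TrainConfig | None = None,
) -> Checkpoint:
    """Train the diagnosis model; retain the best-validation checkpoint.

    Fully deterministic given ``train_config.seed`` (initialization,
    shuffling and dropout streams all derive from it). Diseases present
    in validation but absent from training stay in the output space
    (the class space is vocabulary-defined) with a logged warning.
    """
    if not train_corpus.dialogues:
        raise ValueError("training split is empty")
    train_config = train_config or TrainConfig()
    model_config = model_config or ModelConfig(mode=train_config.ablation_mode)
    if model_config.mode != train_config.ablation_mode:
        model_config = ModelConfig(**{**vars(model_config), "mode": train_config.ablation_mode})
    model = _make_model(train_corpus, kg, model_config, encoder_config, train_config)

    seen = {d.disease for d in train_corpus.dialogues}
    for dlg in val_corpus.dialogues:
        if dlg.disease not in seen:
            logger.warning("disease %r in validation never seen in training", dlg.disease)

    prepared = [model.prepare(d) for d in train_corpus.dialogues]
    prepared_val = [model.prepare(d) for d in val_corpus.dialogues]
    labels = np.array([p.label for p in prepared], dtype=int)

    rng = np.random.default_rng(train_config.seed)
    opt = model.make_optimizer(lr=train_config.learning_rate)
    best_state = model.state_dict()
    best_val = -1.0
    history: list[dict] = []
    n = len(prepared)
    for epoch in range(train_config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, train_config.batch_size):
            batch = order[start:start + train_config.batch_size]
            probs = [
                model.forward_prepared(prepared[i], training=True, rng=rng)[0]
                for i in batch
            ]
            loss = cross_entropy_loss(probs, labels[batch]) * (1.0 / len(batch))
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(batch)
        epoch_loss /= n
        val_acc = _accuracy_prepared(model, prepared_val) if prepared_val else float("nan")
        history.append({"epoch": epoch, "train_loss": epoch_loss, "val_accuracy": val_acc})
        if prepared_val and val_acc > best_val:
            best_val = val_acc
            best_state = model.state_dict()
        logger.info("epoch %d: train loss %.4f, val acc %s", epoch, epoch_loss, val_acc)
    if not prepared_val:
        best_state = model.state_dict()
    return Checkpoint(
        state=best_state,
        vocab=model.vocab,
        disease_vocab=model.disease_vocab,
        model_config=model.config,
        encoder_config=model.encoder_config,
        distill_config=model.distill_config,
        history=history,
    )


def _accuracy_prepared(model: KIDDIModel, prepared: list) -> float:
    hits = 0
    for prep in prepared:
        probs, _, _ = model.forward_prepared(prep, training=False)
        hits += int(predict_index(probs.data) == prep.label)
    return hits / len(prepared)


# -- metrics ------------------------------------------------------------


def jaccard(a: set, b: set) -> float:
    """|a ∩ b| / |a ∪ b| between two label sets (1.0 when both empty)."""
    union = a | b
    if not union:
        return 1.0
    return len(a & b) / len(union)


def topk_hit(probs: np.ndarray, label: int, k: int) -> bool:
    """Is the true label among the k most probable classes?
    Ties resolve toward lower indices (stable sort)."""
    order = np.argsort(-probs, kind="stable")
    return label in order[:k]


@dataclass
class EvalReport:
    accuracy: float
    macro_f1: float
    mean_jaccard: float
    top_k: dict[int, float]
    per_class: dict[str, dict[str, float]]
    confusion: list[list[int]]
    predictions: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_f1": self.macro_f1,
            "mean_jaccard": self.mean_jaccard,
            "top_k": {str(k): v for k, v in self.top_k.items()},
            "per_class": self.per_class,
            "confusion": self.confusion,
        }

    def write_predictions_tsv(self, path: str | Path) -> None:
        """Per-example predictions (id, true, predicted, top-5, attention
        weights) for attention-style inspection."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("dialogue_id\ttrue\tpredicted\ttop5\talpha_self_report\talpha_dialog\n")
            for row in self.predictions:
                fh.write(
                    "{id}\t{true}\t{predicted}\t{top5}\t{a1}\t{a2}\n".format(
                        id=row["id"], true=row["true"], predicted=row["predicted"],
                        top5=",".join(row["top5"]),
                        a1="" if row["alpha"] is None else f"{row['alpha'][0]:.6f}",
                        a2="" if row["alpha"] is None else f"{row['alpha'][1]:.6f}",
                    )
                )


def evaluate(checkpoint: Checkpoint, corpus: Corpus, kg: SSDGraph) -> EvalReport:
    """Evaluate a checkpoint on a corpus split (deterministic)."""
    if not corpus.dialogues:
        raise ValueError("evaluation split is empty")
    model = checkpoint.build_model(kg)
    return evaluate_model(model, corpus)


def evaluate_model(model: KIDDIModel, corpus: Corpus) -> EvalReport:
    prob_rows = []
    y_true = []
    ids = []
    alphas = []
    for dlg in corpus.dialogues:
        prep = model.prepare(dlg)
        probs_t, alpha, _ = model.forward_prepared(prep, training=False)
        prob_rows.append(probs_t.data)
        y_true.append(prep.label)
        ids.append(dlg.id)
        alphas.append(None if alpha is None else (float(alpha[0]), float(alpha[1])))
    return compute_report(y_true, np.array(prob_rows), model.disease_vocab,
                          ids=ids, alphas=alphas)


def compute_report(
    y_true: list[int],
    probs: np.ndarray,
    diseases: list[str],
    ids: list[str] | None = None,
    alphas: list | None = None,
) -> EvalReport:
    """Assemble the evaluation report from true labels and a probability
    matrix (one row per example, one column per disease)."""
    m, n_classes = probs.shape
    ids = ids or [str(i) for i in range(m)]
    alphas = alphas or [None] * m
    y_pred: list[int] = []
    jaccards: list[float] = []
    topk_hits = {k: 0 for k in (1, 3, 5)}
    predictions: list[dict] = []
    for i in range(m):
        pred = predict_index(probs[i])
        y_pred.append(pred)
        jaccards.append(jaccard({y_true[i]}, {pred}))
        for k in topk_hits:
            topk_hits[k] += int(topk_hit(probs[i], y_true[i], k))
        order = np.argsort(-probs[i], kind="stable")[:5]
        predictions.append({
            "id": ids[i],
            "true": diseases[y_true[i]],
            "predicted": diseases[pred],
            "top5": [diseases[j] for j in order],
            "alpha": alphas[i],
        })
    labels = list(range(n_classes))
    prec, rec, _, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, zero_division=0)
    return EvalReport(
        accuracy=float(np.mean(np.array(y_true) == np.array(y_pred))),
        macro_f1=float(f1_score(y_true, y_pred, labels=labels,
                                average="macro", zero_division=0)),
        mean_jaccard=float(np.mean(jaccards)),
        top_k={k: v / m for k, v in topk_hits.items()},
        per_class={
            diseases[i]: {"precision": float(prec[i]), "recall": float(rec[i])}
            for i in labels
        },
        confusion=confusion_matrix(y_true, y_pred, labels=labels).tolist(),
        predictions=predictions,
    )


# -- ablation harness ---------------------------------------------------


def run_ablation(
    corpus: Corpus,
    modes: tuple[str, ...] = ("full", "sre_only", "de_only", "de_linear", "de_knowledge"),
    model_config: ModelConfig | None = None,
    encoder_config: EncoderConfig | None = None,
    train_config: TrainConfig | None = None,
    kg: SSDGraph | None = None,
) -> dict[str, EvalReport]:
    """Train and evaluate several head wirings on shared splits and seed.

    The knowledge graph is built from the training split only, so the
    test split never leaks into the edge weights.
    """
    train_config = train_config or TrainConfig()
    tr, va, te = split_corpus(corpus, (0.7, 0.1, 0.2), seed=train_config.seed)
    if kg is None:
        kg = build_graph(tr)
    reports: dict[str, EvalReport] = {}
    for mode in modes:
        tc = TrainConfig(**{**vars(train_config), "ablation_mode": mode})
        base = model_config or ModelConfig()
        mc = ModelConfig(**{**vars(base), "mode": mode})
        ckpt = train(tr, va, kg, mc, encoder_config, tc)
        reports[mode] = evaluate(ckpt, te, kg)
    return reports


# -- hierarchical classification ----------------------------------------


@dataclass
class HierarchicalCheckpoint:
    group_checkpoint: Checkpoint
    per_group: dict[str, Checkpoint]
    group_map: dict[str, str]


def _relabel(corpus: Corpus, mapping: dict[str, str]) -> Corpus:
    dialogues = [
        Dialogue(id=d.id, disease=mapping[d.disease], turns=d.turns)
        for d in corpus.dialogues
    ]
    out = Corpus(dialogues=dialogues, symptom_vocab=list(corpus.symptom_vocab),
                 disease_vocab=sorted(set(mapping.values())))
    return out


def _filter_group(corpus: Corpus, group: str, group_map: dict[str, str]) -> Corpus:
    members = sorted(d for d, g in group_map.items() if g == group)
    dialogues = [d for d in corpus.dialogues if group_map[d.disease] == group]
    return Corpus(dialogues=dialogues, symptom_vocab=list(corpus.symptom_vocab),
                  disease_vocab=members)


def train_hierarchical(
    train_corpus: Corpus,
    val_corpus: Corpus,
    kg: SSDGraph,
    group_map: dict[str, str],
    model_config: ModelConfig | None = None,
    encoder_config: EncoderConfig | None = None,
    train_config: TrainConfig | None = None,
) -> HierarchicalCheckpoint:
    """Two-level classifier: disease group first, then disease within group."""
    missing = [d for d in train_corpus.disease_vocab if d not in group_map]
    if missing:
        raise ValueError(f"group_map missing diseases: {missing}")
    train_config = train_config or TrainConfig()
    group_ckpt = train(
        _relabel(train_corpus, group_map), _relabel(val_corpus, group_map),
        kg, model_config, encoder_config, train_config)
    per_group: dict[str, Checkpoint] = {}
    for group in sorted(set(group_map.values())):
        tr_g = _filter_group(train_corpus, group, group_map)
        va_g = _filter_group(val_corpus, group, group_map)
        if not tr_g.dialogues:
            continue
        per_group[group] = train(tr_g, va_g, kg, model_config, encoder_config, train_config)
    return HierarchicalCheckpoint(group_ckpt, per_group, dict(group_map))


def hierarchical_classify(
    hier: HierarchicalCheckpoint, dialogue: Dialogue, kg: SSDGraph
) -> str:
    """Pick a group with the group classifier, then the disease within it."""
    group_model = hier.group_checkpoint.build_model(kg)
    probs, _, _ = group_model.forward(dialogue)
    group = group_model.disease_vocab[predict_index(probs.data)]
    if group not in hier.per_group:
        raise ValueError(f"no disease classifier for group {group!r}")
    disease_model = hier.per_group[group].build_model(kg)
    dprobs, _, _ = disease_model.forward(dialogue)
    return disease_model.disease_vocab[predict_index(dprobs.data)]


def evaluate_hierarchical(
    hier: HierarchicalCheckpoint, corpus: Corpus, kg: SSDGraph
) -> dict[str, float]:
    """Group accuracy and end-to-end disease accuracy/F1/Jaccard."""
    if not corpus.dialogues:
        raise ValueError("evaluation split is empty")
    group_model = hier.group_checkpoint.build_model(kg)
    disease_models = {g: c.build_model(kg) for g, c in hier.per_group.items()}
    group_hits = 0
    y_true: list[str] = []
    y_pred: list[str] = []
    for dlg in corpus.dialogues:
        probs, _, _ = group_model.forward(dlg)
        group = group_model.disease_vocab[predict_index(probs.data)]
        group_hits += int(group == hier.group_map[dlg.disease])
        if group in disease_models:
            dm = disease_models[group]
            dprobs, _, _ = dm.forward(dlg)
            pred = dm.disease_vocab[predict_index(dprobs.data)]
        else:
            pred = ""
        y_true.append(dlg.disease)
        y_pred.append(pred)
    m = len(y_true)
    classes = sorted(set(y_true) | (set(y_pred) - {""}))
    return {
        "group_accuracy": group_hits / m,
        "accuracy": float(np.mean([t == p for t, p in zip(y_true, y_pred)])),
        "macro_f1": float(f1_score(y_true, y_pred, labels=classes,
                                   average="macro", zero_division=0)),
        "mean_jaccard": float(np.mean([jaccard({t}, {p}) for t, p in zip(y_true, y_pred)])),
    }
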