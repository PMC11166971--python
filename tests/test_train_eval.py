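"""Training dynamics, metric arithmetic, ablation plumbing, hierarchy."""

import math

import numpy as np
import pytest

from kiddi.corpus import split_corpus
from kiddi.encoder import EncoderConfig
from kiddi.gat_fusion import KIDDIModel, ModelConfig
from kiddi.knowledge_graph import build_graph
from kiddi.synthetic_data import GeneratorConfig, generate
from kiddi.train_eval import (
    Checkpoint,
    TrainConfig,
    compute_report,
    evaluate,
    evaluate_hierarchical,
    hierarchical_classify,
    jaccard,
    topk_hit,
    train,
    train_hierarchical,
)

TINY_MODEL = dict(d1=6, d2=8, d3=4, n_layers=2, n_heads=2, dropout=0.5)


def _setup(n_dialogues=50, n_diseases=5, seed=0, **gen_overrides):
    gen = dict(n_diseases=n_diseases, n_symptoms=20, symptoms_per_disease=4,
               n_common_symptoms=2, self_report_symptoms=2, n_dialogues=n_dialogues,
               seed=seed)
    gen.update(gen_overrides)
    corpus, truth = generate(GeneratorConfig(**gen))
    tr, va, te = split_corpus(corpus, (0.7, 0.1, 0.2), seed=seed)
    kg = build_graph(tr)
    return tr, va, te, kg


def test_training_loss_strictly_decreases():
    # dropout off: the smoke test probes optimization, not regularization noise
    tr, va, te, kg = _setup()
    ckpt = train(tr, va, kg, ModelConfig(**{**TINY_MODEL, "dropout": 0.0}),
                 EncoderConfig(d2=8), TrainConfig(epochs=3, seed=0))
    losses = [h["train_loss"] for h in ckpt.history]
    assert len(losses) == 3
    assert losses[0] > losses[1] > losses[2]


def test_training_is_seed_deterministic():
    tr, va, te, kg = _setup(n_dialogues=30)
    kwargs = dict(model_config=ModelConfig(**TINY_MODEL),
                  encoder_config=EncoderConfig(d2=8),
                  train_config=TrainConfig(epochs=2, seed=7))
    c1 = train(tr, va, kg, **kwargs)
    c2 = train(tr, va, kg, **kwargs)
    assert c1.history == c2.history
    for key in c1.state:
        np.testing.assert_array_equal(c1.state[key], c2.state[key])


def test_zero_learning_rate_leaves_parameters_unchanged():
    tr, va, te, kg = _setup(n_dialogues=20)
    tc = TrainConfig(epochs=2, learning_rate=0.0, seed=3)
    ckpt = train(tr, va, kg, ModelConfig(**TINY_MODEL), EncoderConfig(d2=8), tc)
    from kiddi.encoder import build_vocab
    vocab = build_vocab(tr)
    ec = EncoderConfig(vocab_size=len(vocab), d2=8)
    fresh = KIDDIModel(vocab, list(tr.disease_vocab), kg,
                       ModelConfig(**TINY_MODEL), ec, seed=3)
    for key, value in fresh.state_dict().items():
        np.testing.assert_array_equal(ckpt.state[key], value)


def test_warns_on_validation_disease_unseen_in_training(caplog):
    tr, va, te, kg = _setup(n_dialogues=30)
    # drop one disease from training only
    victim = tr.dialogues[0].disease
    tr.dialogues = [d for d in tr.dialogues if d.disease != victim]
    va.dialogues = [d for d in va.dialogues] + [d for d in te.dialogues
                                               if d.disease == victim][:1]
    with caplog.at_level("WARNING"):
        ckpt = train(tr, va, kg, ModelConfig(**TINY_MODEL), EncoderConfig(d2=8),
                     TrainConfig(epochs=1, seed=0))
    assert any(victim in rec.message for rec in caplog.records)
    assert victim in ckpt.disease_vocab  # class space stays vocabulary-defined


def test_perfect_predictions_score_one():
    probs = np.eye(4)
    report = compute_report([0, 1, 2, 3], probs, ["a", "b", "c", "d"])
    assert report.accuracy == report.macro_f1 == report.mean_jaccard == 1.0


def test_jaccard_singletons_and_sets():
    assert jaccard({"a"}, {"b"}) == 0.0
    assert jaccard({"a"}, {"a"}) == 1.0
    assert jaccard({"a", "b"}, {"b", "c"}) == pytest.approx(1 / 3)
    assert jaccard(set(), set()) == 1.0


def test_metrics_match_hand_computed_confusion_matrix():
    """3-class confusion worked out by hand.

    y_true = [a,a,b,b,c,c], y_pred = [a,b,b,b,c,a]:
    accuracy 4/6; precision (1/2, 2/3, 1); recall (1/2, 1, 1/2);
    per-class F1 (1/2, 4/5, 2/3) -> macro F1 = 59/90.
    """
    probs = np.array([
        [0.6, 0.3, 0.1],
        [0.2, 0.5, 0.3],
        [0.1, 0.8, 0.1],
        [0.3, 0.4, 0.3],
        [0.1, 0.2, 0.7],
        [0.5, 0.1, 0.4],
    ])
    report = compute_report([0, 0, 1, 1, 2, 2], probs, ["a", "b", "c"])
    assert report.accuracy == pytest.approx(4 / 6)
    assert report.mean_jaccard == pytest.approx(4 / 6)
    assert report.macro_f1 == pytest.approx((0.5 + 0.8 + 2 / 3) / 3)
    assert report.per_class["a"] == {"precision": pytest.approx(0.5),
                                     "recall": pytest.approx(0.5)}
    assert report.per_class["b"] == {"precision": pytest.approx(2 / 3),
                                     "recall": pytest.approx(1.0)}
    assert report.per_class["c"] == {"precision": pytest.approx(1.0),
                                     "recall": pytest.approx(0.5)}
    assert report.confusion == [[1, 1, 0], [0, 2, 0], [1, 0, 1]]
    assert report.top_k[1] == pytest.approx(4 / 6)
    assert report.top_k[1] <= report.top_k[3] <= report.top_k[5] == 1.0


def test_uniform_and_perfect_loss_closed_forms():
    from kiddi.autodiff import Tensor
    from kiddi.gat_fusion import cross_entropy_loss

    n = 7
    uniform = Tensor(np.full((1, n), 1.0 / n))
    assert float(cross_entropy_loss(uniform, [2]).data) == pytest.approx(math.log(n))
    one_hot = np.zeros((1, n))
    one_hot[0, 2] = 1.0
    assert float(cross_entropy_loss(Tensor(one_hot), [2]).data) == pytest.approx(0.0)


def test_topk_hit_tie_handling():
    probs = np.array([0.4, 0.4, 0.2])
    assert topk_hit(probs, 0, 1)
    assert not topk_hit(probs, 1, 1)  # tie resolves to the lower index
    assert topk_hit(probs, 1, 3)


def test_evaluate_requires_nonempty_split():
    tr, va, te, kg = _setup(n_dialogues=20)
    ckpt = train(tr, va, kg, ModelConfig(**TINY_MODEL), EncoderConfig(d2=8),
                 TrainConfig(epochs=1, seed=0))
    from kiddi.corpus import Corpus
    with pytest.raises(ValueError, match="empty"):
        evaluate(ckpt, Corpus(dialogues=[]), kg)


def test_checkpoint_round_trip(tmp_path):
    tr, va, te, kg = _setup(n_dialogues=30)
    ckpt = train(tr, va, kg, ModelConfig(**TINY_MODEL), EncoderConfig(d2=8),
                 TrainConfig(epochs=2, seed=1))
    path = tmp_path / "model.npz"
    ckpt.save(path)
    loaded = Checkpoint.load(path)
    for key in ckpt.state:
        np.testing.assert_array_equal(loaded.state[key], ckpt.state[key])
    r1 = evaluate(ckpt, te, kg)
    r2 = evaluate(loaded, te, kg)
    assert r1.accuracy == r2.accuracy
    assert r1.to_dict() == r2.to_dict()


def test_predictions_tsv_written(tmp_path):
    tr, va, te, kg = _setup(n_dialogues=30)
    ckpt = train(tr, va, kg, ModelConfig(**TINY_MODEL), EncoderConfig(d2=8),
                 TrainConfig(epochs=1, seed=0))
    report = evaluate(ckpt, te, kg)
    path = tmp_path / "pred.tsv"
    report.write_predictions_tsv(path)
    lines = path.read_text().strip().split("\n")
    assert lines[0].startswith("dialogue_id\t")
    assert len(lines) == 1 + len(te.dialogues)


def test_single_group_hierarchy_equals_flat_classification():
    tr, va, te, kg = _setup(n_dialogues=40, n_diseases=4)
    group_map = {d: "all" for d in tr.disease_vocab}
    mc, ec = ModelConfig(**TINY_MODEL), EncoderConfig(d2=8)
    tc = TrainConfig(epochs=2, seed=0)
    hier = train_hierarchical(tr, va, kg, group_map, mc, ec, tc)
    flat = train(tr, va, kg, mc, ec, tc)
    flat_report = evaluate(flat, te, kg)
    metrics = evaluate_hierarchical(hier, te, kg)
    assert metrics["group_accuracy"] == 1.0
    # the within-group classifier sees the same task as the flat one
    assert metrics["accuracy"] == pytest.approx(flat_report.accuracy)
    pred = hierarchical_classify(hier, te.dialogues[0], kg)
    assert pred in tr.disease_vocab


def test_group_accuracy_bounds_disease_accuracy():
    tr, va, te, kg = _setup(n_dialogues=60, n_diseases=6, noise_rate=0.0)
    diseases = sorted(tr.disease_vocab)
    group_map = {d: ("g0" if i < 3 else "g1") for i, d in enumerate(diseases)}
    mc, ec = ModelConfig(**TINY_MODEL), EncoderConfig(d2=8)
    tc = TrainConfig(epochs=4, seed=0)
    hier = train_hierarchical(tr, va, kg, group_map, mc, ec, tc)
    metrics = evaluate_hierarchical(hier, te, kg)
    assert metrics["group_accuracy"] >= metrics["accuracy"]
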