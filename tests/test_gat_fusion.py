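"""Model core: GAT vs dense oracle, attention arithmetic, classifier, loss."""

import math

import numpy as np
import pytest

from _oracles import cross_entropy_oracle, gat_layer_oracle
from kiddi.autodiff import Tensor, param
from kiddi.corpus import Dialogue, Utterance
from kiddi.distillation import DistillationConfig
from kiddi.encoder import EncoderConfig, build_vocab
from kiddi.gat_fusion import (
    GATParams,
    KIDDIModel,
    ModelConfig,
    additive_attention,
    classify,
    cross_entropy_loss,
    gat_layer,
    mean_pool,
    predict_index,
)
from kiddi.knowledge_graph import SSDGraph, build_graph
from kiddi.synthetic_data import GeneratorConfig, generate


def _random_heads(rng, n_heads, head_dim, d1):
    return [
        (param(rng.normal(size=(head_dim, d1))), param(rng.normal(size=2 * head_dim)))
        for _ in range(n_heads)
    ]


def test_single_node_self_loop_exact():
    """Softmax over one neighbor is 1; update reduces to LeakyReLU(W h)."""
    rng = np.random.default_rng(0)
    heads = _random_heads(rng, 1, 3, 3)
    h = rng.normal(size=(1, 3))
    out = gat_layer(np.zeros((1, 1), dtype=bool), Tensor(h), GATParams(heads), slope=0.2)
    wh = heads[0][0].data @ h[0]
    expected = np.where(wh > 0, wh, 0.2 * wh)
    np.testing.assert_allclose(out.data[0], expected, atol=1e-12)


@pytest.mark.parametrize("seed", range(20))
def test_gat_matches_dense_oracle_random_graphs(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 7))
    d1 = 6
    n_heads = int(rng.choice([1, 2, 3]))
    adj = rng.random((n, n)) < 0.5
    adj = np.triu(adj, 1)
    adj = adj | adj.T
    heads = _random_heads(rng, n_heads, d1 // n_heads * 0 + 2, d1)
    h = rng.normal(size=(n, d1))
    out = gat_layer(adj, Tensor(h), GATParams(heads), slope=0.2)
    expected = gat_layer_oracle(adj, h, [(w.data, a.data) for w, a in heads], slope=0.2)
    np.testing.assert_allclose(out.data, expected, atol=1e-6)


def test_attention_rows_sum_to_one_over_neighborhoods():
    from kiddi.autodiff import masked_softmax

    rng = np.random.default_rng(3)
    n = 5
    adj = rng.random((n, n)) < 0.4
    adj = np.triu(adj, 1)
    adj = adj | adj.T
    mask = adj | np.eye(n, dtype=bool)
    alpha = masked_softmax(Tensor(rng.normal(size=(n, n))), mask, axis=1).data
    np.testing.assert_allclose(alpha.sum(axis=1), np.ones(n), atol=1e-12)


def test_mean_pool_closed_forms():
    x = np.array([1.5, -2.0, 3.0])
    same = Tensor(np.tile(x, (4, 1)))
    np.testing.assert_allclose(mean_pool(same).data, x)
    anti = Tensor(np.stack([x, -x]))
    np.testing.assert_allclose(mean_pool(anti).data, np.zeros(3), atol=1e-15)
    rng = np.random.default_rng(1)
    table = rng.normal(size=(5, 4))
    np.testing.assert_allclose(mean_pool(Tensor(table)).data, table.mean(axis=0))


def test_additive_attention_symmetry_and_simplex():
    rng = np.random.default_rng(2)
    s = Tensor(rng.normal(size=3))
    h = Tensor(rng.normal(size=5))
    w1 = Tensor(rng.normal(size=(4, 5)))
    w2 = Tensor(rng.normal(size=(4, 3)))
    v = Tensor(rng.normal(size=4))
    context, alpha = additive_attention(s, h, h, w1, w2, v)
    np.testing.assert_allclose(alpha.data, [0.5, 0.5], atol=1e-12)
    np.testing.assert_allclose(context.data, h.data, atol=1e-12)
    assert alpha.data.sum() == pytest.approx(1.0)
    assert np.all(alpha.data > 0)


def test_additive_attention_hand_example():
    """d1=d2=2, d3=1, all-ones weights, h1=(1,0), h2=(0,1), s=(1,1).

    e_i = tanh(h_i.sum() + s.sum()) = tanh(3) for both, so alpha=(1/2,1/2)
    and context = (1/2, 1/2). Worked out by hand.
    """
    ones = Tensor(np.ones((1, 2)))
    v = Tensor(np.ones(1))
    context, alpha = additive_attention(
        Tensor([1.0, 1.0]), Tensor([1.0, 0.0]), Tensor([0.0, 1.0]), ones, ones, v)
    np.testing.assert_allclose(alpha.data, [0.5, 0.5], atol=1e-12)
    np.testing.assert_allclose(context.data, [0.5, 0.5], atol=1e-12)


def test_classify_uniform_simplex_and_shift_invariance():
    x = Tensor(np.array([0.3, -0.7]))
    w0 = Tensor(np.zeros((4, 2)))
    b0 = Tensor(np.zeros(4))
    np.testing.assert_allclose(classify(x, w0, b0).data, np.full(4, 0.25))
    rng = np.random.default_rng(4)
    w = Tensor(rng.normal(size=(4, 2)))
    b = rng.normal(size=4)
    p1 = classify(x, w, Tensor(b)).data
    p2 = classify(x, w, Tensor(b + 7.3)).data
    assert p1.sum() == pytest.approx(1.0, abs=1e-6)
    np.testing.assert_allclose(p1, p2, atol=1e-12)


def test_cross_entropy_closed_forms_and_oracle():
    perfect = Tensor(np.array([[0.0, 1.0, 0.0]]))
    assert float(cross_entropy_loss(perfect, [1]).data) == pytest.approx(0.0)
    uniform = Tensor(np.full((1, 5), 0.2))
    assert float(cross_entropy_loss(uniform, [3]).data) == pytest.approx(math.log(5))
    rng = np.random.default_rng(5)
    raw = rng.random((6, 4))
    probs = raw / raw.sum(axis=1, keepdims=True)
    labels = rng.integers(0, 4, size=6)
    got = float(cross_entropy_loss(Tensor(probs), labels).data)
    assert got == pytest.approx(cross_entropy_oracle(probs, labels), abs=1e-12)


def _tiny_model(mode="full", seed=0):
    corpus, _ = generate(GeneratorConfig(n_diseases=3, n_symptoms=12,
                                         symptoms_per_disease=4, n_common_symptoms=1,
                                         self_report_symptoms=1, n_dialogues=9, seed=0))
    kg = build_graph(corpus)
    vocab = build_vocab(corpus)
    model = KIDDIModel(
        vocab=vocab,
        disease_vocab=list(corpus.disease_vocab),
        kg=kg,
        model_config=ModelConfig(d1=6, d2=8, d3=4, n_layers=2, n_heads=2,
                                 dropout=0.0, mode=mode),
        encoder_config=EncoderConfig(vocab_size=len(vocab), d2=8),
        distill_config=DistillationConfig(K=2),
        seed=seed,
    )
    return model, corpus


def test_forward_degenerate_dialogue_still_valid_distribution():
    model, _ = _tiny_model()
    lonely = Dialogue(id="x", disease=model.disease_vocab[0], turns=[
        Utterance("patient", "I feel unwell.", intent=None, symptoms=[])])
    probs, alpha, graph_emb = model.forward(lonely)
    assert probs.data.shape == (3,)
    assert probs.data.sum() == pytest.approx(1.0, abs=1e-9)
    assert np.all(probs.data > 0)
    assert alpha is not None and alpha.sum() == pytest.approx(1.0)
    assert graph_emb is not None


def test_forward_is_deterministic_without_dropout():
    model, corpus = _tiny_model()
    dlg = corpus.dialogues[0]
    p1, a1, _ = model.forward(dlg)
    p2, a2, _ = model.forward(dlg)
    np.testing.assert_array_equal(p1.data, p2.data)
    np.testing.assert_array_equal(a1, a2)


@pytest.mark.parametrize("mode", ["full", "sre_only", "de_only", "knowledge_only",
                                  "sre_linear", "de_linear", "sre_knowledge",
                                  "de_knowledge"])
def test_every_mode_emits_valid_distribution(mode):
    model, corpus = _tiny_model(mode=mode)
    probs, _, _ = model.forward(corpus.dialogues[0])
    assert probs.data.shape == (3,)
    assert probs.data.sum() == pytest.approx(1.0, abs=1e-9)


def test_full_model_gradient_matches_finite_differences():
    """End-to-end loss gradient vs central differences on sampled entries."""
    model, corpus = _tiny_model()
    prep = model.prepare(corpus.dialogues[0])
    label = prep.label

    def loss_value() -> float:
        probs, _, _ = model.forward_prepared(prep)
        return float(cross_entropy_loss(probs.reshape(1, -1), [label]).data)

    for p in model.params.values():
        p.grad = None
    probs, _, _ = model.forward_prepared(prep)
    cross_entropy_loss(probs.reshape(1, -1), [label]).backward()

    rng = np.random.default_rng(0)
    eps = 1e-6
    checked = 0
    for name in ("enc/emb", "gat/0/0/W", "gat/1/1/a", "att/W1", "att/v", "clf/W"):
        tensor = model.params[name]
        grad = tensor.grad if tensor.grad is not None else np.zeros_like(tensor.data)
        flat = tensor.data.reshape(-1)
        gflat = grad.reshape(-1)
        for idx in rng.choice(flat.size, size=min(3, flat.size), replace=False):
            orig = flat[idx]
            flat[idx] = orig + eps
            hi = loss_value()
            flat[idx] = orig - eps
            lo = loss_value()
            flat[idx] = orig
            fd = (hi - lo) / (2 * eps)
            assert gflat[idx] == pytest.approx(fd, rel=1e-4, abs=1e-7)
            checked += 1
    assert checked >= 10


def test_predict_tie_break_lowest_index():
    assert predict_index(np.array([0.4, 0.4, 0.2])) == 0
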