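"""Utterance encoding: token serialization and a pluggable encoder.

The self-report is serialized as ``<sr_start> ... <sr_end>`` and the full
conversation interleaves turns in conversational order, each patient
utterance prefixed with ``<pat>`` and each doctor utterance with
``<doc>``. A pluggable encoder maps a token sequence to a fixed-width
vector (width ``d2``):

* ``reference_small`` -- the in-package trainable encoder: learned token
  embeddings, mean-pooled and affine-transformed to width d2. It is
  deliberately simple; the synthetic corpora are templated, so all the
  signal an encoder must carry lives in which symptom words appear.
* ``pretrained_adapter`` -- a contract-level slot for an external
  transformer encoder (e.g. a biomedical BERT with first-position
  pooling); any callable mapping a token sequence to a width-d2 vector
  qualifies. No pretrained weights ship with the package.

Entity names (symptom/disease node labels) and the dialog encoding are
projected from d2 to the graph feature width d1 by a shared learned map.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .autodiff import Tensor, glorot, param
from .corpus import DOCTOR, Corpus, Dialogue

__all__ = [
    "EncoderConfig",
    "UNK",
    "SR_START",
    "SR_END",
    "PAT",
    "DOC",
    "tokenize",
    "build_vocab",
    "tokens_to_ids",
    "serialize_self_report",
    "serialize_dialogue",
    "init_encoder_params",
    "encode_many",
    "encode",
    "encode_entity_name",
    "PretrainedAdapter",
]

UNK = "<unk>"
SR_START = "<sr_start>"
SR_END = "<sr_end>"
PAT = "<pat>"
DOC = "<doc>"
SPECIAL_TOKENS = (UNK, SR_START, SR_END, PAT, DOC)

_TOKEN = re.compile(r"[a-z0-9']+")


@dataclass
class EncoderConfig:
    vocab_size: int = 0  # filled by build_vocab
    d2: int = 768
    max_sequence_length: int = 512
    encoder_kind: str = "reference_small"

    def __post_init__(self) -> None:
        if self.d2 < 1:
            raise ValueError("d2 must be >= 1")
        if self.max_sequence_length < 8:
            raise ValueError("max_sequence_length must be >= 8")
        if self.encoder_kind not in ("reference_small", "pretrained_adapter"):
            raise ValueError(f"unknown encoder_kind {self.encoder_kind!r}")


def tokenize(text: str) -> list[str]:
    """Lowercased whitespace/punctuation tokenization."""
    return _TOKEN.findall(text.lower())


def build_vocab(corpus: Corpus) -> dict[str, int]:
    """Token vocabulary over all utterance texts and entity names.

    Special tokens occupy the first ids; the rest is lexicographic so
    ids are stable across runs.
    """
    tokens: set[str] = set()
    for dlg in corpus.dialogues:
        for turn in dlg.turns:
            tokens.update(tokenize(turn.text))
    for name in list(corpus.symptom_vocab) + list(corpus.disease_vocab):
        tokens.update(tokenize(name))
    vocab = {tok: i for i, tok in enumerate(SPECIAL_TOKENS)}
    for tok in sorted(tokens):
        if tok not in vocab:
            vocab[tok] = len(vocab)
    return vocab


def tokens_to_ids(tokens: Sequence[str], vocab: dict[str, int]) -> list[int]:
    unk = vocab[UNK]
    return [vocab.get(t, unk) for t in tokens]


def serialize_self_report(dialogue: Dialogue, max_sequence_length: int = 512) -> list[str]:
    """``[<sr_start>] + tokens(first patient utterance) + [<sr_end>]``,
    truncated to the length budget while keeping both sentinels."""
    body = tokenize(dialogue.self_report.text)
    body = body[: max_sequence_length - 2]
    return [SR_START] + body + [SR_END]


def serialize_dialogue(dialogue: Dialogue, max_sequence_length: int = 512) -> list[str]:
    """Turns in conversational order, each prefixed with its speaker marker,
    truncated from the tail to the length budget."""
    out: list[str] = []
    for turn in dialogue.turns:
        out.append(DOC if turn.speaker == DOCTOR else PAT)
        out.extend(tokenize(turn.text))
    return out[:max_sequence_length]


def init_encoder_params(
    config: EncoderConfig, d1: int, rng: np.random.Generator
) -> dict[str, Tensor]:
    """Trainable tables of the reference encoder.

    ``emb`` token embeddings (V, d2); ``enc_W``/``enc_b`` the post-pool
    affine map (d2 -> d2); ``proj_W``/``proj_b`` the shared entity/dialog
    projection (d2 -> d1).
    """
    d2 = config.d2
    return {
        "enc/emb": param(rng.normal(0.0, 0.1, size=(config.vocab_size, d2))),
        "enc/W": param(glorot(rng, d2, d2)),
        "enc/b": param(np.zeros(d2)),
        "enc/proj_W": param(glorot(rng, d1, d2)),
        "enc/proj_b": param(np.zeros(d1)),
    }


def _pool_matrix(id_lists: list[list[int]], vocab_size: int) -> np.ndarray:
    """Fixed averaging matrix M (B, V): row b averages the embeddings of
    sequence b's tokens, so mean-pooled encodings are one matmul M @ emb."""
    m = np.zeros((len(id_lists), vocab_size))
    for b, ids in enumerate(id_lists):
        if ids:
            w = 1.0 / len(ids)
            for i in ids:
                m[b, i] += w
    return m


def encode_many(id_lists: list[list[int]], params: dict[str, Tensor]) -> Tensor:
    """Encode a batch of token-id sequences to (B, d2) in three matmuls."""
    emb = params["enc/emb"]
    pool = _pool_matrix(id_lists, emb.shape[0])
    pooled = Tensor(pool) @ emb
    return pooled @ _t(params["enc/W"]) + params["enc/b"]


def _t(t: Tensor) -> Tensor:
    # 2-D transpose via reshape-free matmul orientation
    out = Tensor(t.data.T, parents=(t,))
    out._backward = lambda g: t._accumulate(g.T)
    return out


def encode(
    tokens: Sequence[str], params: dict[str, Tensor], vocab: dict[str, int]
) -> Tensor:
    """Encode one token sequence to a width-d2 vector.

    The empty sequence maps to the encoder's learned null vector (the
    affine bias); unknown tokens map to the reserved unknown id.
    """
    ids = tokens_to_ids(tokens, vocab)
    return encode_many([ids], params)[0]


def encode_entity_name(
    name: str, params: dict[str, Tensor], vocab: dict[str, int]
) -> Tensor:
    """Entity-name feature: encode the name, then project d2 -> d1."""
    enc = encode(tokenize(name), params, vocab)
    return params["enc/proj_W"] @ enc + params["enc/proj_b"]


def project_to_graph(enc: Tensor, params: dict[str, Tensor]) -> Tensor:
    """Shared d2 -> d1 projection (dialog node and entity names alike)."""
    return params["enc/proj_W"] @ enc + params["enc/proj_b"]


@dataclass
class PretrainedAdapter:
    """Wrapper satisfying the encoder contract with an external model.

    ``fn`` maps a token sequence to a width-d2 numpy vector (typically
    the first-position pooled output of a frozen transformer). Encodings
    pass through as constants: the external encoder is not trained here.
    """

    fn: Callable[[Sequence[str]], np.ndarray]
    d2: int

    def encode(self, tokens: Sequence[str]) -> Tensor:
        vec = np.asarray(self.fn(tokens), dtype=np.float64)
        if vec.shape != (self.d2,):
            raise ValueError(f"adapter returned shape {vec.shape}, expected ({self.d2},)")
        return Tensor(vec)
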