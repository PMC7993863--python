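"""The gated knowledge-infused relation-extraction network.

Two branches read a masked tweet.  A position-aware branch concatenates word
and entity-relative position embeddings, encodes them with a multi-window
CNN, and pools with an attention whose scores see each token's hidden state,
a sentence aggregate vector, and both entities' position embeddings.  A
contextual branch mean-pools a chosen hidden layer of a BERT-style
transformer encoder (special tokens zero-masked).  A learned sigmoid gate
fuses the two sentence representations elementwise, and a single softmax
layer classifies the relation into {Reason, Effect, Addiction, Ambiguous}.

Ablation variants switch off individual components: the contextual branch,
the position-aware attention (mean pooling instead), the position embeddings
at the input, the CNN (attention directly over the input encoding), a
word-level "vanilla" attention that ignores entity positions, and plain
concatenation instead of the gate.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .autodiff import Tensor, concat
from .locator import MaskedTweet
from .positions import EmbeddingTables, relative_positions

__all__ = [
    "LABELS",
    "ARCH_VARIANTS",
    "ConvConfig",
    "ContextEncoderSpec",
    "ModelConfig",
    "AttentionParams",
    "VanillaAttentionParams",
    "FusionParams",
    "ClassifierParams",
    "ContextEncoder",
    "RelationModel",
    "conv_encode",
    "aggregate_vector",
    "position_aware_attention",
    "vanilla_attention",
    "gated_fusion",
    "classify",
    "cross_entropy",
]

LABELS: tuple[str, ...] = ("Reason", "Effect", "Addiction", "Ambiguous")

ARCH_VARIANTS: tuple[str, ...] = (
    "full",
    "no_context",
    "no_position_attention",
    "no_position_embedding",
    "no_cnn",
    "vanilla_attention",
    "concat_fusion",
)


@dataclass(frozen=True)
class ConvConfig:
    """Multi-window CNN: window lengths 2/3/4, 128 features each, stride 1."""

    window_sizes: tuple[int, ...] = (2, 3, 4)
    features_per_window: int = 128
    stride: int = 1

    def __post_init__(self) -> None:
        if self.stride != 1:
            raise ValueError("only stride 1 is supported")
        if not self.window_sizes or any(m < 1 for m in self.window_sizes):
            raise ValueError("window sizes must be positive")

    @property
    def hidden_dim(self) -> int:
        return len(self.window_sizes) * self.features_per_window


@dataclass(frozen=True)
class ContextEncoderSpec:
    """Shape of the transformer sentence encoder.

    The default profile mirrors a 12-layer, 12-head, 768-dim pretrained
    encoder; the test profile is a small randomly initialized encoder so the
    suite needs no model download.  ``layer_used`` defaults to the
    second-last layer, whose representation is less tied to the pretraining
    objectives than the last.
    """

    n_layers: int = 12
    n_heads: int = 12
    hidden: int = 768
    layer_used: int | None = None  # defaults to n_layers - 1
    special_token_masking: bool = True
    pooling: str = "mean"  # or "cls"
    include_special_in_count: bool = False
    max_len: int = 128
    vocab_buckets: int = 2048

    def __post_init__(self) -> None:
        if self.hidden % self.n_heads:
            raise ValueError("hidden must be divisible by n_heads")
        layer = self.resolved_layer
        if not 1 <= layer <= self.n_layers:
            raise ValueError("layer_used must lie in [1, n_layers]")
        if self.pooling not in ("mean", "cls"):
            raise ValueError("pooling must be 'mean' or 'cls'")

    @property
    def resolved_layer(self) -> int:
        return self.n_layers - 1 if self.layer_used is None else self.layer_used

    @classmethod
    def small(cls, **kw) -> "ContextEncoderSpec":
        """2-layer, 2-head, 32-dim random-init profile for tests/CI."""
        defaults = dict(n_layers=2, n_heads=2, hidden=32, max_len=64, vocab_buckets=256)
        defaults.update(kw)
        return cls(**defaults)


@dataclass(frozen=True)
class ModelConfig:
    """Dimensions, variant and regularization of the full network."""

    conv: ConvConfig = ConvConfig()
    attention_dim: int = 50
    encoder: ContextEncoderSpec = ContextEncoderSpec()
    fusion_dim: int | None = None  # defaults to the CNN hidden dim
    dropout: float = 0.3
    variant: str = "full"
    trainable_word_embeddings: bool = True
    trainable_context_encoder: bool = True

    def __post_init__(self) -> None:
        if self.variant not in ARCH_VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; one of {ARCH_VARIANTS}")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")

    @classmethod
    def small(cls, variant: str = "full", **kw) -> "ModelConfig":
        defaults = dict(
            conv=ConvConfig(features_per_window=24),
            attention_dim=16,
            encoder=ContextEncoderSpec.small(),
            variant=variant,
        )
        defaults.update(kw)
        return cls(**defaults)


# --------------------------------------------------------------------------
# Parameter bundles and the individual layer operations.  Each operation is
# a pure function of Tensors so the training graph and the unit oracles
# exercise the very same code.
# --------------------------------------------------------------------------


@dataclass
class AttentionParams:
    W_h: Tensor  # (d_a, d_h)
    W_q: Tensor  # (d_a, d_h)
    W_c: Tensor  # (d_a, d_p)
    W_d: Tensor  # (d_a, d_p)
    v: Tensor  # (d_a,)


@dataclass
class VanillaAttentionParams:
    W_u: Tensor  # (d_h, d_h)
    b_u: Tensor  # (d_h,)
    v: Tensor  # (d_h,)


@dataclass
class FusionParams:
    W_R: Tensor  # (f, d_h)
    W_B: Tensor  # (f, h_b)
    W_g: Tensor  # (f, d_h + h_b)


@dataclass
class ClassifierParams:
    W: Tensor  # (|Y|, f)
    a: Tensor  # (|Y|,)
    labels: tuple[str, ...] = LABELS


def conv_encode(x: Tensor, filters: list[tuple[int, Tensor, Tensor]]) -> Tensor:
    """Multi-window CNN with tanh and same-length zero padding.

    ``filters`` is a list of (window, weight (window*d_in, F), bias (F,));
    hidden state h_i concatenates every window's features at position i.
    """
    return concat([x.conv1d_same(W, b, m).tanh() for m, W, b in filters], axis=1)


def aggregate_vector(h: Tensor) -> Tensor:
    """Sentence aggregate q: the arithmetic mean of the hidden states."""
    return h.mean(axis=0)


def position_aware_attention(
    h: Tensor, q: Tensor, P_c: Tensor, P_d: Tensor, params: AttentionParams
) -> tuple[Tensor, Tensor]:
    """Entity position-aware attention pooling.

    Scores combine hidden state, aggregate vector and both entities'
    position embeddings; returns (R, alpha) with alpha a softmax over
    positions and R the alpha-weighted sum of hidden states.
    """
    pre = (
        h @ params.W_h.transpose()
        + params.W_q @ q
        + P_c @ params.W_c.transpose()
        + P_d @ params.W_d.transpose()
    )
    u = pre.tanh() @ params.v  # (n,)
    alpha = u.softmax()
    return alpha @ h, alpha


def vanilla_attention(h: Tensor, params: VanillaAttentionParams) -> tuple[Tensor, Tensor]:
    """Word-level attention that ignores entity positions."""
    u = (h @ params.W_u.transpose() + params.b_u).tanh()  # (n, d_h)
    alpha = (u @ params.v).softmax()
    return alpha @ h, alpha


def gated_fusion(R: Tensor, B: Tensor, params: FusionParams) -> Tensor:
    """Elementwise convex combination of the two projected representations,
    weighted by a learned sigmoid gate over their concatenation."""
    h_R = (params.W_R @ R).tanh()
    h_B = (params.W_B @ B).tanh()
    g = (params.W_g @ concat([R, B], axis=0)).sigmoid()
    return g * h_R + (1.0 - g) * h_B


def classify(fused: Tensor, params: ClassifierParams) -> Tensor:
    """Single-layer softmax classifier over the relation labels."""
    return (params.W @ fused + params.a).softmax()


def cross_entropy(fused: Tensor, params: ClassifierParams, label_idx: int) -> Tensor:
    """Numerically stable negative log-likelihood of the gold label."""
    logits = params.W @ fused + params.a
    shift = float(logits.data.max())
    lse = (logits - shift).exp().sum().log() + shift
    return lse - logits[label_idx]


# --------------------------------------------------------------------------
# Transformer context encoder
# --------------------------------------------------------------------------


def _layer_norm(x: Tensor, g: Tensor, b: Tensor, eps: float = 1e-5) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    cent = x - mu
    var = (cent * cent).mean(axis=-1, keepdims=True)
    return cent * (var + eps).pow(-0.5) * g + b


class ContextEncoder:
    """Small BERT-style transformer exposing per-layer hidden states.

    Tokens are hashed into a fixed bucket vocabulary ([CLS]=0, [SEP]=1,
    buckets from 2), embedded with learned token + absolute-position
    embeddings, and passed through post-layer-norm self-attention blocks.
    """

    CLS, SEP = 0, 1

    def __init__(self, spec: ContextEncoderSpec, seed: int = 0, trainable: bool = True):
        self.spec = spec
        h = spec.hidden
        rng = np.random.default_rng(seed)

        def p(*shape, scale=None):
            scale = scale if scale is not None else 1 / np.sqrt(shape[-1])
            return Tensor(rng.standard_normal(shape) * scale, requires_grad=trainable)

        V = 2 + spec.vocab_buckets
        self.tok_emb = p(V, h)
        self.pos_emb = p(spec.max_len, h)
        self.layers = []
        for _ in range(spec.n_layers):
            self.layers.append(
                {
                    "Wq": p(h, h), "bq": Tensor(np.zeros(h), requires_grad=trainable),
                    "Wk": p(h, h), "bk": Tensor(np.zeros(h), requires_grad=trainable),
                    "Wv": p(h, h), "bv": Tensor(np.zeros(h), requires_grad=trainable),
                    "Wo": p(h, h), "bo": Tensor(np.zeros(h), requires_grad=trainable),
                    "ln1_g": Tensor(np.ones(h), requires_grad=trainable),
                    "ln1_b": Tensor(np.zeros(h), requires_grad=trainable),
                    "W1": p(h, 4 * h), "b1": Tensor(np.zeros(4 * h), requires_grad=trainable),
                    "W2": p(4 * h, h), "b2": Tensor(np.zeros(h), requires_grad=trainable),
                    "ln2_g": Tensor(np.ones(h), requires_grad=trainable),
                    "ln2_b": Tensor(np.zeros(h), requires_grad=trainable),
                }
            )

    def parameters(self) -> list[Tensor]:
        out = [self.tok_emb, self.pos_emb]
        for layer in self.layers:
            out.extend(layer.values())
        return out

    def token_ids(self, tokens) -> np.ndarray:
        content = [2 + zlib.crc32(t.encode("utf-8")) % self.spec.vocab_buckets for t in tokens]
        return np.asarray([self.CLS] + content + [self.SEP], dtype=np.int64)

    def _attention(self, x: Tensor, layer: dict) -> Tensor:
        spec = self.spec
        n = x.shape[0]
        hd = spec.hidden // spec.n_heads

        def heads(t: Tensor) -> Tensor:
            return t.reshape(n, spec.n_heads, hd).transpose(1, 0, 2)

        q = heads(x @ layer["Wq"] + layer["bq"])
        k = heads(x @ layer["Wk"] + layer["bk"])
        v = heads(x @ layer["Wv"] + layer["bv"])
        scores = (q @ k.transpose(0, 2, 1)) * (1.0 / np.sqrt(hd))
        att = scores.softmax(axis=-1) @ v  # (heads, n, hd)
        merged = att.transpose(1, 0, 2).reshape(n, spec.hidden)
        return merged @ layer["Wo"] + layer["bo"]

    def hidden_states(self, tokens) -> list[Tensor]:
        """Embedding plus every layer's output, for [CLS] + tokens + [SEP]."""
        spec = self.spec
        tokens = list(tokens)
        if len(tokens) + 2 > spec.max_len:
            warnings.warn(
                f"sequence of {len(tokens)} tokens exceeds encoder max_len={spec.max_len}; truncating",
                stacklevel=2,
            )
            tokens = tokens[: spec.max_len - 2]
        ids = self.token_ids(tokens)
        x = self.tok_emb.take_rows(ids) + self.pos_emb.take_rows(np.arange(len(ids)))
        states = [x]
        for layer in self.layers:
            x = _layer_norm(x + self._attention(x, layer), layer["ln1_g"], layer["ln1_b"])
            ffn = ((x @ layer["W1"] + layer["b1"]).relu()) @ layer["W2"] + layer["b2"]
            x = _layer_norm(x + ffn, layer["ln2_g"], layer["ln2_b"])
            states.append(x)
        return states

    def representation(self, tokens) -> Tensor:
        """Pooled sentence vector B from the configured layer.

        Special-token rows are zero-masked and the remaining rows are
        averaged over the content-token count (optionally over the padded
        length including [CLS]/[SEP]); ``pooling='cls'`` returns the [CLS]
        row instead.
        """
        spec = self.spec
        states = self.hidden_states(tokens)
        H = states[spec.resolved_layer]
        if spec.pooling == "cls":
            return H[0]
        n_total = H.shape[0]
        n_content = n_total - 2
        if n_content < 1:
            raise ValueError("cannot pool an empty sequence")
        if spec.special_token_masking:
            mask = np.ones((n_total, 1))
            mask[0, 0] = mask[-1, 0] = 0.0
            H = H * Tensor(mask)
        divisor = n_total if spec.include_special_in_count else n_content
        return H.sum(axis=0) * (1.0 / divisor)


# --------------------------------------------------------------------------
# Full network
# --------------------------------------------------------------------------


class RelationModel:
    """One architecture variant with its trainable parameters.

    Composes locate→mask→encode→conv→attend→context→fuse→classify from the
    layer functions above; the preprocessing (tokenize/locate/mask) happens
    upstream, this class maps a :class:`MaskedTweet` to class probabilities.
    """

    def __init__(self, tables: EmbeddingTables, config: ModelConfig = ModelConfig.small(), seed: int = 0):
        self.tables = tables
        self.config = config
        rng = np.random.default_rng(seed)
        cfg = config

        def p(*shape):
            return Tensor(rng.standard_normal(shape) / np.sqrt(shape[-1]), requires_grad=True)

        d_w, d_p = tables.word_dim, tables.position_dim
        d_in = d_w if cfg.variant == "no_position_embedding" else d_w + 2 * d_p
        self.word_table = Tensor(tables.word_table.copy(), requires_grad=cfg.trainable_word_embeddings)
        self.position_table = Tensor(tables.position_table.copy(), requires_grad=True)

        if cfg.variant == "no_cnn":
            self.filters = []
            d_h = d_in
        else:
            self.filters = [
                (m, p(m * d_in, cfg.conv.features_per_window),
                 Tensor(np.zeros(cfg.conv.features_per_window), requires_grad=True))
                for m in cfg.conv.window_sizes
            ]
            d_h = cfg.conv.hidden_dim
        self.hidden_dim = d_h

        d_a = cfg.attention_dim
        self.attention = AttentionParams(
            W_h=p(d_a, d_h), W_q=p(d_a, d_h), W_c=p(d_a, d_p), W_d=p(d_a, d_p), v=p(d_a)
        )
        self.vanilla = VanillaAttentionParams(W_u=p(d_h, d_h), b_u=Tensor(np.zeros(d_h), requires_grad=True), v=p(d_h))

        self.encoder: ContextEncoder | None = None
        h_b = cfg.encoder.hidden
        if cfg.variant != "no_context":
            self.encoder = ContextEncoder(
                cfg.encoder, seed=seed + 1, trainable=cfg.trainable_context_encoder
            )

        f = cfg.fusion_dim if cfg.fusion_dim is not None else d_h
        self.fusion = FusionParams(W_R=p(f, d_h), W_B=p(f, h_b), W_g=p(f, d_h + h_b))
        cls_in = d_h + h_b if cfg.variant == "concat_fusion" else f
        self.classifier = ClassifierParams(
            W=p(len(LABELS), cls_in), a=Tensor(np.zeros(len(LABELS)), requires_grad=True)
        )
        self.label_index = {lab: i for i, lab in enumerate(LABELS)}

    def parameters(self) -> list[Tensor]:
        out = [self.word_table, self.position_table]
        for _, W, b in self.filters:
            out += [W, b]
        a, vp, fu, cl = self.attention, self.vanilla, self.fusion, self.classifier
        out += [a.W_h, a.W_q, a.W_c, a.W_d, a.v, vp.W_u, vp.b_u, vp.v]
        out += [fu.W_R, fu.W_B, fu.W_g, cl.W, cl.a]
        if self.encoder is not None:
            out += self.encoder.parameters()
        return [t for t in out if t.requires_grad]

    # -- forward ----------------------------------------------------------

    def _input_encoding(self, masked: MaskedTweet) -> tuple[Tensor, Tensor, Tensor]:
        tokens = masked.tokens
        n = len(tokens)
        vocab = self.tables.vocab
        idx = np.zeros(n, dtype=np.int64)
        in_vocab = np.zeros((n, 1))
        oov = np.zeros((n, self.tables.word_dim))
        for i, tok in enumerate(tokens):
            j = vocab.get(tok)
            if j is None:
                oov[i] = self.tables.oov_vector(tok)
            else:
                idx[i] = j
                in_vocab[i, 0] = 1.0
        E = self.word_table.take_rows(idx) * Tensor(in_vocab) + Tensor(oov)
        clip = self.tables.clip
        pc = relative_positions(n, masked.cannabis_span, clip).indices()
        pd = relative_positions(n, masked.depression_span, clip).indices()
        P_c = self.position_table.take_rows(pc)
        P_d = self.position_table.take_rows(pd)
        return E, P_c, P_d

    def _fused(self, masked: MaskedTweet, training: bool, rng: np.random.Generator | None) -> Tensor:
        cfg = self.config
        E, P_c, P_d = self._input_encoding(masked)
        x = E if cfg.variant == "no_position_embedding" else concat([E, P_c, P_d], axis=1)
        h = x if cfg.variant == "no_cnn" else conv_encode(x, self.filters)
        q = aggregate_vector(h)
        if cfg.variant == "no_position_attention":
            R = q
        elif cfg.variant == "vanilla_attention":
            R, _ = vanilla_attention(h, self.vanilla)
        else:
            R, _ = position_aware_attention(h, q, P_c, P_d, self.attention)

        if cfg.variant == "no_context":
            fused = (self.fusion.W_R @ R).tanh()
        else:
            B = self.encoder.representation(masked.tokens)
            if cfg.variant == "concat_fusion":
                fused = concat([R, B], axis=0)
            else:
                fused = gated_fusion(R, B, self.fusion)

        if training and cfg.dropout > 0:
            if rng is None:
                raise ValueError("training-mode forward needs an rng for dropout")
            keep = (rng.random(fused.shape) >= cfg.dropout) / (1.0 - cfg.dropout)
            fused = fused * Tensor(keep)
        return fused

    def forward(self, masked: MaskedTweet, training: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        """Class-probability vector over (Reason, Effect, Addiction, Ambiguous)."""
        return classify(self._fused(masked, training, rng), self.classifier)

    def loss(self, masked: MaskedTweet, label: str, training: bool = True,
             rng: np.random.Generator | None = None) -> Tensor:
        return cross_entropy(
            self._fused(masked, training, rng), self.classifier, self.label_index[label]
        )

    def predict(self, masked: MaskedTweet) -> tuple[str, np.ndarray]:
        probs = self.forward(masked).data
        return LABELS[int(np.argmax(probs))], probs
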