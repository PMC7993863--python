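"""Training loop, cross-validation, metrics and the ablation harness.

Overall precision/recall/F1 are support-weighted across the four relation
classes, which is the convention under which the per-class scores of an
imbalanced corpus aggregate to a single headline number.  Folds are
stratified so the rarest class (Addiction at ~2.7% of records) appears in
every fold.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.metrics import cohen_kappa_score, confusion_matrix, precision_recall_fscore_support
from sklearn.model_selection import StratifiedKFold

from .autodiff import Adadelta, Adam
from .lexicon import Lexicon
from .locator import DEFAULT_MAX_DIST, EntityAbsentError, MaskedTweet, locate_and_mask
from .model import LABELS, ModelConfig, RelationModel
from .positions import EmbeddingTables
from .synthetic import LabeledTweet

__all__ = [
    "TrainConfig",
    "MetricsReport",
    "Pipeline",
    "TrainResult",
    "CVResult",
    "train",
    "evaluate",
    "cross_validate",
    "compute_metrics",
    "pairwise_kappa",
    "ablate",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class TrainConfig:
    optimizer: str = "adam"
    learning_rate: float = 0.001
    dropout: float = 0.3
    epochs: int = 20
    batch_size: int = 16
    seed: int = 0
    folds: int = 5
    variant: str = "full"
    max_dist: float = DEFAULT_MAX_DIST
    word_dim: int = 24
    position_dim: int = 8

    def __post_init__(self) -> None:
        if self.optimizer not in ("adam", "adadelta"):
            raise ValueError("optimizer must be 'adam' or 'adadelta'")


@dataclass
class MetricsReport:
    """Support-weighted overall P/R/F1 (percent), per-class scores, confusion."""

    precision: float
    recall: float
    f1: float
    per_class: dict[str, dict[str, float]]
    confusion: np.ndarray
    labels: tuple[str, ...] = LABELS

    def to_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "per_class": self.per_class,
            "confusion": self.confusion.tolist(),
            "labels": list(self.labels),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def to_text(self) -> str:
        rows = [f"{'class':<12}{'P':>8}{'R':>8}{'F1':>8}{'support':>9}"]
        for lab in self.labels:
            c = self.per_class[lab]
            rows.append(
                f"{lab:<12}{c['precision']:>8.2f}{c['recall']:>8.2f}"
                f"{c['f1']:>8.2f}{int(c['support']):>9d}"
            )
        rows.append(
            f"{'overall':<12}{self.precision:>8.2f}{self.recall:>8.2f}{self.f1:>8.2f}"
            f"{int(sum(c['support'] for c in self.per_class.values())):>9d}"
        )
        return "\n".join(rows)


def compute_metrics(gold: Sequence[str], predicted: Sequence[str]) -> MetricsReport:
    """Per-class and support-weighted overall precision/recall/F1, in percent."""
    if len(gold) != len(predicted):
        raise ValueError("gold and predicted label sequences differ in length")
    unknown = {l for l in list(gold) + list(predicted) if l not in LABELS}
    if unknown:
        raise ValueError(f"unknown labels: {sorted(unknown)}")
    labels = list(LABELS)
    p, r, f, support = precision_recall_fscore_support(
        gold, predicted, labels=labels, zero_division=0
    )
    weights = support / support.sum()
    per_class = {
        lab: {
            "precision": 100 * p[i],
            "recall": 100 * r[i],
            "f1": 100 * f[i],
            "support": int(support[i]),
        }
        for i, lab in enumerate(labels)
    }
    return MetricsReport(
        precision=float(100 * (p * weights).sum()),
        recall=float(100 * (r * weights).sum()),
        f1=float(100 * (f * weights).sum()),
        per_class=per_class,
        confusion=confusion_matrix(gold, predicted, labels=labels),
    )


@dataclass
class Pipeline:
    """Locator + embedding tables + trained model, applied to raw text."""

    lexicon: Lexicon
    tables: EmbeddingTables
    model: RelationModel
    max_dist: float = DEFAULT_MAX_DIST

    def preprocess(self, text: str) -> MaskedTweet:
        return locate_and_mask(text, self.lexicon, self.max_dist)

    def predict_text(self, text: str) -> tuple[str, np.ndarray]:
        return self.model.predict(self.preprocess(text))

    def predict_records(
        self, records: Sequence[LabeledTweet]
    ) -> tuple[list[str], list[str], list[str]]:
        """Return (gold, predicted, skipped-record ids); records whose
        entities cannot be located are skipped with a warning."""
        gold, pred, skipped = [], [], []
        for rec in records:
            try:
                masked = self.preprocess(rec.text)
            except (EntityAbsentError, ValueError):
                skipped.append(rec.id)
                continue
            gold.append(rec.label)
            pred.append(self.model.predict(masked)[0])
        if skipped:
            warnings.warn(f"{len(skipped)} record(s) failed entity location", stacklevel=2)
        return gold, pred, skipped


@dataclass
class TrainResult:
    pipeline: Pipeline
    loss_trace: list[float]
    excluded: list[str]


def _preprocess_corpus(
    records: Sequence[LabeledTweet], lexicon: Lexicon, max_dist: float
) -> tuple[list[tuple[MaskedTweet, str]], list[str]]:
    prepared, excluded = [], []
    for rec in records:
        try:
            prepared.append((locate_and_mask(rec.text, lexicon, max_dist), rec.label))
        except (EntityAbsentError, ValueError):
            excluded.append(rec.id)
    if excluded:
        warnings.warn(
            f"{len(excluded)} record(s) failed entity location and were excluded",
            stacklevel=2,
        )
    return prepared, excluded


def _build_tables(
    prepared: Iterable[tuple[MaskedTweet, str]], config: TrainConfig
) -> EmbeddingTables:
    vocab: list[str] = []
    seen: set[str] = set()
    for masked, _ in prepared:
        for tok in masked.tokens:
            if tok not in seen:
                seen.add(tok)
                vocab.append(tok)
    return EmbeddingTables.random_init(
        vocab, word_dim=config.word_dim, position_dim=config.position_dim, seed=config.seed
    )


def train(
    corpus: Sequence[LabeledTweet],
    lexicon: Lexicon,
    config: TrainConfig = TrainConfig(),
    model_config: ModelConfig | None = None,
    tables: EmbeddingTables | None = None,
) -> TrainResult:
    """Train one model; deterministic for a fixed config and seed.

    The vocabulary and embedding tables are built from the training records
    unless supplied.  Returns the fitted pipeline plus the per-epoch mean
    cross-entropy trace.
    """
    if model_config is None:
        model_config = ModelConfig.small(variant=config.variant, dropout=config.dropout)
    prepared, excluded = _preprocess_corpus(corpus, lexicon, config.max_dist)
    if not prepared:
        raise ValueError("no trainable records after entity location")
    if tables is None:
        tables = _build_tables(prepared, config)
    model = RelationModel(tables, model_config, seed=config.seed)
    params = model.parameters()
    if config.optimizer == "adam":
        opt = Adam(params, lr=config.learning_rate)
    else:
        opt = Adadelta(params, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)

    trace: list[float] = []
    n = len(prepared)
    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            batch = order[start : start + config.batch_size]
            opt.zero_grad()
            scale = np.ones(()) / len(batch)
            for idx in batch:
                masked, label = prepared[idx]
                loss = model.loss(masked, label, training=True, rng=rng)
                epoch_loss += float(loss.data)
                loss.backward(scale)
            opt.step()
        trace.append(epoch_loss / n)
    return TrainResult(Pipeline(lexicon, tables, model, config.max_dist), trace, excluded)


def evaluate(pipeline: Pipeline, records: Sequence[LabeledTweet]) -> MetricsReport:
    gold, pred, _ = pipeline.predict_records(records)
    return compute_metrics(gold, pred)


@dataclass
class CVResult:
    mean: MetricsReport
    folds: list[MetricsReport]


def _mean_report(reports: Sequence[MetricsReport]) -> MetricsReport:
    per_class = {
        lab: {
            "precision": float(np.mean([r.per_class[lab]["precision"] for r in reports])),
            "recall": float(np.mean([r.per_class[lab]["recall"] for r in reports])),
            "f1": float(np.mean([r.per_class[lab]["f1"] for r in reports])),
            "support": int(sum(r.per_class[lab]["support"] for r in reports)),
        }
        for lab in LABELS
    }
    return MetricsReport(
        precision=float(np.mean([r.precision for r in reports])),
        recall=float(np.mean([r.recall for r in reports])),
        f1=float(np.mean([r.f1 for r in reports])),
        per_class=per_class,
        confusion=np.sum([r.confusion for r in reports], axis=0),
    )


def cross_validate(
    corpus: Sequence[LabeledTweet],
    lexicon: Lexicon,
    config: TrainConfig = TrainConfig(),
    model_config: ModelConfig | None = None,
) -> CVResult:
    """Stratified k-fold cross-validation; reports per-fold and mean metrics."""
    if config.folds < 2:
        raise ValueError("folds must be >= 2")
    labels = [r.label for r in corpus]
    for lab in LABELS:
        count = labels.count(lab)
        if 0 < count < config.folds:
            raise ValueError(
                f"class {lab!r} has only {count} record(s), fewer than folds={config.folds}"
            )
    present = [lab for lab in LABELS if lab in labels]
    if not present:
        raise ValueError("corpus is empty")
    skf = StratifiedKFold(n_splits=config.folds, shuffle=True, random_state=config.seed)
    reports = []
    corpus = list(corpus)
    y = np.asarray(labels)
    for train_idx, test_idx in skf.split(np.zeros(len(corpus)), y):
        result = train([corpus[i] for i in train_idx], lexicon, config, model_config)
        reports.append(evaluate(result.pipeline, [corpus[i] for i in test_idx]))
    return CVResult(_mean_report(reports), reports)


def pairwise_kappa(annotations: Sequence[Sequence[object]] | np.ndarray) -> tuple[np.ndarray, float]:
    """Cohen's kappa for every annotator pair of a records × annotators table.

    Returns the symmetric kappa matrix (diagonal 1) and the mean over the
    distinct pairs.  A pair in which either annotator is perfectly constant
    has no chance-corrected agreement; its kappa is reported as NaN and
    propagates to the mean.
    """
    table = np.asarray(annotations, dtype=object)
    if table.ndim != 2 or table.shape[1] < 2:
        raise ValueError("need a records x annotators table with >= 2 annotators")
    n_ann = table.shape[1]
    K = np.full((n_ann, n_ann), np.nan)
    np.fill_diagonal(K, 1.0)
    pair_values = []
    for i in range(n_ann):
        for j in range(i + 1, n_ann):
            a, b = table[:, i], table[:, j]
            if len(set(a)) == 1 and len(set(b)) == 1:
                k = np.nan  # chance agreement undefined for constant codings
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    k = float(cohen_kappa_score(a.astype(str), b.astype(str)))
            K[i, j] = K[j, i] = k
            pair_values.append(k)
    return K, float(np.mean(pair_values))


DEFAULT_ABLATION_VARIANTS: tuple[str, ...] = (
    "full",
    "no_context",
    "no_position_attention",
    "no_position_embedding",
    "no_cnn",
    "vanilla_attention",
    "concat_fusion",
)


def ablate(
    corpus: Sequence[LabeledTweet],
    lexicon: Lexicon,
    config: TrainConfig = TrainConfig(),
    variants: Sequence[str] = DEFAULT_ABLATION_VARIANTS,
) -> dict[str, CVResult]:
    """Cross-validate each architecture variant under identical folds and seeds."""
    return {
        v: cross_validate(corpus, lexicon, replace(config, variant=v)) for v in variants
    }


# -- checkpointing ---------------------------------------------------------


def save_model(pipeline: Pipeline, path: str | Path) -> None:
    """Single-file parameter bundle (npz) with a JSON config sidecar."""
    path = Path(path)
    if path.suffix != ".npz":
        path = Path(str(path) + ".npz")
    model = pipeline.model
    arrays = {f"param_{i}": p.data for i, p in enumerate(model.parameters())}
    arrays["word_table"] = pipeline.tables.word_table
    arrays["position_table"] = pipeline.tables.position_table
    np.savez(path, **arrays)
    cfg = model.config
    sidecar = {
        "variant": cfg.variant,
        "attention_dim": cfg.attention_dim,
        "fusion_dim": cfg.fusion_dim,
        "dropout": cfg.dropout,
        "conv": {
            "window_sizes": list(cfg.conv.window_sizes),
            "features_per_window": cfg.conv.features_per_window,
        },
        "encoder": {
            "n_layers": cfg.encoder.n_layers,
            "n_heads": cfg.encoder.n_heads,
            "hidden": cfg.encoder.hidden,
            "layer_used": cfg.encoder.layer_used,
            "special_token_masking": cfg.encoder.special_token_masking,
            "pooling": cfg.encoder.pooling,
            "max_len": cfg.encoder.max_len,
            "vocab_buckets": cfg.encoder.vocab_buckets,
        },
        "max_dist": pipeline.max_dist,
        "clip": pipeline.tables.clip,
        "oov_mode": pipeline.tables.oov_mode,
        "vocab": sorted(pipeline.tables.vocab, key=pipeline.tables.vocab.get),
        "lexicon": [
            {"surface": e.surface, "concept": e.concept, "category": e.category.value}
            for e in pipeline.lexicon
        ],
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar), encoding="utf-8")


def load_model(path: str | Path) -> Pipeline:
    from .lexicon import Category, Lexicon, LexiconEntry
    from .model import ContextEncoderSpec, ConvConfig

    path = Path(path)
    npz_path = path if path.suffix == ".npz" else Path(str(path) + ".npz")
    if not npz_path.exists():
        npz_path = path
    sidecar = json.loads(Path(str(npz_path) + ".json").read_text(encoding="utf-8"))
    data = np.load(npz_path)
    tables = EmbeddingTables(
        word_table=data["word_table"],
        vocab={t: i for i, t in enumerate(sidecar["vocab"])},
        position_table=data["position_table"],
        clip=sidecar["clip"],
        oov_mode=sidecar["oov_mode"],
    )
    cfg = ModelConfig(
        conv=ConvConfig(
            window_sizes=tuple(sidecar["conv"]["window_sizes"]),
            features_per_window=sidecar["conv"]["features_per_window"],
        ),
        attention_dim=sidecar["attention_dim"],
        encoder=ContextEncoderSpec(**sidecar["encoder"]),
        fusion_dim=sidecar["fusion_dim"],
        dropout=sidecar["dropout"],
        variant=sidecar["variant"],
    )
    model = RelationModel(tables, cfg, seed=0)
    for i, p in enumerate(model.parameters()):
        p.data[...] = data[f"param_{i}"]
    lexicon = Lexicon(
        tuple(
            LexiconEntry(e["surface"], e["concept"], Category(e["category"]))
            for e in sidecar["lexicon"]
        )
    )
    return Pipeline(lexicon, tables, model, sidecar["max_dist"])
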