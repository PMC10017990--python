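"""Supervised fine-tuning: a pooled softmax head on top of the encoder.

The encoder may start from pre-trained weights (transferring the seasonal
structure learned from unlabeled data) or from a seeded random
initialization; the classification head is always newly initialized.
Hidden states are summarized by a mean over valid timesteps and mapped to
class logits by a single affine layer.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import nn
from .data import (
    Batch,
    SampleSet,
    SpectralSequence,
    ValidationError,
    bucketed_batch_order,
    pad_batch,
)
from .encoder import (
    CropformerEncoder,
    EncoderWeights,
    ModelConfig,
    load_checkpoint,
    save_checkpoint,
)
from .nn import Tensor

__all__ = ["FinetuneConfig", "Classifier", "pool", "finetune",
           "save_classifier", "load_classifier", "SMALL_FINETUNE"]

POOLING_MODES = ("mean_valid", "last_valid")


@dataclass(frozen=True)
class FinetuneConfig:
    """Optimization settings for the supervised stage (full-size defaults:
    10 epochs, batch 256, Adam at 1e-5)."""

    epochs: int = 10
    batch_size: int = 256
    learning_rate: float = 1e-5
    dropout: float = 0.1
    seed: int = 0
    freeze_encoder: bool = False


#: Desk-scale supervised recipe matching the small model profile.
SMALL_FINETUNE = FinetuneConfig(epochs=30, batch_size=32, learning_rate=1e-3)


def pool(hidden: Tensor, valid_mask: np.ndarray, mode: str = "mean_valid") -> Tensor:
    """Summarize per-timestep hidden states into one vector per sample.

    ``mean_valid`` averages over valid positions; ``last_valid`` takes the
    hidden state at each sample's final observation.  Padded positions
    never contribute.
    """
    if mode not in POOLING_MODES:
        raise ValidationError(f"unknown pooling mode {mode!r}")
    counts = valid_mask.sum(axis=1)
    if np.any(counts < 1):
        raise ValidationError("a sample has no valid positions to pool over")
    if mode == "last_valid":
        last = counts - 1
        return hidden[np.arange(hidden.shape[0]), last, :]
    m = Tensor(valid_mask[:, :, None].astype(float))
    return (hidden * m).sum(axis=1) * Tensor((1.0 / counts)[:, None])


def _log_softmax(logits: Tensor) -> Tensor:
    shift = Tensor(logits.data.max(axis=-1, keepdims=True))
    z = logits - shift
    lse = z.exp().sum(axis=-1, keepdims=True).log()
    return z - lse


def _cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    logp = _log_softmax(logits)
    picked = logp[np.arange(len(labels)), labels]
    return -picked.mean()


class Classifier:
    """A trained encoder plus affine classification head."""

    def __init__(self, encoder_weights: EncoderWeights, head: nn.Linear,
                 classes: Sequence[str], pooling: str = "mean_valid"):
        if len(classes) == 0:
            raise ValidationError("class vocabulary is empty")
        if head.weight.shape[1] != len(classes):
            raise ValidationError("head width does not match class count")
        if pooling not in POOLING_MODES:
            raise ValidationError(f"unknown pooling mode {pooling!r}")
        self.encoder_weights = encoder_weights
        self.head = head
        self.classes = list(classes)
        self.pooling = pooling
        self._encoder = encoder_weights.build()
        self._encoder.eval()
        self.head.eval()

    @property
    def config(self) -> ModelConfig:
        return self.encoder_weights.config

    def _forward(self, batch: Batch) -> Tensor:
        hidden = self._encoder(batch)
        return self.head(pool(hidden, batch.valid_mask, self.pooling))

    def predict_proba(self, samples: Sequence[SpectralSequence] | SampleSet | Batch,
                      batch_size: int = 512) -> np.ndarray:
        """Class-probability matrix (n x n_classes); rows sum to one."""
        if isinstance(samples, Batch):
            batches = [samples]
        else:
            seqs = samples.samples if isinstance(samples, SampleSet) else list(samples)
            batches = [pad_batch(seqs[i : i + batch_size])
                       for i in range(0, len(seqs), batch_size)]
        out = []
        for b in batches:
            if b.spectra.shape[2] != self.config.n_bands:
                raise ValidationError("band count does not match the classifier")
            logits = self._forward(b)
            out.append(np.exp(_log_softmax(logits).data))
        return np.concatenate(out, axis=0)

    def predict(self, samples) -> list[str]:
        proba = self.predict_proba(samples)
        return [self.classes[i] for i in proba.argmax(axis=1)]


def _iter_batches(samples: list[SpectralSequence], labels: np.ndarray,
                  batch_size: int, rng: np.random.Generator):
    lengths = np.array([s.t for s in samples])
    for idx in bucketed_batch_order(lengths, batch_size, rng):
        yield pad_batch([samples[i] for i in idx], labels=labels[idx])


def _accuracy(encoder, head, pooling, sample_set: SampleSet) -> float:
    batch = pad_batch(sample_set.samples)
    hidden = encoder(batch)
    logits = head(pool(hidden, batch.valid_mask, pooling))
    pred = logits.data.argmax(axis=1)
    return float((pred == sample_set.class_indices()).mean())


def finetune(pretrained: Optional[EncoderWeights], train: SampleSet,
             val: SampleSet, model_config: ModelConfig,
             config: FinetuneConfig, pooling: str = "mean_valid") -> Classifier:
    """Train a classifier, warm-starting the encoder when weights are given.

    Minimizes cross-entropy; the weights with the best validation overall
    accuracy across epochs are returned (ties resolve to the earlier epoch).
    """
    if train.role != "train":
        raise ValidationError("finetune expects a SampleSet with role='train'")
    if any(s.label is None for s in train.samples):
        raise ValidationError("all training samples must be labeled")
    for s in val.samples:
        if s.label is not None and s.label not in train.classes:
            raise ValidationError(f"validation label {s.label!r} missing from "
                                  "the training vocabulary")
    # dropout is a per-stage training setting, not part of the architecture
    if pretrained is not None and (
        replace(pretrained.config, dropout=0.0) != replace(model_config, dropout=0.0)
    ):
        raise ValidationError("pre-trained weights were built with a different "
                              "model configuration")

    seed_seq = np.random.SeedSequence(config.seed)
    init_rng, order_rng, drop_rng = [np.random.default_rng(s) for s in seed_seq.spawn(3)]

    mc = replace(model_config, dropout=config.dropout)
    encoder = CropformerEncoder(mc, init_rng)
    if pretrained is not None:
        encoder.load_state_dict(pretrained.state)
    head = nn.Linear(mc.d_model, len(train.classes), init_rng)
    encoder.seed_dropout(drop_rng)

    params = head.parameters() if config.freeze_encoder \
        else encoder.parameters() + head.parameters()
    opt = nn.Adam(params, lr=config.learning_rate)

    labels = train.class_indices()
    classes = list(train.classes)
    best_state = (encoder.state_dict(), head.state_dict())
    best_acc = -1.0

    for _ in range(config.epochs):
        encoder.train()
        head.train()
        if config.freeze_encoder:
            encoder.eval()   # keep normalization statistics frozen too
        for batch in _iter_batches(train.samples, labels, config.batch_size, order_rng):
            logits = head(pool(encoder(batch), batch.valid_mask, pooling))
            loss = _cross_entropy(logits, batch.labels)
            opt.zero_grad()
            loss.backward()
            opt.step()
        encoder.eval()
        head.eval()
        acc = _accuracy(encoder, head, pooling, val)
        if acc > best_acc:
            best_acc = acc
            best_state = (encoder.state_dict(), head.state_dict())

    encoder.load_state_dict(best_state[0])
    head.load_state_dict(best_state[1])
    weights = EncoderWeights(state=best_state[0], config=mc)
    return Classifier(weights, head, classes, pooling)


def save_classifier(clf: Classifier, path: str | Path) -> None:
    """Persist encoder + head parameters with class vocabulary metadata."""
    head_state = {f"head.{k}": v for k, v in clf.head.state_dict().items()}
    save_checkpoint(clf.encoder_weights, path,
                    extra_state=head_state,
                    extra_meta={"classes": clf.classes, "pooling": clf.pooling})


def load_classifier(path: str | Path) -> Classifier:
    weights, extra, meta = load_checkpoint(path)
    head = nn.Linear(weights.config.d_model, len(meta["classes"]),
                     np.random.default_rng(0))
    head.load_state_dict({k[len("head."):]: v for k, v in extra.items()
                          if k.startswith("head.")})
    return Classifier(weights, head, meta["classes"], meta["pooling"])
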