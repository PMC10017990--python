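"""Self-supervised masked-value pre-training.

A fraction of each sequence's timesteps is corrupted and the network is
trained to regress the original reflectances at exactly those positions,
minimizing mean squared error over the masked scalar values.  Only
unlabeled data enters this stage; the learned encoder parameters are the
prior handed to supervised fine-tuning.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

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
from .encoder import CropformerEncoder, EncoderWeights, ModelConfig
from .nn import Tensor

__all__ = ["PretrainConfig", "MaskResult", "mask_sequence", "pretrain_loss",
           "pretrain", "mean_predictor_mse", "SMALL_PRETRAIN"]

MASK_STRATEGIES = ("random_value", "zero", "noise")


@dataclass(frozen=True)
class PretrainConfig:
    """Masking and optimization settings for the self-supervised stage.

    Training defaults are the full-size recipe (200 epochs, batch 512,
    Adam at 1e-4 decayed every 10 epochs); the masking defaults follow the
    masked-language-model convention of hiding 15% of positions.
    """

    mask_ratio: float = 0.15
    mask_strategy: str = "random_value"
    noise_sd: float = 0.1          # for the 'noise' strategy
    epochs: int = 200
    batch_size: int = 512
    learning_rate: float = 1e-4
    lr_decay_epoch: int = 10
    lr_decay_factor: float = 0.9
    dropout: float = 0.1
    optimizer: str = "adam"
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.mask_ratio <= 1.0:
            raise ValidationError("mask_ratio must be in (0, 1]")
        if self.mask_strategy not in MASK_STRATEGIES:
            raise ValidationError(f"unknown mask strategy {self.mask_strategy!r}")
        if self.optimizer != "adam":
            raise ValidationError("only the adam optimizer is supported")


@dataclass(frozen=True)
class MaskResult:
    """A corrupted sequence plus everything needed to score reconstruction."""

    corrupted: SpectralSequence
    masked_index: tuple[int, ...]       # timestep indices, sorted
    targets: np.ndarray                 # (|masked_index|, B) original spectra
    n_masked: int                       # count of masked scalar values

    def __post_init__(self):
        object.__setattr__(self, "masked_index", tuple(sorted(self.masked_index)))


#: Desk-scale training recipe for CPU runs on a few thousand sequences:
#: fewer epochs at a larger learning rate than the full-size defaults.
SMALL_PRETRAIN = PretrainConfig(epochs=60, batch_size=64, learning_rate=3e-3,
                                lr_decay_epoch=15, lr_decay_factor=0.85)


def mask_sequence(sample: SpectralSequence, config: PretrainConfig,
                  rng: np.random.Generator,
                  value_pool: Optional[np.ndarray] = None) -> MaskResult:
    """Corrupt ``round(mask_ratio * T)`` timesteps (at least one).

    ``random_value`` replaces masked spectra with draws from the empirical
    per-band distribution of ``value_pool`` (any (M, B) matrix of observed
    reflectances; defaults to the sample's own rows), ``zero`` blanks them,
    and ``noise`` adds Gaussian noise of sd ``noise_sd``.  DOY stamps are
    never altered and the input sample is never mutated.
    """
    T, B = sample.spectra.shape
    n_mask = max(1, int(round(config.mask_ratio * T)))
    n_mask = min(n_mask, T)
    idx = np.sort(rng.choice(T, size=n_mask, replace=False))
    targets = sample.spectra[idx].copy()

    corrupted = sample.spectra.copy()
    if config.mask_strategy == "random_value":
        pool = sample.spectra if value_pool is None else np.asarray(value_pool)
        rows = rng.integers(0, pool.shape[0], size=(n_mask, B))
        corrupted[idx] = pool[rows, np.arange(B)]
    elif config.mask_strategy == "zero":
        corrupted[idx] = 0.0
    else:  # noise
        corrupted[idx] = targets + rng.normal(0.0, config.noise_sd, size=targets.shape)

    return MaskResult(
        corrupted=replace(sample, spectra=corrupted),
        masked_index=tuple(int(i) for i in idx),
        targets=targets,
        n_masked=int(n_mask * B),
    )


def pretrain_loss(predicted, targets) -> Tensor:
    """Mean squared error over all masked scalar values.

    The denominator is the count of masked scalars (timesteps x bands).
    Accepts autodiff tensors or plain arrays; returns a scalar tensor.
    """
    p = predicted if isinstance(predicted, Tensor) else Tensor(np.asarray(predicted))
    t = targets if isinstance(targets, Tensor) else Tensor(np.asarray(targets))
    if p.shape != t.shape:
        raise ValidationError(f"shape mismatch: {p.shape} vs {t.shape}")
    d = p - t
    return (d * d).mean()


class ReconstructionHead(nn.Module):
    """Affine map from hidden states back to band reflectances; used only
    during pre-training and discarded afterwards."""

    def __init__(self, d_model: int, n_bands: int, rng: np.random.Generator):
        super().__init__()
        self.proj = nn.Linear(d_model, n_bands, rng)

    def __call__(self, h: Tensor) -> Tensor:
        return self.proj(h)


def _masked_batch(samples: list[SpectralSequence], config: PretrainConfig,
                  rng: np.random.Generator) -> tuple[Batch, np.ndarray, np.ndarray]:
    """Corrupt a list of samples and pad them into a batch.

    Returns (batch, masked position matrix (n, T_max) bool, target matrix
    (total_masked_timesteps, B) in row-major batch order).
    """
    pool = np.concatenate([s.spectra for s in samples], axis=0)
    results = [mask_sequence(s, config, rng, value_pool=pool) for s in samples]
    batch = pad_batch([r.corrupted for r in results])
    mask_pos = np.zeros((batch.n, batch.t_max), dtype=bool)
    for i, r in enumerate(results):
        mask_pos[i, list(r.masked_index)] = True
    targets = np.concatenate([r.targets for r in results], axis=0)
    return batch, mask_pos, targets


def pretrain(unlabeled: SampleSet, model_config: ModelConfig,
             config: PretrainConfig) -> tuple[EncoderWeights, list[float]]:
    """Train the encoder on unlabeled sequences by masked-value regression.

    Returns the encoder weights (the reconstruction head is dropped) and
    the per-epoch mean training loss.  Fully reproducible given the seed.
    """
    if unlabeled.role != "unlabeled":
        raise ValidationError("pre-training requires a SampleSet with role='unlabeled'")
    if len(unlabeled) == 0:
        raise ValidationError("pre-training set is empty")

    seed_seq = np.random.SeedSequence(config.seed)
    init_rng, mask_rng, order_rng, drop_rng = [
        np.random.default_rng(s) for s in seed_seq.spawn(4)
    ]

    mc = replace(model_config, dropout=config.dropout)
    encoder = CropformerEncoder(mc, init_rng)
    head = ReconstructionHead(mc.d_model, mc.n_bands, init_rng)
    encoder.seed_dropout(drop_rng)
    encoder.train()
    head.train()

    opt = nn.Adam(encoder.parameters() + head.parameters(), lr=config.learning_rate)
    history: list[float] = []
    n = len(unlabeled)

    for epoch in range(config.epochs):
        if epoch > 0 and epoch % config.lr_decay_epoch == 0:
            opt.lr *= config.lr_decay_factor
        lengths = np.array([s.t for s in unlabeled.samples])
        losses, weights = [], []
        for idx in bucketed_batch_order(lengths, config.batch_size, order_rng):
            chunk = [unlabeled.samples[i] for i in idx]
            batch, mask_pos, targets = _masked_batch(chunk, config, mask_rng)
            hidden = encoder(batch)
            pred = head(hidden)[mask_pos]          # (masked timesteps, B)
            loss = pretrain_loss(pred, targets)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            weights.append(targets.size)
        history.append(float(np.average(losses, weights=weights)))

    return EncoderWeights.from_encoder(encoder), history


def mean_predictor_mse(samples: SampleSet) -> float:
    """MSE of the constant per-band-mean predictor over all observations.

    This is the per-band variance of the data, averaged over bands — the
    floor any context-using reconstruction must beat to show it has learned
    seasonal structure rather than the marginal distribution.
    """
    stacked = np.concatenate([s.spectra for s in samples.samples], axis=0)
    return float(stacked.var(axis=0).mean())
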