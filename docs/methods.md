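# Methods

This note records the model, its parameters, what the synthetic data
generator does and does not emulate, the numerical choices behind the
implementation, and the package's known limitations.

## Problem setting

A sample is one field's growing season observed by an optical satellite: a
sequence of acquisition days-of-year (DOY) $t_1 < \dots < t_T$ and, at each
day, reflectances $s_t \in [0,1]^B$ over $B$ spectral bands (default
blue/green/red/NIR). Cloudy acquisitions are discarded, so both the number
and the spacing of observations differ per sample — the series is
*irregular*. The task is to predict the field's crop class; a large pool of
unlabeled series is typically available alongside a small labeled set.

## Model

### Embedding

Each timestep is embedded as the concatenation of a temporal and a
spectral part, giving $d_\text{model} = d_\text{time} + d_\text{spec}$
channels:

- **Token embedding** — an affine map $\mathbb{R}^B \to
  \mathbb{R}^{d_\text{spec}}$ shared over timesteps.
- **Position embedding** — a parameter-free sinusoid of the calendar day:
  $PE(t, 2k) = \sin(t / \beta^{2k/d_\text{time}})$,
  $PE(t, 2k+1) = \cos(t / \beta^{2k/d_\text{time}})$ with base
  $\beta = 10^4$ by default (configurable via `pe_base`). Using the
  absolute DOY rather than the sequence index lets the model align spectra
  to growth stage even when dates are missing.

The flattened input size of a series is therefore
$T \cdot B + T$ scalars (spectra plus one DOY per acquisition), exposed as
`input_shape(t_num, band_num)`.

### Encoder blocks

The encoder stacks $N$ identical blocks, each with three residual stages:

```
x1 = x  + LN(MHA(x))        # global, whole-season dependencies
x2 = x1 + CM(x1)            # local, growth-stage features
y  = x2 + LN(FFN(x2))       # position-wise mixing
```

- **MHA** — multi-head scaled dot-product self-attention. Padded keys
  receive logit $-10^{30}$, which underflows to an exactly-zero attention
  weight after the stable softmax, so padding cannot leak into valid
  positions.
- **CM (convolution module)** — `LayerNorm` followed by $n$ **crop
  residual** (CR) units and dropout. Each CR unit is a depthwise-separable
  temporal convolution with its own internal shortcut:
  `u + PW2(BN(Swish(DW(GLU(PW1(u))))))`, where DW is a depthwise
  convolution over time (kernel 7, zero-padded to preserve length) and
  PW1/PW2 are pointwise maps. Padded positions are zeroed before and
  after DW, and the batch norm computes statistics over valid positions
  only (`MaskedBatchNorm`), so convolution arithmetic also never mixes
  padding into results.
- **FFN** — two affine maps with a Swish nonlinearity, width
  $d_\text{ffn}$.

### Pooling and head

For classification, hidden states are averaged over valid timesteps
(`mean_valid`; `last_valid` is also available) and mapped to class logits
by one affine layer trained with cross-entropy.

## Training stages

### Masked pre-training

`round(0.15·T)` timesteps (at least one) of each unlabeled sequence are
corrupted — by default replaced with draws from the batch's empirical
per-band value pool (`random_value`; `zero` and additive `noise` variants
exist) — and a temporary affine reconstruction head regresses the original
reflectances. The loss is the mean squared error over masked scalar values
only. The reconstruction head is discarded; the encoder weights seed
fine-tuning. The natural baseline is the constant per-band-mean predictor,
whose MSE equals the per-band variance of the data
(`mean_predictor_mse`); a model that has learned seasonal structure must
land well below it.

### Fine-tuning

Cross-entropy on the labeled training set, with the encoder warm-started
from pre-training (or freshly initialized), a new head, and best-epoch
selection by validation overall accuracy (ties keep the earlier epoch).
`freeze_encoder` restricts updates to the head and freezes normalization
statistics.

## Parameters

### Architecture (`ModelConfig`)

| parameter | full | small | meaning |
|---|---|---|---|
| `d_spec` | 128 | 16 | token-embedding width (channels) |
| `d_time` | 128 | 16 | position-embedding width (channels, even) |
| `n_blocks` | 3 | 1 | encoder blocks |
| `n_heads` | 8 | 4 | attention heads (divides `d_model`) |
| `d_ffn` | 1024 | 64 | feed-forward width |
| `kernel_size` | 7 | 7 | depthwise conv width (days of context ≈ 7 revisit steps) |
| `n_crop_residual` | 2 | 2 | CR units per convolution module |
| `dropout` | 0.1 | 0.1 | dropout rate during training |
| `pe_base` | 10000 | 10000 | sinusoid frequency base |

The **small profile** (`SMALL_PROFILE`, `d_model` 32) is this package's
own desk-scale choice: it keeps every architectural mechanism (attention,
CR units, residual structure) while training in seconds-to-minutes on one
CPU. The full profile is provided for completeness.

### Training recipes

| stage | full | small (`SMALL_PRETRAIN` / `SMALL_FINETUNE`) |
|---|---|---|
| pre-train epochs / batch / lr | 200 / 512 / 1e-4 | 60 / 64 / 3e-3 |
| pre-train lr decay | ×0.9 every 10 epochs | ×0.85 every 15 epochs |
| mask ratio | 0.15 | 0.15 |
| fine-tune epochs / batch / lr | 10 / 256 / 1e-5 | 30 / 32 / 1e-3 |
| optimizer | Adam | Adam |

The small recipes were fixed by convergence runs on the default benchmark
before any evaluation thresholds were examined: 60 epochs brings the
masked MSE to roughly 0.2× the mean-predictor baseline, after which
returns diminish.

## Synthetic data generator

### What it emulates

- **Phenology** — each class follows a double-logistic vegetation-index
  curve, the canonical single-season crop model:
  $v(t) = v_\min + (v_\max - v_\min)\,[\sigma(r_\text{up}(t -
  t_\text{sos})) - \sigma(r_\text{down}(t - t_\text{eos}))]$, flat outside
  the season and peaking mid-season. Classes differ in season timing
  (`sos`/`eos`), slopes, and amplitude.
- **Spectral coupling** — bands are affine in the index, clipped to
  $[0,1]$: visible bands darken and NIR brightens as the canopy closes, so
  the implied NDVI rises with growth.
- **Irregular sampling** — a 4-day revisit grid over days 60–270 is
  thinned by independent per-date Bernoulli cloud loss ($p_\text{obs} =
  0.7$), redrawn until at least 8 dates survive; i.i.d. Gaussian noise
  (sd 0.015) is added and values re-clipped.
- **Class structure** — a balanced 4-class benchmark (early cereal, late
  maize, low-amplitude legume, long flat perennial) of 250 labeled samples
  per class plus 2000 unlabeled draws from the same mixture, and an
  imbalanced 8-class preset (counts 500 down to 15) mimicking real survey
  skew.

These defaults are the package's fixed study conditions; evaluations are
run under them rather than treating them as free dials.

### What it does not emulate

- No spatial structure: no pixel adjacency, parcel shapes, or
  geographic autocorrelation.
- Cloud loss is independent per date; real cloud outages are correlated
  over days and across a scene.
- No atmospheric, illumination, or sensor-calibration effects; noise is
  i.i.d. Gaussian.
- No within-class phenology variation beyond observation noise (every
  sample of a class shares one curve); no mixed pixels, no double
  cropping.

Consequently the benchmark is *easier* than real imagery — a
nearest-centroid oracle on noiseless curves reaches OA 1.0 — and absolute
accuracies here should not be compared with field studies. The benchmark's
job is to make relative claims (pre-training benefit, in-season
degradation, transfer loss) measurable and reproducible.

## Numerical choices

- **Autodiff engine** — the package ships its own small reverse-mode
  engine over NumPy (`cropformer.nn`): a `Tensor` graph with topological
  backward, and fused primitives (softmax, layer norm, depthwise temporal
  convolution) with hand-derived gradients, all verified against central
  finite differences in the test suite.
- **Precision** — training runs in float32 (the global default;
  `set_default_dtype` switches the engine), which roughly halves memory
  traffic; oracle-equality tests run in float64.
- **Masked softmax** — masked logits are set to $-10^{30}$, giving
  exactly-zero weights after max-shifted exponentiation (no renormalizing
  epsilon needed).
- **Batching** — variable-length sequences are right-padded per batch;
  batches are formed by shuffling, stably sorting by length, and
  shuffling batch order (`bucketed_batch_order`), which minimizes padding
  without biasing batch composition.
- **Seeds** — every stochastic stage draws from
  `numpy.random.SeedSequence` spawns of a single seed; the CLI derives
  stage seeds from one `master_seed` by fixed offsets, all below $2^{31}$.
- **Checkpoints** — weights as `.npz` plus a JSON sidecar holding the
  architecture and metadata; round trips are bit-exact.

## Limitations

- The generator's optimism (above) means absolute metrics saturate near
  1.0 on the full-season balanced benchmark; the informative regimes are
  few-label, early-cutoff, and transfer.
- The engine is CPU-only and single-threaded beyond BLAS; the full
  profile is impractical without hours of compute.
- `last_valid` pooling and the `zero`/`noise` masking variants are
  implemented and tested but not exercised by the shipped configurations.
- Transfer experiments shift phenology parameters of the same generative
  family; distribution shift in real cross-region transfer is richer
  (different class sets, sensors, and practices).
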