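# cropformer

Crop-type classification of **irregular multispectral satellite time
series** with a Transformer–convolution hybrid encoder and masked
self-supervised pre-training.

## The problem

Optical satellites revisit a field every few days, but cloudy acquisitions
are discarded, so each field's season is an *irregular* series: its own
number and spacing of observation days. A sample is

- days-of-year $t_1 < t_2 < \dots < t_T$ (the surviving acquisitions), and
- reflectances $s_{t_i} \in [0,1]^B$ over $B$ spectral bands at each day,

and the task is to predict the field's crop class. Labels are expensive
(field surveys), while unlabeled series are abundant — so the package
pre-trains on unlabeled data and fine-tunes on few labels.

## The model

Each timestep is embedded as the concatenation of a sinusoidal
**position embedding** of the calendar day,
$PE(t, 2k) = \sin\!\big(t / \beta^{2k/d_\text{time}}\big)$,
$PE(t, 2k{+}1) = \cos\!\big(t / \beta^{2k/d_\text{time}}\big)$,
and an affine **token embedding** of the band vector. A stack of encoder
blocks with three residual stages follows:

$$\tilde{x} = x + \mathrm{LN}(\mathrm{MHA}(x)), \qquad
x' = \tilde{x} + \mathrm{CM}(\tilde{x}), \qquad
y = x' + \mathrm{LN}(\mathrm{FFN}(x'))$$

where MHA is masked multi-head self-attention (global, whole-season
dependencies) and CM is a convolution module of depthwise-separable
temporal convolutions with internal shortcuts (local growth-stage
features). Padded positions receive exactly-zero attention weight and are
excluded from convolution and normalization statistics.

**Pre-training** hides `round(0.15·T)` timesteps of each unlabeled
sequence and regresses their original reflectances (MSE over masked
values); **fine-tuning** pools hidden states over valid timesteps and
trains a softmax head with cross-entropy, warm-started from the
pre-trained encoder. See [docs/methods.md](docs/methods.md) for the full
method description and parameter tables.

No deep-learning framework is required: the package ships a small
NumPy reverse-mode autodiff engine (`cropformer.nn`) whose gradients are
verified against finite differences in the test suite.

## Worked example

### Library

```python
import numpy as np
import cropformer as cf

# a labeled sample: 5 cloud-free acquisitions over 4 bands
seq = cf.SpectralSequence(
    sample_id="field-001",
    doy=np.array([92, 108, 140, 180, 240]),
    spectra=np.array([[0.06, 0.08, 0.12, 0.22],
                      [0.05, 0.08, 0.09, 0.35],
                      [0.04, 0.07, 0.05, 0.55],
                      [0.04, 0.07, 0.04, 0.57],
                      [0.06, 0.08, 0.11, 0.25]]),
    label="early_cereal",
)
print("length:", seq.t, "bands:", seq.n_bands)
print("flat input size:", cf.input_shape(seq.t, seq.n_bands))

pe = cf.position_encode(seq.doy, d_time=16)
print("position embedding shape:", pe.shape)
print("pe[0, :4]:", np.round(pe[0, :4], 4))
```

prints

```
length: 5 bands: 4
flat input size: 25
position embedding shape: (5, 16)
pe[0, :4]: [-0.7795 -0.6264 -0.7302 -0.6832]
```

### Command line

The shipped desk-scale config runs the full pipeline — simulate a 4-class
synthetic benchmark (250 labeled samples per class, 2000 unlabeled),
pre-train, fine-tune, evaluate — in a few minutes on one CPU:

```
cropformer simulate --config configs/small.yaml --out-dir runs/data
cropformer pretrain --unlabeled runs/data/unlabeled.csv \
    --config configs/small.yaml --out runs/encoder.npz
cropformer finetune --train runs/data/train.csv --val runs/data/val.csv \
    --pretrained runs/encoder.npz --config configs/small.yaml \
    --out runs/classifier.npz
cropformer evaluate --classifier runs/classifier.npz \
    --test runs/data/test.csv --out runs/metrics.json
```

prints

```
wrote 600/200/200 labeled and 2000 unlabeled samples to runs/data
pre-trained 60 epochs; final loss 0.000602
trained classifier over 4 classes -> runs/classifier.npz
OA 1.0000  AA 1.0000
```

The final masked-reconstruction loss (0.000602) is about 0.21× the
mean-predictor baseline (0.00285 — the per-band variance of the data), so
the encoder has learned seasonal structure, and the full-season benchmark
saturates (OA 1.0; by construction its classes are separable — the
informative regimes are below). A label-scarce scenario on the same
tables, three repeats of 10 training labels per class:

```
cropformer scenario --type few_sample --config configs/small.yaml \
    --out runs/few.json \
    --set paths.train=runs/data/train.csv \
    --set paths.val=runs/data/val.csv \
    --set paths.test=runs/data/test.csv \
    --set scenario.n_repeats=3 --set scenario.few_value=0.0667
```

prints

```
few_sample: OA 0.5883  AA 0.5883
```

for a randomly initialized encoder — versus **0.88** when the same
fine-tuning starts from the pre-trained encoder (see below), which is the
package's central effect.

Every command writes a JSON manifest (config echo, derived seeds, output
checksums) beside its artifacts; the same config and `master_seed`
reproduce every file bit-identically.

## Package layout

| module | contents |
|---|---|
| `cropformer.data` | `SpectralSequence`, `SampleSet`, batching, CSV round trips |
| `cropformer.encoder` | position encoding, attention, convolution module, encoder, checkpoints |
| `cropformer.pretraining` | masking, masked-MSE loss, `pretrain`, mean-predictor baseline |
| `cropformer.classification` | pooling, `finetune`, `Classifier`, persistence |
| `cropformer.evaluation` | OA/AA/F1, confusion matrices, the four scenario kinds |
| `cropformer.simulate` | double-logistic phenology generator, presets, splits |
| `cropformer.config` / `cropformer.cli` | YAML schema, seed derivation, manifests, CLI |
| `cropformer.nn` | the NumPy autodiff engine and layers |
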