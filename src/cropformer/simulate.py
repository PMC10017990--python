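"""Synthetic crop phenology generator.

Emulates the statistical structure the classifier assumes: each crop class
follows a class-specific double-logistic seasonal vegetation-index curve,
mapped linearly to four reflectance bands (blue, green, red, near-infrared)
with a coupling that makes NDVI increase with canopy development.  Samples
are observed on a 4-day revisit grid thinned by independent per-date cloud
loss, so every sample has its own irregular set of acquisition days, and
Gaussian observation noise is added.  Class imbalance is supported through
per-class counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .data import SampleSet, SpectralSequence, ValidationError

__all__ = [
    "CropClassSpec",
    "SimConfig",
    "double_logistic",
    "index_to_bands",
    "sample_doys",
    "simulate",
    "train_val_test_split",
    "default_four_classes",
    "imbalanced_eight_classes",
]

BAND_NAMES = ["blue", "green", "red", "nir"]

# Baseline soil/canopy reflectance and per-band sensitivity to the
# vegetation index; visible bands darken and NIR brightens as the canopy
# closes, so the implied NDVI rises with the index.
DEFAULT_BAND_BASE = (0.06, 0.08, 0.12, 0.20)
DEFAULT_BAND_COUPLING = (-0.03, -0.02, -0.10, 0.45)


@dataclass(frozen=True)
class CropClassSpec:
    """Phenology parameters of one crop class (days in day-of-year units,
    index values unitless)."""

    name: str
    sos: float                  # start of season
    eos: float                  # end of season
    rate_up: float              # green-up logistic slope (1/day)
    rate_down: float            # senescence logistic slope (1/day)
    v_min: float = 0.1
    v_max: float = 0.8
    band_base: tuple[float, ...] = DEFAULT_BAND_BASE
    band_coupling: tuple[float, ...] = DEFAULT_BAND_COUPLING

    def __post_init__(self):
        if not self.sos < self.eos:
            raise ValidationError(f"{self.name}: sos must precede eos")
        if not self.v_min < self.v_max:
            raise ValidationError(f"{self.name}: v_min must be below v_max")
        if self.rate_up <= 0 or self.rate_down <= 0:
            raise ValidationError(f"{self.name}: logistic rates must be positive")
        if len(self.band_base) != len(self.band_coupling):
            raise ValidationError(f"{self.name}: band parameter length mismatch")


def default_four_classes() -> list[CropClassSpec]:
    """Four separable templates: early vs late season, high vs low amplitude."""
    return [
        CropClassSpec("early_cereal", sos=95, eos=185, rate_up=0.10,
                      rate_down=0.09, v_min=0.12, v_max=0.80),
        CropClassSpec("late_maize", sos=140, eos=250, rate_up=0.09,
                      rate_down=0.08, v_min=0.10, v_max=0.85),
        CropClassSpec("low_legume", sos=120, eos=230, rate_up=0.07,
                      rate_down=0.07, v_min=0.15, v_max=0.50),
        CropClassSpec("perennial_grass", sos=70, eos=260, rate_up=0.04,
                      rate_down=0.05, v_min=0.20, v_max=0.62),
    ]


def imbalanced_eight_classes() -> tuple[list[CropClassSpec], list[int]]:
    """Eight classes with strongly skewed counts, mimicking real surveys
    where one or two crops dominate a region."""
    specs = [
        CropClassSpec("maize_main", 135, 250, 0.09, 0.08, 0.10, 0.85),
        CropClassSpec("cotton", 145, 265, 0.08, 0.07, 0.10, 0.75),
        CropClassSpec("winter_wheat", 75, 170, 0.10, 0.10, 0.12, 0.80),
        CropClassSpec("spring_wheat", 100, 195, 0.10, 0.09, 0.12, 0.78),
        CropClassSpec("sunflower", 150, 240, 0.09, 0.09, 0.10, 0.70),
        CropClassSpec("alfalfa", 70, 260, 0.05, 0.05, 0.22, 0.65),
        CropClassSpec("vineyard", 110, 255, 0.05, 0.06, 0.18, 0.55),
        CropClassSpec("bare_fallow", 65, 268, 0.02, 0.02, 0.05, 0.15),
    ]
    counts = [500, 300, 200, 120, 80, 50, 30, 15]
    return specs, counts


@dataclass(frozen=True)
class SimConfig:
    """Study conditions: season window March-September, 4-day revisit
    thinned by 30% cloud loss, mild observation noise, four balanced
    classes of 250 samples plus 2000 unlabeled draws."""

    classes: tuple[CropClassSpec, ...] = tuple(default_four_classes())
    n_per_class: tuple[int, ...] = (250, 250, 250, 250)
    n_unlabeled: int = 2000
    doy_start: int = 60
    doy_end: int = 270
    revisit: int = 4
    p_obs: float = 0.7
    min_len: int = 8
    noise_sd: float = 0.015
    seed: int = 0

    def __post_init__(self):
        if self.doy_start >= self.doy_end:
            raise ValidationError("doy_start must precede doy_end")
        if self.min_len < 1:
            raise ValidationError("min_len must be >= 1")
        if len(self.n_per_class) != len(self.classes):
            raise ValidationError("n_per_class length must match classes")
        if not 0.0 < self.p_obs <= 1.0:
            raise ValidationError("p_obs must be in (0, 1]")
        grid = (self.doy_end - self.doy_start) // self.revisit + 1
        if grid < self.min_len:
            raise ValidationError("revisit grid shorter than min_len")


def _sigma(x):
    return 1.0 / (1.0 + np.exp(-x))


def double_logistic(t, spec: CropClassSpec):
    """Canonical single-season vegetation-index curve:

        v(t) = v_min + (v_max - v_min) * [sigma(r_up (t - sos)) - sigma(r_down (t - eos))]

    flat at ``v_min`` outside the season and peaking between green-up and
    senescence.  Vectorized over ``t``.
    """
    t = np.asarray(t, dtype=np.float64)
    rise = _sigma(spec.rate_up * (t - spec.sos))
    fall = _sigma(spec.rate_down * (t - spec.eos))
    return spec.v_min + (spec.v_max - spec.v_min) * (rise - fall)


def index_to_bands(v, spec: CropClassSpec) -> np.ndarray:
    """Map index values to per-band reflectance, clipped to [0, 1].

    ``band_b = base_b + coupling_b * v``; with the default coupling the red
    band darkens and near-infrared brightens as ``v`` grows.
    Returns shape ``v.shape + (n_bands,)``.
    """
    v = np.asarray(v, dtype=np.float64)
    base = np.asarray(spec.band_base)
    coup = np.asarray(spec.band_coupling)
    return np.clip(base + coup * v[..., None], 0.0, 1.0)


def sample_doys(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw one sample's acquisition days: each grid date survives the
    cloud screen independently with probability ``p_obs``; redrawn until at
    least ``min_len`` dates remain."""
    grid = np.arange(config.doy_start, config.doy_end + 1, config.revisit)
    while True:
        keep = rng.random(grid.size) < config.p_obs
        if keep.sum() >= config.min_len:
            return grid[keep].astype(np.int64)


def _make_sample(sid: str, spec: CropClassSpec, config: SimConfig,
                 rng: np.random.Generator, label: Optional[str]) -> SpectralSequence:
    doy = sample_doys(config, rng)
    clean = index_to_bands(double_logistic(doy, spec), spec)
    noisy = np.clip(clean + rng.normal(0.0, config.noise_sd, size=clean.shape), 0.0, 1.0)
    return SpectralSequence(sample_id=sid, doy=doy, spectra=noisy, label=label)


def simulate(config: SimConfig) -> tuple[SampleSet, SampleSet]:
    """Generate (labeled, unlabeled) sample sets under the configured
    conditions; fully determined by ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    class_names = [c.name for c in config.classes]
    bands = list(BAND_NAMES[: len(config.classes[0].band_base)])

    labeled = []
    for spec, n in zip(config.classes, config.n_per_class):
        for j in range(n):
            labeled.append(_make_sample(f"lab-{spec.name}-{j:05d}", spec,
                                        config, rng, spec.name))

    # unlabeled draws follow the same class mixture, labels discarded
    probs = np.asarray(config.n_per_class, dtype=float)
    probs /= probs.sum()
    which = rng.choice(len(config.classes), size=config.n_unlabeled, p=probs)
    unlabeled = [_make_sample(f"unl-{j:05d}", config.classes[w], config, rng, None)
                 for j, w in enumerate(which)]

    labeled_set = SampleSet(samples=labeled, classes=sorted(class_names),
                            bands=bands, role="train")
    unlabeled_set = SampleSet(samples=unlabeled, classes=[], bands=bands,
                              role="unlabeled")
    return labeled_set, unlabeled_set


def train_val_test_split(labeled: SampleSet, fractions: Sequence[float] = (0.6, 0.2, 0.2),
                         seed: int = 0) -> tuple[SampleSet, SampleSet, SampleSet]:
    """Stratified split into train/val/test sets (default 6:2:2)."""
    if len(fractions) != 3 or not np.isclose(sum(fractions), 1.0):
        raise ValidationError("fractions must be three values summing to 1")
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[int]] = {}
    for i, s in enumerate(labeled.samples):
        if s.label is None:
            raise ValidationError("split requires a fully labeled set")
        by_class.setdefault(s.label, []).append(i)
    parts: tuple[list[int], list[int], list[int]] = ([], [], [])
    for label in sorted(by_class):
        idx = np.array(by_class[label])
        rng.shuffle(idx)
        n = len(idx)
        n_train = int(round(fractions[0] * n))
        n_val = int(round(fractions[1] * n))
        parts[0].extend(idx[:n_train])
        parts[1].extend(idx[n_train : n_train + n_val])
        parts[2].extend(idx[n_train + n_val :])
    return (labeled.subset(sorted(parts[0]), role="train"),
            labeled.subset(sorted(parts[1]), role="val"),
            labeled.subset(sorted(parts[2]), role="test"))
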