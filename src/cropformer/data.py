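"""Domain types and I/O for irregular multispectral time series.

A sample is a strictly increasing vector of acquisition days-of-year (DOY)
plus a ``T x B`` matrix of surface reflectances over B spectral bands, with
an optional crop-class label.  Samples travel as long-format CSV tables
(one row per observation) because sequences are ragged: every sample has
its own number and spacing of cloud-free acquisitions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpectralSequence",
    "SampleSet",
    "Batch",
    "read_samples",
    "write_samples",
    "pad_batch",
    "input_shape",
    "DEFAULT_BANDS",
]

DEFAULT_BANDS = ("blue", "green", "red", "nir")

ROLES = ("unlabeled", "train", "val", "test")


class ValidationError(ValueError):
    """Raised when domain invariants are violated."""


class FormatError(ValueError):
    """Raised when an input table is malformed."""


@dataclass(frozen=True)
class SpectralSequence:
    """One sample: DOY stamps, a T x B reflectance matrix, optional label."""

    sample_id: str
    doy: np.ndarray          # (T,) int, strictly increasing
    spectra: np.ndarray      # (T, B) float
    label: Optional[str] = None

    def __post_init__(self):
        doy = np.asarray(self.doy, dtype=np.int64)
        spectra = np.asarray(self.spectra, dtype=np.float64)
        object.__setattr__(self, "doy", doy)
        object.__setattr__(self, "spectra", spectra)
        if doy.ndim != 1 or spectra.ndim != 2:
            raise ValidationError(f"{self.sample_id}: doy must be 1-d, spectra 2-d")
        if len(doy) != spectra.shape[0] or len(doy) < 1:
            raise ValidationError(f"{self.sample_id}: doy/spectra length mismatch or empty")
        if spectra.shape[1] < 1:
            raise ValidationError(f"{self.sample_id}: need at least one band")
        if np.any(np.diff(doy) <= 0):
            raise ValidationError(f"{self.sample_id}: doy must be strictly increasing")
        if not np.all(np.isfinite(spectra)):
            raise ValidationError(f"{self.sample_id}: non-finite reflectance")

    @property
    def t(self) -> int:
        return len(self.doy)

    @property
    def n_bands(self) -> int:
        return self.spectra.shape[1]

    def rebase_doy(self) -> "SpectralSequence":
        """Re-express DOY as offset from the first observation (first = 0)."""
        return replace(self, doy=self.doy - self.doy[0])


@dataclass
class SampleSet:
    """A named collection of sequences sharing a band layout and class vocabulary."""

    samples: list[SpectralSequence]
    classes: list[str] = field(default_factory=list)
    bands: list[str] = field(default_factory=lambda: list(DEFAULT_BANDS))
    role: str = "train"

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValidationError(f"unknown role {self.role!r}")
        nb = len(self.bands)
        for s in self.samples:
            if s.n_bands != nb:
                raise ValidationError(
                    f"{s.sample_id}: {s.n_bands} bands, expected {nb}"
                )
            if s.label is not None:
                if self.role == "unlabeled":
                    raise ValidationError("unlabeled set contains a labeled sample")
                if s.label not in self.classes:
                    raise ValidationError(f"label {s.label!r} not in class vocabulary")

    def __len__(self) -> int:
        return len(self.samples)

    def labels(self) -> list[Optional[str]]:
        return [s.label for s in self.samples]

    def class_indices(self) -> np.ndarray:
        idx = {c: i for i, c in enumerate(self.classes)}
        return np.array([idx[s.label] for s in self.samples], dtype=np.int64)

    def subset(self, indices: Sequence[int], role: Optional[str] = None) -> "SampleSet":
        return SampleSet(
            samples=[self.samples[i] for i in indices],
            classes=list(self.classes),
            bands=list(self.bands),
            role=role or self.role,
        )


@dataclass(frozen=True)
class Batch:
    """Right-padded stack of sequences with a validity mask.

    Padded positions carry spectra = 0 and doy = 0; correctness downstream
    is enforced exclusively through ``valid_mask``, never the pad value.
    """

    spectra: np.ndarray     # (n, T_max, B)
    doy: np.ndarray         # (n, T_max) int
    valid_mask: np.ndarray  # (n, T_max) bool
    labels: Optional[np.ndarray] = None  # (n,) int

    @property
    def n(self) -> int:
        return self.spectra.shape[0]

    @property
    def t_max(self) -> int:
        return self.spectra.shape[1]

    def lengths(self) -> np.ndarray:
        return self.valid_mask.sum(axis=1)


def pad_batch(samples: Sequence[SpectralSequence],
              labels: Optional[np.ndarray] = None) -> Batch:
    """Stack variable-length sequences into a right-padded batch."""
    if len(samples) == 0:
        raise ValidationError("cannot batch an empty sample list")
    n_bands = samples[0].n_bands
    if any(s.n_bands != n_bands for s in samples):
        raise ValidationError("inconsistent band counts in batch")
    t_max = max(s.t for s in samples)
    n = len(samples)
    spectra = np.zeros((n, t_max, n_bands))
    doy = np.zeros((n, t_max), dtype=np.int64)
    mask = np.zeros((n, t_max), dtype=bool)
    for i, s in enumerate(samples):
        spectra[i, : s.t] = s.spectra
        doy[i, : s.t] = s.doy
        mask[i, : s.t] = True
    return Batch(spectra=spectra, doy=doy, valid_mask=mask,
                 labels=None if labels is None else np.asarray(labels, dtype=np.int64))


def bucketed_batch_order(lengths: np.ndarray, batch_size: int,
                         rng: np.random.Generator) -> list[np.ndarray]:
    """Shuffled mini-batch index lists, grouped by sequence length.

    Samples are shuffled, stably sorted by length so each batch holds
    similar-length sequences (minimal padding), and the batch order is
    shuffled again.  Purely an efficiency device: contents stay random.
    """
    lengths = np.asarray(lengths)
    perm = rng.permutation(len(lengths))
    perm = perm[np.argsort(lengths[perm], kind="stable")]
    batches = [perm[i : i + batch_size] for i in range(0, len(perm), batch_size)]
    return [batches[i] for i in rng.permutation(len(batches))]


def input_shape(t_num: int, band_num: int) -> int:
    """Flattened model input size for a series of ``t_num`` acquisitions over
    ``band_num`` bands: ``t_num * band_num + t_num`` (spectra plus one DOY
    stamp per acquisition)."""
    if t_num < 0 or band_num < 1:
        raise ValidationError("t_num must be >= 0 and band_num >= 1")
    return t_num * band_num + t_num


# -- table I/O -------------------------------------------------------------------

def write_samples(sample_set: SampleSet, path: str | Path) -> None:
    """Write a SampleSet as a long-format CSV plus a JSON metadata sidecar."""
    if len(sample_set) == 0:
        raise ValidationError("refusing to write an empty SampleSet")
    path = Path(path)
    rows = []
    for s in sample_set.samples:
        for t in range(s.t):
            row = {"sample_id": s.sample_id, "doy": int(s.doy[t])}
            row.update({b: s.spectra[t, j] for j, b in enumerate(sample_set.bands)})
            row["label"] = s.label if s.label is not None else ""
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(json.dumps({
        "classes": sample_set.classes,
        "bands": sample_set.bands,
        "role": sample_set.role,
    }, indent=1))


def read_samples(path: str | Path) -> SampleSet:
    """Read a long-format sample table written by :func:`write_samples`.

    Without a metadata sidecar, bands are inferred from the header and the
    class vocabulary is the sorted set of observed labels.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path, dtype={"sample_id": str}, float_precision="round_trip")
    if df.empty:
        raise ValidationError(f"{path}: empty sample table")

    sidecar = path.with_suffix(path.suffix + ".meta.json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else None

    for col in ("sample_id", "doy"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if meta is not None:
        bands = list(meta["bands"])
        for b in bands:
            if b not in df.columns:
                raise FormatError(f"{path}: missing band column {b!r}")
    else:
        bands = [c for c in df.columns if c not in ("sample_id", "doy", "label")]
        if not bands:
            raise FormatError(f"{path}: no band columns found")

    has_label = "label" in df.columns
    if df.duplicated(subset=["sample_id", "doy"]).any():
        dup = df[df.duplicated(subset=["sample_id", "doy"])].iloc[0]
        raise ValidationError(
            f"{path}: duplicate observation for sample {dup['sample_id']} doy {dup['doy']}"
        )

    samples = []
    for sid, g in df.groupby("sample_id", sort=True):
        g = g.sort_values("doy")
        label = None
        if has_label:
            vals = g["label"].astype("string").fillna("")
            uniq = set(vals)
            if len(uniq) > 1:
                raise ValidationError(f"{path}: conflicting labels for sample {sid}")
            lab = uniq.pop()
            label = lab if lab != "" else None
        samples.append(SpectralSequence(
            sample_id=str(sid),
            doy=g["doy"].to_numpy(dtype=np.int64),
            spectra=g[bands].to_numpy(dtype=np.float64),
            label=label,
        ))

    if meta is not None:
        classes, role = list(meta["classes"]), meta["role"]
    else:
        classes = sorted({s.label for s in samples if s.label is not None})
        role = "unlabeled" if not classes else "train"
    return SampleSet(samples=samples, classes=classes, bands=bands, role=role)
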