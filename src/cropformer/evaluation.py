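"""Metrics and the four evaluation scenarios.

Classification quality is summarized by overall accuracy (OA, fraction of
correct predictions), average accuracy (AA, macro-averaged per-class
recall, insensitive to class imbalance) and per-class F1.  The scenario
runner covers full-season classification, in-season classification with
calendar cutoffs, few-sample fine-tuning draws, and cross-region transfer,
each repeated over independent seeds and averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

from .classification import FinetuneConfig, finetune
from .data import SampleSet, SpectralSequence, ValidationError
from .encoder import EncoderWeights, ModelConfig
from .pretraining import PretrainConfig, pretrain

__all__ = [
    "EvalReport",
    "confusion_matrix",
    "metrics",
    "truncate_to_doy",
    "subsample_per_class",
    "ScenarioConfig",
    "run_scenario",
    "evaluate_classifier",
    "MONTH_END_DOY",
]

#: Default day-of-year for "end of month" calendar cutoffs.
MONTH_END_DOY = {"april": 120, "may": 151, "june": 181, "july": 212,
                 "august": 243, "september": 273}


@dataclass
class EvalReport:
    """Confusion matrix plus summary metrics for one evaluation.

    For multi-repeat reports, ``oa``/``aa``/``f1`` are the arithmetic means
    of the per-repeat values and ``confusion`` is the summed count matrix.
    """

    confusion: np.ndarray
    oa: float
    aa: float
    f1: np.ndarray
    classes: list[str]
    n_repeats: int = 1
    scenario: dict = field(default_factory=dict)
    per_repeat: list["EvalReport"] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "confusion": self.confusion.tolist(),
            "oa": self.oa,
            "aa": self.aa,
            "f1": {c: float(f) for c, f in zip(self.classes, self.f1)},
            "classes": self.classes,
            "n_repeats": self.n_repeats,
            "scenario": self.scenario,
        }
        if self.per_repeat:
            d["per_repeat"] = [r.to_dict() for r in self.per_repeat]
        return d


def confusion_matrix(truth: Sequence[str], pred: Sequence[str],
                     classes: Sequence[str]) -> np.ndarray:
    """Count matrix with rows = truth, columns = prediction."""
    if len(truth) != len(pred):
        raise ValidationError("truth and prediction lengths differ")
    known = set(classes)
    for lab in list(truth) + list(pred):
        if lab not in known:
            raise ValidationError(f"label {lab!r} not in vocabulary")
    return _sk_confusion(list(truth), list(pred), labels=list(classes))


def metrics(confusion: np.ndarray) -> tuple[float, float, np.ndarray]:
    """(OA, AA, per-class F1) from a confusion matrix.

    OA is trace/total; AA averages per-class recall over classes with at
    least one true instance; F1 is 0 for classes where precision + recall
    is 0.
    """
    cm = np.asarray(confusion, dtype=np.float64)
    total = cm.sum()
    if cm.size == 0 or total == 0:
        raise ValidationError("empty confusion matrix")
    diag = np.diag(cm)
    row = cm.sum(axis=1)   # true counts
    col = cm.sum(axis=0)   # predicted counts
    oa = float(diag.sum() / total)
    with np.errstate(divide="ignore", invalid="ignore"):
        recall = np.where(row > 0, diag / row, np.nan)
        precision = np.where(col > 0, diag / col, 0.0)
    aa = float(np.nanmean(recall))
    r = np.where(row > 0, diag / np.maximum(row, 1), 0.0)
    denom = precision + r
    f1 = np.where(denom > 0, 2 * precision * r / np.maximum(denom, 1e-300), 0.0)
    return oa, aa, f1


def truncate_to_doy(sample: SpectralSequence, cutoff_doy: int) -> SpectralSequence:
    """Keep exactly the observations with doy <= cutoff (in-season use)."""
    keep = sample.doy <= cutoff_doy
    if not keep.any():
        raise ValidationError(
            f"{sample.sample_id}: no observation at or before doy {cutoff_doy}"
        )
    return replace(sample, doy=sample.doy[keep], spectra=sample.spectra[keep])


def subsample_per_class(sample_set: SampleSet, mode: str, value: float,
                        rng: np.random.Generator) -> SampleSet:
    """Few-sample draws from a labeled set.

    ``fraction`` keeps ``ceil(value * n_c)`` samples of each class c (at
    least one); ``fixed_min`` keeps k per class where k is the size of the
    smallest class, yielding an exactly balanced subset.
    """
    if any(s.label is None for s in sample_set.samples):
        raise ValidationError("subsampling requires a fully labeled set")
    by_class: dict[str, list[int]] = {}
    for i, s in enumerate(sample_set.samples):
        by_class.setdefault(s.label, []).append(i)

    if mode == "fraction":
        if not 0.0 < value <= 1.0:
            raise ValidationError("fraction must be in (0, 1]")
        take = {c: max(1, int(np.ceil(value * len(ix)))) for c, ix in by_class.items()}
    elif mode == "fixed_min":
        k = min(len(ix) for ix in by_class.values())
        take = {c: k for c in by_class}
    else:
        raise ValidationError(f"unknown subsampling mode {mode!r}")

    chosen: list[int] = []
    for c in sorted(by_class):
        ix = np.array(by_class[c])
        chosen.extend(rng.choice(ix, size=take[c], replace=False))
    return sample_set.subset(sorted(int(i) for i in chosen))


def evaluate_classifier(clf, test: SampleSet, scenario: Optional[dict] = None) -> EvalReport:
    """Score a trained classifier on a labeled test set."""
    truth = [s.label for s in test.samples]
    pred = clf.predict(test)
    cm = confusion_matrix(truth, pred, clf.classes)
    oa, aa, f1 = metrics(cm)
    return EvalReport(confusion=cm, oa=oa, aa=aa, f1=f1, classes=list(clf.classes),
                      scenario=scenario or {})


def _aggregate(reports: list[EvalReport], scenario: dict) -> EvalReport:
    cm = np.sum([r.confusion for r in reports], axis=0)
    return EvalReport(
        confusion=cm,
        oa=float(np.mean([r.oa for r in reports])),
        aa=float(np.mean([r.aa for r in reports])),
        f1=np.mean([r.f1 for r in reports], axis=0),
        classes=reports[0].classes,
        n_repeats=len(reports),
        scenario=scenario,
        per_repeat=reports,
    )


@dataclass
class ScenarioConfig:
    """One evaluation scenario over prepared sample sets.

    For ``transfer``, ``train``/``val`` come from the source region and
    ``test`` from the target region; the audit trail in the report records
    that no target labels entered training.
    """

    kind: str                       # full_season | in_season | few_sample | transfer
    train: SampleSet
    val: SampleSet
    test: SampleSet
    model_config: ModelConfig
    finetune_config: FinetuneConfig
    unlabeled: Optional[SampleSet] = None
    pretrain_config: Optional[PretrainConfig] = None
    pretrained: Optional[EncoderWeights] = None
    n_repeats: int = 3
    seed: int = 0
    cutoffs: tuple[int, ...] = ()               # in_season
    few_mode: str = "fraction"                  # few_sample
    few_value: float = 0.01
    source_name: str = "source"
    target_name: str = "target"

    def __post_init__(self):
        kinds = ("full_season", "in_season", "few_sample", "transfer")
        if self.kind not in kinds:
            raise ValidationError(f"scenario kind must be one of {kinds}")
        if self.kind == "in_season" and not self.cutoffs:
            raise ValidationError("in_season scenario needs at least one cutoff")


def _truncate_set(sample_set: SampleSet, cutoff: int) -> SampleSet:
    kept = []
    for s in sample_set.samples:
        if s.doy[0] > cutoff:
            continue   # sample has no usable observation at this stage
        kept.append(truncate_to_doy(s, cutoff))
    if not kept:
        raise ValidationError(f"no samples survive cutoff doy {cutoff}")
    return SampleSet(samples=kept, classes=list(sample_set.classes),
                     bands=list(sample_set.bands), role=sample_set.role)


def run_scenario(config: ScenarioConfig) -> list[EvalReport]:
    """Execute a scenario over ``n_repeats`` independent seeds.

    Returns one aggregated report per evaluation setting (one for
    full_season/few_sample/transfer; one per cutoff for in_season), each
    carrying its per-repeat reports.
    """
    settings: list[dict]
    if config.kind == "in_season":
        settings = [{"cutoff_doy": int(c)} for c in config.cutoffs]
    else:
        settings = [{}]

    out: list[EvalReport] = []
    for setting in settings:
        reports = []
        for r in range(config.n_repeats):
            seed_r = config.seed + r
            train, val, test = config.train, config.val, config.test

            if config.kind == "in_season":
                cut = setting["cutoff_doy"]
                train = _truncate_set(train, cut)
                val = _truncate_set(val, cut)
                test = _truncate_set(test, cut)
            elif config.kind == "few_sample":
                rng = np.random.default_rng(seed_r)
                train = subsample_per_class(train, config.few_mode,
                                            config.few_value, rng)

            pretrained = config.pretrained
            if pretrained is None and config.pretrain_config is not None:
                if config.unlabeled is None:
                    raise ValidationError("pretrain_config given without unlabeled data")
                pc = replace(config.pretrain_config, seed=seed_r)
                pretrained, _ = pretrain(config.unlabeled, config.model_config, pc)

            fc = replace(config.finetune_config, seed=seed_r)
            clf = finetune(pretrained, train, val, config.model_config, fc)
            desc = {"kind": config.kind, "repeat": r, "seed": seed_r,
                    "n_train": len(train), **setting}
            if config.kind == "transfer":
                desc["trained_on"] = config.source_name
                desc["evaluated_on"] = config.target_name
                desc["target_labels_used_in_training"] = False
            reports.append(evaluate_classifier(clf, test, scenario=desc))

        agg_desc = {"kind": config.kind, "n_repeats": config.n_repeats,
                    "seed": config.seed, **setting}
        if config.kind == "few_sample":
            agg_desc.update({"mode": config.few_mode, "value": config.few_value})
        if config.kind == "transfer":
            agg_desc.update({"trained_on": config.source_name,
                             "evaluated_on": config.target_name,
                             "target_labels_used_in_training": False})
        out.append(_aggregate(reports, agg_desc))
    return out
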