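"""Detection of mislabelled training tiles, and the planted-noise benchmark.

A tile that the model misclassifies *confidently* (low predictive entropy H)
is a strong mislabelling candidate: the model has learned the class well and
still disagrees with the annotation.  Given the expected mislabelled
fraction p_m (in percent), the detector computes, separately for each
assigned class c, the p_m-th percentile of the empirical H distribution in
that class, and flags every misclassified tile with H strictly below its
class threshold.  The final candidate set is the union over classes.

The benchmark plants known noise: a fraction p_m of tiles is relabelled
uniformly to one of the other M-1 classes, the model is retrained, and the
detector is scored against the planted set.  Following the reference
protocol, "sensitivity" is |planted ∩ candidates| / |candidates| — a
precision — and "specificity" is the clean fraction of the non-candidates;
standard recall |planted ∩ candidates| / |planted| is reported alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import ImagePatch, PatchDataset
from .uncertainty import UncertaintyRecord

__all__ = [
    "MislabelConfig",
    "MislabelReport",
    "plant_label_noise",
    "per_class_thresholds",
    "identify_mislabelled",
    "evaluate_identification",
]


@dataclass(frozen=True)
class MislabelConfig:
    p_m: float = 10.0  # expected mislabelled percentage in [0, 100]
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_m <= 100.0:
            raise ValueError("p_m must lie in [0, 100]")


@dataclass(frozen=True)
class MislabelReport:
    thresholds: dict[int, float]
    candidate_ids: frozenset[str]
    sensitivity: float | None = None
    specificity: float | None = None
    recall: float | None = None


def plant_label_noise(
    dataset: PatchDataset, p_m: float, seed: int
) -> tuple[PatchDataset, frozenset[str]]:
    """Relabel round(p_m/100 * N) tiles to a uniformly random *other* class.

    Returns the corrupted dataset and the planted id set as ground truth.
    """
    if not 0.0 <= p_m <= 100.0:
        raise ValueError("p_m must lie in [0, 100]")
    m = dataset.n_classes
    if m < 2:
        raise ValueError("need at least 2 classes to mislabel")
    n = len(dataset)
    n_flip = int(np.rint(p_m / 100.0 * n))
    rng = np.random.default_rng(seed)
    flip_idx = set(rng.choice(n, size=n_flip, replace=False).tolist()) if n_flip else set()
    patches: list[ImagePatch] = []
    planted: list[str] = []
    for i, p in enumerate(dataset.patches):
        if i in flip_idx:
            # uniform over the M-1 other classes — the label always changes
            offset = int(rng.integers(1, m))
            new_label = (p.label + offset) % m
            patches.append(ImagePatch(id=p.id, pixels=p.pixels, label=new_label))
            planted.append(p.id)
        else:
            patches.append(p)
    return PatchDataset(patches=patches, catalog=dataset.catalog), frozenset(planted)


def per_class_thresholds(
    records: list[UncertaintyRecord], p_m: float
) -> dict[int, float]:
    """p_m-th percentile of H per assigned class (linear interpolation)."""
    if not 0.0 <= p_m <= 100.0:
        raise ValueError("p_m must lie in [0, 100]")
    by_class: dict[int, list[float]] = {}
    for r in records:
        if r.true_label is None:
            raise ValueError(f"record {r.patch_id!r} carries no assigned label")
        by_class.setdefault(r.true_label, []).append(r.H)
    thresholds: dict[int, float] = {}
    for c, values in sorted(by_class.items()):
        if not values:
            warnings.warn(f"class {c} has no records; omitted", stacklevel=2)
            continue
        thresholds[c] = float(np.percentile(values, p_m, method="linear"))
    return thresholds


def identify_mislabelled(
    records: list[UncertaintyRecord], p_m: float
) -> MislabelReport:
    """Union over classes of confidently misclassified tiles.

    A record with assigned class c is a candidate iff its prediction differs
    from c and its H lies strictly below that class's threshold.
    """
    thresholds = per_class_thresholds(records, p_m)
    candidates = {
        r.patch_id
        for r in records
        if r.predicted != r.true_label
        and r.true_label in thresholds
        and r.H < thresholds[r.true_label]
    }
    return MislabelReport(thresholds=thresholds, candidate_ids=frozenset(candidates))


def evaluate_identification(
    report: MislabelReport, planted: frozenset[str] | set[str], all_ids: set[str]
) -> MislabelReport:
    """Score the candidate set against planted ground truth.

    sensitivity = |planted ∩ candidates| / |candidates| (None if no
    candidates), specificity = |clean ∩ non-candidates| / |non-candidates|,
    recall = |planted ∩ candidates| / |planted|.
    """
    planted = frozenset(planted)
    if not planted <= set(all_ids):
        raise ValueError("planted ids must be a subset of all ids")
    cand = report.candidate_ids
    tp = len(planted & cand)
    sensitivity = tp / len(cand) if cand else None
    non_cand = set(all_ids) - cand
    clean_non_cand = len(non_cand - planted)
    specificity = clean_non_cand / len(non_cand) if non_cand else None
    recall = tp / len(planted) if planted else None
    return MislabelReport(
        thresholds=report.thresholds,
        candidate_ids=cand,
        sensitivity=sensitivity,
        specificity=specificity,
        recall=recall,
    )
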