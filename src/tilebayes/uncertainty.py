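"""Monte-Carlo dropout inference and the Entropy-H / BALD uncertainty measures.

T stochastic forward passes (dropout kept active) give a T x M matrix of
class-probability rows; their unweighted average approximates the predictive
distribution P(y*|o, D).  Two uncertainties are derived from it, both in
nats:

* Entropy H — Shannon entropy of the predictive mean.  Total uncertainty:
  it does not distinguish disagreement between weight samples (epistemic)
  from inherent class ambiguity (aleatoric).
* BALD — mutual information between the label and the model weights,
  H(mean) minus the mean per-pass entropy.  Vanishes when every pass agrees,
  however flat the shared distribution is, so it isolates the epistemic part.

Hence 0 <= BALD <= H <= ln M always.  Because the 0.2/0.8 rules of thumb for
"very low"/"very high" H are scale-ambiguous, the normalised value H/ln M is
reported alongside the raw one.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .core import ImagePatch, PatchDataset
from .model import TrainedClassifier, patches_to_array

__all__ = [
    "PredictivePosterior",
    "UncertaintyRecord",
    "mc_predict",
    "entropy_H",
    "bald",
    "classify",
    "score_dataset",
    "save_records_csv",
    "load_records_csv",
]

DEFAULT_T = 50  # variational samples per prediction


@dataclass(frozen=True)
class PredictivePosterior:
    """T x M row-stochastic matrix of per-pass class probabilities."""

    samples: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=np.float64)
        if s.ndim != 2 or s.shape[0] < 1:
            raise ValueError("samples must be a T x M matrix with T >= 1")
        if not np.allclose(s.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("every sample row must sum to 1")
        if (s < -1e-12).any():
            raise ValueError("probabilities must be non-negative")
        object.__setattr__(self, "samples", s)

    @property
    def T(self) -> int:
        return self.samples.shape[0]

    @property
    def n_classes(self) -> int:
        return self.samples.shape[1]

    @property
    def mean(self) -> np.ndarray:
        return self.samples.mean(axis=0)


@dataclass(frozen=True)
class UncertaintyRecord:
    """Per-tile prediction with both uncertainty measures."""

    patch_id: str
    predicted: int
    H: float
    H_normalized: float
    BALD: float
    true_label: int | None = None


def _entropy(p: np.ndarray) -> np.ndarray:
    """Shannon entropy along the last axis, nats, with 0 ln 0 := 0."""
    p = np.asarray(p, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, -p * np.log(p), 0.0)
    return terms.sum(axis=-1)


def mc_predict(
    model: TrainedClassifier,
    patch: ImagePatch,
    T: int = DEFAULT_T,
    rng: np.random.Generator | None = None,
) -> PredictivePosterior:
    """T stochastic passes on one patch."""
    if T < 1:
        raise ValueError("T must be >= 1")
    if rng is None:
        rng = model._predict_rng
    x = patches_to_array([patch], model.config.input_size)
    samples = model.mc_posterior_batch(x, T, [rng])[0]
    return PredictivePosterior(samples=samples)


def entropy_H(posterior: PredictivePosterior) -> float:
    """Entropy of the predictive mean, in nats."""
    return float(_entropy(posterior.mean))


def bald(posterior: PredictivePosterior) -> float:
    """H(mean) minus mean per-pass entropy; clipped at 0.

    Mutual information is provably non-negative but floating-point
    cancellation can leave a ~-1e-16 residue.
    """
    value = entropy_H(posterior) - float(_entropy(posterior.samples).mean())
    return max(value, 0.0)


def classify(posterior: PredictivePosterior) -> int:
    """Argmax of the predictive mean; ties go to the lowest class index."""
    return int(np.argmax(posterior.mean))


def score_dataset(
    model: TrainedClassifier,
    patches: PatchDataset | Sequence[ImagePatch],
    T: int = DEFAULT_T,
    seed: int = 0,
    eval_batch: int = 128,
) -> list[UncertaintyRecord]:
    """One record per patch, order-preserving, batched.

    Each patch draws its MC masks from its own substream of ``seed``, so the
    records do not depend on batch composition.
    """
    patch_list = list(patches)
    if not patch_list:
        return []
    m = model.config.n_classes
    ln_m = np.log(m)
    streams = np.random.SeedSequence(seed).spawn(len(patch_list))
    records: list[UncertaintyRecord] = []
    for start in range(0, len(patch_list), eval_batch):
        chunk = patch_list[start : start + eval_batch]
        x = patches_to_array(chunk, model.config.input_size)
        rngs = [np.random.default_rng(s) for s in streams[start : start + len(chunk)]]
        samples = model.mc_posterior_batch(x, T, rngs)
        for p, s in zip(chunk, samples):
            post = PredictivePosterior(samples=s)
            h = entropy_H(post)
            records.append(
                UncertaintyRecord(
                    patch_id=p.id,
                    predicted=classify(post),
                    H=h,
                    H_normalized=h / ln_m,
                    BALD=bald(post),
                    true_label=p.label,
                )
            )
    return records


def save_records_csv(records: Sequence[UncertaintyRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "true_label", "predicted", "H", "H_normalized", "BALD"])
        for r in records:
            writer.writerow(
                [
                    r.patch_id,
                    "" if r.true_label is None else r.true_label,
                    r.predicted,
                    f"{r.H:.10g}",
                    f"{r.H_normalized:.10g}",
                    f"{r.BALD:.10g}",
                ]
            )


def load_records_csv(path: str | Path) -> list[UncertaintyRecord]:
    records: list[UncertaintyRecord] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            records.append(
                UncertaintyRecord(
                    patch_id=row["id"],
                    true_label=int(row["true_label"]) if row["true_label"] else None,
                    predicted=int(row["predicted"]),
                    H=float(row["H"]),
                    H_normalized=float(row["H_normalized"]),
                    BALD=float(row["BALD"]),
                )
            )
    return records
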