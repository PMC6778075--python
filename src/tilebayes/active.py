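"""Uncertainty-driven active learning over a pool of labelled tiles.

The loop emulates an annotation workflow: start from a small stratified
seed set (40 tiles per class by default), train, score the remaining pool
with an acquisition function — predictive-entropy H, BALD, or uniform
random as the baseline — move the top ``step_size`` (160 by default) tiles
into the labelled set, and retrain from a fresh pre-initialisation.  Steps
are 0-indexed: step 0 is the seed training, and the labelled-set size at
step s is ``min(M * seed_per_class + s * step_size, pool_total)``, so the
last step may be partial.  With an 8-class pool of 4496 tiles this yields
28 steps (0..27) with sizes 320, 480, ..., 4480, 4496.

``compare_strategies`` is the experiment harness: it averages per-step test
accuracy over ``n_splits`` dataset splits x ``n_inits`` weight
initialisations for each strategy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .core import PatchDataset, stratified_holdout
from .model import ModelConfig, TrainConfig, TrainedClassifier, build_classifier, patches_to_array, train_classifier
from .uncertainty import UncertaintyRecord, score_dataset

__all__ = [
    "AcquisitionConfig",
    "ActiveLearningTrace",
    "schedule_size",
    "n_schedule_steps",
    "select_top_k",
    "select_random",
    "run_active_learning",
    "compare_strategies",
    "trace_auc",
]

STRATEGIES = ("random", "entropy_H", "bald")


@dataclass(frozen=True)
class AcquisitionConfig:
    strategy: str = "entropy_H"
    seed_per_class: int = 40
    step_size: int = 160
    T: int = 50
    n_inits: int = 8
    n_splits: int = 3
    epochs_per_step: int = 100
    val_fraction: float = 0.3
    learning_rate: float = 1e-3
    train_batch: int = 32
    eval_batch: int = 128
    seed: int = 0

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"strategy must be one of {STRATEGIES}")
        if self.seed_per_class < 1 or self.step_size < 1:
            raise ValueError("seed_per_class and step_size must be >= 1")


@dataclass
class ActiveLearningTrace:
    """Per-step labelled-set size and test accuracy for one strategy."""

    strategy: str
    steps: list[int] = field(default_factory=list)
    sizes: list[int] = field(default_factory=list)
    accuracies: list[float] = field(default_factory=list)

    def append(self, step: int, size: int, accuracy: float) -> None:
        if self.sizes and size <= self.sizes[-1]:
            raise ValueError("labelled-set sizes must be strictly increasing")
        self.steps.append(step)
        self.sizes.append(size)
        self.accuracies.append(accuracy)


def schedule_size(
    step: int, n_classes: int, config: AcquisitionConfig, pool_total: int
) -> int:
    """Labelled-set size at a 0-indexed step, capped by the pool."""
    if step < 0:
        raise ValueError("step must be >= 0")
    return min(n_classes * config.seed_per_class + step * config.step_size, pool_total)


def n_schedule_steps(n_classes: int, config: AcquisitionConfig, pool_total: int) -> int:
    """Total number of steps (counting step 0) until the pool is exhausted."""
    start = n_classes * config.seed_per_class
    if pool_total <= start:
        return 1
    remaining = pool_total - start
    return 1 + -(-remaining // config.step_size)  # ceil division


def select_top_k(
    records: list[UncertaintyRecord], measure: str, k: int
) -> set[str]:
    """Ids of the k most-uncertain records; ties broken by lexicographic id."""
    if measure not in ("entropy_H", "bald"):
        raise ValueError("measure must be 'entropy_H' or 'bald'")
    if k > len(records):
        warnings.warn("k exceeds the pool; returning every id", stacklevel=2)
        return {r.patch_id for r in records}
    key = (lambda r: r.H) if measure == "entropy_H" else (lambda r: r.BALD)
    ranked = sorted(records, key=lambda r: (-key(r), r.patch_id))
    return {r.patch_id for r in ranked[:k]}


def select_random(pool_ids: set[str], k: int, rng_seed: int) -> set[str]:
    """k distinct ids drawn uniformly without replacement."""
    if k > len(pool_ids):
        raise ValueError(f"k={k} exceeds pool of {len(pool_ids)}")
    ordered = sorted(pool_ids)
    rng = np.random.default_rng(rng_seed)
    chosen = rng.choice(len(ordered), size=k, replace=False)
    return {ordered[i] for i in chosen}


def _seed_set(full_train: PatchDataset, per_class: int, rng: np.random.Generator) -> set[str]:
    chosen: set[str] = set()
    labels = full_train.labels()
    ids = full_train.ids
    for c in range(full_train.n_classes):
        idx = np.flatnonzero(labels == c)
        if len(idx) < per_class:
            raise ValueError(f"class {c} smaller than seed_per_class")
        pick = rng.choice(len(idx), size=per_class, replace=False)
        chosen.update(ids[idx[i]] for i in pick)
    return chosen


def _test_accuracy(model: TrainedClassifier, test: PatchDataset, eval_batch: int) -> float:
    x = patches_to_array(test.patches, model.config.input_size)
    y = test.labels()
    correct = 0
    for start in range(0, len(x), eval_batch):
        probs = model.forward_batch(x[start : start + eval_batch])
        correct += int((probs.argmax(axis=1) == y[start : start + eval_batch]).sum())
    return correct / len(x)


def run_active_learning(
    full_train: PatchDataset,
    test: PatchDataset,
    model_config: ModelConfig,
    config: AcquisitionConfig,
    init_seed: int | None = None,
) -> ActiveLearningTrace:
    """One full acquisition loop for one strategy / split / initialisation.

    Each step rebuilds the model from the same fresh initialisation seed and
    retrains on the grown labelled set (no fine-tuning); acquisition scores
    are computed on the remaining pool only.
    """
    if set(full_train.ids) & set(test.ids):
        raise ValueError("train and test ids overlap")
    m = full_train.n_classes
    pool_total = len(full_train)
    if pool_total < m * config.seed_per_class:
        raise ValueError("pool smaller than the seed set")
    if init_seed is None:
        init_seed = config.seed
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    labelled = _seed_set(full_train, config.seed_per_class, rng)
    pool = set(full_train.ids) - labelled
    trace = ActiveLearningTrace(strategy=config.strategy)
    total_steps = n_schedule_steps(m, config, pool_total)
    for step in range(total_steps):
        model = build_classifier(model_config, seed=init_seed)
        tcfg = TrainConfig(
            epochs=config.epochs_per_step,
            train_batch=config.train_batch,
            eval_batch=config.eval_batch,
            learning_rate=config.learning_rate,
            val_fraction=config.val_fraction,
            seed=int(rng.integers(2**31)),
        )
        train_classifier(model, full_train.subset(sorted(labelled)), tcfg)
        acc = _test_accuracy(model, test, config.eval_batch)
        size = len(labelled)
        if size != schedule_size(step, m, config, pool_total):
            raise AssertionError("labelled-set size diverged from the schedule")
        trace.append(step, size, acc)
        if not pool:
            break
        k = min(config.step_size, len(pool))
        if config.strategy == "random":
            new_ids = select_random(pool, k, rng_seed=int(rng.integers(2**31)))
        else:
            pool_patches = full_train.subset(sorted(pool))
            records = score_dataset(
                model, pool_patches, T=config.T, seed=int(rng.integers(2**31))
            )
            measure = "entropy_H" if config.strategy == "entropy_H" else "bald"
            new_ids = select_top_k(records, measure, k)
        if new_ids & labelled:
            raise AssertionError("acquired an already-labelled id")
        labelled |= new_ids
        pool -= new_ids
    return trace


def compare_strategies(
    dataset: PatchDataset,
    model_config: ModelConfig,
    config: AcquisitionConfig,
    strategies: tuple[str, ...] = ("random", "entropy_H"),
    k_folds: int | None = None,
) -> dict[str, ActiveLearningTrace]:
    """Mean trace per strategy over n_splits splits x n_inits initialisations.

    ``k_folds`` sets the holdout denominator (test fraction 1/k_folds per
    split); it defaults to 5 so most of the data forms the acquisition
    pool.  The same splits and the same pre-initialisation seeds are reused
    for every strategy, so the comparison is paired.
    """
    n_splits = config.n_splits
    if k_folds is None:
        k_folds = max(5, n_splits)
    splits = stratified_holdout(dataset, k=k_folds, seed=config.seed)[:n_splits]
    init_seeds = [int(s) for s in np.random.default_rng(config.seed).integers(2**31, size=config.n_inits)]
    out: dict[str, ActiveLearningTrace] = {}
    for strategy in strategies:
        acc_sum: np.ndarray | None = None
        count = 0
        template: ActiveLearningTrace | None = None
        for split_i, split in enumerate(splits):
            train = dataset.subset(split.train_ids)
            test = dataset.subset(split.test_ids)
            for init_seed in init_seeds:
                cfg = replace(config, strategy=strategy, seed=config.seed + 1000 * split_i)
                trace = run_active_learning(train, test, model_config, cfg, init_seed=init_seed)
                accs = np.asarray(trace.accuracies)
                acc_sum = accs if acc_sum is None else acc_sum + accs
                count += 1
                template = trace
        mean = ActiveLearningTrace(strategy=strategy)
        for step, size, acc in zip(template.steps, template.sizes, (acc_sum / count)):
            mean.append(step, size, float(acc))
        out[strategy] = mean
    return out


def trace_auc(trace: ActiveLearningTrace) -> float:
    """Area under the accuracy-vs-labelled-size curve, normalised to the
    size span, i.e. the mean accuracy over the acquisition schedule."""
    sizes = np.asarray(trace.sizes, dtype=float)
    accs = np.asarray(trace.accuracies, dtype=float)
    if len(sizes) < 2:
        return float(accs[0])
    return float(np.trapezoid(accs, sizes) / (sizes[-1] - sizes[0]))
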