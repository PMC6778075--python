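"""The dropout-regularised dual-head convolutional classifier.

A compact residual CNN trunk (configurable width/depth) feeds two small
fully connected heads of 32 units each, both carrying dropout at rate 0.5:
an *auxiliary* softmax output used only to regularise training (loss weight
0.1) and the *final* softmax output (loss weight 0.9).  Keeping dropout
active at prediction time turns the network into an approximate Bayesian
model: each stochastic forward pass samples one set of weights from the
variational posterior, and averaging T passes approximates the predictive
distribution P(y*|o, D).

Batch-normalisation statistics are frozen in every prediction mode, so the
dropout masks on the two 32-unit layers are the only stochastic element of
a Monte-Carlo pass.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image

from .core import ImagePatch, PatchDataset
from .nn import Adam, BatchNorm2d, Conv2d, Dense, Dropout, ReLU, ResidualBlock, softmax

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "TrainedClassifier",
    "build_classifier",
    "dual_head_loss",
    "train_classifier",
    "predict_single_pass",
    "patches_to_array",
    "save_checkpoint",
    "load_checkpoint",
]

_EPS = 1e-12  # probability clamp inside cross-entropy


@dataclass(frozen=True)
class ModelConfig:
    """Architecture knobs.

    ``filters`` sets the trunk width/depth: a stem convolution to
    ``filters[0]`` followed by one stride-2 residual block per further
    entry.  The 128 px default input matches the resolution segmentation
    tiles are upscaled to; smaller inputs (with a narrower trunk) are used
    for fast reduced-scale runs.
    """

    n_classes: int
    input_size: int = 128
    dropout_rate: float = 0.5
    filters: tuple[int, ...] = (16, 32, 64)
    head_hidden_units: int = 32

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if not 0.0 < self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in (0, 1)")
        if len(self.filters) < 1:
            raise ValueError("filters must be non-empty")


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation schedule.

    Defaults follow the reference protocol: Adam at 1e-3, batches of 32 for
    training and 128 for evaluation, validation split 0.1 (0.3 in
    active-learning mode where the labelled set starts tiny), and a
    plateau-based learning-rate reduction by a factor of 0.1 whenever
    validation accuracy fails to improve for ``lr_patience`` epochs.  The
    dual-head loss weights 0.9/0.1 must sum to 1.
    """

    epochs: int = 200
    train_batch: int = 32
    eval_batch: int = 128
    learning_rate: float = 1e-3
    lr_reduce_factor: float = 0.1
    lr_patience: int = 5
    val_fraction: float = 0.1
    final_weight: float = 0.9
    aux_weight: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.final_weight + self.aux_weight - 1.0) > 1e-9:
            raise ValueError("head weights must sum to 1")
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in (0, 1)")


class TrainedClassifier:
    """Residual trunk + dual dropout heads with explicit forward/backward.

    Construct via :func:`build_classifier`.  The instance is mutated in
    place by :func:`train_classifier`; ``history`` holds one record per
    epoch (loss, accuracies, learning rate).
    """

    def __init__(self, config: ModelConfig, seed: int):
        self.config = config
        self.seed = seed
        rng = np.random.default_rng(seed)
        f = config.filters
        self.stem_conv = Conv2d(3, f[0], 3, 1, 1, rng)
        self.stem_bn = BatchNorm2d(f[0])
        self.stem_relu = ReLU()
        self.blocks = [
            ResidualBlock(f[i - 1], f[i], stride=2, rng=rng) for i in range(1, len(f))
        ]
        h = config.head_hidden_units
        feat = f[-1]
        m = config.n_classes
        self.aux_fc = Dense(feat, h, rng)
        self.aux_relu = ReLU()
        self.aux_drop = Dropout(config.dropout_rate)
        self.aux_out = Dense(h, m, rng)
        self.fin_fc = Dense(feat, h, rng)
        self.fin_relu = ReLU()
        self.fin_drop = Dropout(config.dropout_rate)
        self.fin_out = Dense(h, m, rng)
        self.history: list[dict] = []
        # default stream for stochastic predictions when no rng is supplied
        self._predict_rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
        self._gap_shape: tuple | None = None

    # ------------------------------------------------------------------ forward
    def _all_layers(self) -> list:
        layers = [self.stem_conv, self.stem_bn, self.stem_relu]
        for b in self.blocks:
            layers.extend(b.sublayers())
        layers.extend(
            [self.aux_fc, self.aux_relu, self.aux_drop, self.aux_out,
             self.fin_fc, self.fin_relu, self.fin_drop, self.fin_out]
        )
        return layers

    def n_params(self) -> int:
        return sum(p.size for layer in self._all_layers() for p in layer.params.values())

    def features(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Trunk forward: (N, S, S, 3) float32 -> (N, F) global-average-pooled."""
        h = self.stem_relu.forward(
            self.stem_bn.forward(self.stem_conv.forward(x, train), train), train
        )
        for b in self.blocks:
            h = b.forward(h, train)
        if train:
            self._gap_shape = h.shape
        return h.mean(axis=(1, 2))

    def heads(
        self,
        feat: np.ndarray,
        train: bool = False,
        stochastic: bool = False,
        rng: np.random.Generator | None = None,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Both heads' probabilities.  Returns (final_probs, aux_probs)."""
        if stochastic and rng is None:
            rng = self._predict_rng
        a = self.aux_relu.forward(self.aux_fc.forward(feat, train), train)
        a = self.aux_drop.forward(a, train, rng=rng, stochastic=stochastic)
        a = self.aux_out.forward(a, train)
        g = self.fin_relu.forward(self.fin_fc.forward(feat, train), train)
        g = self.fin_drop.forward(g, train, rng=rng, stochastic=stochastic)
        g = self.fin_out.forward(g, train)
        return softmax(g), softmax(a)

    def forward_batch(
        self,
        x: np.ndarray,
        stochastic: bool = False,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        """Final-head probabilities for a prepared image batch (eval mode)."""
        feat = self.features(x, train=False)
        final, _ = self.heads(feat, train=False, stochastic=stochastic, rng=rng)
        return final

    def mc_posterior_batch(
        self,
        x: np.ndarray,
        T: int,
        rngs: Sequence[np.random.Generator],
    ) -> np.ndarray:
        """(N, T, M) stochastic final-head samples; one rng stream per image.

        The trunk is deterministic at prediction time (batch norm frozen,
        no trunk dropout), so its features are computed once and only the
        dropout-bearing heads are resampled T times.
        """
        if T < 1:
            raise ValueError("T must be >= 1")
        feat = self.features(x, train=False)
        n = feat.shape[0]
        out = np.empty((n, T, self.config.n_classes), dtype=np.float64)
        for i in range(n):
            tiled = np.repeat(feat[i : i + 1], T, axis=0)
            final, _ = self.heads(tiled, train=False, stochastic=True, rng=rngs[i])
            out[i] = final
        return out

    # ----------------------------------------------------------------- backward
    def _backward(self, d_final_logits: np.ndarray, d_aux_logits: np.ndarray) -> None:
        da = self.aux_out.backward(d_aux_logits)
        da = self.aux_drop.backward(da)
        da = self.aux_relu.backward(da)
        dfeat_a = self.aux_fc.backward(da)
        dg = self.fin_out.backward(d_final_logits)
        dg = self.fin_drop.backward(dg)
        dg = self.fin_relu.backward(dg)
        dfeat_g = self.fin_fc.backward(dg)
        dfeat = dfeat_a + dfeat_g
        n, hh, ww, c = self._gap_shape
        dh = np.broadcast_to(dfeat[:, None, None, :], (n, hh, ww, c)) / (hh * ww)
        dh = np.ascontiguousarray(dh)
        for b in reversed(self.blocks):
            dh = b.backward(dh)
        dh = self.stem_relu.backward(dh)
        dh = self.stem_bn.backward(dh)
        self.stem_conv.backward(dh)


def build_classifier(config: ModelConfig, seed: int = 0) -> TrainedClassifier:
    """A freshly initialised (untrained) classifier."""
    return TrainedClassifier(config, seed)


def dual_head_loss(
    final_probs: np.ndarray,
    aux_probs: np.ndarray,
    true_label: int | np.ndarray,
    weights: tuple[float, float] = (0.9, 0.1),
) -> float:
    """Weighted categorical cross-entropy over the two heads, in nats.

    ``0.9 * CE(final) + 0.1 * CE(aux)`` with natural-log cross-entropy;
    probabilities are clamped at 1e-12 so the loss stays finite.  Accepts a
    single (M,) pair of vectors or (N, M) batches (mean over the batch).
    """
    final_probs = np.atleast_2d(np.asarray(final_probs, dtype=np.float64))
    aux_probs = np.atleast_2d(np.asarray(aux_probs, dtype=np.float64))
    y = np.atleast_1d(np.asarray(true_label, dtype=np.int64))
    idx = np.arange(len(y))
    ce_final = -np.log(np.clip(final_probs[idx, y], _EPS, 1.0))
    ce_aux = -np.log(np.clip(aux_probs[idx, y], _EPS, 1.0))
    return float(np.mean(weights[0] * ce_final + weights[1] * ce_aux))


def patches_to_array(patches: Sequence[ImagePatch], size: int) -> np.ndarray:
    """Stack patches into a (N, size, size, 3) float32 batch scaled to [0, 1].

    Patches whose resolution differs from ``size`` are bilinearly resized,
    matching how 50 px segmentation tiles are upscaled before classification.
    """
    out = np.empty((len(patches), size, size, 3), dtype=np.float32)
    for i, p in enumerate(patches):
        px = p.pixels
        if px.shape[0] != size or px.shape[1] != size:
            px = np.asarray(
                Image.fromarray(px).resize((size, size), Image.BILINEAR), dtype=np.uint8
            )
        out[i] = px.astype(np.float32) / 255.0
    return out


def _stratified_val_split(
    labels: np.ndarray, val_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    train_idx: list[int] = []
    val_idx: list[int] = []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        n_val = max(1, int(round(val_fraction * len(idx))))
        if n_val >= len(idx):
            n_val = len(idx) - 1
        perm = rng.permutation(len(idx))
        val_idx.extend(idx[perm[:n_val]])
        train_idx.extend(idx[perm[n_val:]])
    return np.sort(np.array(train_idx)), np.sort(np.array(val_idx))


def train_classifier(
    model: TrainedClassifier, train_data: PatchDataset, config: TrainConfig
) -> TrainedClassifier:
    """Train in place with Adam and plateau-based learning-rate reduction.

    An internal stratified validation split of ``val_fraction`` monitors
    accuracy; whenever it fails to improve for ``lr_patience`` consecutive
    epochs the learning rate is multiplied by ``lr_reduce_factor``.  One
    history record is appended per epoch.
    """
    if len(train_data) == 0:
        raise ValueError("empty training data")
    labels = train_data.labels()
    if (labels < 0).any() or any(p.label is None for p in train_data):
        raise ValueError("all training patches must be labelled")
    if len(np.unique(labels)) < 2:
        raise ValueError("training data contains a single class")

    rng = np.random.default_rng(config.seed)
    x_all = patches_to_array(train_data.patches, model.config.input_size)
    tr_idx, va_idx = _stratified_val_split(labels, config.val_fraction, rng)
    x_tr, y_tr = x_all[tr_idx], labels[tr_idx]
    x_va, y_va = x_all[va_idx], labels[va_idx]

    opt = Adam(model._all_layers(), lr=config.learning_rate)
    drop_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    best_val = -np.inf
    stale = 0
    w = (config.final_weight, config.aux_weight)
    n = len(x_tr)
    for epoch in range(config.epochs):
        perm = rng.permutation(n)
        losses: list[float] = []
        correct = 0
        for start in range(0, n, config.train_batch):
            idx = perm[start : start + config.train_batch]
            xb, yb = x_tr[idx], y_tr[idx]
            feat = model.features(xb, train=True)
            # heads in training mode draw dropout masks from drop_rng
            a = model.aux_relu.forward(model.aux_fc.forward(feat, True), True)
            a = model.aux_drop.forward(a, True, rng=drop_rng)
            a_logits = model.aux_out.forward(a, True)
            g = model.fin_relu.forward(model.fin_fc.forward(feat, True), True)
            g = model.fin_drop.forward(g, True, rng=drop_rng)
            g_logits = model.fin_out.forward(g, True)
            p_fin, p_aux = softmax(g_logits), softmax(a_logits)
            losses.append(dual_head_loss(p_fin, p_aux, yb, weights=w))
            correct += int((p_fin.argmax(axis=1) == yb).sum())
            onehot = np.zeros_like(p_fin)
            onehot[np.arange(len(yb)), yb] = 1.0
            bsz = len(yb)
            model._backward(
                (w[0] / bsz) * (p_fin - onehot), (w[1] / bsz) * (p_aux - onehot)
            )
            opt.step()
        val_acc = _eval_accuracy(model, x_va, y_va, config.eval_batch)
        model.history.append(
            {
                "epoch": epoch,
                "lr": opt.lr,
                "train_loss": float(np.mean(losses)),
                "train_acc": correct / n,
                "val_acc": val_acc,
            }
        )
        if val_acc > best_val + 1e-12:
            best_val = val_acc
            stale = 0
        else:
            stale += 1
            if stale >= config.lr_patience:
                opt.lr *= config.lr_reduce_factor
                stale = 0
    return model


def _eval_accuracy(
    model: TrainedClassifier, x: np.ndarray, y: np.ndarray, batch: int
) -> float:
    if len(x) == 0:
        return float("nan")
    correct = 0
    for start in range(0, len(x), batch):
        probs = model.forward_batch(x[start : start + batch])
        correct += int((probs.argmax(axis=1) == y[start : start + batch]).sum())
    return correct / len(x)


def predict_single_pass(
    model: TrainedClassifier,
    patch: ImagePatch,
    stochastic: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One forward pass.  ``stochastic=True`` keeps dropout active (one
    variational weight sample); ``False`` disables it for a repeatable pass."""
    if patch.pixels.shape[2] != 3:
        raise ValueError("patch must have 3 channels")
    x = patches_to_array([patch], model.config.input_size)
    return model.forward_batch(x, stochastic=stochastic, rng=rng)[0]


# --------------------------------------------------------------- checkpoints

def save_checkpoint(model: TrainedClassifier, path: str | Path) -> None:
    arrays: dict[str, np.ndarray] = {}
    for i, layer in enumerate(model._all_layers()):
        for name, p in layer.params.items():
            arrays[f"{i}:{name}"] = p
        if isinstance(layer, BatchNorm2d):
            arrays[f"{i}:running_mean"] = layer.running_mean
            arrays[f"{i}:running_var"] = layer.running_var
    meta = {"config": asdict(model.config), "seed": model.seed, "history": model.history}
    arrays["_meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path: str | Path) -> TrainedClassifier:
    data = np.load(path)
    meta = json.loads(bytes(data["_meta"]).decode())
    cfg = meta["config"]
    cfg["filters"] = tuple(cfg["filters"])
    model = TrainedClassifier(ModelConfig(**cfg), seed=meta["seed"])
    model.history = meta["history"]
    for i, layer in enumerate(model._all_layers()):
        for name in layer.params:
            layer.params[name][...] = data[f"{i}:{name}"]
        if isinstance(layer, BatchNorm2d):
            layer.running_mean[...] = data[f"{i}:running_mean"]
            layer.running_var[...] = data[f"{i}:running_var"]
    return model
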