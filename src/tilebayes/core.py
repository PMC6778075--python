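"""Domain types and dataset IO for tile-based histopathology classification.

A *patch* (tile) is a small square RGB crop of a whole-slide image carrying a
single tissue-class label.  Datasets live on disk as one subdirectory per
class, each holding the image files of that class — the layout used by the
public colorectal tile collections (8 classes x 625 tiles of 150x150 px).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from PIL import Image

__all__ = [
    "ImagePatch",
    "ClassCatalog",
    "PatchDataset",
    "SplitSpec",
    "default_catalog",
    "load_tile_dataset",
    "save_tile_dataset",
    "stratified_holdout",
    "save_splits",
    "load_splits",
]

# Distinct, high-contrast colours for up to 10 classes (tab10-like).
_PALETTE: tuple[tuple[int, int, int], ...] = (
    (31, 119, 180),
    (255, 127, 14),
    (44, 160, 44),
    (214, 39, 40),
    (148, 103, 189),
    (140, 86, 75),
    (227, 119, 194),
    (127, 127, 127),
    (188, 189, 34),
    (23, 190, 207),
)


@dataclass(frozen=True)
class ImagePatch:
    """One RGB tile with an optional class label and a stable identifier."""

    id: str
    pixels: np.ndarray  # (H, W, 3) uint8
    label: int | None = None
    row: int | None = None  # grid coordinates when cut from a slide
    col: int | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"patch {self.id!r}: pixels must be HxWx3, got {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError(f"patch {self.id!r}: empty image")
        if px.dtype != np.uint8:
            raise ValueError(f"patch {self.id!r}: pixels must be uint8, got {px.dtype}")
        if self.label is not None and self.label < 0:
            raise ValueError(f"patch {self.id!r}: negative label")

    @property
    def size(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass(frozen=True)
class ClassCatalog:
    """Ordered class names with one display colour per class."""

    names: tuple[str, ...]
    colors: tuple[tuple[int, int, int], ...]

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("class names must be unique")
        if len(self.colors) != len(self.names):
            raise ValueError("need exactly one colour per class")

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)


def default_catalog(n_classes: int, names: Sequence[str] | None = None) -> ClassCatalog:
    """A catalog with generic names and distinct colours."""
    if names is None:
        names = tuple(f"class{i}" for i in range(n_classes))
    colors = tuple(_PALETTE[i % len(_PALETTE)] for i in range(n_classes))
    return ClassCatalog(names=tuple(names), colors=colors)


@dataclass
class PatchDataset:
    """A sequence of patches plus the class catalog they are labelled against."""

    patches: list[ImagePatch]
    catalog: ClassCatalog

    def __post_init__(self) -> None:
        m = len(self.catalog)
        for p in self.patches:
            if p.label is not None and p.label >= m:
                raise ValueError(f"patch {p.id!r}: label {p.label} >= {m} classes")
        ids = [p.id for p in self.patches]
        if len(set(ids)) != len(ids):
            raise ValueError("patch ids must be unique")

    def __len__(self) -> int:
        return len(self.patches)

    def __iter__(self) -> Iterator[ImagePatch]:
        return iter(self.patches)

    @property
    def n_classes(self) -> int:
        return len(self.catalog)

    @property
    def ids(self) -> list[str]:
        return [p.id for p in self.patches]

    def labels(self) -> np.ndarray:
        return np.array([p.label for p in self.patches], dtype=np.int64)

    def class_counts(self) -> np.ndarray:
        counts = np.zeros(self.n_classes, dtype=np.int64)
        for p in self.patches:
            if p.label is not None:
                counts[p.label] += 1
        return counts

    def by_id(self, patch_id: str) -> ImagePatch:
        for p in self.patches:
            if p.id == patch_id:
                return p
        raise KeyError(patch_id)

    def subset(self, ids: Sequence[str]) -> "PatchDataset":
        """Sub-dataset of the given ids, preserving this dataset's order."""
        wanted = set(ids)
        missing = wanted - set(self.ids)
        if missing:
            raise KeyError(f"unknown ids: {sorted(missing)[:5]}")
        return PatchDataset(
            patches=[p for p in self.patches if p.id in wanted], catalog=self.catalog
        )

    def restrict_classes(self, class_indices: Sequence[int]) -> "PatchDataset":
        """Keep only the given classes, relabelled to 0..len(class_indices)-1.

        Used e.g. for the binary tumour-vs-stroma restriction of a multi-class
        tile collection.
        """
        mapping = {c: i for i, c in enumerate(class_indices)}
        names = tuple(self.catalog.names[c] for c in class_indices)
        colors = tuple(self.catalog.colors[c] for c in class_indices)
        patches = [
            ImagePatch(id=p.id, pixels=p.pixels, label=mapping[p.label])
            for p in self.patches
            if p.label in mapping
        ]
        return PatchDataset(patches=patches, catalog=ClassCatalog(names, colors))


@dataclass(frozen=True)
class SplitSpec:
    """One train/test division by patch id."""

    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    seed: int

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test ids overlap")


_IMAGE_SUFFIXES = {".png", ".tif", ".tiff", ".jpg", ".jpeg"}


def load_tile_dataset(root_path: str | os.PathLike, catalog: ClassCatalog) -> PatchDataset:
    """Load a class-per-directory tile tree.

    Every image file under ``root/<class name>/`` becomes a labelled patch;
    ids are the POSIX relative paths, ordered lexicographically so that two
    loads of the same tree agree exactly.
    """
    root = Path(root_path)
    patches: list[ImagePatch] = []
    for label, name in enumerate(catalog.names):
        class_dir = root / name
        if not class_dir.is_dir():
            raise FileNotFoundError(f"missing class directory for {name!r}: {class_dir}")
        files = sorted(
            f for f in class_dir.iterdir() if f.suffix.lower() in _IMAGE_SUFFIXES
        )
        for f in files:
            try:
                with Image.open(f) as im:
                    px = np.asarray(im.convert("RGB"), dtype=np.uint8)
            except Exception as exc:  # noqa: BLE001 - report the offending file
                raise OSError(f"unreadable image file: {f}") from exc
            patches.append(ImagePatch(id=f"{name}/{f.name}", pixels=px, label=label))
    return PatchDataset(patches=patches, catalog=catalog)


def save_tile_dataset(dataset: PatchDataset, root_path: str | os.PathLike) -> None:
    """Write a dataset to a class-per-directory tree of PNG files.

    Ids of the form ``<class name>/<file>`` are written at exactly that
    relative path, so ``load_tile_dataset`` round-trips ids, labels and
    pixels.
    """
    root = Path(root_path)
    for name in dataset.catalog.names:
        (root / name).mkdir(parents=True, exist_ok=True)
    for p in dataset.patches:
        if p.label is None:
            raise ValueError(f"patch {p.id!r} has no label; cannot place in a class tree")
        name = dataset.catalog.names[p.label]
        base = Path(p.id).name
        if not Path(base).suffix:
            base += ".png"
        Image.fromarray(p.pixels).save(root / name / base)


def stratified_holdout(
    dataset: PatchDataset, k: int, seed: int
) -> list[SplitSpec]:
    """k seeded stratified holdout splits.

    Each split's test set holds ``ceil(n_c / k)`` patches per class, drawn
    without replacement under the seed; the train set is the complement.
    With 8 classes x 625 tiles and k=10 this gives the canonical 504-image
    test / 4496-image train division (63 and 562 per class).  The k splits
    are independent seeded draws, not a strict partition.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    by_class: dict[int, list[str]] = {}
    for p in dataset.patches:
        if p.label is None:
            raise ValueError(f"patch {p.id!r} is unlabelled")
        by_class.setdefault(p.label, []).append(p.id)
    for c, ids in by_class.items():
        if len(ids) < k:
            raise ValueError(
                f"class {dataset.catalog.names[c]!r} has {len(ids)} < k={k} members"
            )
    splits: list[SplitSpec] = []
    for fold in range(k):
        rng = np.random.default_rng(np.random.SeedSequence([seed, fold]))
        test: list[str] = []
        for c in sorted(by_class):
            ids = sorted(by_class[c])
            n_test = -(-len(ids) // k)  # ceil
            chosen = rng.choice(len(ids), size=n_test, replace=False)
            test.extend(ids[i] for i in sorted(chosen))
        test_set = set(test)
        train = tuple(i for i in dataset.ids if i not in test_set and i in _all_ids(by_class))
        splits.append(SplitSpec(train_ids=train, test_ids=tuple(sorted(test)), seed=seed))
    return splits


def _all_ids(by_class: dict[int, list[str]]) -> set[str]:
    out: set[str] = set()
    for ids in by_class.values():
        out.update(ids)
    return out


def save_splits(splits: Sequence[SplitSpec], path: str | os.PathLike) -> None:
    """Serialise splits to a plain-text three-column table (fold, id, role)."""
    with open(path, "w") as fh:
        fh.write("fold\tid\trole\n")
        for fold, s in enumerate(splits):
            for pid in s.train_ids:
                fh.write(f"{fold}\t{pid}\ttrain\n")
            for pid in s.test_ids:
                fh.write(f"{fold}\t{pid}\ttest\n")


def load_splits(path: str | os.PathLike, seed: int = 0) -> list[SplitSpec]:
    folds: dict[int, dict[str, list[str]]] = {}
    with open(path) as fh:
        header = fh.readline()
        if header.strip() != "fold\tid\trole":
            raise ValueError("not a split table")
        for line in fh:
            fold_s, pid, role = line.rstrip("\n").split("\t")
            folds.setdefault(int(fold_s), {"train": [], "test": []})[role].append(pid)
    return [
        SplitSpec(
            train_ids=tuple(folds[f]["train"]),
            test_ids=tuple(folds[f]["test"]),
            seed=seed,
        )
        for f in sorted(folds)
    ]
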