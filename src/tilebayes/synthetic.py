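"""Procedural generator of textured tiles and composite slides.

Stands in for stained-tissue tiles in every test: each class is an oriented
sinusoidal grating rendered between two class-specific colours, perturbed by
a smooth blob field and per-pixel Gaussian noise.  A *confusability* dial
blends the generative parameters of a designated pair of classes toward each
other, emulating the intrinsically ambiguous tissue pairs (e.g. simple
stroma vs complex stroma) that dominate real uncertainty: at confusability 1
the two classes' patch distributions coincide, so no classifier can separate
them and the residual uncertainty is purely aleatoric.

One master seed spawns an independent substream per patch, so generation is
reproducible regardless of order.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .core import ClassCatalog, ImagePatch, PatchDataset, default_catalog

__all__ = [
    "TextureSpec",
    "Region",
    "SlideLayout",
    "default_texture_specs",
    "generate_patch",
    "generate_dataset",
    "generate_slide",
    "checkerboard_layout",
]


@dataclass(frozen=True)
class TextureSpec:
    """Generative parameters for one class's texture."""

    class_index: int
    base_frequency: float  # grating cycles per tile
    orientation: float  # degrees
    palette: tuple[tuple[float, float, float], tuple[float, float, float]]
    noise_sd: float = 10.0  # 8-bit intensity units
    confusability: float = 0.0  # blend weight toward the partner class
    partner: "TextureSpec | None" = None

    def __post_init__(self) -> None:
        if self.base_frequency <= 0:
            raise ValueError("base_frequency must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.confusability <= 1.0:
            raise ValueError("confusability must lie in [0, 1]")
        if self.confusability > 0 and self.partner is None:
            raise ValueError("confusability > 0 requires a partner spec")

    def effective(self) -> "TextureSpec":
        """Parameters after blending toward the partner class.

        Convex combination of every generative parameter; confusability 1
        reproduces the partner's parameters exactly.
        """
        if self.partner is None or self.confusability == 0.0:
            return self
        c = self.confusability
        other = self.partner
        pal = tuple(
            tuple((1 - c) * a + c * b for a, b in zip(p_self, p_other))
            for p_self, p_other in zip(self.palette, other.palette)
        )
        return replace(
            self,
            base_frequency=(1 - c) * self.base_frequency + c * other.base_frequency,
            orientation=(1 - c) * self.orientation + c * other.orientation,
            palette=pal,  # type: ignore[arg-type]
            noise_sd=(1 - c) * self.noise_sd + c * other.noise_sd,
            confusability=0.0,
            partner=None,
        )


def default_texture_specs(
    n_classes: int,
    noise_sd: float = 10.0,
    confusable_pair: tuple[int, int] | None = None,
    confusability: float = 0.0,
) -> list[TextureSpec]:
    """One spec per class: distinct palette, frequency and orientation.

    When a confusable pair is given, each member is blended toward the
    other with weight ``confusability / 2``, i.e. toward the pair midpoint.
    The separation between the two effective parameter sets then shrinks by
    the factor ``1 - confusability``: at 0 the classes are untouched and at
    1 both render the identical midpoint texture, so no classifier can
    separate them and the residual uncertainty is purely aleatoric.
    """
    from .core import _PALETTE  # reuse the distinct colour table

    specs: list[TextureSpec] = []
    for c in range(n_classes):
        dark = tuple(0.35 * v for v in _PALETTE[c % len(_PALETTE)])
        light = tuple(min(255.0, 0.85 * v + 70) for v in _PALETTE[c % len(_PALETTE)])
        specs.append(
            TextureSpec(
                class_index=c,
                base_frequency=3.0 + 1.5 * c,
                orientation=180.0 * c / n_classes,
                palette=(dark, light),  # type: ignore[arg-type]
                noise_sd=noise_sd,
            )
        )
    if confusable_pair is not None and confusability > 0:
        a, b = confusable_pair
        base_a, base_b = specs[a], specs[b]
        # half-weight toward the partner = full weight toward the midpoint
        specs[a] = replace(base_a, confusability=confusability / 2, partner=base_b)
        specs[b] = replace(base_b, confusability=confusability / 2, partner=base_a)
    return specs


def _texture_field(
    spec: TextureSpec, height: int, width: int, rng: np.random.Generator
) -> np.ndarray:
    """Render one (height, width, 3) uint8 texture from effective parameters."""
    eff = spec.effective()
    theta = np.deg2rad(eff.orientation)
    yy, xx = np.mgrid[0:height, 0:width]
    scale = max(height, width)
    phase = rng.uniform(0.0, 2 * np.pi)
    grating = np.sin(
        2 * np.pi * eff.base_frequency * (xx * np.cos(theta) + yy * np.sin(theta)) / scale
        + phase
    )
    t = 0.5 * (grating + 1.0)  # [0, 1]
    lo = np.asarray(eff.palette[0], dtype=np.float64)
    hi = np.asarray(eff.palette[1], dtype=np.float64)
    img = lo + t[..., None] * (hi - lo)
    if eff.noise_sd > 0:
        # Smooth blob field: coarse Gaussian grid bilinearly upsampled.
        ch, cw = max(2, height // 8), max(2, width // 8)
        coarse = rng.normal(0.0, 1.0, size=(ch, cw))
        blobs = _bilinear_upsample(coarse, height, width)
        img += (2.0 * eff.noise_sd) * blobs[..., None]
        img += rng.normal(0.0, eff.noise_sd, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def _bilinear_upsample(field: np.ndarray, height: int, width: int) -> np.ndarray:
    h, w = field.shape
    yi = np.linspace(0, h - 1, height)
    xi = np.linspace(0, w - 1, width)
    y0 = np.floor(yi).astype(int)
    x0 = np.floor(xi).astype(int)
    y1 = np.minimum(y0 + 1, h - 1)
    x1 = np.minimum(x0 + 1, w - 1)
    fy = (yi - y0)[:, None]
    fx = (xi - x0)[None, :]
    a = field[np.ix_(y0, x0)]
    b = field[np.ix_(y0, x1)]
    c = field[np.ix_(y1, x0)]
    d = field[np.ix_(y1, x1)]
    return a * (1 - fy) * (1 - fx) + b * (1 - fy) * fx + c * fy * (1 - fx) + d * fy * fx


def generate_patch(
    spec: TextureSpec,
    size: int,
    rng_seed: int | np.random.SeedSequence,
    patch_id: str | None = None,
) -> ImagePatch:
    """One textured tile; deterministic for fixed (spec, size, seed)."""
    if size < 8:
        raise ValueError("size must be >= 8")
    rng = np.random.default_rng(rng_seed)
    px = _texture_field(spec, size, size, rng)
    pid = patch_id if patch_id is not None else f"class{spec.class_index}/seed{rng_seed}"
    return ImagePatch(id=pid, pixels=px, label=spec.class_index)


def generate_dataset(
    n_classes: int,
    n_per_class: int,
    size: int = 16,
    confusable_pair: tuple[int, int] | None = None,
    confusability: float = 0.0,
    noise_sd: float = 10.0,
    seed: int = 0,
    catalog: ClassCatalog | None = None,
) -> PatchDataset:
    """Balanced dataset of M x n_per_class textured tiles.

    Ids encode class, master seed and index (``class2/class2_s7_0013.png``)
    so that tile sets generated under different seeds never collide; one
    master seed spawns a substream per patch.
    """
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if catalog is None:
        catalog = default_catalog(n_classes)
    specs = default_texture_specs(
        n_classes,
        noise_sd=noise_sd,
        confusable_pair=confusable_pair,
        confusability=confusability,
    )
    streams = np.random.SeedSequence(seed).spawn(n_classes * n_per_class)
    patches: list[ImagePatch] = []
    for c in range(n_classes):
        name = catalog.names[c]
        for i in range(n_per_class):
            ss = streams[c * n_per_class + i]
            patches.append(
                generate_patch(
                    specs[c], size, ss, patch_id=f"{name}/{name}_s{seed}_{i:04d}.png"
                )
            )
    return PatchDataset(patches=patches, catalog=catalog)


@dataclass(frozen=True)
class Region:
    """A rectangular slide region: half-open pixel box [y, y+h) x [x, x+w)."""

    y: int
    x: int
    height: int
    width: int
    class_index: int


@dataclass(frozen=True)
class SlideLayout:
    """Canvas size plus rectangular regions that tile it exactly."""

    height: int
    width: int
    regions: tuple[Region, ...]

    def validate(self) -> None:
        cover = np.zeros((self.height, self.width), dtype=np.int32)
        for r in self.regions:
            if r.y < 0 or r.x < 0 or r.y + r.height > self.height or r.x + r.width > self.width:
                raise ValueError(f"region {r} exceeds the canvas")
            cover[r.y : r.y + r.height, r.x : r.x + r.width] += 1
        if (cover != 1).any():
            raise ValueError("regions must tile the canvas exactly (no gaps, no overlap)")

    def true_area_fractions(self, n_classes: int) -> np.ndarray:
        areas = np.zeros(n_classes)
        for r in self.regions:
            areas[r.class_index] += r.height * r.width
        return areas / (self.height * self.width)


def checkerboard_layout(
    height: int, width: int, n_cells: int, classes: tuple[int, int]
) -> SlideLayout:
    """n_cells x n_cells checkerboard of two classes."""
    ys = np.linspace(0, height, n_cells + 1, dtype=int)
    xs = np.linspace(0, width, n_cells + 1, dtype=int)
    regions = []
    for i in range(n_cells):
        for j in range(n_cells):
            cls = classes[(i + j) % 2]
            regions.append(
                Region(
                    y=int(ys[i]),
                    x=int(xs[j]),
                    height=int(ys[i + 1] - ys[i]),
                    width=int(xs[j + 1] - xs[j]),
                    class_index=cls,
                )
            )
    return SlideLayout(height=height, width=width, regions=tuple(regions))


def generate_slide(
    layout: SlideLayout,
    seed: int = 0,
    specs: Sequence[TextureSpec] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Render a composite slide and its ground-truth pixel mask.

    Returns ``(slide, mask)``: slide is (H, W, 3) uint8, mask is (H, W) int
    giving the true class of every pixel.
    """
    layout.validate()
    if specs is None:
        n_classes = max(r.class_index for r in layout.regions) + 1
        specs = default_texture_specs(n_classes)
    slide = np.zeros((layout.height, layout.width, 3), dtype=np.uint8)
    mask = np.zeros((layout.height, layout.width), dtype=np.int64)
    streams = np.random.SeedSequence(seed).spawn(len(layout.regions))
    for region, ss in zip(layout.regions, streams):
        rng = np.random.default_rng(ss)
        tex = _texture_field(specs[region.class_index], region.height, region.width, rng)
        slide[region.y : region.y + region.height, region.x : region.x + region.width] = tex
        mask[region.y : region.y + region.height, region.x : region.x + region.width] = (
            region.class_index
        )
    return slide, mask
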