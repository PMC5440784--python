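"""Seeded synthetic image classes with controlled richness and variability.

Four classes span the corners of the richness/variability plane that
separates artworks from other image categories:

``art_like``
    Dense multi-color, multi-orientation elements whose motif is resampled
    per tile — rich (many filters respond everywhere) *and* variable across
    the image.  Labeled as the positive ("art") class.
``pattern_like``
    One dense motif tiled over the whole image — rich but highly
    self-similar, like photographs of plant patterns or vegetation.
``sparse_like``
    A large homogeneous color field with only a small fraction of structured
    area, like a large-vista scene or a single object on a plain ground.
``noise``
    I.i.d. uniform pixels — a degenerate control that is maximally rich and
    maximally self-similar at the same time.

Tile sizes are class dependent at the 512 px canvas: texture-like classes
repeat at 32 px, so a perfectly tiled motif has a response-map period
(32/4 = 8 map px for an 11/4 conv) smaller than the pooling windows of the
mid-range grids and its per-filter maxima are nearly constant across
subregions — the variability measure collapses.  Art-like images instead
carry composition-scale regions of 64 px, larger than those windows, so
different subregions see genuinely different content and variability stays
high.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from matplotlib.colors import hsv_to_rgb

from .errors import ParameterError
from .images import ImageRGB

CLASSES = ("art_like", "pattern_like", "sparse_like", "noise")

#: Per-class default tile size: art-like images carry composition-scale
#: regions (64 px) larger than the repeat period of texture-like patterns.
_DEFAULT_TILE = {
    "art_like": 64,
    "pattern_like": 32,
    "sparse_like": 32,
    "noise": 32,
}

#: Per-class default tile-deviation probability.
_DEFAULT_VARIABILITY = {
    "art_like": 0.95,
    "pattern_like": 0.0,
    "sparse_like": 0.0,
    "noise": 0.0,
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic image.

    ``variability`` is the probability that a tile deviates from the base
    motif; ``element_density`` is the fraction of tiles carrying a structured
    element in the sparse class; ``noise`` is the SD of additive pixel noise
    (0 keeps degenerate cases, e.g. zero-density sparse images, exactly
    constant).
    """

    image_class: str
    size: int = 512
    tile: int | None = None
    palette_k: int = 6
    element_density: float = 0.05
    variability: float | None = None
    noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_class not in CLASSES:
            raise ParameterError(
                f"unknown class {self.image_class!r}; expected one of {CLASSES}"
            )
        if self.size < 64:
            raise ParameterError("size must be >= 64")
        if self.size % self.resolved_tile != 0:
            raise ParameterError(
                f"tile {self.resolved_tile} does not divide image size {self.size}"
            )
        if self.palette_k < 2:
            raise ParameterError("palette_k must be >= 2")
        v = self.resolved_variability
        if not 0.0 <= v <= 1.0:
            raise ParameterError("variability must lie in [0, 1]")
        if not 0.0 <= self.element_density <= 1.0:
            raise ParameterError("element_density must lie in [0, 1]")

    @property
    def resolved_tile(self) -> int:
        return _DEFAULT_TILE[self.image_class] if self.tile is None else self.tile

    @property
    def resolved_variability(self) -> float:
        if self.variability is None:
            return _DEFAULT_VARIABILITY[self.image_class]
        return self.variability


def _palette(rng: np.random.Generator, k: int) -> np.ndarray:
    """k saturated colors with hues spread around the circle (jittered)."""
    hues = (np.arange(k) / k + rng.uniform(0, 1)) % 1.0
    hues += rng.uniform(-0.04, 0.04, size=k)
    sat = rng.uniform(0.55, 0.95, size=k)
    val = rng.uniform(0.45, 0.95, size=k)
    return hsv_to_rgb(np.stack([hues % 1.0, sat, val], axis=1))


def _render_tile(rng: np.random.Generator, t: int, palette: np.ndarray) -> np.ndarray:
    """One dense motif tile: background + 3..6 bars/disks/gradient elements."""
    # each motif draws on a small sub-palette, so resampled tiles differ in
    # dominant color, not just in element layout
    colors = palette[rng.permutation(len(palette))][:4]
    canvas = np.empty((t, t, 3))
    canvas[:] = colors[0]
    yy, xx = np.mgrid[0:t, 0:t].astype(float)
    if rng.random() < 0.5:  # soft two-color gradient underlay
        theta = rng.uniform(0, np.pi)
        ramp = (xx * np.cos(theta) + yy * np.sin(theta)) / t
        ramp = (ramp - ramp.min()) / max(np.ptp(ramp), 1e-9)
        canvas = canvas * (1 - ramp[:, :, None]) + colors[1] * ramp[:, :, None]
    n_elem = rng.integers(3, 7)
    for e in range(n_elem):
        color = colors[1 + rng.integers(0, len(colors) - 1)]
        cx, cy = rng.uniform(0, t, size=2)
        if rng.random() < 0.6:  # oriented bar
            theta = rng.uniform(0, np.pi)
            length = rng.uniform(0.4, 1.2) * t
            thick = rng.uniform(0.06, 0.2) * t
            xr = (xx - cx) * np.cos(theta) + (yy - cy) * np.sin(theta)
            yr = -(xx - cx) * np.sin(theta) + (yy - cy) * np.cos(theta)
            mask = (np.abs(xr) < length / 2) & (np.abs(yr) < thick / 2)
        else:  # disk
            r = rng.uniform(0.08, 0.25) * t
            mask = (xx - cx) ** 2 + (yy - cy) ** 2 < r**2
        canvas[mask] = color
    return np.clip(canvas, 0.0, 1.0)


def _tiled_image(
    rng: np.random.Generator, size: int, tile: int, palette: np.ndarray, variability: float
) -> np.ndarray:
    base = _render_tile(rng, tile, palette)
    n = size // tile
    img = np.empty((size, size, 3))
    for i in range(n):
        for j in range(n):
            if variability > 0.0 and rng.random() < variability:
                img[i * tile : (i + 1) * tile, j * tile : (j + 1) * tile] = _render_tile(
                    rng, tile, palette
                )
            else:
                img[i * tile : (i + 1) * tile, j * tile : (j + 1) * tile] = base
    return img


def _sparse_image(rng: np.random.Generator, spec: SyntheticSpec, palette: np.ndarray) -> np.ndarray:
    img = np.empty((spec.size, spec.size, 3))
    img[:] = palette[rng.integers(0, len(palette))]
    tile = spec.resolved_tile
    n = spec.size // tile
    n_struct = int(round(spec.element_density * n * n))
    if n_struct == 0:
        return img  # constant-color image at zero density
    slots = rng.choice(n * n, size=n_struct, replace=False)
    for slot in slots:
        i, j = divmod(int(slot), n)
        img[i * tile : (i + 1) * tile, j * tile : (j + 1) * tile] = (
            _render_tile(rng, tile, palette)
        )
    return img


def generate(spec: SyntheticSpec) -> ImageRGB:
    """Render one image; deterministic given the spec (including its seed)."""
    rng = np.random.default_rng(spec.seed)
    palette = _palette(rng, spec.palette_k)
    if spec.image_class == "noise":
        img = rng.random((spec.size, spec.size, 3))
    elif spec.image_class == "sparse_like":
        img = _sparse_image(rng, spec, palette)
    else:
        img = _tiled_image(
            rng, spec.size, spec.resolved_tile, palette, spec.resolved_variability
        )
    if spec.noise > 0.0:
        img = np.clip(img + rng.normal(0.0, spec.noise, img.shape), 0.0, 1.0)
    return ImageRGB(img, source_path=f"<synthetic:{spec.image_class}:{spec.seed}>")


@dataclass
class LabeledImage:
    image: ImageRGB
    label: int  # 1 = art
    category: str
    image_id: str
    seed: int


def generate_labeled_set(
    n_per_class: int,
    seed: int,
    classes: Iterable[str] = CLASSES,
    size: int = 512,
    out_dir: str | Path | None = None,
) -> tuple[list[LabeledImage], pd.DataFrame]:
    """Balanced labeled image set: ``art_like`` is art, everything else is not.

    Returns the images and a manifest table; if ``out_dir`` is given, PNGs and
    ``manifest.csv`` are written there.
    """
    if n_per_class < 10:
        raise ParameterError("n_per_class must be >= 10")
    classes = tuple(classes)
    records: list[LabeledImage] = []
    rows = []
    for ci, cls in enumerate(classes):
        for i in range(n_per_class):
            child = int(np.random.SeedSequence([seed, ci, i]).generate_state(1)[0] % 2**31)
            spec = SyntheticSpec(image_class=cls, size=size, seed=child)
            img = generate(spec)
            image_id = f"{cls}_{i:04d}"
            rec = LabeledImage(img, int(cls == "art_like"), cls, image_id, child)
            records.append(rec)
            rows.append(
                {"image_id": image_id, "category": cls, "label": rec.label, "seed": child}
            )
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        from PIL import Image as PILImage

        for rec in records:
            arr = (rec.image.pixels * 255.0 + 0.5).astype(np.uint8)
            PILImage.fromarray(arr).save(out / f"{rec.image_id}.png")
        manifest.to_csv(out / "manifest.csv", index=False)
    return records, manifest
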