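"""Visual-field geometry, glyph rendering, and synthetic stimulus generation.

The simulated visual field is a square grayscale raster with a fixed
pixels-per-degree calibration.  Stimuli are dark glyphs on a uniform white
background, placed at a given size (arcmin) and horizontal eccentricity
(signed degrees; negative = left visual field).

Two families of glyphs are generated procedurally from stroke skeletons:

* labeled "digit-like" classes for supervised training, and
* novel target/distractor pairs for one-shot same/different testing, where
  each distractor shares the target's stroke skeleton with one stroke
  replaced.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from PIL import Image

__all__ = [
    "DEFAULT_FIELD_SPAN",
    "FieldCalibration",
    "StimulusSpec",
    "GlyphSet",
    "AugmentationPolicy",
    "VisualFieldImage",
    "LabeledImages",
    "OutOfFieldError",
    "arcmin_to_pixels",
    "blank_field",
    "render_stimulus",
    "make_novel_pairs",
    "make_training_classes",
    "build_training_set",
    "iter_training_set",
    "resize_raster",
    "save_png",
    "load_png",
    "save_glyphset",
    "load_glyphset",
    "read_idx",
    "mnist_glyphset",
]

#: Field span (degrees) covered by a 10-channel, factor-1.5 pyramid whose
#: smallest (foveal) crop is 225 px at 450 px/deg: 225 * 1.5**9 / 450.
DEFAULT_FIELD_SPAN = 225.0 * 1.5**9 / 450.0

_REF_GRID = 64  # reference resolution of glyph templates (px)


class OutOfFieldError(ValueError):
    """Raised when a stimulus does not fit inside the visual field."""


@dataclass(frozen=True)
class FieldCalibration:
    """Pixel/visual-angle calibration of the simulated visual field."""

    pixels_per_degree: float = 450.0
    field_span: float = DEFAULT_FIELD_SPAN

    def __post_init__(self) -> None:
        if self.pixels_per_degree <= 0 or self.field_span <= 0:
            raise ValueError("pixels_per_degree and field_span must be positive")
        if self.field_pixels <= 0:
            raise ValueError("calibration yields an empty field")

    @property
    def field_pixels(self) -> int:
        return int(np.floor(self.pixels_per_degree * self.field_span + 0.5))


@dataclass(frozen=True)
class StimulusSpec:
    """Placement of one glyph on the visual field.

    ``size`` is in arcmin; ``eccentricity`` is the signed horizontal offset
    in degrees (0 = fixation).
    """

    glyph_id: str
    size: float
    eccentricity: float = 0.0
    polarity: str = "dark-on-light"

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ValueError(f"stimulus size must be positive, got {self.size}")
        if self.polarity not in ("dark-on-light", "light-on-dark"):
            raise ValueError(f"unknown polarity {self.polarity!r}")

    def validate_bounds(self, calib: FieldCalibration) -> None:
        # size/120: arcmin -> degrees radius
        if abs(self.eccentricity) + self.size / 120.0 > calib.field_span / 2.0 + 1e-9:
            raise OutOfFieldError(
                f"stimulus {self.glyph_id!r} (size {self.size}', "
                f"ecc {self.eccentricity} deg) exceeds the "
                f"{calib.field_span:.2f} deg field"
            )


@dataclass
class GlyphSet:
    """A collection of glyph rasters with optional pairing and class labels.

    ``glyphs`` maps id -> 2-D float array in [0, 1] where 1 = ink.
    ``pairing`` maps each target id to its distractor id (one-shot sets).
    ``labels`` maps id -> integer class label (training sets).
    """

    glyphs: dict[str, np.ndarray]
    pairing: dict[str, str] = field(default_factory=dict)
    labels: dict[str, int] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        for tgt, dis in self.pairing.items():
            if tgt == dis:
                raise ValueError(f"glyph {tgt!r} paired with itself")
            if tgt not in self.glyphs or dis not in self.glyphs:
                raise ValueError(f"pairing references unknown glyph ({tgt!r}, {dis!r})")

    @property
    def target_ids(self) -> list[str]:
        return sorted(self.pairing)

    def distractor_of(self, glyph_id: str) -> str:
        return self.pairing[glyph_id]

    def __len__(self) -> int:
        return len(self.glyphs)


@dataclass(frozen=True)
class AugmentationPolicy:
    """Uniform size/eccentricity sampling for training-set generation."""

    size_range: tuple[float, float]
    eccentricity_range: tuple[float, float]
    samples_per_item: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size_range[0] > self.size_range[1] or self.size_range[0] <= 0:
            raise ValueError(f"invalid size range {self.size_range}")
        if self.eccentricity_range[0] > self.eccentricity_range[1]:
            raise ValueError(f"invalid eccentricity range {self.eccentricity_range}")
        if self.samples_per_item < 1:
            raise ValueError("samples_per_item must be >= 1")


@dataclass
class VisualFieldImage:
    """Square grayscale raster of the simulated visual field, values in [0, 1]."""

    pixels: np.ndarray
    calibration: FieldCalibration
    provenance: StimulusSpec | str = "blank"
    background: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError("visual field raster must be square")
        if self.pixels.shape[0] != self.calibration.field_pixels:
            raise ValueError(
                f"raster side {self.pixels.shape[0]} != calibrated "
                f"field_pixels {self.calibration.field_pixels}"
            )


@dataclass
class LabeledImages:
    """A labeled collection of rendered visual-field images."""

    images: list[VisualFieldImage]
    labels: np.ndarray
    specs: list[StimulusSpec]

    def __len__(self) -> int:
        return len(self.images)

    def __iter__(self) -> Iterator[tuple[VisualFieldImage, int]]:
        return zip(self.images, self.labels.tolist())


# ---------------------------------------------------------------------------
# geometry


def arcmin_to_pixels(size: float, calib: FieldCalibration) -> int:
    """Convert a stimulus size in arcmin to pixels (30' -> 225 px at 450 px/deg)."""
    if size <= 0:
        raise ValueError(f"size must be positive, got {size}")
    return int(np.floor(size / 60.0 * calib.pixels_per_degree + 0.5))


def resize_raster(arr: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    """Anti-aliased resize: area averaging when shrinking, bilinear when growing."""
    arr = np.asarray(arr, dtype=np.float32)
    h, w = out_shape
    if (h, w) == arr.shape:
        return arr.copy()
    shrinking = h * w < arr.shape[0] * arr.shape[1]
    resample = Image.Resampling.BOX if shrinking else Image.Resampling.BILINEAR
    img = Image.fromarray(arr, mode="F").resize((w, h), resample=resample)
    return np.asarray(img, dtype=np.float32)


def render_stimulus(
    spec: StimulusSpec, glyphs: GlyphSet, calib: FieldCalibration
) -> VisualFieldImage:
    """Render one glyph on a uniform white field.

    The glyph raster is resampled to ``arcmin_to_pixels(spec.size)`` and its
    center placed at a horizontal offset of ``eccentricity * ppd`` pixels
    (rounded to the nearest pixel) from the field center.  Rendering is
    deterministic: identical specs give bit-identical images, and changing
    only the eccentricity gives an exact integer translation.
    """
    spec.validate_bounds(calib)
    if spec.glyph_id not in glyphs.glyphs:
        raise KeyError(f"glyph {spec.glyph_id!r} not in glyph set")

    size_px = arcmin_to_pixels(spec.size, calib)
    ink = resize_raster(glyphs.glyphs[spec.glyph_id], (size_px, size_px))
    ink = np.clip(ink, 0.0, 1.0)

    n = calib.field_pixels
    fieldpix = np.ones((n, n), dtype=np.float32)
    cx = n // 2 + int(np.floor(spec.eccentricity * calib.pixels_per_degree + 0.5))
    cy = n // 2
    top, left = cy - size_px // 2, cx - size_px // 2
    if top < 0 or left < 0 or top + size_px > n or left + size_px > n:
        raise OutOfFieldError(
            f"rendered stimulus [{left}:{left + size_px}] px falls outside the "
            f"{n}-px field"
        )
    region = fieldpix[top : top + size_px, left : left + size_px]
    fieldpix[top : top + size_px, left : left + size_px] = np.minimum(region, 1.0 - ink)
    if spec.polarity == "light-on-dark":
        fieldpix = 1.0 - fieldpix
    return VisualFieldImage(fieldpix, calib, provenance=spec,
                            background=0.0 if spec.polarity == "light-on-dark" else 1.0)


def blank_field(calib: FieldCalibration, background: float = 1.0) -> VisualFieldImage:
    n = calib.field_pixels
    return VisualFieldImage(
        np.full((n, n), background, dtype=np.float32), calib, "blank", background
    )


# ---------------------------------------------------------------------------
# procedural glyphs


def _segment_distance(px: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Distance from points ``px`` (N, 2) to segment a-b."""
    ab = b - a
    denom = float(ab @ ab)
    if denom < 1e-12:
        return np.linalg.norm(px - a, axis=1)
    t = np.clip((px - a) @ ab / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(px - proj, axis=1)


def _sample_stroke(rng: np.random.Generator) -> np.ndarray:
    """One stroke as a polyline (control points in unit coordinates)."""
    kind = rng.integers(0, 3)
    if kind == 0:  # straight line
        pts = rng.uniform(0.0, 1.0, size=(2, 2))
    elif kind == 1:  # corner (two joined segments)
        pts = rng.uniform(0.0, 1.0, size=(3, 2))
    else:  # quadratic bezier, sampled
        ctrl = rng.uniform(0.0, 1.0, size=(3, 2))
        t = np.linspace(0.0, 1.0, 9)[:, None]
        pts = (1 - t) ** 2 * ctrl[0] + 2 * (1 - t) * t * ctrl[1] + t**2 * ctrl[2]
    return pts


def _rasterize(strokes: Sequence[np.ndarray], width: float, grid: int = _REF_GRID) -> np.ndarray:
    """Rasterize strokes with soft (anti-aliased) edges; content fills the grid."""
    allpts = np.concatenate(strokes, axis=0)
    lo, hi = allpts.min(axis=0), allpts.max(axis=0)
    span = np.maximum(hi - lo, 1e-6)
    # normalize the skeleton so ink (skeleton +/- width) spans the full cell
    margin = width
    norm = [(s - lo) / span * (1.0 - 2 * margin) + margin for s in strokes]

    coords = (np.arange(grid, dtype=np.float64) + 0.5) / grid
    yy, xx = np.meshgrid(coords, coords, indexing="ij")
    px = np.stack([xx.ravel(), yy.ravel()], axis=1)

    aa = 1.2 / grid  # anti-alias ramp of ~1 px
    ink = np.zeros(grid * grid)
    for s in norm:
        d = np.full(grid * grid, np.inf)
        for a, b in zip(s[:-1], s[1:]):
            d = np.minimum(d, _segment_distance(px, a, b))
        ink = np.maximum(ink, np.clip((width - d) / aa + 0.5, 0.0, 1.0))
    return ink.reshape(grid, grid).astype(np.float32)


def _stroke_set(rng: np.random.Generator, n_strokes: int) -> list[np.ndarray]:
    return [_sample_stroke(rng) for _ in range(n_strokes)]


def make_novel_pairs(n_pairs: int, seed: int, grid: int = _REF_GRID) -> GlyphSet:
    """Generate ``n_pairs`` novel target glyphs, each with a structurally
    similar distractor (shared stroke skeleton, one stroke replaced).

    Deterministic in ``seed``; glyph ids are ``t00``/``d00``, ``t01``/``d01``, ...
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rng = np.random.default_rng(seed)
    glyphs: dict[str, np.ndarray] = {}
    pairing: dict[str, str] = {}
    for i in range(n_pairs):
        n_strokes = int(rng.integers(2, 5))
        width = float(rng.uniform(0.08, 0.12))
        strokes = _stroke_set(rng, n_strokes)
        tid, did = f"t{i:02d}", f"d{i:02d}"
        glyphs[tid] = _rasterize(strokes, width, grid)
        perturbed = list(strokes)
        perturbed[int(rng.integers(0, n_strokes))] = _sample_stroke(rng)
        glyphs[did] = _rasterize(perturbed, width, grid)
        pairing[tid] = did
    return GlyphSet(glyphs, pairing, seed=seed)


def make_training_classes(
    n_classes: int, items_per_class: int, seed: int, grid: int = _REF_GRID
) -> GlyphSet:
    """Labeled digit-like glyph classes: each class is a base stroke skeleton,
    items are jittered copies of it."""
    if n_classes < 1 or items_per_class < 1:
        raise ValueError("n_classes and items_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    glyphs: dict[str, np.ndarray] = {}
    labels: dict[str, int] = {}
    for c in range(n_classes):
        n_strokes = int(rng.integers(2, 4))
        width = float(rng.uniform(0.08, 0.12))
        base = _stroke_set(rng, n_strokes)
        for j in range(items_per_class):
            jittered = [s + rng.normal(0.0, 0.06, size=s.shape) for s in base]
            w = width * float(rng.uniform(0.75, 1.25))
            gid = f"c{c:02d}_i{j:03d}"
            glyphs[gid] = _rasterize(jittered, w, grid)
            labels[gid] = c
    return GlyphSet(glyphs, labels=labels, seed=seed)


def iter_training_set(
    glyphs: GlyphSet, policy: AugmentationPolicy, calib: FieldCalibration
) -> Iterator[tuple[VisualFieldImage, int, StimulusSpec]]:
    """Stream (image, label, spec) training samples: every labeled glyph is
    rendered ``samples_per_item`` times at sizes and eccentricities drawn
    uniformly from the policy ranges.  Deterministic in ``policy.seed``."""
    if glyphs.labels is None:
        raise ValueError("training glyph set must carry class labels")
    worst = abs(max(policy.eccentricity_range, key=abs)) + policy.size_range[1] / 120.0
    if worst > calib.field_span / 2.0 + 1e-9:
        raise OutOfFieldError(
            f"augmentation policy (max ecc+radius {worst:.2f} deg) exceeds the "
            f"{calib.field_span:.2f} deg field"
        )
    rng = np.random.default_rng(policy.seed)
    for gid in sorted(glyphs.labels):
        for _ in range(policy.samples_per_item):
            size = float(rng.uniform(*policy.size_range))
            ecc = float(rng.uniform(*policy.eccentricity_range))
            spec = StimulusSpec(gid, size=size, eccentricity=ecc)
            yield render_stimulus(spec, glyphs, calib), glyphs.labels[gid], spec


def build_training_set(
    glyphs: GlyphSet, policy: AugmentationPolicy, calib: FieldCalibration
) -> LabeledImages:
    """Materialized version of :func:`iter_training_set`.  For large sets
    prefer the iterator: full-field rasters are big."""
    images, labels, specs = [], [], []
    for img, label, spec in iter_training_set(glyphs, policy, calib):
        images.append(img)
        labels.append(label)
        specs.append(spec)
    return LabeledImages(images, np.asarray(labels, dtype=np.int64), specs)


# ---------------------------------------------------------------------------
# I/O


def save_png(arr: np.ndarray, path: str | Path) -> None:
    a = np.clip(np.asarray(arr, dtype=np.float32), 0.0, 1.0)
    Image.fromarray((a * 255.0 + 0.5).astype(np.uint8), mode="L").save(path)


def load_png(path: str | Path) -> np.ndarray:
    img = Image.open(path).convert("L")
    return np.asarray(img, dtype=np.float32) / 255.0


def save_glyphset(gs: GlyphSet, directory: str | Path) -> Path:
    """Write glyph PNGs plus a JSON manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for gid, arr in gs.glyphs.items():
        save_png(arr, directory / f"{gid}.png")
    manifest = {
        "glyph_ids": sorted(gs.glyphs),
        "pairing": gs.pairing,
        "labels": gs.labels,
        "seed": gs.seed,
    }
    path = directory / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def load_glyphset(directory: str | Path) -> GlyphSet:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    glyphs = {gid: load_png(directory / f"{gid}.png") for gid in manifest["glyph_ids"]}
    labels = manifest["labels"]
    if labels is not None:
        labels = {k: int(v) for k, v in labels.items()}
    return GlyphSet(glyphs, manifest["pairing"], labels, manifest["seed"])


def mnist_glyphset(
    images: np.ndarray, labels: np.ndarray, items_per_class: int, seed: int = 0
) -> GlyphSet:
    """Build a labeled GlyphSet from MNIST-style arrays ((N, H, W) uint8
    intensities, ink high) by sampling ``items_per_class`` digits per class."""
    images = np.asarray(images)
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    glyphs: dict[str, np.ndarray] = {}
    out_labels: dict[str, int] = {}
    for c in sorted(set(labels.tolist())):
        idx = np.flatnonzero(labels == c)
        take = rng.choice(idx, size=min(items_per_class, idx.size), replace=False)
        for j, i in enumerate(sorted(take.tolist())):
            gid = f"m{c}_{j:04d}"
            glyphs[gid] = images[i].astype(np.float32) / 255.0
            out_labels[gid] = int(c)
    return GlyphSet(glyphs, labels=out_labels, seed=seed)


def read_idx(path: str | Path) -> np.ndarray:
    """Read an IDX-format array (the MNIST container format)."""
    data = Path(path).read_bytes()
    zero1, zero2, dtype_code, ndim = struct.unpack(">BBBB", data[:4])
    if zero1 != 0 or zero2 != 0:
        raise ValueError(f"{path}: not an IDX file")
    dtypes = {0x08: np.uint8, 0x09: np.int8, 0x0B: ">i2", 0x0C: ">i4",
              0x0D: ">f4", 0x0E: ">f8"}
    if dtype_code not in dtypes:
        raise ValueError(f"{path}: unknown IDX dtype 0x{dtype_code:02x}")
    shape = struct.unpack(f">{ndim}I", data[4 : 4 + 4 * ndim])
    arr = np.frombuffer(data[4 + 4 * ndim :], dtype=dtypes[dtype_code])
    return arr.reshape(shape)
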