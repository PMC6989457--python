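"""Foveated input sampling: multi-scale centered crops on a common grid.

Channel ``k`` is a centered square crop of span ``round(smallest_span *
growth_factor**k)`` pixels, resampled (anti-aliased) to ``common_grid``
pixels per side.  The image center is thereby seen at every resolution
while the periphery appears only in the coarse channels.  Crops larger
than the rendered field are padded with the background value.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .stimuli import FieldCalibration, VisualFieldImage, resize_raster

__all__ = [
    "PyramidSpec",
    "CropPyramid",
    "crop_spans",
    "channel_resolution",
    "sample_pyramid",
    "save_pyramid",
    "load_pyramid",
]


@dataclass(frozen=True)
class PyramidSpec:
    """Geometry of the centered-crop pyramid.

    Defaults: 10 channels growing exponentially by a factor of 1.5 from a
    225-px (0.5 deg at 450 px/deg) foveal crop, so the largest crop spans
    225 * 1.5**9 = 8650 px, approximately 19.2 deg.
    """

    n_channels: int = 10
    growth_factor: float = 1.5
    smallest_span: int = 225
    common_grid: int = 225

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.growth_factor < 1.0:
            raise ValueError("growth_factor must be >= 1")
        if self.smallest_span < 1 or self.common_grid < 1:
            raise ValueError("spans must be positive")
        spans = crop_spans(self)
        if any(b <= a for a, b in zip(spans, spans[1:])):
            raise ValueError("crop spans must be strictly increasing")


@dataclass
class CropPyramid:
    """Ordered multi-scale crops of one visual-field image.

    ``channels`` has shape (n_channels, common_grid, common_grid); channel 0
    is the highest-resolution (foveal) crop.
    """

    channels: np.ndarray
    spans_deg: list[float]
    source_calibration: FieldCalibration
    background: float = 1.0

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=np.float32)
        if self.channels.ndim != 3 or self.channels.shape[1] != self.channels.shape[2]:
            raise ValueError("channels must be (n, grid, grid)")
        if self.channels.shape[0] != len(self.spans_deg):
            raise ValueError("spans_deg length mismatch")

    @property
    def n_channels(self) -> int:
        return self.channels.shape[0]


def crop_spans(spec: PyramidSpec) -> list[int]:
    """Pixel span of each channel: round(smallest_span * factor**k)."""
    return [
        int(np.floor(spec.smallest_span * spec.growth_factor**k + 0.5))
        for k in range(spec.n_channels)
    ]


def channel_resolution(
    spec: PyramidSpec, k: int, pixels_per_degree: float = 450.0
) -> float:
    """Effective sampling resolution of channel ``k`` in px/deg:
    common_grid / (span(k) / ppd)."""
    spans = crop_spans(spec)
    if not 0 <= k < spec.n_channels:
        raise IndexError(f"channel {k} out of range 0..{spec.n_channels - 1}")
    return spec.common_grid * pixels_per_degree / spans[k]


def sample_pyramid(image: VisualFieldImage, spec: PyramidSpec) -> CropPyramid:
    """Extract the centered multi-scale crops of ``image``.

    Channels whose span exceeds the rendered field are padded with the
    image background value, so an image rendered on a small field behaves
    exactly like the same stimulus on a full-span field.

    Only the non-background bounding box of the image is actually resampled
    (the rest of each crop is uniform background), so the cost scales with
    the stimulus, not the field.
    """
    pix = image.pixels
    n = pix.shape[0]
    c = n // 2
    grid = spec.common_grid
    bg = float(image.background)
    channels = np.full((spec.n_channels, grid, grid), bg, dtype=np.float32)
    spans = crop_spans(spec)
    ppd = image.calibration.pixels_per_degree

    content = np.abs(pix - bg) > 1e-6
    rows = np.flatnonzero(content.any(axis=1))
    cols = np.flatnonzero(content.any(axis=0))
    if rows.size:
        r0, r1 = int(rows[0]), int(rows[-1]) + 1
        c0, c1 = int(cols[0]), int(cols[-1]) + 1
        for k, s in enumerate(spans):
            lo = c - s // 2  # crop window is [lo, lo + s) in both axes
            f = grid / s
            rr0, rr1 = max(r0, lo), min(r1, lo + s)
            cc0, cc1 = max(c0, lo), min(c1, lo + s)
            if rr1 <= rr0 or cc1 <= cc0:
                continue  # stimulus entirely outside this crop
            oh = max(1, int(np.floor((rr1 - rr0) * f + 0.5)))
            ow = max(1, int(np.floor((cc1 - cc0) * f + 0.5)))
            orr = min(grid - oh, max(0, int(np.floor((rr0 - lo) * f + 0.5))))
            occ = min(grid - ow, max(0, int(np.floor((cc0 - lo) * f + 0.5))))
            region = resize_raster(pix[rr0:rr1, cc0:cc1], (oh, ow))
            channels[k, orr : orr + oh, occ : occ + ow] = region
    spans_deg = [s / ppd for s in spans]
    return CropPyramid(channels, spans_deg, image.calibration, bg)


def save_pyramid(pyr: CropPyramid, stem: str | Path) -> tuple[Path, Path]:
    """Write ``<stem>.npy`` (stacked channel tensor) and ``<stem>.json``
    (spans in degrees, calibration, background)."""
    stem = Path(stem)
    tensor_path = stem.with_suffix(".npy")
    meta_path = stem.with_suffix(".json")
    np.save(tensor_path, pyr.channels)
    meta = {
        "spans_deg": pyr.spans_deg,
        "pixels_per_degree": pyr.source_calibration.pixels_per_degree,
        "field_span": pyr.source_calibration.field_span,
        "background": pyr.background,
    }
    meta_path.write_text(json.dumps(meta, indent=2))
    return tensor_path, meta_path


def load_pyramid(stem: str | Path) -> CropPyramid:
    stem = Path(stem)
    channels = np.load(stem.with_suffix(".npy"))
    meta = json.loads(stem.with_suffix(".json").read_text())
    calib = FieldCalibration(meta["pixels_per_degree"], meta["field_span"])
    return CropPyramid(channels, meta["spans_deg"], calib, meta["background"])
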