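"""Deterministic preprocessing of raw images into training-ready tensors.

The pipeline standardises heterogeneous grayscale-convertible medical images
(fundus photographs, CT slices) into small quantized tensors a DCGAN can
train on:

1. tensorize (float, 0–255 intensity scale)
2. resize to ``target_size`` (bilinear, anti-aliased)
3. grayscale (ITU-R BT.601 luminance weights)
4. CLAHE on the 8-bit image (clip-limited per-tile histogram equalization)
5. normalise to [0, 1]
6. gamma correction ``x -> x**gamma``
7. quantize to ``n_levels`` gray shades (round-half-up)
8. rescale to [-1, 1] via ``x -> 2x - 1``

The result is byte-identical for identical input and configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import ConfigError, InvalidInputError

log = logging.getLogger(__name__)

__all__ = [
    "RawImage",
    "ProcessedImage",
    "PipelineConfig",
    "to_grayscale",
    "apply_clahe",
    "quantize_levels",
    "preprocess",
    "preprocess_dataset",
    "load_image_dir",
]

#: ITU-R BT.601 luminance weights for RGB -> gray conversion.
BT601 = np.array([0.299, 0.587, 0.114])


@dataclass
class RawImage:
    """An unprocessed image: H x W (or H x W x 3) intensities, 8-bit scale."""

    pixels: np.ndarray
    label: int | None = None
    source_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.label is not None and self.label not in (0, 1, 2, 3, 4):
            raise InvalidInputError(f"severity label must be 0..4, got {self.label}")


@dataclass
class ProcessedImage:
    """A (S, S, 1) float32 image in [-1, 1] with at most ``n_levels`` values."""

    pixels: np.ndarray
    label: int | None = None
    source_id: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float32)


@dataclass
class PipelineConfig:
    target_size: int = 128
    clahe_clip_limit: float = 2.0
    clahe_tile_grid: tuple[int, int] = (8, 8)
    gamma: float = 1.2
    n_levels: int = 16

    def __post_init__(self):
        s = self.target_size
        if s < 16 or (s & (s - 1)) != 0:
            raise ConfigError(f"target_size must be a power of two >= 16, got {s}")
        if self.n_levels < 2:
            raise ConfigError("n_levels must be >= 2")
        if self.clahe_clip_limit <= 0:
            raise ConfigError("clahe_clip_limit must be positive")
        if self.gamma <= 0:
            raise ConfigError("gamma must be positive")


def to_grayscale(img: RawImage) -> RawImage:
    """Collapse RGB to luminance with BT.601 weights; 1-channel passthrough."""
    px = img.pixels
    if px.ndim == 2 or (px.ndim == 3 and px.shape[2] == 1):
        return img
    if px.ndim == 3 and px.shape[2] == 3:
        gray = px.astype(np.float64) @ BT601
        return RawImage(gray, img.label, img.source_id, img.meta)
    raise InvalidInputError(f"expected 1 or 3 channels, got shape {px.shape}")


def _clahe_tile_luts(img8: np.ndarray, grid: tuple[int, int], clip_limit: float):
    """Per-tile clipped-histogram equalization LUTs (and the tile geometry)."""
    gh, gw = grid
    h, w = img8.shape
    th, tw = -(-h // gh), -(-w // gw)
    padded = np.pad(img8, ((0, th * gh - h), (0, tw * gw - w)), mode="edge")
    area = th * tw
    clip = max(int(clip_limit * area / 256.0), 1)
    luts = np.empty((gh, gw, 256), dtype=np.float64)
    for ty in range(gh):
        for tx in range(gw):
            tile = padded[ty * th : (ty + 1) * th, tx * tw : (tx + 1) * tw]
            hist = np.bincount(tile.ravel(), minlength=256).astype(np.float64)
            excess = np.maximum(hist - clip, 0).sum()
            hist = np.minimum(hist, clip) + excess / 256.0
            luts[ty, tx] = np.round(np.cumsum(hist) * 255.0 / area)
    return luts, th, tw


def apply_clahe(img, clip_limit: float = 2.0, tile_grid: tuple[int, int] = (8, 8)):
    """Contrast-limited adaptive histogram equalization on an 8-bit image.

    Accepts a uint8 array or a unit-scaled float array (converted to 8-bit,
    equalized, and scaled back).  Per-tile histograms are clipped at
    ``clip_limit * tile_area / 256`` counts with the excess redistributed
    uniformly; pixel values are mapped by bilinear interpolation between the
    four surrounding tile mappings, so tile-center pixels take exactly their
    own tile's mapping.
    """
    if clip_limit <= 0:
        raise ConfigError("clip_limit must be positive")
    arr = np.asarray(img)
    if arr.ndim == 3 and arr.shape[2] == 1:
        return apply_clahe(arr[:, :, 0], clip_limit, tile_grid)[:, :, None]
    if arr.ndim != 2:
        raise InvalidInputError("apply_clahe expects a single-channel image")
    as_float = np.issubdtype(arr.dtype, np.floating)
    img8 = np.clip(np.round(arr * 255.0 if as_float else arr), 0, 255).astype(np.uint8)

    luts, th, tw = _clahe_tile_luts(img8, tile_grid, clip_limit)
    gh, gw = luts.shape[:2]
    h, w = img8.shape
    fy = (np.arange(h) + 0.5) / th - 0.5
    fx = (np.arange(w) + 0.5) / tw - 0.5
    iy0 = np.clip(np.floor(fy).astype(int), 0, gh - 1)
    ix0 = np.clip(np.floor(fx).astype(int), 0, gw - 1)
    iy1 = np.minimum(iy0 + 1, gh - 1)
    ix1 = np.minimum(ix0 + 1, gw - 1)
    wy = np.clip(fy - iy0, 0.0, 1.0)[:, None]
    wx = np.clip(fx - ix0, 0.0, 1.0)[None, :]

    v = img8
    yy0, yy1 = iy0[:, None], iy1[:, None]
    xx0, xx1 = ix0[None, :], ix1[None, :]
    out = (
        (1 - wy) * (1 - wx) * luts[yy0, xx0, v]
        + (1 - wy) * wx * luts[yy0, xx1, v]
        + wy * (1 - wx) * luts[yy1, xx0, v]
        + wy * wx * luts[yy1, xx1, v]
    )
    out8 = np.clip(np.round(out), 0, 255).astype(np.uint8)
    return out8.astype(arr.dtype) / 255.0 if as_float else out8


def quantize_levels(img01: np.ndarray, n_levels: int = 16) -> np.ndarray:
    """Project unit-scaled values onto ``{k/(n_levels-1)}`` by round-half-up."""
    x = np.asarray(img01, dtype=np.float64)
    if x.size and (x.min() < 0 or x.max() > 1):
        raise InvalidInputError("quantize_levels expects values in [0, 1]")
    if n_levels < 2:
        raise ConfigError("n_levels must be >= 2")
    m = n_levels - 1
    return np.floor(x * m + 0.5) / m


def _is_degenerate(px: np.ndarray) -> str | None:
    if px.ndim not in (2, 3):
        return f"unsupported ndim {px.ndim}"
    if px.shape[0] < 8 or px.shape[1] < 8:
        return f"too small {px.shape[:2]}"
    if not np.all(np.isfinite(px)):
        return "non-finite pixel values"
    if float(px.max()) == float(px.min()):
        return "constant image"
    return None


def preprocess(raw: RawImage, cfg: PipelineConfig | None = None) -> ProcessedImage | None:
    """Run the full pipeline; returns ``None`` (skip sentinel) for degenerate input."""
    from skimage.transform import resize

    cfg = cfg or PipelineConfig()
    px = np.asarray(raw.pixels, dtype=np.float64)
    reason = _is_degenerate(px)
    if reason is not None:
        log.warning("skipping image %r: %s", raw.source_id, reason)
        return None
    # tensorize on the 0-255 intensity scale
    if np.issubdtype(np.asarray(raw.pixels).dtype, np.floating) and px.max() <= 1.0:
        px = px * 255.0
    s = cfg.target_size
    if px.ndim == 3:
        px = resize(px, (s, s, px.shape[2]), order=1, anti_aliasing=True,
                    preserve_range=True)
    else:
        px = resize(px, (s, s), order=1, anti_aliasing=True, preserve_range=True)
    gray = to_grayscale(RawImage(px, raw.label, raw.source_id)).pixels
    if gray.ndim == 3:
        gray = gray[:, :, 0]
    eq = apply_clahe(np.clip(np.round(gray), 0, 255).astype(np.uint8),
                     cfg.clahe_clip_limit, cfg.clahe_tile_grid)
    x01 = eq.astype(np.float64) / 255.0
    x01 = x01**cfg.gamma
    xq = quantize_levels(x01, cfg.n_levels)
    out = (2.0 * xq - 1.0).astype(np.float32)[:, :, None]
    return ProcessedImage(out, label=raw.label, source_id=raw.source_id)


def preprocess_dataset(raws, cfg: PipelineConfig | None = None):
    """Preprocess a list of RawImage; returns (processed, n_skipped)."""
    out, skipped = [], 0
    for raw in raws:
        p = preprocess(raw, cfg)
        if p is None:
            skipped += 1
        else:
            out.append(p)
    return out, skipped


def load_image_dir(directory, labels_csv=None) -> list[RawImage]:
    """Load PNG/JPEG images (sorted by filename) with optional severity labels.

    ``labels_csv`` has columns ``filename,label``; files without an entry stay
    unlabeled.
    """
    import pandas as pd

    directory = Path(directory)
    labels: dict[str, int] = {}
    if labels_csv is not None:
        df = pd.read_csv(labels_csv)
        labels = {str(r.filename): int(r.label) for r in df.itertuples()}
    out = []
    for f in sorted(directory.iterdir()):
        if f.suffix.lower() not in (".png", ".jpg", ".jpeg"):
            continue
        arr = np.asarray(Image.open(f))
        out.append(RawImage(arr, label=labels.get(f.name), source_id=f.name))
    return out
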