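"""Labeled phantom image generation for the two imaging domains.

The framework's study design needs two morphologically distinct grayscale
domains: a severity-graded retinal-fundus-like domain for federated
fine-tuning, and a CT-like abdominal domain for transfer pretraining.  These
phantoms are statistical stand-ins, not anatomical simulations: the fundus
domain has a circular field of view, a radial vignette, dark vessel-like
random walks, and a severity-dependent Poisson number of lesions (bright
"exudate" discs and dark "hemorrhage" blobs); the CT domain has an elliptical
body outline with a few smooth interior ellipses and no lesions.  The two
domains share low-level statistics (smooth grayscale anatomy on a dark
background) but not high-level structure, mirroring the transfer premise of
pretraining on one modality before fine-tuning on another.

Default severity model: expected lesion count lambda(label) = 3 * label, so
grade 0 images carry no lesions and the count grows with severity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .errors import ConfigError, InvalidInputError
from .pipeline import RawImage

__all__ = ["PhantomConfig", "make_phantom_image", "make_dataset", "save_dataset_png"]


def default_lesion_rate(label: int) -> float:
    """Expected lesion count per image: 3 per severity grade."""
    return 3.0 * label


@dataclass
class PhantomConfig:
    n_images: int = 100
    image_size: int = 128
    label_probs: Sequence[float] = (0.2, 0.2, 0.2, 0.2, 0.2)
    lesion_rate: Callable[[int], float] = default_lesion_rate
    domain: str = "fundus"
    seed: int = 0

    def __post_init__(self):
        p = np.asarray(self.label_probs, dtype=float)
        if p.shape != (5,) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ConfigError("label_probs must be a nonnegative 5-vector summing to 1")
        if self.lesion_rate(0) != 0:
            raise ConfigError("lesion_rate must satisfy lambda(0) = 0")
        rates = [self.lesion_rate(l) for l in range(5)]
        if any(b < a for a, b in zip(rates, rates[1:])):
            raise ConfigError("lesion_rate must be nondecreasing in the label")
        if self.domain not in ("fundus", "ct"):
            raise ConfigError(f"unknown domain {self.domain!r}")


def _disc_mask(size: int, cy: float, cx: float, r: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


def _fundus(label: int, size: int, rng: np.random.Generator,
            lesion_rate: Callable[[int], float]):
    s = size
    c = (s - 1) / 2.0
    fov_r = 0.48 * s
    yy, xx = np.mgrid[0:s, 0:s]
    r2 = ((yy - c) ** 2 + (xx - c) ** 2) / fov_r**2
    fov = r2 <= 1.0

    img = np.full((s, s), 8.0)  # dark exterior, constant
    base = 150.0 + rng.uniform(-15, 15)
    vignette = base * (1.0 - 0.45 * r2)
    img[fov] = vignette[fov]
    img[fov] += rng.normal(0.0, 4.0, size=int(fov.sum()))

    # vessel-like random walks from near the centre outward
    for _ in range(rng.integers(2, 5)):
        y, x = c + rng.uniform(-2, 2), c + rng.uniform(-2, 2)
        ang = rng.uniform(0, 2 * np.pi)
        for _ in range(int(1.2 * s)):
            ang += rng.normal(0.0, 0.3)
            y += np.sin(ang)
            x += np.cos(ang)
            iy, ix = int(round(y)), int(round(x))
            if not (0 <= iy < s and 0 <= ix < s) or not fov[iy, ix]:
                break
            img[max(iy - 1, 0) : iy + 1, max(ix - 1, 0) : ix + 1] *= 0.55

    # severity-dependent lesions inside the field of view
    n_lesions = int(rng.poisson(lesion_rate(label)))
    scale = s / 128.0
    for _ in range(n_lesions):
        rad = max(rng.uniform(2.0, 5.0) * scale, 1.0)
        rho = np.sqrt(rng.uniform(0, 0.64)) * fov_r  # within 0.8 of fov radius
        theta = rng.uniform(0, 2 * np.pi)
        ly, lx = c + rho * np.sin(theta), c + rho * np.cos(theta)
        m = _disc_mask(s, ly, lx, rad)
        if rng.random() < 0.5:
            img[m] = np.minimum(img[m] + rng.uniform(70, 100), 255)  # bright exudate
        else:
            img[m] *= rng.uniform(0.2, 0.4)  # dark hemorrhage
    img[~fov] = 8.0
    return img, n_lesions


def _ct(size: int, rng: np.random.Generator):
    s = size
    c = (s - 1) / 2.0
    yy, xx = np.mgrid[0:s, 0:s]
    a, b = 0.46 * s, 0.36 * s * rng.uniform(0.9, 1.1)
    body = ((xx - c) / a) ** 2 + ((yy - c) / b) ** 2 <= 1.0
    outline = (((xx - c) / a) ** 2 + ((yy - c) / b) ** 2 <= 1.0) & (
        ((xx - c) / (a * 0.93)) ** 2 + ((yy - c) / (b * 0.93)) ** 2 > 1.0
    )
    img = np.full((s, s), 5.0)
    img[body] = 90.0 + rng.normal(0.0, 5.0, size=int(body.sum()))
    img[outline] = 220.0  # bright rim like subcutaneous fat / skin line
    for _ in range(rng.integers(3, 7)):
        oa = rng.uniform(0.06, 0.22) * s
        ob = rng.uniform(0.06, 0.22) * s
        oy = c + rng.uniform(-0.2, 0.2) * s
        ox = c + rng.uniform(-0.25, 0.25) * s
        organ = ((xx - ox) / oa) ** 2 + ((yy - oy) / ob) ** 2 <= 1.0
        organ &= body
        img[organ] = np.clip(img[organ] * rng.uniform(0.5, 1.6), 0, 255)
    img[~body] = 5.0
    return img


def make_phantom_image(label: int, image_size: int, rng: np.random.Generator,
                       domain: str = "fundus",
                       lesion_rate: Callable[[int], float] = default_lesion_rate) -> RawImage:
    """Draw one phantom; lesion count is recorded in ``meta['n_lesions']``."""
    if label not in (0, 1, 2, 3, 4):
        raise InvalidInputError(f"label must be in 0..4, got {label}")
    if domain == "fundus":
        img, n_lesions = _fundus(label, image_size, rng, lesion_rate)
    elif domain == "ct":
        img, n_lesions = _ct(image_size, rng), 0
    else:
        raise ConfigError(f"unknown domain {domain!r}")
    px = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return RawImage(px, label=label, meta={"n_lesions": n_lesions})


def make_dataset(cfg: PhantomConfig) -> list[RawImage]:
    """Generate ``cfg.n_images`` labeled phantoms, reproducible from the seed."""
    if cfg.n_images < 0:
        raise ConfigError("n_images must be >= 0")
    rng = np.random.default_rng(cfg.seed)
    labels = rng.choice(5, size=cfg.n_images, p=np.asarray(cfg.label_probs, dtype=float))
    out = []
    for i, label in enumerate(labels):
        img = make_phantom_image(int(label), cfg.image_size, rng,
                                 domain=cfg.domain, lesion_rate=cfg.lesion_rate)
        img.source_id = f"{cfg.domain}-{cfg.seed}-{i:05d}"
        out.append(img)
    return out


def save_dataset_png(images: list[RawImage], out_dir) -> Path:
    """Write PNGs plus a ``labels.csv`` sidecar consumable by the pipeline."""
    import pandas as pd
    from PIL import Image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for img in images:
        name = f"{img.source_id}.png"
        Image.fromarray(img.pixels).save(out_dir / name)
        if img.label is not None:
            rows.append({"filename": name, "label": img.label})
    pd.DataFrame(rows).to_csv(out_dir / "labels.csv", index=False)
    return out_dir
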