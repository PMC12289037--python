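"""Quantitative evaluation: realism score, FID, and loss-variance analysis.

The realism score is the mean probability a frozen, centrally-trained
discriminator assigns to the generator's samples.  FID is the Fréchet
distance between Gaussians fitted to embedded real and synthetic images,
``||mu_r - mu_f||^2 + Tr(S_r + S_f - 2 (S_r S_f)^{1/2})``.  The embedding is
pluggable: production users can supply any pretrained feature extractor
(e.g. an InceptionV3 wrapper with grayscale replicated to three channels);
the built-in :class:`RandomConvEmbedding` is a fixed-seed random-projection
convolutional feature map, which needs no downloaded weights and still
separates distributions by their low-order spatial statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from . import nn
from .errors import InvalidInputError

__all__ = ["realism_score", "fid", "loss_variance", "RandomConvEmbedding", "VarianceStats"]


def realism_score(generator: nn.Sequential, discriminator: nn.Sequential,
                  n: int = 256, seed: int = 0, batch: int = 64) -> float:
    """Mean D(G(z)) over ``n`` fixed-seed latent draws, in eval mode."""
    if n < 1:
        raise InvalidInputError("n must be >= 1")
    g_size = generator.arch.get("out_size")
    d_size = discriminator.arch.get("in_size")
    if g_size is not None and d_size is not None and g_size != d_size:
        raise InvalidInputError(
            f"generator outputs {g_size}x{g_size} but discriminator expects {d_size}")
    total, count = 0.0, 0
    rng = np.random.default_rng(seed)
    dim = generator.arch.get("latent_dim", 200)
    for start in range(0, n, batch):
        bs = min(batch, n - start)
        z = rng.standard_normal((bs, dim))
        probs = discriminator.forward(generator.forward(z, train=False), train=False)
        total += float(probs.sum())
        count += bs
    return total / count


def fid(real_features: np.ndarray, fake_features: np.ndarray,
        cov_reg: float = 1e-6) -> float:
    """Fréchet distance between Gaussian fits of two feature clouds.

    Sample means and covariances (n-1 denominator); ``cov_reg * I`` is added
    to both covariances before the matrix square root for numerical safety.
    Tiny negative residuals (above -1e-6) are truncated to zero.
    """
    xr = np.asarray(real_features, dtype=np.float64)
    xf = np.asarray(fake_features, dtype=np.float64)
    if xr.ndim != 2 or xf.ndim != 2 or xr.shape[1] != xf.shape[1]:
        raise InvalidInputError("feature arrays must be 2-D with equal dimension")
    if xr.shape[0] < 2 or xf.shape[0] < 2:
        raise InvalidInputError("need at least 2 samples per side")
    if not (np.all(np.isfinite(xr)) and np.all(np.isfinite(xf))):
        raise InvalidInputError("features must be finite")
    mu_r, mu_f = xr.mean(axis=0), xf.mean(axis=0)
    d = xr.shape[1]
    sig_r = np.cov(xr, rowvar=False).reshape(d, d) + cov_reg * np.eye(d)
    sig_f = np.cov(xf, rowvar=False).reshape(d, d) + cov_reg * np.eye(d)
    covmean = linalg.sqrtm(sig_r @ sig_f)
    if np.iscomplexobj(covmean):
        covmean = covmean.real
    val = float(np.sum((mu_r - mu_f) ** 2) + np.trace(sig_r + sig_f - 2.0 * covmean))
    if -1e-6 < val < 0.0:
        val = 0.0
    return val


class RandomConvEmbedding:
    """Deterministic random-convolution feature map satisfying the embedding
    contract (same input -> same features; d >= 2).

    Two fixed-seed 3x3 convolution layers with ReLU and stride-2 subsampling;
    features are the per-channel spatial mean and standard deviation of the
    final maps, giving d = 2 * channels.
    """

    def __init__(self, channels: tuple[int, int] = (8, 16), seed: int = 1234):
        rng = np.random.default_rng(seed)
        self.conv1 = nn.Conv2D(1, channels[0], rng, kernel=3, stride=2, w_std=0.5)
        self.conv2 = nn.Conv2D(channels[0], channels[1], rng, kernel=3, stride=2, w_std=0.5)
        self.d = 2 * channels[1]
        self.identifier = f"random-conv-{channels[0]}x{channels[1]}-seed{seed}"

    def __call__(self, images: np.ndarray) -> np.ndarray:
        x = np.asarray(images, dtype=np.float64)
        if x.ndim == 3:
            x = x[:, :, :, None]
        h = np.maximum(self.conv1.forward(x), 0.0)
        h = np.maximum(self.conv2.forward(h), 0.0)
        return np.concatenate([h.mean(axis=(1, 2)), h.std(axis=(1, 2))], axis=1)


@dataclass
class VarianceStats:
    mean: float
    sd: float


def loss_variance(series_per_config: dict) -> dict[str, VarianceStats]:
    """Sample mean and sample sd (n-1 denominator) of each loss series."""
    report = {}
    for key, series in series_per_config.items():
        arr = np.asarray(series, dtype=np.float64)
        if arr.size < 2:
            raise InvalidInputError(f"series {key!r} needs length >= 2")
        report[key] = VarianceStats(float(arr.mean()), float(arr.std(ddof=1)))
    return report
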