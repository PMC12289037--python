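"""DCGAN construction, adversarial losses, and single-client training.

Architecture (at full 128x128 scale): the generator projects a 200-d standard
normal latent vector through a dense layer to an 8x8x256 stem and upsamples
with four stride-2 4x4 transposed-conv blocks of (128, 64, 32, 1) filters —
batch norm + ReLU on hidden blocks, tanh on the output.  The discriminator
mirrors it with stride-2 convs of (32, 64, 128, 256) filters, LeakyReLU(0.2),
batch norm from the second block on, then flatten -> dense(1) -> sigmoid.

For smaller output sizes the 8x8x256 stem is kept and blocks are dropped from
the wide end, so ``out_size = 8 * 2**n_blocks``; e.g. 32x32 uses generator
filters (32, 1) and discriminator filters (32, 64).

Training uses the non-saturating generator loss -E[log D(G(z))] and a
label-smoothed discriminator loss (real target 0.9 by default) with
Adam(lr=2e-4, beta1=0.5), the standard DCGAN stability recipe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .errors import ConfigError, InvalidInputError

__all__ = [
    "TrainConfig",
    "build_generator",
    "build_discriminator",
    "generator_loss",
    "discriminator_loss",
    "sample_latent",
    "generate_images",
    "local_train",
]

#: filter ladders at the full 128-pixel scale
G_FILTERS_128 = (128, 64, 32, 1)
D_FILTERS_128 = (32, 64, 128, 256)
STEM = 8          # spatial side of the dense stem
STEM_CH = 256     # channels of the dense stem
EPS = 1e-7        # probability clamp before logs


@dataclass
class TrainConfig:
    batch_size: int = 64
    learning_rate: float = 2e-4
    adam_beta1: float = 0.5
    adam_beta2: float = 0.999
    label_smooth: float = 0.9
    latent_dim: int = 200
    local_epochs: int = 5
    image_size: int = 128
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.label_smooth <= 1):
            raise ConfigError("label_smooth must be in (0, 1]")
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be positive")


def _n_blocks(size: int) -> int:
    if size < 16 or size > 128 or size & (size - 1):
        raise ConfigError(f"image size must be a power of two in [16, 128], got {size}")
    return int(np.log2(size // STEM))


def build_generator(latent_dim: int = 200, out_size: int = 128,
                    seed: int = 0) -> nn.Sequential:
    """DCGAN generator producing (out_size, out_size, 1) tanh images."""
    nb = _n_blocks(out_size)
    filters = G_FILTERS_128[-nb:]
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = [
        nn.Dense(latent_dim, STEM * STEM * STEM_CH, rng),
        nn.Reshape((STEM, STEM, STEM_CH)),
        nn.BatchNorm(STEM_CH),
        nn.ReLU(),
    ]
    c_in = STEM_CH
    for i, c_out in enumerate(filters):
        layers.append(nn.ConvTranspose2D(c_in, c_out, rng))
        if i < len(filters) - 1:
            layers += [nn.BatchNorm(c_out), nn.ReLU()]
        else:
            layers.append(nn.Tanh())
        c_in = c_out
    arch = {"net": "generator", "latent_dim": latent_dim, "out_size": out_size}
    return nn.Sequential(layers, tag="generator", arch=arch)


def build_discriminator(in_size: int = 128, seed: int = 0) -> nn.Sequential:
    """DCGAN discriminator mapping (in_size, in_size, 1) to P(real)."""
    nb = _n_blocks(in_size)
    filters = D_FILTERS_128[:nb]
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = []
    c_in = 1
    for i, c_out in enumerate(filters):
        layers.append(nn.Conv2D(c_in, c_out, rng))
        if i > 0:
            layers.append(nn.BatchNorm(c_out))
        layers.append(nn.LeakyReLU(0.2))
        c_in = c_out
    layers += [
        nn.Flatten(),
        nn.Dense(STEM * STEM * filters[-1], 1, rng),
        nn.Sigmoid(),
    ]
    arch = {"net": "discriminator", "in_size": in_size}
    return nn.Sequential(layers, tag="discriminator", arch=arch)


def _clamp(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=np.float64)
    if p.size == 0 or not np.all(np.isfinite(p)):
        raise InvalidInputError("probabilities must be finite and non-empty")
    return np.clip(p, EPS, 1.0 - EPS)


def generator_loss(fake_probs) -> float:
    """Non-saturating loss: -mean(log D(G(z)))."""
    return float(-np.mean(np.log(_clamp(fake_probs))))


def discriminator_loss(real_probs, fake_probs, smooth: float = 0.9) -> float:
    """Label-smoothed BCE: real target ``smooth``, fake target 0."""
    pr = _clamp(real_probs)
    pf = _clamp(fake_probs)
    real_term = -np.mean(smooth * np.log(pr) + (1.0 - smooth) * np.log(1.0 - pr))
    fake_term = -np.mean(np.log(1.0 - pf))
    return float(real_term + fake_term)


def sample_latent(rng: np.random.Generator, n: int, latent_dim: int = 200) -> np.ndarray:
    return rng.standard_normal((n, latent_dim))


def generate_images(gen: nn.Sequential, n: int, seed: int, batch: int = 64) -> np.ndarray:
    """Sample n images in eval mode (running batch-norm statistics)."""
    rng = np.random.default_rng(seed)
    dim = gen.arch.get("latent_dim", 200)
    out = []
    for start in range(0, n, batch):
        z = sample_latent(rng, min(batch, n - start), dim)
        out.append(gen.forward(z, train=False))
    return np.concatenate(out, axis=0)


def _d_prob_grad(p: np.ndarray, target: float) -> np.ndarray:
    """d/dp of the mean BCE against ``target`` (clamped p)."""
    pc = np.clip(p, EPS, 1 - EPS)
    return (-target / pc + (1.0 - target) / (1.0 - pc)) / p.shape[0]


def local_train(g_weights: nn.WeightSet, d_weights: nn.WeightSet, images: np.ndarray,
                cfg: TrainConfig, seed: int | None = None):
    """Train one client's G and D for ``cfg.local_epochs`` epochs.

    ``images`` is an (n, S, S, 1) array in [-1, 1].  Per batch: one
    discriminator step (real batch against the smoothed target, a fresh fake
    batch against 0), then one generator step on a fresh latent batch.
    Returns (g_weights', d_weights', trace) where trace is a dict of
    per-batch generator/discriminator losses.  Deterministic given the seed.
    """
    if images.ndim != 4 or images.shape[0] == 0:
        raise InvalidInputError("local_train needs a non-empty (n, S, S, 1) image array")
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)

    gen = build_generator(cfg.latent_dim, cfg.image_size)
    disc = build_discriminator(cfg.image_size)
    gen.set_weights(g_weights)
    disc.set_weights(d_weights)
    opt_g = nn.Adam(gen, cfg.learning_rate, cfg.adam_beta1, cfg.adam_beta2)
    opt_d = nn.Adam(disc, cfg.learning_rate, cfg.adam_beta1, cfg.adam_beta2)

    trace = {"g_loss": [], "d_loss": []}
    n = images.shape[0]
    for _ in range(cfg.local_epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            real = images[order[start : start + cfg.batch_size]]
            bs = real.shape[0]

            # --- discriminator step
            z = sample_latent(rng, bs, cfg.latent_dim)
            fake = gen.forward(z, train=True)
            p_real = disc.forward(real, train=True)
            disc.backward(_d_prob_grad(p_real, cfg.label_smooth))
            g_real = {k: lyr.grads[name].copy() for k, lyr, name in disc.parameters()}
            p_fake = disc.forward(fake, train=True)
            disc.backward(_d_prob_grad(p_fake, 0.0))
            for key, lyr, name in disc.parameters():
                lyr.grads[name] = lyr.grads[name] + g_real[key]
            opt_d.step()
            d_loss = discriminator_loss(p_real[:, 0], p_fake[:, 0], cfg.label_smooth)

            # --- generator step (fresh latents; gradients flow through D)
            z = sample_latent(rng, bs, cfg.latent_dim)
            fake = gen.forward(z, train=True)
            p_fake = disc.forward(fake, train=True)
            dp = -1.0 / np.clip(p_fake, EPS, 1 - EPS) / bs
            dfake = disc.backward(dp)
            gen.backward(dfake)
            opt_g.step()
            g_loss = generator_loss(p_fake[:, 0])

            if not (np.isfinite(d_loss) and np.isfinite(g_loss)):
                raise FloatingPointError(
                    f"non-finite loss (G={g_loss}, D={d_loss}) at step "
                    f"{len(trace['g_loss'])}; trace so far: {trace}")
            trace["d_loss"].append(d_loss)
            trace["g_loss"].append(g_loss)
    return gen.get_weights(), disc.get_weights(), trace
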