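"""Privacy-leakage audit for a trained generator and its training data.

Four attacks plus a composite risk score:

* **Membership inference** — a small convolutional classifier is trained to
  distinguish real training images from the generator's synthetic outputs;
  held-out accuracy and AUC quantify distinguishability.  (Caveat: this is
  the training-real-versus-synthetic design, not the classic member-versus-
  non-member formulation; an attack that separates the two distributions may
  reflect generator quality as much as memorization.)
* **Model inversion** — latent vectors are optimized by gradient descent to
  reconstruct given target images; low best-case reconstruction error means
  the generator can be steered back onto training-like samples.
* **Empirical epsilon** — a differential-privacy-style leakage bound read off
  the membership attack's ROC curve: ``max_t ln(TPR_t / FPR_t)`` with rates
  floored at 1/n (the one-sided distinguishability bound; a two-sided variant
  adding ``ln((1-FPR)/(1-TPR))`` is available via ``two_sided=True``).
* **Minimum-distance analysis** — for each synthetic image, the per-pixel RMS
  distance (in [-1, 1] space, so values are resolution-independent) to its
  nearest real image; near-zero distances flag copied training samples.

The composite score maps these onto 0-100 (higher = more leakage) with an
explicit, configurable convex combination.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.metrics import roc_auc_score, roc_curve

from . import nn
from .errors import ConfigError, InvalidInputError

__all__ = [
    "AttackConfig",
    "PrivacyReport",
    "membership_inference",
    "model_inversion",
    "estimate_epsilon",
    "epsilon_from_roc",
    "min_distance_analysis",
    "privacy_risk_score",
    "run_privacy_audit",
]

DEFAULT_RISK_WEIGHTS = {"mia_auc": 0.4, "mia_accuracy": 0.2,
                        "inversion": 0.2, "min_dist": 0.2}


@dataclass
class AttackConfig:
    split: float = 0.5                 # train fraction for the attack classifier
    attack_channels: tuple[int, int] = (8, 16)
    attack_epochs: int = 5
    attack_lr: float = 1e-3
    attack_batch: int = 32
    inversion_steps: int = 500
    inversion_step_size: float = 0.05
    inversion_restarts: int = 5
    distance_norm: str = "rms"
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.split < 1):
            raise ConfigError("split must be in (0, 1)")
        if self.inversion_steps < 1 or self.inversion_restarts < 1:
            raise ConfigError("inversion steps and restarts must be >= 1")


@dataclass
class PrivacyReport:
    mia_accuracy: float
    mia_auc: float
    inversion_loss: float
    epsilon_hat: float
    min_dist_mean: float
    min_dist_min: float
    min_dist_max: float
    composite_score: float = 0.0
    schema_version: int = 1

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PrivacyReport":
        return cls(**json.loads(text))


def _attack_net(size: int, channels: tuple[int, int], seed: int) -> nn.Sequential:
    rng = np.random.default_rng(seed)
    c1, c2 = channels
    side = size // 4
    layers = [
        nn.Conv2D(1, c1, rng), nn.LeakyReLU(0.2),
        nn.Conv2D(c1, c2, rng), nn.LeakyReLU(0.2),
        nn.Flatten(), nn.Dense(side * side * c2, 1, rng), nn.Sigmoid(),
    ]
    return nn.Sequential(layers, tag="discriminator", arch={"in_size": size})


def membership_inference(train_real: np.ndarray, synthetic: np.ndarray,
                         cfg: AttackConfig | None = None) -> tuple[float, float]:
    """Train the attack classifier; return held-out (accuracy, AUC)."""
    acc, auc, _, _ = _membership_inference_full(train_real, synthetic, cfg)
    return acc, auc


def _membership_inference_full(train_real, synthetic, cfg=None):
    cfg = cfg or AttackConfig()
    real = np.asarray(train_real, dtype=np.float64)
    fake = np.asarray(synthetic, dtype=np.float64)
    if real.shape[0] < 20 or fake.shape[0] < 20:
        raise InvalidInputError("need at least 20 images per side")
    ratio = max(real.shape[0], fake.shape[0]) / min(real.shape[0], fake.shape[0])
    if ratio > 10:
        raise InvalidInputError("class imbalance exceeds 10:1; attack undefined")

    rng = np.random.default_rng(cfg.seed)
    x = np.concatenate([real, fake])
    y = np.concatenate([np.ones(real.shape[0]), np.zeros(fake.shape[0])])
    # stratified split: shuffle within each class, take the first split-fraction
    train_idx, test_idx = [], []
    for cls in (0, 1):
        idx = rng.permutation(np.flatnonzero(y == cls))
        cut = int(round(cfg.split * idx.size))
        train_idx.extend(idx[:cut])
        test_idx.extend(idx[cut:])
    train_idx = np.array(train_idx)
    test_idx = np.array(test_idx)

    net = _attack_net(x.shape[1], cfg.attack_channels, cfg.seed + 1)
    opt = nn.Adam(net, cfg.attack_lr, beta1=0.5)
    for _ in range(cfg.attack_epochs):
        order = rng.permutation(train_idx)
        for start in range(0, order.size, cfg.attack_batch):
            bidx = order[start : start + cfg.attack_batch]
            p = net.forward(x[bidx], train=True)
            t = y[bidx][:, None]
            pc = np.clip(p, 1e-7, 1 - 1e-7)
            net.backward((-t / pc + (1 - t) / (1 - pc)) / bidx.size)
            opt.step()
    scores = net.forward(x[test_idx], train=False)[:, 0]
    truth = y[test_idx]
    accuracy = float(np.mean((scores >= 0.5) == truth))
    auc = float(roc_auc_score(truth, scores))
    return accuracy, auc, truth, scores


def model_inversion(generator, targets: np.ndarray, cfg: AttackConfig | None = None,
                    return_traces: bool = False):
    """Best-case latent-space reconstruction error, averaged over targets.

    For each target, ``cfg.inversion_restarts`` random latent initializations
    are descended for ``cfg.inversion_steps`` plain gradient steps minimizing
    pixel MSE; the best final loss across restarts is kept.  ``generator``
    needs ``forward(z, train=False)``, ``backward(dy)`` and an ``arch`` dict
    with ``latent_dim``.
    """
    cfg = cfg or AttackConfig()
    targets = np.asarray(targets, dtype=np.float64)
    if targets.ndim == 3:
        targets = targets[:, :, :, None]
    rng = np.random.default_rng(cfg.seed)
    dim = generator.arch.get("latent_dim", 200)
    npx = int(np.prod(targets.shape[1:]))
    best_losses, traces = [], []
    for target in targets:
        best = np.inf
        best_trace = None
        for _ in range(cfg.inversion_restarts):
            z = rng.standard_normal((1, dim))
            trace = []
            running_best = np.inf
            for _ in range(cfg.inversion_steps):
                out = generator.forward(z, train=False)
                resid = out - target[None]
                loss = float(np.mean(resid**2))
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"inversion diverged (loss={loss}); trace: {trace[-5:]}")
                running_best = min(running_best, loss)
                trace.append(running_best)
                dz = generator.backward(2.0 * resid / npx)
                z = z - cfg.inversion_step_size * dz
            if running_best < best:
                best, best_trace = running_best, trace
        best_losses.append(best)
        traces.append(best_trace)
    mean_loss = float(np.mean(best_losses))
    return (mean_loss, traces) if return_traces else mean_loss


def epsilon_from_roc(tpr, fpr, floor: float = 0.0, two_sided: bool = False) -> float:
    """Empirical epsilon from ROC operating points, rates floored at ``floor``."""
    tpr = np.clip(np.asarray(tpr, dtype=np.float64), floor, 1.0)
    fpr = np.clip(np.asarray(fpr, dtype=np.float64), floor, 1.0)
    ratios = [np.log(tpr / fpr)]
    if two_sided:
        comp = np.clip(1.0 - np.asarray(fpr), floor, 1.0) / np.clip(
            1.0 - np.asarray(tpr), floor, 1.0)
        ratios.append(np.log(comp))
    eps = max(float(np.max(r)) for r in ratios)
    return max(eps, 0.0)


def estimate_epsilon(y_true, scores, two_sided: bool = False) -> float:
    """Epsilon-hat from membership-attack scores via the ROC curve.

    TPR is floored at 1/n_positives and FPR at 1/n_negatives, so a perfect
    but finite-sample attack yields ln(n) rather than infinity.  A degenerate
    single-point ROC falls back to the floor-based bound with a warning.
    """
    import warnings

    y_true = np.asarray(y_true)
    scores = np.asarray(scores)
    n_pos = int((y_true == 1).sum())
    n_neg = int((y_true == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise InvalidInputError("need both classes to estimate epsilon")
    fpr, tpr, _ = roc_curve(y_true, scores)
    # drop the (0,0) and (1,1) anchor points, which carry no information
    interior = ~((fpr == 0) & (tpr == 0)) & ~((fpr == 1) & (tpr == 1))
    if not interior.any():
        warnings.warn("degenerate single-point ROC; returning floor-based bound")
        interior = np.ones_like(fpr, dtype=bool)
    floor = 1.0 / max(n_pos, 2)
    tprf = np.clip(tpr[interior], 1.0 / n_pos, 1.0)
    fprf = np.clip(fpr[interior], 1.0 / n_neg, 1.0)
    return epsilon_from_roc(tprf, fprf, floor=0.0, two_sided=two_sided)


@dataclass
class DistanceStats:
    mean: float
    min: float
    max: float


def min_distance_analysis(real: np.ndarray, synthetic: np.ndarray,
                          norm: str = "rms") -> DistanceStats:
    """Nearest-real distance for every synthetic image (per-pixel RMS)."""
    real = np.asarray(real, dtype=np.float64)
    synthetic = np.asarray(synthetic, dtype=np.float64)
    if real.size == 0 or synthetic.size == 0:
        raise InvalidInputError("empty image set")
    if real.shape[1:] != synthetic.shape[1:]:
        raise InvalidInputError("image sizes differ")
    if norm != "rms":
        raise ConfigError(f"unsupported norm {norm!r}")
    npx = int(np.prod(real.shape[1:]))
    d = cdist(synthetic.reshape(len(synthetic), -1),
              real.reshape(len(real), -1)) / np.sqrt(npx)
    nearest = d.min(axis=1)
    return DistanceStats(float(nearest.mean()), float(nearest.min()), float(nearest.max()))


def privacy_risk_score(mia_auc: float, mia_accuracy: float, inversion_loss: float,
                       min_dist_mean: float, weights: dict | None = None) -> float:
    """Composite leakage score on 0-100 (higher = more leakage)."""
    for name, v in [("mia_auc", mia_auc), ("mia_accuracy", mia_accuracy),
                    ("inversion_loss", inversion_loss), ("min_dist_mean", min_dist_mean)]:
        if v is None or not np.isfinite(v):
            raise InvalidInputError(f"missing or non-finite field {name}")
    w = weights or DEFAULT_RISK_WEIGHTS
    return 100.0 * (
        w["mia_auc"] * mia_auc
        + w["mia_accuracy"] * mia_accuracy
        + w["inversion"] * (1.0 - min(inversion_loss, 1.0))
        + w["min_dist"] * (1.0 - min(min_dist_mean, 1.0))
    )


def run_privacy_audit(generator, train_images: np.ndarray, n_synthetic: int = 128,
                      cfg: AttackConfig | None = None,
                      n_inversion_targets: int = 8) -> PrivacyReport:
    """Full four-part audit of a generator against its training images."""
    from .gan import generate_images

    cfg = cfg or AttackConfig()
    synthetic = generate_images(generator, n_synthetic, seed=cfg.seed)
    acc, auc, truth, scores = _membership_inference_full(train_images, synthetic, cfg)
    eps = estimate_epsilon(truth, scores)
    rng = np.random.default_rng(cfg.seed + 1)
    pick = rng.choice(train_images.shape[0], size=min(n_inversion_targets,
                                                      train_images.shape[0]),
                      replace=False)
    inv = model_inversion(generator, train_images[pick], cfg)
    dist = min_distance_analysis(train_images, synthetic, cfg.distance_norm)
    report = PrivacyReport(
        mia_accuracy=acc, mia_auc=auc, inversion_loss=inv, epsilon_hat=eps,
        min_dist_mean=dist.mean, min_dist_min=dist.min, min_dist_max=dist.max)
    report.composite_score = privacy_risk_score(auc, acc, inv, dist.mean)
    return report
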