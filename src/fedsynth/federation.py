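"""In-process simulation of cross-silo federated DCGAN training.

One "server" and K "clients" are program components sharing a process: each
round the server distributes the global generator and discriminator weights,
every client trains locally on its own shard, and the server replaces the
globals with the dataset-size-weighted average of the client weights
(federated averaging) — applied layer-wise to both networks, batch-norm
running statistics included.  After aggregation the new global generator is
scored by a frozen discriminator taken from a non-federated baseline trained
on the full centralized dataset.

Transfer pretraining: before any federated round the global weights can be
initialized from a short centralized training run on a morphologically
different domain (CT-like images), the warm start the framework relies on
when the fine-tuning dataset is small.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigError, InvalidInputError
from .gan import TrainConfig, build_discriminator, build_generator, local_train
from .metrics import realism_score
from .nn import WeightSet
from .partition import PartitionConfig, partition_noniid

__all__ = [
    "FederationConfig",
    "GlobalState",
    "RoundLog",
    "fedavg",
    "pretrain_global",
    "run_round",
    "run_experiment",
    "stack_images",
]


@dataclass
class FederationConfig:
    K: int = 3
    rounds: int = 2
    local_epochs: int = 5
    aggregation: str = "weighted"
    train: TrainConfig = field(default_factory=TrainConfig)
    seed: int = 0

    def __post_init__(self):
        if self.K < 1 or self.rounds < 1 or self.local_epochs < 0:
            raise ConfigError("need K >= 1, rounds >= 1, local_epochs >= 0")
        if self.aggregation not in ("weighted", "uniform"):
            raise ConfigError(f"unknown aggregation mode {self.aggregation!r}")


@dataclass
class GlobalState:
    g_global: WeightSet
    d_global: WeightSet
    round: int = 0


@dataclass
class RoundLog:
    round: int
    client_g_loss: list[list[float]]
    client_d_loss: list[list[float]]
    shard_sizes: list[int]
    realism: float | None = None

    def to_dict(self):
        return {
            "round": self.round,
            "client_g_loss": self.client_g_loss,
            "client_d_loss": self.client_d_loss,
            "shard_sizes": self.shard_sizes,
            "realism": self.realism,
        }


def stack_images(processed) -> np.ndarray:
    """(n, S, S, 1) float array from a list of ProcessedImage."""
    return np.stack([p.pixels for p in processed]).astype(np.float64)


def fedavg(weight_sets: list[WeightSet], sizes=None, mode: str = "weighted") -> WeightSet:
    """Layer-wise convex combination of client weight sets.

    Weighted mode uses coefficients ``|D_k| / sum_j |D_j|``; uniform mode uses
    ``1/K``.  Layer names, order and shapes must agree across inputs.
    """
    if not weight_sets:
        raise InvalidInputError("fedavg needs at least one weight set")
    ref = weight_sets[0]
    for ws in weight_sets[1:]:
        if ws.names() != ref.names():
            diff = next(a for a, b in zip(ws.names(), ref.names()) if a != b)
            raise InvalidInputError(f"architecture mismatch at layer {diff!r}")
    if mode == "uniform":
        coef = np.full(len(weight_sets), 1.0 / len(weight_sets))
    elif mode == "weighted":
        if sizes is None or len(sizes) != len(weight_sets):
            raise InvalidInputError("weighted fedavg needs one size per weight set")
        sizes = np.asarray(sizes, dtype=np.float64)
        if (sizes <= 0).any() or sizes.sum() <= 0:
            raise InvalidInputError("dataset sizes must be positive")
        coef = sizes / sizes.sum()
    else:
        raise ConfigError(f"unknown aggregation mode {mode!r}")
    tensors = []
    for i, (name, _) in enumerate(ref.tensors):
        acc = sum(c * ws.tensors[i][1] for c, ws in zip(coef, weight_sets))
        tensors.append((name, acc))
    return WeightSet(tensors, ref.tag, dict(ref.arch))


def pretrain_global(images: np.ndarray, cfg: TrainConfig,
                    epochs: int = 1) -> tuple[WeightSet, WeightSet]:
    """Centralized warm start: train fresh G and D on the full dataset.

    With ``epochs=0`` the freshly initialized weights are returned untouched.
    The returned weight sets are tagged as the pretrained initialization.
    """
    g0 = build_generator(cfg.latent_dim, cfg.image_size, seed=cfg.seed).get_weights()
    d0 = build_discriminator(cfg.image_size, seed=cfg.seed + 1).get_weights()
    if epochs == 0:
        pre = TrainConfig(**{**cfg.__dict__, "local_epochs": 0})
        g1, d1 = g0, d0
    else:
        pre = TrainConfig(**{**cfg.__dict__, "local_epochs": epochs})
        g1, d1, _ = local_train(g0, d0, images, pre)
    g1.arch["pretrained"] = d1.arch["pretrained"] = True
    return g1, d1


def _client_seed(base_seed: int, round_idx: int, client_id: int) -> int:
    ss = np.random.SeedSequence(base_seed, spawn_key=(round_idx, client_id))
    return int(ss.generate_state(1)[0] % (2**31))


def run_round(state: GlobalState, client_images: list[np.ndarray],
              cfg: FederationConfig, scorer=None) -> tuple[GlobalState, RoundLog]:
    """One federated round: distribute, train locally, aggregate, evaluate.

    ``client_images`` holds one (n_k, S, S, 1) array per client.  ``scorer``
    is the frozen centralized discriminator used for the realism score of the
    aggregated generator (skipped when None).
    """
    t = state.round + 1
    tc = cfg.train
    g_sets, d_sets, g_traces, d_traces = [], [], [], []
    sizes = [imgs.shape[0] for imgs in client_images]
    for client_id, imgs in enumerate(client_images, start=1):
        seed = _client_seed(cfg.seed, t, client_id)
        local_cfg = TrainConfig(**{**tc.__dict__, "local_epochs": cfg.local_epochs})
        try:
            g_k, d_k, trace = local_train(state.g_global, state.d_global, imgs,
                                          local_cfg, seed=seed)
        except Exception as exc:
            raise RuntimeError(f"client {client_id} failed in round {t}: {exc}") from exc
        g_sets.append(g_k)
        d_sets.append(d_k)
        g_traces.append(trace["g_loss"])
        d_traces.append(trace["d_loss"])
    g_new = fedavg(g_sets, sizes, cfg.aggregation)
    d_new = fedavg(d_sets, sizes, cfg.aggregation)
    # convexity guard: averaged tensors stay within the clients' envelope
    for i, (name, t_new) in enumerate(g_new.tensors):
        lo = np.min([ws.tensors[i][1] for ws in g_sets], axis=0)
        hi = np.max([ws.tensors[i][1] for ws in g_sets], axis=0)
        if not (np.all(t_new >= lo - 1e-9) and np.all(t_new <= hi + 1e-9)):
            raise AssertionError(f"aggregation left convex hull at {name}")
    new_state = GlobalState(g_new, d_new, t)
    log = RoundLog(t, g_traces, d_traces, sizes)
    if scorer is not None:
        gen = build_generator(tc.latent_dim, tc.image_size)
        gen.set_weights(g_new)
        log.realism = realism_score(gen, scorer, n=256, seed=cfg.seed)
    return new_state, log


def train_baseline(images: np.ndarray, cfg: TrainConfig, epochs: int = 5):
    """Non-federated DCGAN on the centralized dataset; its discriminator is
    the frozen realism scorer for every federated run."""
    g0 = build_generator(cfg.latent_dim, cfg.image_size, seed=cfg.seed + 101).get_weights()
    d0 = build_discriminator(cfg.image_size, seed=cfg.seed + 102).get_weights()
    bc = TrainConfig(**{**cfg.__dict__, "local_epochs": epochs})
    g1, d1, trace = local_train(g0, d0, images, bc)
    disc = build_discriminator(cfg.image_size)
    disc.set_weights(d1)
    return g1, d1, disc, trace


def run_experiment(dataset, client_grid=(3, 5, 7, 10), cfg: FederationConfig | None = None,
                   pretrain_dataset=None, out_dir=None, baseline_epochs: int = 5,
                   pretrain_epochs: int = 1, with_pretraining: bool = True):
    """Full study: baseline, optional pretraining, one federated run per K.

    ``dataset`` and ``pretrain_dataset`` are lists of ProcessedImage.  The
    same seed gives identical shards whether or not pretraining is used.
    Returns the history dict (and writes history/checkpoints/sample grids
    under ``out_dir`` when given).
    """
    cfg = cfg or FederationConfig()
    tc = cfg.train
    images = stack_images(dataset)
    _, _, scorer, baseline_trace = train_baseline(images, tc, baseline_epochs)

    if with_pretraining:
        pre_imgs = images if pretrain_dataset is None else stack_images(pretrain_dataset)
        g_init, d_init = pretrain_global(pre_imgs, tc, pretrain_epochs)
    else:
        g_init, d_init = pretrain_global(images, tc, epochs=0)

    init_gen = build_generator(tc.latent_dim, tc.image_size)
    init_gen.set_weights(g_init)
    init_realism = realism_score(init_gen, scorer, n=256, seed=cfg.seed)

    history = {"config": {"rounds": cfg.rounds, "local_epochs": cfg.local_epochs,
                          "aggregation": cfg.aggregation, "seed": cfg.seed,
                          "image_size": tc.image_size,
                          "with_pretraining": with_pretraining},
               "baseline": baseline_trace, "init_realism": init_realism, "runs": {}}
    out_dir = Path(out_dir) if out_dir is not None else None
    for K in client_grid:
        shards = partition_noniid(dataset, PartitionConfig(K=K, seed=cfg.seed))
        client_images = [images[s.indices] for s in shards]
        kcfg = FederationConfig(K=K, rounds=cfg.rounds, local_epochs=cfg.local_epochs,
                                aggregation=cfg.aggregation, train=tc, seed=cfg.seed)
        state = GlobalState(g_init.copy(), d_init.copy())
        logs = []
        for _ in range(cfg.rounds):
            state, log = run_round(state, client_images, kcfg, scorer=scorer)
            logs.append(log.to_dict())
        history["runs"][str(K)] = {
            "shard_sizes": [len(s) for s in shards],
            "rounds": logs,
            "final_realism": logs[-1]["realism"],
        }
        if out_dir is not None:
            kdir = out_dir / f"K{K}"
            kdir.mkdir(parents=True, exist_ok=True)
            state.g_global.save(kdir / "generator.npz")
            state.d_global.save(kdir / "discriminator.npz")
            _save_sample_grid(state.g_global, tc, kdir / "samples.png", seed=cfg.seed)
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "history.json").write_text(json.dumps(history, indent=2))
    return history


def _save_sample_grid(g_weights: WeightSet, tc: TrainConfig, path, seed=0, grid=4):
    from PIL import Image

    from .gan import generate_images

    gen = build_generator(tc.latent_dim, tc.image_size)
    gen.set_weights(g_weights)
    imgs = generate_images(gen, grid * grid, seed=seed)[:, :, :, 0]
    s = tc.image_size
    canvas = np.zeros((grid * s, grid * s))
    for i, img in enumerate(imgs):
        r, c = divmod(i, grid)
        canvas[r * s : (r + 1) * s, c * s : (c + 1) * s] = img
    arr = np.clip((canvas + 1) * 127.5, 0, 255).astype(np.uint8)
    Image.fromarray(arr).save(path)
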