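"""Desk-scale study runner: the full workflow on phantoms at reduced size.

Problem sizes here are the package's reference configuration for running the
complete federated study on a laptop-class CPU: 16x16 images, 192 fundus-like
phantoms for federated fine-tuning, 192 CT-like phantoms for transfer
pretraining, 2 federated rounds of 1 local epoch.  The full-scale settings
(128x128, batch 64, latent 200, 5 local epochs) remain the defaults of the
underlying configs.
"""

from __future__ import annotations

from .federation import FederationConfig, run_experiment
from .gan import TrainConfig
from .phantoms import PhantomConfig, make_dataset
from .pipeline import PipelineConfig, preprocess_dataset

__all__ = ["phantom_dataset", "desk_scale_study", "ablation_pair"]


def phantom_dataset(n: int, seed: int, domain: str = "fundus", image_size: int = 16):
    """Generate phantoms at 2x target resolution and run the full pipeline."""
    raws = make_dataset(PhantomConfig(n_images=n, image_size=2 * image_size,
                                      seed=seed, domain=domain))
    done, _ = preprocess_dataset(raws, PipelineConfig(target_size=image_size))
    return done


def desk_scale_study(seed: int, with_pretraining: bool = True, n_images: int = 192,
                     image_size: int = 16, client_grid=(3,), rounds: int = 2,
                     local_epochs: int = 1, latent_dim: int = 200, batch_size: int = 8,
                     baseline_epochs: int = 40, out_dir=None) -> dict:
    """One complete run: phantoms -> partition -> (pretrain) -> federate.

    The desk-scale batch size is 8 (scaled with the 8x reduction in image
    side from the full-scale batch of 64) so that one local epoch performs a
    meaningful number of optimizer steps; the centralized baseline is trained
    to its adversarial plateau (~1000 updates) so that its discriminator
    actually separates real phantoms from untrained-generator output before
    it is frozen as the realism scorer.

    Returns the experiment history (per-round client losses, realism of the
    initial and aggregated generators).  Everything derives from ``seed``.
    """
    fundus = phantom_dataset(n_images, seed=seed, image_size=image_size)
    ct = (phantom_dataset(n_images, seed=seed + 10_000, domain="ct",
                          image_size=image_size)
          if with_pretraining else None)
    tc = TrainConfig(batch_size=batch_size, latent_dim=latent_dim,
                     image_size=image_size, seed=seed)
    cfg = FederationConfig(K=client_grid[0], rounds=rounds, local_epochs=local_epochs,
                           train=tc, seed=seed)
    return run_experiment(fundus, client_grid=client_grid, cfg=cfg,
                          pretrain_dataset=ct, with_pretraining=with_pretraining,
                          baseline_epochs=baseline_epochs, out_dir=out_dir)


def ablation_pair(seed: int, n_images: int = 192, image_size: int = 16, K: int = 3,
                  rounds: int = 2, local_epochs: int = 1, latent_dim: int = 200,
                  batch_size: int = 8, baseline_epochs: int = 40) -> dict:
    """Pretraining ablation at desk scale with one shared scorer and shards.

    Runs the federated study twice from the same seed — once initialized from
    a 1-epoch CT-domain pretrain, once from random initialization — against
    the same frozen centralized scorer and identical non-IID shards, and
    returns the realism of the untrained, non-pretrained-final and
    pretrained-final generators plus the per-client loss traces.
    """
    from .federation import (FederationConfig, GlobalState, pretrain_global,
                             run_round, stack_images, train_baseline)
    from .gan import build_generator
    from .metrics import realism_score
    from .partition import PartitionConfig, partition_noniid

    fundus = phantom_dataset(n_images, seed=seed, image_size=image_size)
    ct = phantom_dataset(n_images, seed=seed + 10_000, domain="ct",
                         image_size=image_size)
    images = stack_images(fundus)
    tc = TrainConfig(batch_size=batch_size, latent_dim=latent_dim,
                     image_size=image_size, seed=seed)
    _, _, scorer, baseline_trace = train_baseline(images, tc, baseline_epochs)
    shards = partition_noniid(fundus, PartitionConfig(K=K, seed=seed))
    client_images = [images[s.indices] for s in shards]
    cfg = FederationConfig(K=K, rounds=rounds, local_epochs=local_epochs,
                           train=tc, seed=seed)

    def score(ws):
        gen = build_generator(latent_dim, image_size)
        gen.set_weights(ws)
        return realism_score(gen, scorer, n=256, seed=seed)

    result = {"seed": seed, "shard_sizes": [len(s) for s in shards],
              "baseline_trace": baseline_trace}
    for arm, pre_epochs in (("without_pretraining", 0), ("with_pretraining", 1)):
        g0, d0 = pretrain_global(stack_images(ct) if pre_epochs else images,
                                 tc, epochs=pre_epochs)
        state = GlobalState(g0.copy(), d0.copy())
        logs = []
        for _ in range(rounds):
            state, log = run_round(state, client_images, cfg)
            logs.append(log)
        result[arm] = {
            "init_realism": score(g0),
            "final_realism": score(state.g_global),
            "rounds": [l.to_dict() for l in logs],
            "final_weights": state.g_global,
        }
    return result
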