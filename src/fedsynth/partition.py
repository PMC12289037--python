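"""Non-IID label-skew partitioning of a labeled dataset across simulated silos.

Each severity label is assigned to exactly two randomly chosen clients, and
every sample of that label flips a fair coin between the two — emulating
clinics that specialize in particular severity grades while keeping some
overlap.  A rebalancing pass then tops up any client below a minimum
threshold ``T = ceil(min_frac * |D|)`` by moving randomly chosen samples from
the currently largest shard, so no client is starved of training data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, InvalidInputError

__all__ = ["PartitionConfig", "ClientShard", "assign_by_label", "rebalance", "partition_noniid"]


@dataclass
class ClientShard:
    """Record indices (into the dataset order) owned by one client."""

    client_id: int  # 1..K
    indices: list[int] = field(default_factory=list)

    def __len__(self):
        return len(self.indices)


@dataclass
class PartitionConfig:
    K: int = 3
    min_frac: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.K < 1:
            raise ConfigError("K must be >= 1")
        if self.min_frac < 0:
            raise ConfigError("min_frac must be >= 0")


def _labels_of(dataset) -> np.ndarray:
    labels = np.asarray([getattr(r, "label", r[1] if isinstance(r, tuple) else None)
                         for r in dataset])
    if any(l is None for l in labels.tolist()):
        raise InvalidInputError("partitioning requires a fully labeled dataset")
    return labels.astype(int)


def assign_by_label(dataset, K: int, rng: np.random.Generator) -> list[ClientShard]:
    """Give every label to 2 random clients, splitting its samples 50/50.

    ``dataset`` is a sequence of labeled records (anything with a ``.label``
    attribute, or ``(image, label)`` tuples).  With K=1 everything goes to the
    single client.
    """
    n = len(dataset)
    if n == 0:
        raise InvalidInputError("cannot partition an empty dataset")
    shards = [ClientShard(k + 1) for k in range(K)]
    if K == 1:
        shards[0].indices = list(range(n))
        return shards
    labels = _labels_of(dataset)
    for label in sorted(set(labels.tolist())):
        holders = rng.choice(K, size=2, replace=False)
        idx = np.flatnonzero(labels == label)
        pick = rng.integers(0, 2, size=idx.size)
        for which in (0, 1):
            shards[holders[which]].indices.extend(idx[pick == which].tolist())
    return shards


def rebalance(shards: list[ClientShard], threshold: int,
              rng: np.random.Generator) -> list[ClientShard]:
    """Move random samples largest -> smallest until every shard has >= T.

    Re-evaluates the argmax/argmin each iteration (ties broken by lowest
    client id).  Each move transfers ``min(T - |smallest|, |largest| - T)``
    samples, so the donor never drops below the threshold itself; with a
    feasible threshold (K*T <= |D|) this terminates.  Total size is conserved.
    """
    total = sum(len(s) for s in shards)
    if threshold * len(shards) > total:
        raise ConfigError(
            f"infeasible threshold {threshold} for {len(shards)} shards of {total} records")
    while True:
        sizes = [len(s) for s in shards]
        if min(sizes) >= threshold:
            return shards
        k_min = int(np.argmin(sizes))  # argmin/argmax take the lowest index on ties
        k_max = int(np.argmax(sizes))
        need = min(threshold - sizes[k_min], sizes[k_max] - threshold)
        donor = shards[k_max].indices
        take = rng.choice(len(donor), size=need, replace=False)
        take_set = set(take.tolist())
        moved = [donor[i] for i in sorted(take_set)]
        shards[k_max].indices = [x for i, x in enumerate(donor) if i not in take_set]
        shards[k_min].indices.extend(moved)


def partition_noniid(dataset, cfg: PartitionConfig, out_dir=None):
    """Algorithmic composition: label assignment then threshold rebalancing.

    Returns the shards; when ``out_dir`` is given also writes one record file
    per client plus a JSON manifest of shard sizes and per-label counts
    (requires the dataset records to be ProcessedImage).
    """
    rng = np.random.default_rng(cfg.seed)
    n = len(dataset)
    threshold = int(np.ceil(cfg.min_frac * n))
    if cfg.K * threshold > n:
        raise ConfigError("min_frac infeasible for this dataset size")
    shards = assign_by_label(dataset, cfg.K, rng)
    shards = rebalance(shards, threshold, rng)
    if out_dir is not None:
        import json
        from pathlib import Path

        from .records import write_records

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        labels = _labels_of(dataset)
        manifest = {"n_records": n, "K": cfg.K, "threshold": threshold,
                    "seed": cfg.seed, "shards": {}}
        for shard in shards:
            path = out_dir / f"client{shard.client_id:02d}.tfrecord"
            write_records(path, [dataset[i] for i in shard.indices])
            per_label = np.bincount(labels[shard.indices], minlength=5).tolist()
            manifest["shards"][str(shard.client_id)] = {
                "file": path.name, "size": len(shard), "label_counts": per_label}
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return shards
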