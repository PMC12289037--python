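"""Sequential container and the WeightSet weight-exchange format."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .layers import Layer

__all__ = ["WeightSet", "Sequential"]


@dataclass
class WeightSet:
    """Ordered named tensors for one network, the unit FedAvg averages.

    ``tensors`` preserves layer order; ``tag`` identifies the network kind
    (``"generator"`` or ``"discriminator"``); ``arch`` is a JSON-serialisable
    architecture descriptor used to rebuild the network and to detect
    aggregation mismatches.
    """

    tensors: list[tuple[str, np.ndarray]]
    tag: str = "generator"
    arch: dict = field(default_factory=dict)

    def names(self) -> list[str]:
        return [n for n, _ in self.tensors]

    def copy(self) -> "WeightSet":
        return WeightSet([(n, t.copy()) for n, t in self.tensors], self.tag, dict(self.arch))

    def allclose(self, other: "WeightSet", **kw) -> bool:
        return self.names() == other.names() and all(
            np.allclose(a, b, **kw) for (_, a), (_, b) in zip(self.tensors, other.tensors)
        )

    def save(self, path) -> None:
        """Archive of named float32 tensors plus the JSON architecture descriptor."""
        arrays = {f"t{i}:{n}": t.astype(np.float32) for i, (n, t) in enumerate(self.tensors)}
        meta = json.dumps({"tag": self.tag, "arch": self.arch})
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "WeightSet":
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            keys = sorted((k for k in z.files if k != "__meta__"),
                          key=lambda k: int(k.split(":", 1)[0][1:]))
            tensors = [(k.split(":", 1)[1], z[k].astype(np.float64)) for k in keys]
        return cls(tensors, meta["tag"], meta["arch"])


class Sequential:
    """A plain layer stack with weight import/export and manual backprop."""

    def __init__(self, layers: list[Layer], tag: str = "generator", arch: dict | None = None):
        self.layers = layers
        self.tag = tag
        self.arch = arch or {}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for lyr in self.layers:
            x = lyr.forward(x, train=train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for lyr in reversed(self.layers):
            dy = lyr.backward(dy)
        return dy

    __call__ = forward

    def parameters(self):
        """Yield (key, params-dict, name) triples for the optimizer."""
        for i, lyr in enumerate(self.layers):
            for name in lyr.params:
                yield f"L{i}.{name}", lyr, name

    def get_weights(self) -> WeightSet:
        tensors = []
        for i, lyr in enumerate(self.layers):
            for name, t in lyr.params.items():
                tensors.append((f"L{i}.{name}", t.copy()))
            for name, t in lyr.state.items():
                tensors.append((f"L{i}.{name}", t.copy()))
        return WeightSet(tensors, self.tag, dict(self.arch))

    def set_weights(self, ws: WeightSet) -> None:
        lookup = dict(ws.tensors)
        expected = self.get_weights().names()
        if sorted(lookup) != sorted(expected):
            missing = set(expected) ^ set(lookup)
            raise ValueError(f"weight set does not match architecture: {sorted(missing)[:3]}")
        for i, lyr in enumerate(self.layers):
            for name in lyr.params:
                lyr.params[name] = lookup[f"L{i}.{name}"].copy()
            for name in lyr.state:
                lyr.state[name] = lookup[f"L{i}.{name}"].copy()
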