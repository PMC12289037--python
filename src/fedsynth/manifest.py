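"""Run manifests: config snapshot, seeds, paths, timings, artifact checksums."""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

__all__ = ["write_manifest", "sha256_file"]


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(manifest_path, command: str, config: dict, inputs: list,
                   outputs: list, t_start: float) -> Path:
    """Record what a stage did; every produced file is listed with a checksum."""
    manifest_path = Path(manifest_path)
    manifest_path.parent.mkdir(parents=True, exist_ok=True)
    doc = {
        "command": command,
        "config": config,
        "inputs": [str(p) for p in inputs],
        "outputs": {str(p): sha256_file(p) for p in outputs},
        "duration_s": round(time.time() - t_start, 3),
    }
    manifest_path.write_text(json.dumps(doc, indent=2))
    return manifest_path
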