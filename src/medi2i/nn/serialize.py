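"""Checkpoint containers: weights + config + auxiliary metadata in one .npz."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

__all__ = ["save_checkpoint", "load_checkpoint"]

_META_KEY = "__meta__"


def save_checkpoint(path, state: dict[str, np.ndarray], config: dict) -> None:
    """Write a state dict plus a JSON-serializable config to ``path``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = np.frombuffer(json.dumps(config, sort_keys=True).encode(), dtype=np.uint8)
    np.savez(path, **{_META_KEY: meta}, **state)


def load_checkpoint(path) -> tuple[dict[str, np.ndarray], dict]:
    with np.load(Path(path), allow_pickle=False) as npz:
        config = json.loads(bytes(npz[_META_KEY].tobytes()).decode())
        state = {k: npz[k] for k in npz.files if k != _META_KEY}
    return state, config
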