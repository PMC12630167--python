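"""Small shared helpers: canonical hashing and seed derivation."""

from __future__ import annotations

import hashlib
import json

import numpy as np


def _canonical(obj):
    if isinstance(obj, dict):
        return {str(k): _canonical(v) for k, v in sorted(obj.items(), key=lambda kv: str(kv[0]))}
    if isinstance(obj, (list, tuple)):
        return [_canonical(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def config_hash(obj) -> str:
    """Stable sha256 hex digest of a JSON-serialisable configuration."""
    payload = json.dumps(_canonical(obj), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def derive_seed(seed: int, *keys) -> int:
    """Derive a reproducible child seed (< 2**31) from a base seed and keys."""
    payload = f"{seed}:" + ":".join(map(str, keys))
    h = hashlib.sha256(payload.encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)
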