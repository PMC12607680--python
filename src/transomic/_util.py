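"""Small shared helpers: BH adjustment, deterministic hashing, TSV headers."""

from __future__ import annotations

import hashlib
import json
from typing import Any, Iterable

import numpy as np


def bh_adjust(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up), clipped to [0, 1]."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    # enforce monotonicity from the largest p downwards
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n, dtype=float)
    out[order] = np.clip(adj, 0.0, 1.0)
    return out


def stable_hash(obj: Any) -> str:
    """Deterministic short hash of a JSON-serialisable object."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def report_header(config_hash: str = "none", seed: int | None = None) -> str:
    """Commented first line recording provenance for every TSV writer."""
    from . import __version__

    parts = [f"# transomic={__version__}", f"config_hash={config_hash}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    return "\t".join(parts)
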