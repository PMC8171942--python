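"""Shared numerical helpers: seeded RNG streams and BH adjustment."""

from __future__ import annotations

import zlib

import numpy as np


def rng_for(seed: int, op_name: str) -> np.random.Generator:
    """Independent RNG stream per (seed, operation).

    Each generator operation draws from its own stream so that changing
    one simulation stage never perturbs the randomness of another.
    """
    tag = zlib.crc32(op_name.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (q-values).

    NaN entries are excluded from the family and returned as NaN.
    """
    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    pm = p[mask]
    m = pm.size
    if m == 0:
        return q
    order = np.argsort(pm, kind="stable")
    ranked = pm[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downwards
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(ranked, 0.0, 1.0)
    q[mask] = out
    return q
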