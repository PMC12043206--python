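"""Small shared statistical and RNG helpers."""

from __future__ import annotations

import hashlib

import numpy as np


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Returns q-values in the original order; monotonicity is enforced by the
    running minimum from the largest p downwards, and values are capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("bh_adjust expects a 1-D array of p-values")
    m = p.size
    if m == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m, dtype=float)
    q[order] = np.minimum(ranked, 1.0)
    return q


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Derive a per-stage generator from one pipeline seed.

    The stage name is hashed so adding a stage never perturbs the streams of
    the existing ones.
    """
    digest = hashlib.sha256(stage.encode("utf-8")).digest()
    key = int.from_bytes(digest[:8], "big")
    return np.random.default_rng(np.random.SeedSequence((int(seed), key)))
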