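"""Small shared numerical helpers."""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["as_rng", "child_rng", "perm_pvalue", "bh_adjust"]


def as_rng(seed) -> np.random.Generator:
    """Coerce ``seed`` (int, None, or Generator) to a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def child_rng(seed: int, stream: int) -> np.random.Generator:
    """Independent stream derived from a master seed by a fixed offset.

    Each simulator component consumes its own stream so that any single
    component can be regenerated without replaying the others.
    """
    return np.random.default_rng([int(seed), int(stream)])


def perm_pvalue(perm_stats: np.ndarray, observed: float) -> float:
    """Plus-one permutation p-value, P = (#{perm >= obs} + 1) / (n + 1)."""
    perm_stats = np.asarray(perm_stats, dtype=float)
    return (np.sum(perm_stats >= observed) + 1.0) / (perm_stats.size + 1.0)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaNs passed through)."""
    p = np.asarray(pvals, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.sum():
        out[ok] = stats.false_discovery_control(p[ok], method="bh")
    return out
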