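"""Small shared helpers: seeding, FDR, empirical p-values."""

from __future__ import annotations

import hashlib

import numpy as np
from statsmodels.stats.multitest import multipletests


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a stable per-stage seed (< 2**31) from a master seed and stage name."""
    h = hashlib.sha256(f"{int(master_seed)}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def rng_from(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(int(seed))


def empirical_p(observed: np.ndarray, null: np.ndarray) -> np.ndarray:
    """(1 + #{null >= obs}) / (1 + n_null) upper-tail estimator (never returns 0)."""
    observed = np.atleast_1d(np.asarray(observed, dtype=float))
    null = np.asarray(null, dtype=float).ravel()
    n = null.size
    # count of null values >= each observed value
    snull = np.sort(null)
    ge = n - np.searchsorted(snull, observed, side="left")
    return (1.0 + ge) / (1.0 + n)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]
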