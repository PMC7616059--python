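"""A/B compartment analysis: distance normalization, compartment scores,
saddle plots, contact-scaling and separation-fraction profiles, bootstrap.

The compartment score is the leading eigenvector of the bin-bin correlation
matrix of the distance-normalized (observed/expected) contact matrix, per
chromosome, sign-oriented against a supplied reference track so that
positive = A. Scores are quantile-normalized by rank-mapping onto the
pooled score distribution across chromosomes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import rng_from

SEPARATION_BINS = ("lt10kb", "10kb-100kb", "100kb-1Mb", "1Mb-5Mb", "gt5Mb", "trans")
_SEP_EDGES = (10_000, 100_000, 1_000_000, 5_000_000)


def separation_fractions(contacts: pd.DataFrame) -> pd.Series:
    """Fraction of contacts per separation class (half-open [low, high) bins,
    so a contact at exactly 10 kb falls in the 10-100 kb bin), plus trans."""
    if contacts.empty:
        raise ValueError("empty contact list")
    intra = contacts["chrom_a"] == contacts["chrom_b"]
    sep = (contacts["pos_b"] - contacts["pos_a"]).abs().to_numpy()
    counts = np.zeros(6)
    counts[5] = int((~intra).sum())
    sep = sep[intra.to_numpy()]
    edges = np.asarray(_SEP_EDGES)
    counts[:5] += np.bincount(np.searchsorted(edges, sep, side="right"), minlength=5)
    return pd.Series(counts / counts.sum(), index=SEPARATION_BINS)


def scaling_curve(
    contacts: pd.DataFrame | None = None,
    matrix: np.ndarray | None = None,
    bin_size: int | None = None,
    n_log_bins: int = 25,
) -> pd.DataFrame:
    """Contact probability versus intra-chromosomal sequence separation,
    tallied in log10-spaced separation bins; probabilities sum to 1.

    When ``bin_size`` is given, contact separations are snapped to bin
    multiples so a contact list and its binned matrix produce the same
    curve. A matrix input (single chromosome) uses |i-j| * bin_size.
    """
    if matrix is not None:
        if bin_size is None:
            raise ValueError("bin_size required for matrix input")
        m = np.asarray(matrix, dtype=float)
        n = m.shape[0]
        idx = np.arange(n)
        sep = np.abs(idx[:, None] - idx[None, :]) * bin_size
        iu = np.triu_indices(n, k=1)
        seps, weights = sep[iu].ravel(), m[iu].ravel()
    else:
        intra = contacts[contacts["chrom_a"] == contacts["chrom_b"]]
        if intra.empty:
            raise ValueError("no intra-chromosomal contacts")
        seps = (intra["pos_b"] - intra["pos_a"]).abs().to_numpy(dtype=float)
        if bin_size is not None:
            seps = np.abs(
                intra["pos_b"] // bin_size - intra["pos_a"] // bin_size
            ).to_numpy(dtype=float) * bin_size
        weights = np.ones_like(seps)
    mask = (seps > 0) & (weights > 0)
    seps, weights = seps[mask], weights[mask]
    if seps.size == 0 or weights.sum() == 0:
        raise ValueError("no nonzero-separation contacts")
    lo, hi = np.log10(seps.min()), np.log10(seps.max())
    if lo == hi:
        return pd.DataFrame({"separation": [seps.min()], "probability": [1.0]})
    edges = np.logspace(lo, hi, n_log_bins + 1)
    edges[-1] *= 1.0 + 1e-9
    hist, _ = np.histogram(seps, bins=edges, weights=weights)
    mids = np.sqrt(edges[:-1] * edges[1:])
    keep = hist > 0
    return pd.DataFrame(
        {"separation": mids[keep], "probability": hist[keep] / hist.sum()}
    )


def normalize_matrix(matrix: np.ndarray) -> np.ndarray:
    """Observed/expected: divide each diagonal by its mean contact score.

    Operates on one intra-chromosomal square block; diagonals whose mean is
    zero are left at zero. Idempotent and scale-invariant.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("expected a square intra-chromosomal matrix")
    if not np.any(m):
        raise ValueError("all-zero matrix")
    n = m.shape[0]
    out = np.zeros_like(m)
    for d in range(n):
        diag = np.diagonal(m, offset=d)
        mean = diag.mean()
        if mean > 0:
            vals = diag / mean
            idx = np.arange(n - d)
            out[idx, idx + d] = vals
            out[idx + d, idx] = vals
    return out


def compartment_scores(
    normalized: np.ndarray, orientation_track: np.ndarray
) -> pd.DataFrame:
    """Signed per-bin compartment score from the leading eigenvector of the
    bin-bin correlation matrix of observed/expected; positive = A, oriented
    so the score correlates positively with ``orientation_track``."""
    m = np.asarray(normalized, dtype=float)
    n = m.shape[0]
    orientation = np.asarray(orientation_track, dtype=float)
    if orientation.size != n:
        raise ValueError("orientation track does not cover matrix bins")
    active = m.any(axis=0)
    scores = np.full(n, np.nan)
    labels = np.array(["NA"] * n, dtype=object)
    sub = m[np.ix_(active, active)]
    if active.sum() >= 2:
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(sub)
        corr = np.nan_to_num(corr)
        if np.any(corr):
            w, v = np.linalg.eigh(corr)
            vec = v[:, -1]
            ref = orientation[active]
            if np.std(ref) > 0 and np.std(vec) > 0:
                sign = np.corrcoef(vec, ref)[0, 1]
                if sign < 0:
                    vec = -vec
            scores[active] = vec
            labels[active] = np.where(vec > 0, "A", np.where(vec < 0, "B", "NA"))
    return pd.DataFrame({"score": scores, "label": labels})


def quantile_normalize_scores(score_sets) -> list:
    """Rank-map each score vector onto the pooled distribution of all sets."""
    pooled = np.sort(np.concatenate([s[~np.isnan(s)] for s in score_sets]))
    out = []
    for s in score_sets:
        result = np.full(s.size, np.nan)
        valid = ~np.isnan(s)
        ranks = stats.rankdata(s[valid], method="average")
        q = (ranks - 0.5) / valid.sum()
        result[valid] = np.quantile(pooled, q)
        out.append(result)
    return out


def saddle(
    normalized: np.ndarray,
    scores: np.ndarray,
    n_groups: int = 10,
    corner_fraction: float = 0.2,
) -> dict:
    """Mean normalized contact between equal-size score groups.

    Groups are ordered from the strongest B (lowest score) to the strongest
    A; corner summaries average the outer ``corner_fraction`` of groups on
    each side (the AA, BB, AB boxes), reporting both the contact enrichment
    and the mean score in each corner stratum.
    """
    if n_groups < 2:
        raise ValueError("n_groups must be >= 2")
    m = np.asarray(normalized, dtype=float)
    scores = np.asarray(scores, dtype=float)
    valid = ~np.isnan(scores)
    order = np.argsort(scores[valid], kind="stable")
    idx = np.flatnonzero(valid)[order]
    groups = np.array_split(idx, n_groups)
    sad = np.full((n_groups, n_groups), np.nan)
    for a in range(n_groups):
        for b in range(n_groups):
            block = m[np.ix_(groups[a], groups[b])]
            if block.size:
                sad[a, b] = block.mean()
    k = max(1, int(round(corner_fraction * n_groups)))
    corners = {
        "BB": float(np.nanmean(sad[:k, :k])),
        "AA": float(np.nanmean(sad[-k:, -k:])),
        "AB": float(np.nanmean(sad[:k, -k:])),
        "BA": float(np.nanmean(sad[-k:, :k])),
    }
    corner_scores = {
        "B": float(np.mean(scores[np.concatenate(groups[:k])])),
        "A": float(np.mean(scores[np.concatenate(groups[-k:])])),
    }
    mixing = corners["AB"] / np.sqrt(corners["AA"] * corners["BB"]) if (
        corners["AA"] > 0 and corners["BB"] > 0
    ) else np.nan
    return {
        "matrix": sad,
        "corners": corners,
        "corner_scores": corner_scores,
        "mixing": float(mixing),
    }


def bootstrap_sd(
    statistic, data, n_samples: int = 200, sample_fraction: float = 0.2, seed=0
) -> float:
    """SD of a statistic over random subsamples without replacement."""
    data = np.asarray(data)
    n = data.shape[0]
    k = int(round(sample_fraction * n))
    if k < 1:
        raise ValueError("sample too small for the statistic")
    rng = rng_from(seed)
    vals = np.empty(n_samples)
    for b in range(n_samples):
        pick = rng.choice(n, size=k, replace=False)
        vals[b] = statistic(data[pick])
    return float(vals.std(ddof=1))
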