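"""Multiway hub detection in single-cell contact maps.

A hub is a 40 kb anchor window with a significantly greater than expected
number of long-range (>50 kb sequence separation) intra-chromosomal
contacts. Windows slide in 20 kb steps; where candidate windows overlap,
the one with the larger long-range count wins (ties: leftmost).
Significance comes from a separation-preserving permutation null: each
long-range contact is relocated uniformly along its chromosome keeping its
sequence separation, the identical scan runs on each permuted genome, and
pseudo-anchor counts pooled per chromosome give empirical p-values
((1+r)/(1+n)), Benjamini-Hochberg adjusted within the cell; hubs with
q < 0.05 are kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import bh_adjust, empirical_p, rng_from
from .genome import GenomeAssembly

WINDOW = 40_000
STEP = 20_000
MIN_SEPARATION = 50_000
MIN_COUNT = 4
SPAN_THRESHOLD = 1_000_000


def long_range_ends(contacts: pd.DataFrame, chrom: str, min_separation: int = MIN_SEPARATION):
    """(end position, partner position) pairs for long-range intra contacts.

    Both ends of every qualifying contact are candidate anchor members,
    each with its partner as the contact site.
    """
    sel = (
        (contacts["chrom_a"] == chrom)
        & (contacts["chrom_b"] == chrom)
        & ((contacts["pos_b"] - contacts["pos_a"]).abs() > min_separation)
    )
    sub = contacts.loc[sel]
    ends = np.concatenate([sub["pos_a"].to_numpy(), sub["pos_b"].to_numpy()])
    partners = np.concatenate([sub["pos_b"].to_numpy(), sub["pos_a"].to_numpy()])
    return ends.astype(np.int64), partners.astype(np.int64)


def window_counts(positions: np.ndarray, length: int, window: int = WINDOW, step: int = STEP) -> np.ndarray:
    """Number of long-range contact ends in every sliding window."""
    n_windows = max(0, (length - window) // step + 1)
    counts = np.zeros(n_windows, dtype=np.int64)
    if n_windows == 0 or positions.size == 0:
        return counts
    span = window // step  # windows covering a position
    k_hi = np.minimum(positions // step, n_windows - 1)
    for off in range(span):
        k = k_hi - off
        inside = (k >= 0) & (positions >= k * step) & (positions < k * step + window)
        np.add.at(counts, k[inside], 1)
    return counts


def select_candidates(counts: np.ndarray, min_count: int = MIN_COUNT, window: int = WINDOW, step: int = STEP):
    """Overlap-resolved candidate windows: greedy by descending count,
    ties to the leftmost window. Returns (window index, count) pairs."""
    ks = np.flatnonzero(counts >= min_count)
    if ks.size == 0:
        return []
    order = ks[np.lexsort((ks, -counts[ks]))]
    overlap_span = -(-window // step)  # windows k, k' overlap iff |k-k'| < window/step
    blocked = np.zeros(counts.size, dtype=bool)
    chosen = []
    for k in order:
        if blocked[k]:
            continue
        chosen.append((int(k), int(counts[k])))
        blocked[max(0, k - overlap_span + 1): k + overlap_span] = True
    return sorted(chosen)


def find_candidate_anchors(
    contacts: pd.DataFrame,
    assembly: GenomeAssembly,
    window: int = WINDOW,
    step: int = STEP,
    min_separation: int = MIN_SEPARATION,
    min_count: int = MIN_COUNT,
) -> pd.DataFrame:
    """Sliding-window scan for candidate hub anchors on every chromosome."""
    rows = []
    for chrom in assembly.names:
        length = int(assembly.lengths[chrom])
        ends, partners = long_range_ends(contacts, chrom, min_separation)
        counts = window_counts(ends, length, window, step)
        for k, count in select_candidates(counts, min_count, window, step):
            start = k * step
            inside = (ends >= start) & (ends < start + window)
            sites = np.sort(partners[inside])
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": start + window,
                    "count": count,
                    "sites": sites,
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "count", "sites"])


def permute_long_range_contacts(
    contacts: pd.DataFrame,
    assembly: GenomeAssembly,
    min_separation: int = MIN_SEPARATION,
    seed=0,
) -> pd.DataFrame:
    """Relocate every long-range intra contact uniformly along its
    chromosome, keeping the sequence separation in the contact the same.
    Other records are untouched; a contact whose separation reaches the
    chromosome length stays in place with a warning."""
    rng = rng_from(seed)
    df = contacts.copy()
    intra = (df["chrom_a"] == df["chrom_b"]).to_numpy()
    sep = (df["pos_b"] - df["pos_a"]).abs().to_numpy()
    lengths = df["chrom_a"].map(assembly.lengths).to_numpy()
    movable = intra & (sep > min_separation) & (sep < lengths)
    stuck = intra & (sep > min_separation) & (sep >= lengths)
    if stuck.any():
        warnings.warn(f"{int(stuck.sum())} contacts span a whole chromosome; kept in place")
    if movable.any():
        max_left = (lengths - sep)[movable]
        new_left = rng.integers(0, max_left)  # uniform on [0, L - separation)
        df.loc[movable, "pos_a"] = new_left
        df.loc[movable, "pos_b"] = new_left + sep[movable]
    return df


def hub_significance(
    candidates: pd.DataFrame,
    contacts: pd.DataFrame,
    assembly: GenomeAssembly,
    n_perm: int = 400,
    seed=0,
    q_threshold: float = 0.05,
    window: int = WINDOW,
    step: int = STEP,
    min_separation: int = MIN_SEPARATION,
    min_count: int = MIN_COUNT,
    cell_id: str | None = None,
    keep_all: bool = False,
) -> pd.DataFrame:
    """Permutation significance for candidate anchors of one cell.

    The null pools pseudo-anchor counts (same scan, same overlap rule) per
    chromosome over all permutations; when no pseudo-anchor reaches
    ``min_count`` in any permutation for a chromosome, the per-permutation
    maximum window count is pooled instead so p stays defined.
    """
    if n_perm < 50:
        warnings.warn("n_perm < 50 gives an unstable empirical p floor")
    rng = rng_from(seed)
    null_counts: dict = {}
    for chrom in assembly.names:
        if candidates.empty or not (candidates["chrom"] == chrom).any():
            continue
        length = int(assembly.lengths[chrom])
        sel = (
            (contacts["chrom_a"] == chrom)
            & (contacts["chrom_b"] == chrom)
            & ((contacts["pos_b"] - contacts["pos_a"]).abs() > min_separation)
        )
        sep = (contacts.loc[sel, "pos_b"] - contacts.loc[sel, "pos_a"]).abs().to_numpy()
        sep = sep[sep < length]
        pooled, maxima = [], []
        for _ in range(n_perm):
            left = rng.integers(0, length - sep) if sep.size else np.empty(0, dtype=np.int64)
            ends = np.concatenate([left, left + sep])
            counts = window_counts(ends, length, window, step)
            if counts.size:
                maxima.append(int(counts.max()))
            pooled.extend(c for _, c in select_candidates(counts, min_count, window, step))
        null_counts[chrom] = np.asarray(pooled if pooled else maxima, dtype=float)

    rows = []
    for row in candidates.itertuples(index=False):
        null = null_counts.get(row.chrom, np.empty(0))
        p = float(empirical_p(row.count, null)[0])
        rows.append(
            {
                "cell_id": cell_id,
                "chrom": row.chrom,
                "start": int(row.start),
                "end": int(row.end),
                "count": int(row.count),
                "sites": row.sites,
                "p": p,
                "n_null": int(null.size),
            }
        )
    hubs = pd.DataFrame(
        rows, columns=["cell_id", "chrom", "start", "end", "count", "sites", "p", "n_null"]
    )
    if hubs.empty:
        hubs["q"] = pd.Series(dtype=float)
        hubs["span_class"] = pd.Series(dtype=object)
        return hubs
    hubs["q"] = bh_adjust(hubs["p"].to_numpy())
    hubs["span_class"] = [
        span_class((r.start + r.end) // 2, r.sites) for r in hubs.itertuples(index=False)
    ]
    if not keep_all:
        hubs = hubs[hubs["q"] < q_threshold].reset_index(drop=True)
    return hubs


def span_class(anchor_center: int, intra_site_positions, threshold: int = SPAN_THRESHOLD):
    """"short" if every intra-chromosomal contact lies within 1 Mb of the
    anchor center, "long" otherwise (half-open: exactly 1 Mb is long).
    Returns None when there are no intra contacts to classify."""
    sites = np.asarray(intra_site_positions)
    if sites.size == 0:
        return None
    max_span = int(np.abs(sites - anchor_center).max())
    return "long" if max_span >= threshold else "short"


def detect_hubs(contacts: pd.DataFrame, assembly: GenomeAssembly, seed=0, **kwargs) -> pd.DataFrame:
    """Scan + permutation test in one call (one cell)."""
    sig_keys = {"n_perm", "q_threshold", "cell_id", "keep_all"}
    scan_kwargs = {k: v for k, v in kwargs.items() if k not in sig_keys}
    sig_kwargs = {k: v for k, v in kwargs.items() if k in sig_keys}
    candidates = find_candidate_anchors(contacts, assembly, **scan_kwargs)
    return hub_significance(candidates, contacts, assembly, seed=seed, **scan_kwargs, **sig_kwargs)


@dataclass
class AbundanceProfile:
    scaled: np.ndarray
    sd: np.ndarray
    counts: np.ndarray


def hub_abundance_by_intermingling(
    hub_groups: np.ndarray,
    n_groups: int = 10,
    n_bootstrap: int = 2000,
    sample_fraction: float = 0.3,
    seed=0,
) -> AbundanceProfile:
    """Hub abundance per intermingling group, scaled by the mean across
    groups (profile mean = 1), with bootstrap SDs from random subsamples
    of the hubs."""
    groups = np.asarray(hub_groups, dtype=int)
    groups = groups[groups >= 1]
    if groups.size == 0:
        raise ValueError("no hubs fall in any intermingling group")
    counts = np.bincount(groups, minlength=n_groups + 1)[1:]
    if counts.sum() == 0:
        raise ValueError("empty groups")
    scaled = counts / counts.mean()
    rng = rng_from(seed)
    k = max(1, int(round(sample_fraction * groups.size)))
    boot = np.empty((n_bootstrap, n_groups))
    for b in range(n_bootstrap):
        pick = rng.choice(groups.size, size=k, replace=False)
        c = np.bincount(groups[pick], minlength=n_groups + 1)[1:]
        boot[b] = c / c.mean() if c.mean() > 0 else np.nan
    return AbundanceProfile(scaled=scaled, sd=boot.std(axis=0, ddof=1), counts=counts)
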