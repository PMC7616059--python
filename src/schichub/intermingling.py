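"""Chromosome intermingling scores and trans spatial density.

A locus's intermingling score is the fraction of its spatially proximal
neighborhood (beads consistently within <2 bead radii in every replica
model, both loci positionally precise: ensemble RMSD < 1.5 radii) that lies
on other chromosomes. Because bins are uniform, the "summed length" of
neighbor regions reduces to bead counting. Per-cell tracks are
quantile-normalized, the per-locus median across cells is taken, and loci
are partitioned into equal-size ordered groups.

The trans density of a bead is the sum of reciprocal center-center
distances to all beads on other chromosomes, averaged over replicas and
scaled so the all-bead background median is exactly 1.00.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

from .io import StructureEnsemble
from .structure import align_ensemble

PROXIMITY_RADIUS = 2.0  # bead radii
PRECISION_RMSD = 1.5  # bead radii


def proximity_sets(
    ensemble: StructureEnsemble,
    proximity_radius: float = PROXIMITY_RADIUS,
    precision_rmsd: float = PRECISION_RMSD,
):
    """Per-bead neighbor sets: bead c is a neighbor of b iff both pass the
    precision filter and dist(b, c) < proximity_radius in ALL models.

    Returns (boolean neighbor matrix, boolean per-bead validity mask).
    Beads failing the precision filter are invalid (NA downstream).
    """
    if ensemble.n_models == 0:
        raise ValueError("ensemble has no models")
    aligned, per_bead_rmsd = align_ensemble(ensemble)
    if per_bead_rmsd is None:  # single model: every bead counts as precise
        valid = np.ones(ensemble.n_beads, dtype=bool)
    else:
        valid = per_bead_rmsd < precision_rmsd
    n = ensemble.n_beads
    within_all = np.ones((n, n), dtype=bool)
    for m in range(aligned.n_models):
        d = cdist(aligned.coords[m], aligned.coords[m])
        within_all &= d < proximity_radius
    np.fill_diagonal(within_all, False)
    within_all &= valid[:, None] & valid[None, :]
    return within_all, valid


def intermingling_score(neighbors: np.ndarray, valid: np.ndarray, chrom_codes: np.ndarray) -> np.ndarray:
    """Raw per-bead score: trans neighbors / all neighbors; NaN when the
    bead is imprecise or has an empty proximity set."""
    n = neighbors.shape[0]
    trans = chrom_codes[None, :] != chrom_codes[:, None]
    n_all = neighbors.sum(axis=1).astype(float)
    n_trans = (neighbors & trans).sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        score = n_trans / n_all
    score[(n_all == 0) | ~valid] = np.nan
    return score


def cell_track(ensemble: StructureEnsemble, **kwargs) -> np.ndarray:
    """Raw intermingling track for one cell's ensemble."""
    neighbors, valid = proximity_sets(ensemble, **kwargs)
    return intermingling_score(neighbors, valid, ensemble.chrom_codes())


def normalize_and_aggregate(tracks, n_groups: int = 10):
    """Quantile-normalize per-cell tracks (reference: mean of the sorted
    distributions across cells), take the per-locus median across cells,
    and partition non-NA loci into equal-size ordered groups (1..n_groups,
    lowest scores first; sizes differ by at most one)."""
    tracks = np.asarray(tracks, dtype=float)
    if tracks.ndim != 2 or tracks.shape[0] < 1:
        raise ValueError("expected a cells x loci array with >= 1 cell")
    n_cells, n_loci = tracks.shape

    # reference distribution: mean of sorted per-cell values at matched quantiles
    grid = np.linspace(0, 1, 101)
    per_cell_q = []
    for c in range(n_cells):
        vals = tracks[c][~np.isnan(tracks[c])]
        if vals.size == 0:
            continue
        per_cell_q.append(np.quantile(np.sort(vals), grid))
    if not per_cell_q:
        raise ValueError("all tracks are empty")
    reference = np.mean(per_cell_q, axis=0)

    normalized = np.full_like(tracks, np.nan)
    for c in range(n_cells):
        valid = ~np.isnan(tracks[c])
        if valid.sum() == 0:
            continue
        ranks = stats.rankdata(tracks[c][valid], method="average")
        q = (ranks - 0.5) / valid.sum()
        normalized[c, valid] = np.interp(q, grid, reference)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        median = np.nanmedian(normalized, axis=0)

    groups = np.zeros(n_loci, dtype=int)  # 0 = NA / ungrouped
    valid = ~np.isnan(median)
    order = np.argsort(median[valid], kind="stable")
    idx = np.flatnonzero(valid)[order]
    for g, chunk in enumerate(np.array_split(idx, n_groups), start=1):
        groups[chunk] = g
    return normalized, median, groups


def feature_enrichment(
    feature_per_bin: np.ndarray,
    median_scores: np.ndarray,
    mode: str = "top30_vs_bottom30",
    cap: float = 10.0,
):
    """Compare feature density between intermingling strata.

    ``top30_vs_bottom30``: log2 fold change of mean feature density in the
    top vs bottom 30% of loci by median score (infinite ratios capped at
    +/-``cap`` with a flag). ``fisher``: exact 2x2 test of feature/
    non-feature counts in the highest vs lowest decile groups.
    """
    feature = np.asarray(feature_per_bin, dtype=float)
    med = np.asarray(median_scores, dtype=float)
    valid = ~np.isnan(med)
    if valid.sum() < 4:
        raise ValueError("too few scored loci")
    f, m = feature[valid], med[valid]
    lo_thr, hi_thr = np.quantile(m, [0.3, 0.7])
    bottom, top = f[m <= lo_thr], f[m >= hi_thr]
    if bottom.size == 0 or top.size == 0:
        raise ValueError("empty stratum")
    if mode == "top30_vs_bottom30":
        dt, db = top.mean(), bottom.mean()
        capped = False
        if dt == 0 and db == 0:
            lfc = 0.0
        elif db == 0:
            lfc, capped = cap, True
        elif dt == 0:
            lfc, capped = -cap, True
        else:
            lfc = float(np.clip(np.log2(dt / db), -cap, cap))
            capped = abs(lfc) >= cap
        return {"log2fc": lfc, "capped": capped, "n_top": top.size, "n_bottom": bottom.size}
    if mode == "fisher":
        deciles = np.quantile(m, [0.1, 0.9])
        low, high = f[m <= deciles[0]], f[m >= deciles[1]]
        table = np.array(
            [[(high > 0).sum(), (high == 0).sum()], [(low > 0).sum(), (low == 0).sum()]]
        )
        odds, p = stats.fisher_exact(table)
        return {"table": table, "odds_ratio": float(odds), "p": float(p)}
    raise ValueError(f"unknown mode {mode!r}")


def trans_density(ensemble: StructureEnsemble, class_labels=None):
    """Per-bead trans spatial density: mean over models of the sum of
    reciprocal center-center distances to beads on other chromosomes,
    scaled by the all-bead background median (= 1.00).

    ``class_labels`` (per bead, e.g. "A"/"B"/"hub") selects per-class
    scaled-density distributions for histogramming.
    """
    codes = ensemble.chrom_codes()
    n = ensemble.n_beads
    trans = codes[None, :] != codes[:, None]
    density = np.zeros(n)
    dropped = 0
    for m in range(ensemble.n_models):
        d = cdist(ensemble.coords[m], ensemble.coords[m])
        zero = (d == 0) & trans
        if zero.any():
            dropped += int(zero.sum() // 2)
        with np.errstate(divide="ignore"):
            inv = np.where(trans & (d > 0), 1.0 / np.where(d > 0, d, 1.0), 0.0)
        density += inv.sum(axis=1)
    if dropped:
        warnings.warn(f"excluded {dropped} coincident trans bead pairs")
    density /= ensemble.n_models
    background_median = float(np.median(density))
    if background_median <= 0:
        raise ValueError("degenerate background: median trans density is 0")
    scaled = density / background_median
    result = {"raw": density, "scaled": scaled, "background_median": background_median}
    if class_labels is not None:
        labels = np.asarray(class_labels, dtype=object)
        result["by_class"] = {
            lab: scaled[labels == lab] for lab in pd.unique(labels) if lab is not None
        }
    return result


def discrimination_test(scores_high, scores_low):
    """Rank-sum test that per-cell median scores differ between two arms."""
    return stats.mannwhitneyu(scores_high, scores_low, alternative="greater")
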