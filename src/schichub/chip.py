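"""H3K27me3 promoter trajectory clustering and bivalency tracking.

Each H3K27me3-bound promoter is described by its intensity changes
(24h - naive, primed - 24h) per ChIP replicate, scaled by the gene's
maximum intensity across time points; promoters are clustered on Euclidean
distances with Ward's linkage and the dendrogram is cut top-down, splitting
a branch only while both children keep at least ``min_cluster_size``
members (a conservative analog of dynamic tree cutting at deepSplit 1).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage

TIME_COLUMNS = ("naive", "h24", "primed")

BIVALENCY_CLASSES = (
    "always_bivalent",
    "formed_24h_maintained",
    "bivalent_only_naive",
    "bivalent_only_primed",
    "never_bivalent",
)


def trajectory_features(intensities: pd.DataFrame) -> pd.DataFrame:
    """Scaled change vectors per gene.

    ``intensities`` has one row per (gene, replicate) with columns naive,
    h24, primed. Differences (h24-naive, primed-h24) are divided by the
    per-gene maximum intensity over all time points and replicates; genes
    with all-zero intensity are excluded. Output columns are
    d1_rep<i>, d2_rep<i> in replicate order.
    """
    for col in TIME_COLUMNS:
        if (intensities[col] < 0).any():
            raise ValueError("negative intensity")
    rows = {}
    for gene, sub in intensities.groupby("gene", sort=True):
        vals = sub[list(TIME_COLUMNS)].to_numpy(dtype=float)
        scale = vals.max()
        if scale <= 0:
            continue  # all-zero gene: excluded
        feats = []
        for rep in range(vals.shape[0]):
            naive, h24, primed = vals[rep]
            feats.extend([(h24 - naive) / scale, (primed - h24) / scale])
        rows[gene] = feats
    if not rows:
        return pd.DataFrame()
    n_rep = len(next(iter(rows.values()))) // 2
    cols = [f"{d}_rep{r + 1}" for r in range(n_rep) for d in ("d1", "d2")]
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


def _cut_min_size(link: np.ndarray, n: int, min_cluster_size: int) -> np.ndarray:
    """Top-down cut: split a branch only while both children would keep
    >= min_cluster_size members."""
    # children[k] for merged node n+k
    def members(node, out):
        if node < n:
            out.append(node)
        else:
            a, b = int(link[node - n, 0]), int(link[node - n, 1])
            members(a, out)
            members(b, out)

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 2 * n + 100))
    try:
        labels = np.zeros(n, dtype=int)
        next_label = [0]
        stack = [2 * n - 2]  # root node id
        final_nodes = []
        while stack:
            node = stack.pop()
            if node < n:
                final_nodes.append(node)
                continue
            a, b = int(link[node - n, 0]), int(link[node - n, 1])
            size_a = 1 if a < n else int(link[a - n, 3])
            size_b = 1 if b < n else int(link[b - n, 3])
            if size_a >= min_cluster_size and size_b >= min_cluster_size:
                stack.extend([a, b])
            else:
                final_nodes.append(node)
        for node in sorted(final_nodes):
            out: list = []
            members(node, out)
            labels[out] = next_label[0]
            next_label[0] += 1
    finally:
        sys.setrecursionlimit(old)
    return labels


def cluster_promoters(features: pd.DataFrame, min_cluster_size: int = 100) -> pd.Series:
    """Ward clustering of trajectory features with a minimum cluster size.

    Deterministic given input order. Returns integer labels (1-based)
    indexed by gene; a single cluster (with a warning) when there are too
    few genes to split."""
    x = features.to_numpy(dtype=float)
    n = x.shape[0]
    if n < 2 * min_cluster_size:
        warnings.warn("too few genes to split: returning a single cluster")
        return pd.Series(np.ones(n, dtype=int), index=features.index)
    link = linkage(x, method="ward")
    labels = _cut_min_size(link, n, min_cluster_size)
    # relabel 1..k in order of first appearance for determinism
    _, first = np.unique(labels, return_index=True)
    remap = {labels[i]: r + 1 for r, i in enumerate(sorted(first))}
    return pd.Series([remap[v] for v in labels], index=features.index)


def group_mean_profiles(features: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Per-cluster mean feature profile (simple per-group summary table)."""
    return features.groupby(labels).mean()


def track_bivalency(calls: pd.DataFrame) -> pd.Series:
    """Classify per-gene bivalency trajectories.

    ``calls`` has one row per gene with boolean columns k4_<tp> and
    k27_<tp> for tp in naive, h24, primed. Bivalent = both marks present.
    Unlisted monovalent transition patterns are labelled "other" with the
    per-time-point state string preserved in the label index.
    """
    for tp in TIME_COLUMNS:
        for mark in ("k4", "k27"):
            if f"{mark}_{tp}" not in calls.columns:
                raise ValueError(f"missing time point column {mark}_{tp}")
    out = {}
    for row in calls.itertuples():
        bivalent = tuple(
            bool(getattr(row, f"k4_{tp}")) and bool(getattr(row, f"k27_{tp}"))
            for tp in TIME_COLUMNS
        )
        if bivalent == (True, True, True):
            cls = "always_bivalent"
        elif bivalent == (False, True, True):
            cls = "formed_24h_maintained"
        elif bivalent == (True, False, False):
            cls = "bivalent_only_naive"
        elif bivalent == (False, False, True):
            cls = "bivalent_only_primed"
        elif bivalent == (False, False, False):
            cls = "never_bivalent"
        else:
            cls = "other"
        out[row.Index] = cls
    return pd.Series(out)
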