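"""Regulatory element classes, hub enhancer-promoter contacts and
compartment-matched permutation enrichment tests.

Element rules (marks at a given time point; "48h" is the primed sample):
active enhancer = H3K27ac with no H3K4me3 or H3K27me3 (long H3K27ac peaks
trimmed to 1 kb around the center); active promoter = TSS with H3K4me3 and
H3K27ac and no H3K27me3; bivalent promoter = TSS with H3K4me3 and
H3K27me3; emerging enhancer = H3K27ac absent in naive but present at 48 h
with at least a 3x intensity increase (absent peaks take a pseudo-floor of
1% of the genome-wide median so the ratio is defined); weakening enhancer
is the mirror rule.

E-P contacts are called when a promoter and an enhancer lie no more than
20 kb (inclusive) from the anchor center and the contact site; anchors are
additionally typed by gene-group labels of TSS < 5 kb (exclusive) away.
The enrichment null re-pairs anchors with other hubs' contact sets within
the same A/B compartment, preserving every set's internal composition.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

from ._utils import bh_adjust, rng_from

FLANK = 20_000
TSS_FLANK = 5_000
TRIM_LENGTH = 1_000
RATIO_THRESHOLD = 3.0
PSEUDO_FLOOR_FRACTION = 0.01
TRANS_SUPPORT_RADII = 3.5

PROMOTER_CLASSES = ("active_promoter", "bivalent_promoter")
ENHANCER_CLASSES = ("active_enhancer", "emerging_enhancer", "weakening_enhancer")


def _intensity(track: pd.DataFrame) -> np.ndarray:
    return track[["rep1", "rep2"]].mean(axis=1).to_numpy()


def _overlaps_point(track: pd.DataFrame, chrom: str, pos: int) -> pd.DataFrame:
    return track[(track["chrom"] == chrom) & (track["start"] <= pos) & (track["end"] > pos)]


def _overlaps_interval(track: pd.DataFrame, chrom: str, start: int, end: int) -> pd.DataFrame:
    return track[(track["chrom"] == chrom) & (track["start"] < end) & (track["end"] > start)]


def trim_peak(start: int, end: int, max_length: int = TRIM_LENGTH):
    """Trim long peaks to ``max_length`` bp around the center."""
    if end - start <= max_length:
        return start, end
    center = (start + end) // 2
    return center - max_length // 2, center - max_length // 2 + max_length


def classify_elements(
    tracks: dict,
    tss: pd.DataFrame,
    timepoint: str = "primed",
    naive_timepoint: str = "naive",
) -> pd.DataFrame:
    """Assign regulatory classes from mark peaks at one time point context.

    ``tracks`` maps (mark, timepoint) to peak tables with rep1/rep2
    intensities. Returns one row per element with its (trimmed) interval.
    """
    required = [
        ("H3K4me3", timepoint),
        ("H3K27ac", timepoint),
        ("H3K27me3", timepoint),
        ("H3K27ac", naive_timepoint),
    ]
    missing = [key for key in required if key not in tracks]
    if missing:
        raise ValueError(f"missing mark tracks {missing}; classification rules blocked")

    k4 = tracks[("H3K4me3", timepoint)]
    k27ac = tracks[("H3K27ac", timepoint)]
    k27me3 = tracks[("H3K27me3", timepoint)]
    k27ac_naive = tracks[("H3K27ac", naive_timepoint)]

    all_k27ac = pd.concat([t for (m, _), t in tracks.items() if m == "H3K27ac"])
    floor = PSEUDO_FLOOR_FRACTION * (
        float(np.median(_intensity(all_k27ac))) if len(all_k27ac) else 1.0
    )
    floor = max(floor, 1e-9)

    rows = []
    # --- promoters (per TSS)
    for t in tss.itertuples(index=False):
        has_k4 = not _overlaps_point(k4, t.chrom, t.pos).empty
        has_ac = not _overlaps_point(k27ac, t.chrom, t.pos).empty
        has_me3 = not _overlaps_point(k27me3, t.chrom, t.pos).empty
        cls = None
        if has_k4 and has_me3:
            cls = "bivalent_promoter"
        elif has_k4 and has_ac and not has_me3:
            cls = "active_promoter"
        if cls:
            rows.append(
                {
                    "chrom": t.chrom,
                    "start": max(0, t.pos - TRIM_LENGTH // 2),
                    "end": t.pos + TRIM_LENGTH // 2,
                    "class": cls,
                    "timepoint": timepoint,
                    "gene": t.gene,
                }
            )

    # --- enhancers (per 48h/primed H3K27ac peak)
    for p in k27ac.itertuples(index=False):
        start, end = trim_peak(int(p.start), int(p.end))
        if not _overlaps_interval(k4, p.chrom, start, end).empty:
            continue
        if not _overlaps_interval(k27me3, p.chrom, start, end).empty:
            continue
        naive_hits = _overlaps_interval(k27ac_naive, p.chrom, start, end)
        intensity = (p.rep1 + p.rep2) / 2.0
        if naive_hits.empty and intensity / floor >= RATIO_THRESHOLD:
            cls = "emerging_enhancer"
        else:
            cls = "active_enhancer"
        rows.append(
            {"chrom": p.chrom, "start": start, "end": end, "class": cls,
             "timepoint": timepoint, "gene": None}
        )
    # weakening: naive peaks absent at 48h with >= 3x decrease
    for p in k27ac_naive.itertuples(index=False):
        start, end = trim_peak(int(p.start), int(p.end))
        if not _overlaps_interval(k27ac, p.chrom, start, end).empty:
            continue
        if not _overlaps_interval(tracks[("H3K4me3", naive_timepoint)], p.chrom, start, end).empty:
            continue
        intensity = (p.rep1 + p.rep2) / 2.0
        if intensity / floor >= RATIO_THRESHOLD:
            rows.append(
                {"chrom": p.chrom, "start": start, "end": end,
                 "class": "weakening_enhancer", "timepoint": timepoint, "gene": None}
            )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "class", "timepoint", "gene"]
    )


# ---------------------------------------------------------------------------
# Hub E-P contact typing


def _classes_near(elements: pd.DataFrame, chrom: str, pos: int, flank: int) -> list:
    near = elements[
        (elements["chrom"] == chrom)
        & (elements["start"] - flank <= pos)
        & (elements["end"] + flank > pos)
    ]
    return sorted(set(near["class"]))


def call_hub_ep_contacts(
    hubs: pd.DataFrame,
    elements: pd.DataFrame,
    tss: pd.DataFrame | None = None,
    flank: int = FLANK,
    tss_flank: int = TSS_FLANK,
) -> pd.DataFrame:
    """Type every (anchor, contact site) pair by the element classes within
    ``flank`` (inclusive) of the anchor center and of the contact site.

    When ``tss`` carries a ``group`` column, anchors are additionally typed
    by gene-group labels of TSS strictly closer than ``tss_flank``.
    """
    rows = []
    for hub_idx, hub in enumerate(hubs.itertuples(index=False)):
        center = (hub.start + hub.end) // 2
        anchor_classes = _classes_near(elements, hub.chrom, center, flank)
        anchor_groups = []
        if tss is not None and "group" in tss.columns:
            near = tss[(tss["chrom"] == hub.chrom) & ((tss["pos"] - center).abs() < tss_flank)]
            anchor_groups = sorted(set(near["group"]))
        for site in np.atleast_1d(hub.sites):
            site_classes = _classes_near(elements, hub.chrom, int(site), flank)
            rows.append(
                {
                    "hub": hub_idx,
                    "cell_id": getattr(hub, "cell_id", None),
                    "chrom": hub.chrom,
                    "anchor_center": center,
                    "site": int(site),
                    "anchor_classes": anchor_classes,
                    "anchor_groups": anchor_groups,
                    "site_classes": site_classes,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["hub", "cell_id", "chrom", "anchor_center", "site",
                 "anchor_classes", "anchor_groups", "site_classes"],
    )


# ---------------------------------------------------------------------------
# Compartment-matched shuffle test


def shuffle_and_test(
    anchor_labels,
    site_label_lists,
    compartments,
    n_perm: int = 5000,
    seed=0,
    cap: float = 10.0,
) -> pd.DataFrame:
    """Permutation enrichment of anchor-category x site-category totals.

    The null re-pairs each anchor with the contact-site set of another hub
    from the same compartment (uniform permutation within compartment),
    preserving per-compartment hub counts and every set's composition.
    Two one-sided empirical p-values are combined as min(2p, 1) and BH
    adjusted across category pairs; log2FC compares the observed total to
    the null mean (capped at +/-``cap`` when degenerate).
    """
    anchor_labels = list(anchor_labels)
    site_label_lists = list(site_label_lists)
    compartments = np.asarray(list(compartments), dtype=object)
    n_hubs = len(anchor_labels)
    if n_hubs != len(site_label_lists) or n_hubs != compartments.size:
        raise ValueError("anchor, site and compartment inputs must align")

    a_cats = sorted({a for a in anchor_labels if a is not None})
    s_cats = sorted({s for sites in site_label_lists for s in sites})
    if not a_cats or not s_cats:
        raise ValueError("no labelled anchors or sites")
    a_index = {c: k for k, c in enumerate(a_cats)}
    s_index = {c: k for k, c in enumerate(s_cats)}

    a_mat = np.zeros((n_hubs, len(a_cats)))
    s_mat = np.zeros((n_hubs, len(s_cats)))
    for h, (a, sites) in enumerate(zip(anchor_labels, site_label_lists)):
        if a is not None:
            a_mat[h, a_index[a]] = 1.0
        for s in sites:
            s_mat[h, s_index[s]] += 1.0

    observed = a_mat.T @ s_mat

    strata = []
    for comp in pd.unique(compartments):
        idx = np.flatnonzero(compartments == comp)
        if idx.size < 2:
            warnings.warn(f"compartment {comp!r} has < 2 hubs; skipped in the shuffle")
            continue
        strata.append(idx)
    if not strata:
        raise ValueError("no compartment stratum with >= 2 hubs")

    rng = rng_from(seed)
    ge = np.zeros_like(observed)
    le = np.zeros_like(observed)
    null_sum = np.zeros_like(observed)
    null_sq = np.zeros_like(observed)
    for _ in range(n_perm):
        perm = np.arange(n_hubs)
        for idx in strata:
            perm[idx] = idx[rng.permutation(idx.size)]
        t = a_mat.T @ s_mat[perm]
        ge += t >= observed
        le += t <= observed
        null_sum += t
        null_sq += t**2
    p_up = (1.0 + ge) / (1.0 + n_perm)
    p_down = (1.0 + le) / (1.0 + n_perm)
    p_two = np.minimum(1.0, 2.0 * np.minimum(p_up, p_down))
    null_mean = null_sum / n_perm
    null_sd = np.sqrt(np.maximum(null_sq / n_perm - null_mean**2, 0.0))

    with np.errstate(divide="ignore", invalid="ignore"):
        lfc = np.log2(observed / null_mean)
    capped = ~np.isfinite(lfc)
    lfc = np.clip(np.nan_to_num(lfc, nan=0.0, posinf=cap, neginf=-cap), -cap, cap)

    rows = []
    q = bh_adjust(p_two.ravel()).reshape(p_two.shape)
    for ai, a in enumerate(a_cats):
        for si, s in enumerate(s_cats):
            rows.append(
                {
                    "anchor_category": a,
                    "site_category": s,
                    "observed": observed[ai, si],
                    "null_mean": null_mean[ai, si],
                    "null_sd": null_sd[ai, si],
                    "log2fc": lfc[ai, si],
                    "capped": bool(capped[ai, si]),
                    "p": p_two[ai, si],
                    "p_up": p_up[ai, si],
                    "q": q[ai, si],
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Inter-chromosomal E-P contacts


def filter_trans_by_structure(
    contacts: pd.DataFrame,
    ensemble,
    max_distance: float = TRANS_SUPPORT_RADII,
):
    """Keep inter-chromosomal contacts supported by the 3D structure, i.e.
    whose bead pair lies within ``max_distance`` bead radii (median over
    the replica models). Returns (kept trans contacts, n dropped)."""
    trans = contacts[contacts["chrom_a"] != contacts["chrom_b"]].reset_index(drop=True)
    if trans.empty:
        return trans, 0
    offsets, sizes = {}, {}
    pos = 0
    for chrom in dict.fromkeys(ensemble.chroms):
        n = int(np.sum(ensemble.chroms == chrom))
        offsets[chrom], sizes[chrom] = pos, n
        pos += n
    bi = np.array([offsets[c] + min(p // ensemble.bin_size, sizes[c] - 1)
                   for c, p in zip(trans["chrom_a"], trans["pos_a"])])
    bj = np.array([offsets[c] + min(p // ensemble.bin_size, sizes[c] - 1)
                   for c, p in zip(trans["chrom_b"], trans["pos_b"])])
    dist = np.median(
        np.linalg.norm(ensemble.coords[:, bj, :] - ensemble.coords[:, bi, :], axis=2),
        axis=0,
    )
    keep = dist < max_distance
    return trans.loc[keep].reset_index(drop=True), int((~keep).sum())


def interchrom_ep_enrichment(
    promoter_idx,
    enhancer_idx,
    promoter_labels,
    enhancer_labels,
    promoter_compartments,
    enhancer_compartments,
    n_perm: int = 5000,
    seed=0,
    cap: float = 10.0,
) -> pd.DataFrame:
    """Enrichment of promoter-group x enhancer-class trans contact totals.

    Contacts are given as indices into promoter/enhancer element tables;
    the null shuffles element identities (labels) within the A or B
    compartment, keeping the contact topology fixed.
    """
    p_idx = np.asarray(promoter_idx, dtype=int)
    e_idx = np.asarray(enhancer_idx, dtype=int)
    p_labels = np.asarray(list(promoter_labels), dtype=object)
    e_labels = np.asarray(list(enhancer_labels), dtype=object)
    p_comp = np.asarray(list(promoter_compartments), dtype=object)
    e_comp = np.asarray(list(enhancer_compartments), dtype=object)

    p_cats = sorted(set(p_labels))
    e_cats = sorted(set(e_labels))
    p_code = np.array([p_cats.index(x) for x in p_labels])
    e_code = np.array([e_cats.index(x) for x in e_labels])

    def totals(pc, ec):
        t = np.zeros((len(p_cats), len(e_cats)))
        np.add.at(t, (pc[p_idx], ec[e_idx]), 1.0)
        return t

    observed = totals(p_code, e_code)
    rng = rng_from(seed)
    p_strata = [np.flatnonzero(p_comp == c) for c in pd.unique(p_comp)]
    e_strata = [np.flatnonzero(e_comp == c) for c in pd.unique(e_comp)]
    ge = np.zeros_like(observed)
    le = np.zeros_like(observed)
    null_sum = np.zeros_like(observed)
    for _ in range(n_perm):
        pc = p_code.copy()
        ec = e_code.copy()
        for idx in p_strata:
            pc[idx] = pc[idx[rng.permutation(idx.size)]]
        for idx in e_strata:
            ec[idx] = ec[idx[rng.permutation(idx.size)]]
        t = totals(pc, ec)
        ge += t >= observed
        le += t <= observed
        null_sum += t
    p_up = (1.0 + ge) / (1.0 + n_perm)
    p_down = (1.0 + le) / (1.0 + n_perm)
    p_two = np.minimum(1.0, 2.0 * np.minimum(p_up, p_down))
    null_mean = null_sum / n_perm
    with np.errstate(divide="ignore", invalid="ignore"):
        lfc = np.log2(observed / null_mean)
    lfc = np.clip(np.nan_to_num(lfc, nan=0.0, posinf=cap, neginf=-cap), -cap, cap)
    q = bh_adjust(p_two.ravel()).reshape(p_two.shape)
    rows = []
    for pi, pcat in enumerate(p_cats):
        for ei, ecat in enumerate(e_cats):
            rows.append(
                {"promoter_group": pcat, "enhancer_class": ecat,
                 "observed": observed[pi, ei], "null_mean": null_mean[pi, ei],
                 "log2fc": lfc[pi, ei], "p": p_two[pi, ei], "q": q[pi, ei]}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Hub chromatin-state profiles


def hub_state_profiles(hubs: pd.DataFrame, mark_values: dict, assembly) -> dict:
    """Per-hub mean mark abundance over contact sites, Ward-clustered; the
    anchor profile matrix keeps the same row order so each row stays the
    same hub in both heatmaps.

    ``mark_values`` maps mark name -> per-global-bin abundance array.
    """
    marks = sorted(mark_values)
    offsets = assembly.bin_offsets()
    contact_rows, anchor_rows, kept = [], [], []
    for idx, hub in enumerate(hubs.itertuples(index=False)):
        sites = np.atleast_1d(hub.sites)
        if sites.size == 0:
            continue
        site_bins = offsets[hub.chrom] + sites // assembly.bin_size
        center_bin = offsets[hub.chrom] + ((hub.start + hub.end) // 2) // assembly.bin_size
        contact_rows.append([float(np.mean(mark_values[m][site_bins])) for m in marks])
        anchor_rows.append([float(mark_values[m][center_bin]) for m in marks])
        kept.append(idx)
    if not contact_rows:
        raise ValueError("no hubs with typed contact sites")
    contact = np.asarray(contact_rows)
    anchor = np.asarray(anchor_rows)
    if contact.shape[0] > 2:
        link = linkage(contact, method="ward")
        order = leaves_list(link)
    else:
        link, order = None, np.arange(contact.shape[0])
    return {
        "marks": marks,
        "hubs": np.asarray(kept)[order],
        "contact_matrix": contact[order],
        "anchor_matrix": anchor[order],
        "linkage": link,
    }
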