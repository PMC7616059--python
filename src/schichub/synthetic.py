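"""Ground-truthed synthetic data for every pipeline stage.

The generator emulates a haploid multi-chromosome genome folded as confined
polymers with tunable chromosome-territory intermingling, sparse single-cell
Hi-C contact lists with planted multiway-hub anchors, checkerboard
compartment contact matrices, histone-mark peak tracks over three time
points (naive, 24h, primed), and Poisson-beta distributed expression counts.

Units: distances are in bead radii (bead radius 1, backbone bond length 2).
The study organism's data has no stated generative model, so everything here
is a deliberately simple stand-in whose planted truth downstream stages must
recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from ._utils import rng_from
from .genome import GenomeAssembly, build_genome
from .io import CONTACT_COLUMNS, StructureEnsemble, canonicalize_contacts

BOND_LENGTH = 2.0  # bead diameters of 2 radii; consecutive beads touch
PACKING_FRACTION = 0.08  # bead volume / nucleus volume
HUB_WINDOW = 40_000
MIN_HUB_SEPARATION = 50_000

MARKS = ("H3K4me3", "H3K27ac", "H3K27me3", "H3K9me3")
TIMEPOINTS = ("naive", "24h", "primed")

ELEMENT_KINDS = (
    "active_enhancer",
    "emerging_enhancer",
    "weakening_enhancer",
    "active_promoter",
    "bivalent_promoter",
)


@dataclass(frozen=True)
class PlantedHub:
    """A planted multiway hub: a 40 kb anchor contacting k distal sites.

    ``site_offsets`` are signed bp separations from the anchor-window
    center; each must exceed 50 kb + half a window in magnitude so every
    emitted contact is long-range (>50 kb) wherever the anchor end falls
    inside the window.
    """

    chrom: str
    anchor_start: int
    site_offsets: tuple

    @property
    def k(self) -> int:
        return len(self.site_offsets)

    @property
    def anchor_center(self) -> int:
        return self.anchor_start + HUB_WINDOW // 2


@dataclass
class GroundTruth:
    """Planted truth emitted alongside synthetic data."""

    assembly: GenomeAssembly
    conformation: np.ndarray | None = None
    hubs: list = field(default_factory=list)
    compartments: dict = field(default_factory=dict)
    elements: list = field(default_factory=list)
    kinetics: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# Polymer conformations


def nucleus_radius(n_beads: int) -> float:
    """Confining sphere radius (bead radii) at the model packing fraction."""
    return (n_beads / PACKING_FRACTION) ** (1.0 / 3.0)


def _territory_centers(n_chroms: int, shell_radius: float, rng) -> np.ndarray:
    """Deterministically spread chromosome territory centers on a shell."""
    if n_chroms == 1:
        return np.zeros((1, 3))
    # Fibonacci sphere: near-uniform spread, reproducible.
    k = np.arange(n_chroms)
    phi = np.arccos(1 - 2 * (k + 0.5) / n_chroms)
    theta = np.pi * (1 + 5**0.5) * (k + 0.5)
    pts = np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)],
        axis=1,
    )
    return shell_radius * pts


def simulate_conformation(
    assembly: GenomeAssembly, intermingle_level: float, seed
) -> np.ndarray:
    """Random-walk polymers confined in a sphere, with tunable territories.

    At ``intermingle_level`` 0 each chromosome is confined to a distinct
    sub-sphere on a shell (strict territories); at 1 every chromosome
    shares the full nucleus. Soft self-avoidance by rejection (bounded
    retries). Reproducible for a given seed.
    """
    if not 0.0 <= intermingle_level <= 1.0:
        raise ValueError("intermingle_level must be in [0, 1]")
    rng = rng_from(seed)
    s = float(intermingle_level)
    n_total = assembly.total_bins
    radius = nucleus_radius(n_total)
    shell = radius / 2.0
    centers0 = _territory_centers(assembly.n_chromosomes, shell, rng)
    if assembly.n_chromosomes > 1:
        from scipy.spatial.distance import pdist

        sub_radius = min(radius / 2.0, pdist(centers0).min() / 2.0)
    else:
        sub_radius = radius
    centers = (1.0 - s) * centers0
    conf_radius = sub_radius + s * (radius - sub_radius)

    coords = np.empty((n_total, 3))
    pos = 0
    for ci, chrom in enumerate(assembly.names):
        n = assembly.n_bins(chrom)
        center = centers[ci]
        prev = center + rng.normal(scale=0.5, size=3)
        placed = np.empty((n, 3))
        placed[0] = prev
        for b in range(1, n):
            accepted = None
            for _ in range(30):
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                cand = prev + BOND_LENGTH * direction
                if np.linalg.norm(cand - center) > conf_radius:
                    continue
                if accepted is None:
                    accepted = cand  # confinement-satisfying fallback
                d2 = np.sum((placed[:b] - cand) ** 2, axis=1)
                if d2.min() >= (0.75 * BOND_LENGTH) ** 2:
                    accepted = cand
                    break
            if accepted is None:
                # step straight back toward the territory center
                direction = center - prev
                norm = np.linalg.norm(direction)
                direction = direction / norm if norm > 0 else np.array([1.0, 0, 0])
                accepted = prev + BOND_LENGTH * direction
            placed[b] = accepted
            prev = accepted
        coords[pos : pos + n] = placed
        pos += n
    return coords


def trans_neighbor_fraction(coords: np.ndarray, chrom_codes: np.ndarray, radius: float = 3.0) -> float:
    """Mean per-bead fraction of spatial neighbors on other chromosomes."""
    tree = cKDTree(coords)
    pairs = tree.query_pairs(radius, output_type="ndarray")
    if pairs.size == 0:
        return 0.0
    trans = chrom_codes[pairs[:, 0]] != chrom_codes[pairs[:, 1]]
    return float(trans.mean())


def ensemble_from_truth(
    assembly: GenomeAssembly, conformation: np.ndarray, n_models: int = 5,
    jitter: float = 0.1, seed=0,
) -> StructureEnsemble:
    """Synthetic replica ensemble: the true conformation plus Gaussian jitter.

    Stands in for an annealed ensemble when a test only needs well-defined
    coordinates (labelled synthetic; it is not a model fit).
    """
    rng = rng_from(seed)
    coords = conformation[None, :, :] + rng.normal(
        scale=jitter, size=(n_models,) + conformation.shape
    )
    table = assembly.bead_table()
    chroms = [c for c, _ in table]
    starts = [s for _, s in table]
    return StructureEnsemble(chroms, starts, coords, assembly.bin_size)


# ---------------------------------------------------------------------------
# Contact sampling


def _bead_to_bp(assembly: GenomeAssembly, bead: np.ndarray, rng) -> tuple:
    """Map global bead indices to (chrom, random bp offset within bead)."""
    codes = assembly.bead_chromosomes()
    offsets = assembly.bin_offsets()
    names = np.asarray(assembly.names, dtype=object)
    chrom = names[codes[bead]]
    local = bead - np.asarray([offsets[c] for c in chrom])
    pos = local * assembly.bin_size + rng.integers(0, assembly.bin_size, size=bead.size)
    return chrom, pos


def sample_contacts(
    conformation: np.ndarray,
    assembly: GenomeAssembly,
    n_contacts: int,
    capture_radius: float = 2.0,
    noise_fraction: float = 0.0,
    planted_hubs=(),
    seed=0,
):
    """Draw a sparse single-cell contact list from a conformation.

    ``(1-noise_fraction)*n_contacts`` contacts come uniformly from bead
    pairs within ``capture_radius``; the rest are uniform random bead
    pairs. Each planted hub adds k contacts from its 40 kb anchor window
    to k sites at the specified separations. Returns the canonicalized
    contact list and the ground truth.
    """
    if capture_radius <= 0:
        raise ValueError("capture_radius must be positive")
    if not 0.0 <= noise_fraction <= 1.0:
        raise ValueError("noise_fraction must be in [0, 1]")
    rng = rng_from(seed)
    n_total = assembly.total_bins
    if conformation.shape != (n_total, 3):
        raise ValueError("conformation does not match assembly bead count")

    for hub in planted_hubs:
        length = int(assembly.lengths[hub.chrom])
        if not 0 <= hub.anchor_start <= length - HUB_WINDOW:
            raise ValueError(f"planted anchor outside chromosome {hub.chrom}")
        for off in hub.site_offsets:
            if abs(off) <= MIN_HUB_SEPARATION + HUB_WINDOW // 2:
                raise ValueError(
                    "site offset too small to guarantee long-range separation"
                )
            site = hub.anchor_center + off
            if not 0 <= site < length:
                raise ValueError(f"planted site outside chromosome {hub.chrom}")

    rows_i, rows_j = [], []
    n_noise = int(round(noise_fraction * n_contacts))
    n_prox = n_contacts - n_noise
    if n_prox > 0:
        tree = cKDTree(conformation)
        pairs = tree.query_pairs(capture_radius, output_type="ndarray")
        if pairs.size == 0:
            raise ValueError("no bead pairs within capture_radius")
        pick = rng.integers(0, pairs.shape[0], size=n_prox)
        rows_i.append(pairs[pick, 0])
        rows_j.append(pairs[pick, 1])
    if n_noise > 0:
        i = rng.integers(0, n_total, size=n_noise)
        j = rng.integers(0, n_total - 1, size=n_noise)
        j = np.where(j >= i, j + 1, j)  # exclude self-pairs
        rows_i.append(i)
        rows_j.append(j)

    if rows_i:
        bead_i = np.concatenate(rows_i)
        bead_j = np.concatenate(rows_j)
        chrom_a, pos_a = _bead_to_bp(assembly, bead_i, rng)
        chrom_b, pos_b = _bead_to_bp(assembly, bead_j, rng)
        df = pd.DataFrame(
            {"chrom_a": chrom_a, "pos_a": pos_a, "chrom_b": chrom_b, "pos_b": pos_b}
        )
    else:
        df = pd.DataFrame(columns=CONTACT_COLUMNS)

    hub_rows = []
    for hub in planted_hubs:
        for off in hub.site_offsets:
            anchor_pos = hub.anchor_start + int(rng.integers(0, HUB_WINDOW))
            hub_rows.append((hub.chrom, anchor_pos, hub.chrom, hub.anchor_center + off))
    if hub_rows:
        df = pd.concat(
            [df, pd.DataFrame(hub_rows, columns=CONTACT_COLUMNS)], ignore_index=True
        )
    df = df.astype({"pos_a": np.int64, "pos_b": np.int64}) if not df.empty else df
    truth = GroundTruth(
        assembly=assembly, conformation=conformation, hubs=list(planted_hubs)
    )
    return canonicalize_contacts(df, assembly), truth


# ---------------------------------------------------------------------------
# Compartments


def plant_compartments(assembly: GenomeAssembly, block_bins: int = 10) -> dict:
    """Alternating A/B blocks of ``block_bins`` bins per chromosome."""
    labels = {}
    for chrom in assembly.names:
        n = assembly.n_bins(chrom)
        blocks = (np.arange(n) // block_bins) % 2
        labels[chrom] = np.where(blocks == 0, "A", "B")
    return labels


def simulate_compartment_matrix(
    labels: np.ndarray, depth: float = 50.0, strength: float = 2.0,
    decay: float = 1.0, seed=0,
) -> np.ndarray:
    """Poisson contact counts with distance decay and checkerboard structure.

    Expected counts are ``depth * (1+|i-j|)**-decay``, multiplied by
    ``strength`` when bins i and j share a compartment label.
    """
    rng = rng_from(seed)
    labels = np.asarray(labels)
    n = labels.size
    idx = np.arange(n)
    sep = np.abs(idx[:, None] - idx[None, :])
    same = labels[:, None] == labels[None, :]
    expected = depth * (1.0 + sep) ** (-decay) * np.where(same, strength, 1.0)
    upper = np.triu(rng.poisson(expected), k=0)
    return np.triu(upper) + np.triu(upper, k=1).T


# ---------------------------------------------------------------------------
# ChIP-seq-like tracks


@dataclass(frozen=True)
class PlannedElement:
    kind: str
    chrom: str
    center: int
    gene: str | None = None

    def __post_init__(self):
        if self.kind not in ELEMENT_KINDS:
            raise ValueError(f"unknown element kind {self.kind!r}")


_REPLICATE_CV = 0.2
_BASE_INTENSITY = 10.0
_PROMOTER_PEAK = 1_000
_ENHANCER_PEAK = 1_600  # longer than 1 kb so downstream trimming is exercised


def _peak(rng, chrom, center, width, name, scale=1.0):
    intensity = scale * _BASE_INTENSITY * float(rng.lognormal(0.0, 0.25))
    sigma = np.sqrt(np.log1p(_REPLICATE_CV**2))
    reps = intensity * rng.lognormal(-0.5 * sigma**2, sigma, size=2)
    start = max(0, center - width // 2)
    return (chrom, start, start + width, name, reps[0], reps[1])


def generate_tracks(assembly: GenomeAssembly, plan, seed=0):
    """Per-mark, per-time-point peak tracks plus a TSS table.

    Peaks are built so the planned element classes are recoverable by the
    regulatory rules: e.g. an emerging enhancer has no naive H3K27ac peak
    and a strong (>= 3x over the pseudo-floor) primed peak; a bivalent
    promoter TSS is overlapped by both H3K4me3 and H3K27me3.
    """
    rng = rng_from(seed)
    tracks = {(m, t): [] for m in MARKS for t in TIMEPOINTS}
    tss_rows = []
    for i, el in enumerate(plan):
        length = int(assembly.lengths[el.chrom])
        if not 0 <= el.center < length:
            raise ValueError(f"element center outside chromosome {el.chrom}")
        name = f"{el.kind}_{i}"
        if el.kind == "active_promoter":
            gene = el.gene or f"gene_{i}"
            tss_rows.append((el.chrom, el.center, gene, "+"))
            for t in TIMEPOINTS:
                tracks[("H3K4me3", t)].append(_peak(rng, el.chrom, el.center, _PROMOTER_PEAK, name))
                tracks[("H3K27ac", t)].append(_peak(rng, el.chrom, el.center, _PROMOTER_PEAK, name))
        elif el.kind == "bivalent_promoter":
            gene = el.gene or f"gene_{i}"
            tss_rows.append((el.chrom, el.center, gene, "+"))
            for t in TIMEPOINTS:
                tracks[("H3K4me3", t)].append(_peak(rng, el.chrom, el.center, _PROMOTER_PEAK, name))
                tracks[("H3K27me3", t)].append(_peak(rng, el.chrom, el.center, _PROMOTER_PEAK, name))
        elif el.kind == "active_enhancer":
            for t in TIMEPOINTS:
                tracks[("H3K27ac", t)].append(_peak(rng, el.chrom, el.center, _ENHANCER_PEAK, name))
        elif el.kind == "emerging_enhancer":
            # absent in naive, present by primed/48h with a strong signal
            tracks[("H3K27ac", "24h")].append(_peak(rng, el.chrom, el.center, _ENHANCER_PEAK, name, 0.5))
            tracks[("H3K27ac", "primed")].append(_peak(rng, el.chrom, el.center, _ENHANCER_PEAK, name, 2.0))
        elif el.kind == "weakening_enhancer":
            tracks[("H3K27ac", "naive")].append(_peak(rng, el.chrom, el.center, _ENHANCER_PEAK, name, 2.0))
            tracks[("H3K27ac", "24h")].append(_peak(rng, el.chrom, el.center, _ENHANCER_PEAK, name, 0.5))

    tss = pd.DataFrame(tss_rows, columns=["chrom", "pos", "gene", "strand"])
    if not tss.empty and tss.duplicated(subset=["chrom", "pos"]).any():
        raise ValueError("overlapping TSS entries with identical coordinates")
    columns = ["chrom", "start", "end", "name", "rep1", "rep2"]
    out = {
        key: pd.DataFrame(rows, columns=columns).sort_values(
            ["chrom", "start"], kind="stable", ignore_index=True
        )
        for key, rows in tracks.items()
    }
    return out, tss


# ---------------------------------------------------------------------------
# Poisson-beta expression counts


def simulate_expression_counts(kinetics: pd.DataFrame, n_cells: int, seed=0) -> pd.DataFrame:
    """Counts under the bursting model: p ~ Beta(k_on, k_off), c ~ Poisson(s*p)."""
    rng = rng_from(seed)
    for col in ("k_on", "k_off", "s"):
        if (kinetics[col] < 0).any() or (kinetics[["k_on", "k_off"]] <= 0).any().any():
            raise ValueError("kinetic parameters must be strictly positive")
    counts = np.empty((len(kinetics), n_cells), dtype=np.int64)
    for g, row in enumerate(kinetics.itertuples(index=False)):
        p = rng.beta(row.k_on, row.k_off, size=n_cells)
        counts[g] = rng.poisson(row.s * p)
    genes = kinetics["gene"] if "gene" in kinetics else [f"g{i}" for i in range(len(kinetics))]
    return pd.DataFrame(counts, index=list(genes), columns=[f"cell{j}" for j in range(n_cells)])


__all__ = [
    "GroundTruth",
    "PlantedHub",
    "PlannedElement",
    "build_genome",
    "simulate_conformation",
    "trans_neighbor_fraction",
    "ensemble_from_truth",
    "sample_contacts",
    "plant_compartments",
    "simulate_compartment_matrix",
    "generate_tracks",
    "simulate_expression_counts",
]
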