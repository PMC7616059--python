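"""Single-cell 3D genome structures by hierarchical simulated annealing.

Hi-C contacts become flat-bottom harmonic distance restraints between the
beads of a particle-on-a-string polymer (one bead per genomic bin).
Structures are annealed coarse-to-fine over a resolution ladder with
overdamped Langevin dynamics and a geometric temperature schedule; repeat
calculations from different random starts give a replica ensemble which is
then rigid-body aligned (testing both chiralities) for RMSD and restraint
violation reporting.

Distances are expressed in bead radii of the target resolution; the
restraint target is one bead diameter (2 radii) with a flat bottom between
0.8 and 1.2 diameters. Global chirality is not determinable from distance
data alone, so ensembles are reported up to reflection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from ._utils import rng_from
from .genome import GenomeAssembly
from .io import StructureEnsemble

TARGET_DISTANCE = 2.0  # bead radii (= 1 diameter)
LOWER_BOUND = 1.6
UPPER_BOUND = 2.4
# soft excluded-volume core: beads repel below ~0.8 diameters; a full
# 1-diameter core is geometrically incompatible with contact-derived
# restraints at realistic chromatin densities and inflates the fold
REPULSION_DISTANCE = 1.65
K_RESTRAINT = 50.0
K_REPULSION = 25.0

# proximity shells for validation restraints measured on a known
# conformation: (capture radius, flat-bottom lower, flat-bottom upper)
VALIDATION_SHELLS = (
    (2.0, 1.0, 2.2),
    (3.0, 1.7, 3.3),
    (4.0, 2.6, 4.4),
    (5.0, 3.5, 5.5),
    (6.5, 4.3, 7.0),
)


@dataclass
class RestraintSet:
    """Pairwise flat-bottom distance restraints over a bead layout."""

    i: np.ndarray
    j: np.ndarray
    lower: np.ndarray
    target: np.ndarray
    upper: np.ndarray
    backbone: np.ndarray  # bool: sequence-adjacent backbone bond
    n_beads: int
    chrom_sizes: list = field(default_factory=list)  # (chrom, n_bins) in order

    def __post_init__(self):
        if np.any(self.i == self.j):
            raise ValueError("self-restraints are not allowed")
        if np.any(self.lower > self.target) or np.any(self.target > self.upper):
            raise ValueError("restraint bounds must satisfy lower <= target <= upper")

    @property
    def n_restraints(self) -> int:
        return self.i.size

    @property
    def n_contact_restraints(self) -> int:
        return int((~self.backbone).sum())


@dataclass(frozen=True)
class AnnealingSchedule:
    """Resolution ladder (multiples of the target bin size, strictly
    decreasing to 1) and a geometric temperature ladder per level."""

    ladder: tuple = (8, 4, 2, 1)
    temp_start: float = 5.0
    temp_factor: float = 0.5
    n_temps: int = 12
    steps_per_temp: int = 150
    quench_steps: int = 800
    dt: float = 0.05
    # finer ladder levels refine an already-folded conformation, so each
    # level starts colder than the one before by this factor
    level_temp_factor: float = 0.5

    @classmethod
    def thorough(cls) -> "AnnealingSchedule":
        """Slow-cooled schedule for accuracy-critical reconstructions."""
        return cls(n_temps=24, temp_factor=0.72, steps_per_temp=300,
                   quench_steps=2500, level_temp_factor=0.5)

    def __post_init__(self):
        if list(self.ladder) != sorted(self.ladder, reverse=True) or self.ladder[-1] != 1:
            raise ValueError("ladder must strictly decrease to 1")
        if not 0 < self.temp_factor < 1 or self.temp_start <= 0:
            raise ValueError("temperatures must be positive and decreasing")

    def temperatures(self) -> np.ndarray:
        return self.temp_start * self.temp_factor ** np.arange(self.n_temps)


def contacts_to_restraints(
    contacts: pd.DataFrame,
    assembly: GenomeAssembly,
    bin_size: int | None = None,
    lower: float = LOWER_BOUND,
    target: float = TARGET_DISTANCE,
    upper: float = UPPER_BOUND,
) -> RestraintSet:
    """One restraint per distinct contacted bead pair, plus backbone bonds.

    Duplicate contacts collapse to a single restraint; self-pairs drop, and
    a contact between sequence-adjacent beads is not duplicated over the
    backbone bond. The flat-bottom bounds default to 0.8-1.2 bead diameters
    around a 1-diameter target; widen ``upper`` toward the contact capture
    radius when contacts are known to come from a larger proximity cutoff.
    """
    bin_size = int(bin_size or assembly.bin_size)
    sizes = []
    offsets = {}
    total = 0
    for chrom in assembly.names:
        length = int(assembly.lengths[chrom])
        if length % bin_size != 0:
            raise ValueError(f"chromosome {chrom} length is not a multiple of {bin_size}")
        n = length // bin_size
        offsets[chrom] = total
        sizes.append((chrom, n))
        total += n

    pair_set = set()
    for row in contacts.itertuples(index=False):
        for chrom in (row.chrom_a, row.chrom_b):
            if chrom not in offsets:
                raise ValueError(f"contact on unknown chromosome {chrom!r}")
        if not (0 <= row.pos_a < assembly.lengths[row.chrom_a]) or not (
            0 <= row.pos_b < assembly.lengths[row.chrom_b]
        ):
            raise ValueError("contact position outside assembly")
        bi = offsets[row.chrom_a] + int(row.pos_a) // bin_size
        bj = offsets[row.chrom_b] + int(row.pos_b) // bin_size
        if bi == bj:
            continue
        pair_set.add((min(bi, bj), max(bi, bj)))

    bb_i, bb_j = [], []
    for chrom, n in sizes:
        off = offsets[chrom]
        for b in range(n - 1):
            bb_i.append(off + b)
            bb_j.append(off + b + 1)
    backbone_pairs = set(zip(bb_i, bb_j))
    contact_pairs = sorted(pair_set - backbone_pairs)

    i = np.asarray(bb_i + [p[0] for p in contact_pairs], dtype=np.int64)
    j = np.asarray(bb_j + [p[1] for p in contact_pairs], dtype=np.int64)
    n_rest = i.size
    backbone = np.zeros(n_rest, dtype=bool)
    backbone[: len(bb_i)] = True
    lo = np.where(backbone, LOWER_BOUND, lower)
    tg = np.where(backbone, TARGET_DISTANCE, target)
    up = np.where(backbone, UPPER_BOUND, upper)
    return RestraintSet(
        i=i,
        j=j,
        lower=lo,
        target=tg,
        upper=up,
        backbone=backbone,
        n_beads=total,
        chrom_sizes=sizes,
    )


def restraints_from_conformation(
    conformation: np.ndarray,
    assembly: GenomeAssembly,
    bin_size: int | None = None,
    shells=VALIDATION_SHELLS,
) -> RestraintSet:
    """Graded proximity restraints measured on a known conformation.

    Every bead pair within the outermost shell radius gets a flat-bottom
    restraint whose bounds come from the tightest shell containing the
    pair's true distance. This is the validation-oracle input for
    reconstruction experiments: the engine must refold the conformation
    from coarse distance classes, not from exact distances.
    """
    from scipy.spatial import cKDTree

    empty = pd.DataFrame(columns=["chrom_a", "pos_a", "chrom_b", "pos_b"])
    bb = contacts_to_restraints(empty, assembly, bin_size)
    if conformation.shape[0] != bb.n_beads:
        raise ValueError("conformation does not match the bead layout")
    tree = cKDTree(conformation)
    seen = set(zip(bb.i, bb.j))
    rows = []
    for radius, lo, up in sorted(shells):
        for pi, pj in tree.query_pairs(radius, output_type="ndarray"):
            key = (min(pi, pj), max(pi, pj))
            if key in seen:
                continue
            seen.add(key)
            rows.append((key[0], key[1], lo, 0.5 * (lo + up), up))
    if rows:
        arr = np.asarray(rows)
        i = np.concatenate([bb.i, arr[:, 0].astype(np.int64)])
        j = np.concatenate([bb.j, arr[:, 1].astype(np.int64)])
        lower = np.concatenate([bb.lower, arr[:, 2]])
        target = np.concatenate([bb.target, arr[:, 3]])
        upper = np.concatenate([bb.upper, arr[:, 4]])
        backbone = np.zeros(i.size, dtype=bool)
        backbone[: bb.i.size] = True
        return RestraintSet(i, j, lower, target, upper, backbone, bb.n_beads, bb.chrom_sizes)
    return bb


# ---------------------------------------------------------------------------
# Annealing core (distances in units of the current level's bead radius)


def _forces(x, ri, rj, lower, upper, energy_out=None, repulsion=True):
    d = x[rj] - x[ri]
    dist = np.linalg.norm(d, axis=1)
    dist = np.maximum(dist, 1e-9)
    over = np.clip(dist - upper, 0.0, None)
    under = np.clip(lower - dist, 0.0, None)
    mag = K_RESTRAINT * (over - under)  # signed pull along +d when too long
    fvec = (mag / dist)[:, None] * d
    forces = np.zeros_like(x)
    np.add.at(forces, ri, fvec)
    np.add.at(forces, rj, -fvec)

    # soft excluded volume below 2 radii
    energy = 0.5 * K_RESTRAINT * float(np.sum(over**2 + under**2))
    pairs = np.empty((0, 2), dtype=np.int64)
    if repulsion:
        tree = cKDTree(x)
        pairs = tree.query_pairs(REPULSION_DISTANCE, output_type="ndarray")
    if pairs.size:
        pd_ = x[pairs[:, 1]] - x[pairs[:, 0]]
        pdist = np.maximum(np.linalg.norm(pd_, axis=1), 1e-9)
        gap = REPULSION_DISTANCE - pdist
        pmag = K_REPULSION * gap / pdist
        pvec = pmag[:, None] * pd_
        np.add.at(forces, pairs[:, 0], -pvec)
        np.add.at(forces, pairs[:, 1], pvec)
        energy += 0.5 * K_REPULSION * float(np.sum(gap**2))
    if energy_out is not None:
        energy_out.append(energy)
    return forces


def potential_energy(x, ri, rj, lower, upper) -> float:
    out = []
    _forces(x, ri, rj, lower, upper, energy_out=out)
    return out[0]


def _dynamics(
    x, ri, rj, lower, upper, temps, steps, dt, rng,
    gamma: float = 2.0, max_speed: float = 10.0, repulsion: bool = True,
):
    """Underdamped Langevin dynamics with per-stage temperature.

    Inertia carries beads across the shallow barriers of the flat-bottom
    energy landscape; speeds are capped for stability.
    """
    v = np.zeros_like(x)
    for temp in temps:
        noise_scale = np.sqrt(2.0 * gamma * temp * dt)
        for _ in range(steps):
            f = _forces(x, ri, rj, lower, upper, repulsion=repulsion)
            v += dt * f - gamma * dt * v
            if temp > 0:
                v += noise_scale * rng.standard_normal(x.shape)
            speed = np.linalg.norm(v, axis=1, keepdims=True)
            np.divide(v, speed, out=v, where=speed > max_speed)
            v[np.squeeze(speed > max_speed, axis=1)] *= max_speed
            x += dt * v
    return x


def _coarsen_restraints(restraints: RestraintSet, factor: int):
    """Map restraints onto beads of ``factor`` x the target bin size."""
    fine_off, coarse_off, coarse_sizes = {}, {}, []
    ft = ct = 0
    for chrom, n in restraints.chrom_sizes:
        fine_off[chrom] = ft
        coarse_off[chrom] = ct
        nc = -(-n // factor)
        coarse_sizes.append((chrom, nc))
        ft += n
        ct += nc

    fine2coarse = np.empty(restraints.n_beads, dtype=np.int64)
    for chrom, n in restraints.chrom_sizes:
        local = np.arange(n)
        fine2coarse[fine_off[chrom] : fine_off[chrom] + n] = coarse_off[chrom] + local // factor

    pairs = set()
    for a, b in zip(fine2coarse[restraints.i], fine2coarse[restraints.j]):
        if a != b:
            pairs.add((min(a, b), max(a, b)))
    bb = set()
    for chrom, nc in coarse_sizes:
        off = coarse_off[chrom]
        for b in range(nc - 1):
            bb.add((off + b, off + b + 1))
    all_pairs = sorted(pairs | bb)
    i = np.asarray([p[0] for p in all_pairs], dtype=np.int64)
    j = np.asarray([p[1] for p in all_pairs], dtype=np.int64)
    n_beads = sum(n for _, n in coarse_sizes)
    return i, j, n_beads, coarse_sizes, fine2coarse


def _expand_positions(coarse_x, coarse_sizes, factor, fine_sizes, fine_factor, rng, jitter=0.1):
    """Linear interpolation along each chromosome chain, plus Gaussian jitter.

    ``coarse_x`` is in units of the coarse bead radius; the result is in
    units of the finer level's bead radius.
    """
    r_coarse = factor ** (1.0 / 3.0)
    r_fine = fine_factor ** (1.0 / 3.0)
    out = []
    ci = 0
    for (chrom, nc), (_, nf) in zip(coarse_sizes, fine_sizes):
        block = coarse_x[ci : ci + nc] * r_coarse  # to target-radius units
        ci += nc
        coarse_centers = (np.arange(nc) + 0.5) * factor
        fine_centers = (np.arange(nf) + 0.5) * fine_factor
        interp = np.stack(
            [np.interp(fine_centers, coarse_centers, block[:, k]) for k in range(3)],
            axis=1,
        )
        out.append(interp)
    fine = np.concatenate(out) / r_fine
    fine += jitter * rng.standard_normal(fine.shape)
    return fine


def _anneal_one(restraints: RestraintSet, schedule: AnnealingSchedule, rng):
    x = None
    prev_factor = None
    prev_sizes = None
    for li, factor in enumerate(schedule.ladder):
        if factor == 1:
            i, j = restraints.i, restraints.j
            n_beads, sizes = restraints.n_beads, restraints.chrom_sizes
            lower, upper = restraints.lower, restraints.upper
        else:
            i, j, n_beads, sizes, _ = _coarsen_restraints(restraints, factor)
            lower = np.full(i.size, LOWER_BOUND)
            upper = np.full(i.size, UPPER_BOUND)
        if x is None:
            radius = (n_beads / 0.08) ** (1.0 / 3.0)
            x = rng.uniform(-1, 1, size=(n_beads, 3))
            x *= radius * rng.uniform(0, 1, size=(n_beads, 1)) ** (1 / 3)
        else:
            x = _expand_positions(x, prev_sizes, prev_factor, sizes, factor, rng)
        temps = schedule.temperatures() * schedule.level_temp_factor**li
        x = _dynamics(x, i, j, lower, upper, temps, schedule.steps_per_temp,
                      schedule.dt, rng)
        # zero-temperature quench at every level; deepest at the target level
        quench = schedule.quench_steps if factor == 1 else schedule.quench_steps // 2
        x = _dynamics(x, i, j, lower, upper, [0.0], quench, schedule.dt, rng)
        prev_factor, prev_sizes = factor, sizes
    return x


def anneal(
    restraints: RestraintSet,
    assembly: GenomeAssembly,
    bin_size: int | None = None,
    n_models: int = 10,
    schedule: AnnealingSchedule | None = None,
    seed=0,
) -> StructureEnsemble:
    """Anneal ``n_models`` replica models from independent random starts."""
    if restraints.n_restraints == 0:
        raise ValueError("empty restraint set")
    if restraints.n_contact_restraints == 0:
        warnings.warn("no contact restraints: annealing a backbone-only fold")
    schedule = schedule or AnnealingSchedule()
    bin_size = int(bin_size or assembly.bin_size)
    rng = rng_from(seed)
    model_seeds = rng.integers(0, 2**31 - 1, size=n_models)
    models = [
        _anneal_one(restraints, schedule, rng_from(s)) for s in model_seeds
    ]
    chroms, starts = [], []
    for chrom, n in restraints.chrom_sizes:
        chroms.extend([chrom] * n)
        starts.extend(np.arange(n) * bin_size)
    return StructureEnsemble(chroms, starts, np.stack(models), bin_size)


# ---------------------------------------------------------------------------
# Alignment, RMSD, violations, noise filtering


def superpose(mobile: np.ndarray, reference: np.ndarray, allow_reflection: bool = True):
    """Least-squares rigid superposition (Kabsch), optionally over O(3).

    Returns (aligned coordinates, RMSD, reflected flag).
    """
    mc, rc = mobile.mean(axis=0), reference.mean(axis=0)
    a, b = mobile - mc, reference - rc
    u, s, vt = np.linalg.svd(a.T @ b)
    rot_free = u @ vt  # optimal over O(3); may be a reflection
    reflected = bool(np.linalg.det(rot_free) < 0)
    if reflected and not allow_reflection:
        d = np.ones(3)
        d[-1] = -1.0
        rot_free = (u * d) @ vt
        reflected = False
    aligned = a @ rot_free + rc
    rmsd = float(np.sqrt(np.mean(np.sum((aligned - reference) ** 2, axis=1))))
    return aligned, rmsd, reflected


def align_ensemble(ensemble: StructureEnsemble):
    """Superpose every model onto model 1 (both chiralities tested) and
    report the per-bead positional RMSD about the ensemble mean.

    For a single-model ensemble the RMSD is undefined and returned as None.
    """
    coords = ensemble.coords.copy()
    for m in range(1, ensemble.n_models):
        coords[m], _, _ = superpose(coords[m], coords[0], allow_reflection=True)
    aligned = StructureEnsemble(ensemble.chroms, ensemble.starts, coords, ensemble.bin_size)
    if ensemble.n_models < 2:
        return aligned, None
    mean = coords.mean(axis=0)
    per_bead = np.sqrt(np.mean(np.sum((coords - mean) ** 2, axis=2), axis=0))
    return aligned, per_bead


def bead_errors_vs_reference(ensemble: StructureEnsemble, reference: np.ndarray) -> np.ndarray:
    """Per-bead distance between the aligned ensemble-mean structure and a
    reference conformation, after chirality-matched superposition."""
    aligned, _ = align_ensemble(ensemble)
    mean = aligned.coords.mean(axis=0)
    al, _, _ = superpose(mean, reference, allow_reflection=True)
    return np.linalg.norm(al - reference, axis=1)


def violation_report(ensemble: StructureEnsemble, restraints: RestraintSet, tol: float = 0.0):
    """Per-model fraction of restraints outside their flat-bottom bounds."""
    if restraints.n_restraints == 0:
        raise ValueError("empty restraint set")
    fractions = []
    worst = np.zeros(restraints.n_restraints)
    for m in range(ensemble.n_models):
        x = ensemble.coords[m]
        dist = np.linalg.norm(x[restraints.j] - x[restraints.i], axis=1)
        outside = (dist < restraints.lower - tol) | (dist > restraints.upper + tol)
        fractions.append(float(outside.mean()))
        excess = np.maximum(restraints.lower - dist, dist - restraints.upper)
        worst = np.maximum(worst, excess)
    return {
        "per_model_fraction": np.asarray(fractions),
        "mean_fraction": float(np.mean(fractions)),
        "worst_excess": worst,
    }


def filter_noise_contacts(
    contacts: pd.DataFrame,
    ensemble: StructureEnsemble,
    assembly: GenomeAssembly,
    max_distance: float = 4.0,
):
    """Drop contacts whose bead pair exceeds ``max_distance`` in all models.

    The preliminary ensemble is typically a quick single-model fold; the
    idea is to keep only read pairs that are plausibly close in space.
    Returns (kept contacts, removed fraction).
    """
    if contacts.empty:
        return contacts.copy(), 0.0
    offsets, sizes = {}, {}
    pos = 0
    for chrom in dict.fromkeys(ensemble.chroms):
        n = int(np.sum(ensemble.chroms == chrom))
        offsets[chrom] = pos
        sizes[chrom] = n
        pos += n
    bi = np.array(
        [offsets[c] + min(p // ensemble.bin_size, sizes[c] - 1)
         for c, p in zip(contacts["chrom_a"], contacts["pos_a"])]
    )
    bj = np.array(
        [offsets[c] + min(p // ensemble.bin_size, sizes[c] - 1)
         for c, p in zip(contacts["chrom_b"], contacts["pos_b"])]
    )
    if np.isinf(max_distance):
        return contacts.copy(), 0.0
    dist = np.linalg.norm(
        ensemble.coords[:, bj, :] - ensemble.coords[:, bi, :], axis=2
    )  # (M, n_contacts)
    keep = (dist <= max_distance).any(axis=0)
    removed_fraction = float(1.0 - keep.mean())
    return contacts.loc[keep].reset_index(drop=True), removed_fraction
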