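# Methods

`schichub` re-implements, as a tested pipeline over synthetic data, the
computational chain used to study 3D genome reorganization in mouse
embryonic stem cells leaving naive pluripotency: single-cell Hi-C contacts
are folded into 3D polymer models, chromosome-territory intermingling is
scored from those models, multiway enhancer–promoter hubs are called with a
permutation null, compartment and regulatory-element structure is analysed
around them, and transcriptional bursting kinetics are inferred from
single-cell RNA counts. This note records the models, the parameters that
matter, and the design choices that were genuinely open.

## Synthetic data generator

All pipeline stages are exercised on generated data with planted ground
truth; no external downloads are required. The generator emulates:

* **Genome and conformations.** A haploid genome of equal-length
  chromosomes, one bead per bin (bead radius 1, backbone bond 2 radii).
  Chromosomes are random walks with soft self-avoidance (rejection at
  <1.5 radii, bounded retries) confined in a nucleus whose volume gives a
  bead packing fraction of 0.08. An `intermingle_level` in [0, 1]
  interpolates between strict territories (each chromosome in a disjoint
  sub-sphere on a shell) and full sharing of the nucleus. Self-avoidance is
  enforced within chromosomes only, so trans bead pairs may approach
  arbitrarily closely — a deliberate simplification.
* **Contact lists.** A fraction `1 - noise_fraction` of contacts is drawn
  uniformly from bead pairs within a capture radius (default 2 radii,
  matching the downstream proximity threshold); the rest are uniform random
  bead pairs. Planted multiway hubs add k contacts from a 40 kb anchor
  window to sites at specified separations, each guaranteed to be
  long-range (>50 kb) wherever the anchor end falls. Contact base-pair
  positions are uniform within beads.
* **Compartments.** Alternating A/B blocks per chromosome; contact count
  matrices are Poisson draws around `depth * (1+|i-j|)^-1`, multiplied by
  `strength` for same-compartment pairs (a checkerboard).
* **ChIP tracks.** Peak intervals with two log-normal replicate
  intensities (multiplicative CV 0.2) per mark (H3K4me3, H3K27ac,
  H3K27me3, H3K9me3) and time point (naive, 24h, primed), constructed so
  that the regulatory-element rules below recover the planned classes.
* **Expression counts.** Per gene and cell, activity `p ~ Beta(k_on,
  k_off)` and count `~ Poisson(s * p)` — the steady-state bursting model.

What the generator does **not** emulate: restriction-fragment and ligation
biases, diploid homologs, mappability, cell-cycle structure, or any
realistic sequence composition. Passing tests therefore demonstrate that
the algorithms recover planted structure under the stated statistical
model, not that they are robust to every artefact of real libraries.

## 3D structure engine

Contacts become distance restraints between beads: one flat-bottom
harmonic per distinct contacted bead pair (default bounds 0.8–1.2 bead
diameters around a 1-diameter target; the upper bound should be widened to
the capture radius when that is known to be larger), plus backbone bonds
between sequence-adjacent beads. Models are annealed coarse-to-fine over a
resolution ladder (8x, 4x, 2x, 1x the target bin size; coarse bead radii
scale as the cube root of the grouping factor; positions are expanded by
linear interpolation along the chain plus 0.1-radius jitter).

Dynamics are **underdamped** Langevin (velocity, friction gamma = 2,
dt = 0.05, per-bead speed cap): inertia is needed to cross the shallow
barriers of the flat-bottom landscape — an overdamped integrator stalls at
high violation fractions on problems of a few hundred beads. Temperatures
fall geometrically within each ladder level, and each finer level starts
at half the previous level's temperatures: re-annealing a fine level from
the full starting temperature destroys the inherited coarse topology.
Excluded volume is a soft quadratic repulsion below 1.65 radii (k = 25 vs
k = 50 for restraints). A full 2-radius core is geometrically incompatible
with contact-derived restraints at realistic densities — it inflates the
fold and breaks restraints wholesale — so the core matches the generator's
effective chain self-avoidance instead. Each replica model starts from an
independent random conformation; ensembles are rigid-body aligned to the
first model, testing both chiralities, because global handedness is not
determined by distance data.

**Validation by reconstruction.** The engine is validated by refolding a
known 400-bead, two-chromosome conformation from graded proximity-shell
restraints measured on it (five shells out to 6.5 radii; ~10–30 restraints
per bead). Binary single-radius contact restraints at ~2 per bead satisfy
the restraints perfectly yet leave the embedding underdetermined (median
bead error ~2 radii across seeds) — an information limit of the input, not
an optimizer failure — so the reconstruction check uses the shell
restraints, and error is measured on the ensemble-mean structure after
chirality-matched superposition. The validation conformation uses
intermingle level 0.3: strict territories provide no trans restraints (so
relative chromosome placement and chirality are undetermined), while
near-complete mixing dilutes the polymer so much that it is
under-restrained.

**Noise filtering.** A preliminary single-model fold is used to drop
contacts whose bead pair is farther than a cutoff (default 4 radii) in all
models, mirroring the idea of keeping read pairs that are plausibly close
in space. This filter only has power when the restraint network is dense
enough to be rigid; in the sparse demo regime it passes contacts through
unchanged, and the violation report honestly reflects the remaining noise.

## Compartments and profiles

Distance normalization divides each intra-chromosomal diagonal by its mean
(observed/expected; idempotent, scale-invariant, zeros preserved). The
compartment score is the leading eigenvector of the bin–bin correlation
matrix of O/E per chromosome — the standard eigenvector method stands in
for likelihood-based compartment scores — sign-oriented against a
supplied reference track (planted A density in the synthetic runs), with
positive = A. Saddle analysis ranks bins by score into equal groups and
averages O/E between groups; "corner" summaries average the outer 20% of
groups on each side, and both the contact enrichments and the mean scores
of the corner strata are both reported, since corner summaries can
reasonably mean either. Contact-scaling curves are log-binned contact
probabilities versus intra-chromosomal separation; separation fractions
use half-open bins (<10 kb, 10–100 kb, 100 kb–1 Mb, 1–5 Mb, >=5 Mb,
trans), so a contact at exactly 10 kb belongs to the second bin. Bootstrap
standard deviations are subsamples without replacement (defaults 200
samples of 20%; hub-abundance profiles use 2,000 samples of 30%).

## Intermingling and trans density

A bead's neighborhood is every bead consistently within <2 radii in *all*
replica models, with both beads positionally precise (per-bead ensemble
RMSD < 1.5 radii; imprecise beads are NA). The intermingling score is the
trans fraction of that neighborhood — because bins are uniform, summed
lengths reduce to bead counts. Per-cell tracks are quantile-normalized
(reference: mean of the sorted per-cell distributions), the per-locus
median across cells of a stage is taken, and loci are split into 5 or 10
equal-size ordered groups. Feature enrichment compares the top and bottom
30% of loci (log2 fold change, capped when a stratum is empty) or the
highest and lowest decile groups (Fisher's exact test).

Trans spatial density is the sum of reciprocal center–center distances to
all beads on other chromosomes, averaged over models, scaled so the
all-bead background median is exactly 1.00; coincident-bead pairs are
excluded with a warning. Per-class (A/B/hub) scaled densities are pooled
across cells of a stage for histogramming.

## Multiway hub detection

Windows of 40 kb slide in 20 kb steps (half-window, so any true 40 kb
cluster overlaps some window by at least half; the step size is
otherwise a free choice). Both ends of every long-range (>50 kb) intra-
chromosomal contact are candidate anchor members with the partner as the
contact site. Overlapping candidate windows resolve to the largest count,
ties to the leftmost. A candidate floor of 4 long-range contacts bounds
compute; significance comes entirely from the null: each long-range
contact is relocated uniformly along its chromosome keeping its separation
exactly, 400 times, the identical scan runs on each permuted genome, and
the pseudo-anchor candidate counts are pooled per chromosome. Empirical
p = (1 + #{null >= observed}) / (1 + n_null) (never zero), BH-adjusted
within the cell; hubs with q < 0.05 are kept. When a chromosome yields no
pseudo-anchor at the candidate floor in any permutation, the
per-permutation maximum window count is pooled instead so p stays defined.
Hub span is "short" when every intra contact lies within 1 Mb of the
anchor center (half-open: exactly 1 Mb is "long").

Calibration note: with the conservative (1+r)/(1+n) estimator, p-values on
discrete window counts are super-uniform; the calibration experiments use
cells dense enough (~5,000 long-range contacts on a 20 Mb chromosome) that
counts spread over many values and the p distribution approaches uniform.

## Regulatory elements and enrichment

Element rules at a time point: active enhancer = H3K27ac with no H3K4me3
or H3K27me3 (peaks trimmed to 1 kb about their center); active promoter =
TSS inside H3K4me3 and H3K27ac but not H3K27me3; bivalent promoter = TSS
inside H3K4me3 and H3K27me3; emerging enhancer = H3K27ac absent in naive,
present at 48 h, with at least a 3x intensity increase (absence takes a
pseudo-floor of 1% of the genome-wide median intensity so the ratio is
defined); weakening enhancer is the mirror. E–P contacts are called when
the element is no more than 20 kb (inclusive) from the anchor center or
contact site; anchors additionally carry gene-group labels of TSS strictly
closer than 5 kb.

The enrichment null re-pairs anchors with the contact-site sets of other
hubs within the same A/B compartment (the hub's compartment is its
anchor's bin label), preserving per-compartment hub counts and each set's
composition. Two one-sided empirical p-values are combined as min(2p, 1)
and BH-adjusted across category pairs; log2FC compares the observed total
to the null mean and is capped at +/-10 with a flag when degenerate.
Inter-chromosomal contacts are first filtered by the cell's structure
(bead pair within 3.5 radii; the median over replica models is used as
the consensus of the replicas), pooled across
cells, and the null shuffles element identities within compartments.
Hub chromatin-state profiles are per-hub mean mark abundances over contact
sites, Ward-clustered; the anchor-profile matrix keeps the contact-matrix
row order so each row remains the same hub.

## H3K27me3 promoter trajectories

Per promoter and ChIP replicate, the intensity changes (24h - naive,
primed - 24h) are scaled by the gene's maximum intensity across time
points; replicates contribute separate feature dimensions. Ward linkage on
Euclidean distances is cut top-down, splitting a branch only while both
children keep at least 100 members — a conservative analog of dynamic tree
cutting at its shallowest split setting, which by construction never
produces undersized clusters. Bivalency trajectories are classified from
per-time-point H3K4me3/H3K27me3 calls (always-bivalent, formed at 24 h and
maintained, naive-only, primed-only, never; other monovalent transitions
are labelled "other").

## Bursting kinetics

Counts are modelled as Poisson(s·p) with p ~ Beta(k_on, k_off); k_on /
(k_on + k_off) is the active fraction. Inference is data-augmented MCMC:
vectorized logit-space Metropolis for the per-cell latent p; log-space
random walks for the three rates; and three joint moves along the slow
posterior directions (scaling k_on and k_off together, scaling k_off and
s together, and an activity rescaling s·c, k_off·c, p/c that leaves the
Poisson terms invariant). Proposal scales adapt toward standard acceptance
targets during burn-in only. Defaults: 2,000 iterations, 500 burn-in,
thinning 3; the recovery experiments use 3,000/1,000, which stabilizes the
tail genes at these sample sizes.

Priors are bounded uniform-in-log on all three rates (|log x| <= log
1000), the standard vague choice for this model. The bound matters: the
Poisson-beta likelihood has a ridge along which k_off and s grow together
on genes whose burst size is unidentifiable (including the negative-
binomial limit of small active fraction), and on such genes the posterior
spreads over the flat upper region, so the median lands well above the
k_off = 10 cutoff and the gene is removed by the reliability filter —
which is that filter's purpose. Identifiable, strongly bursty
genes (small k_on, k_off of order 1, large bursts) are unaffected. Two
caveats are documented rather than hidden: (i) for near-Poisson
(constitutive) genes the active fraction is not point-identified (only
s·f is), so its point estimate reflects the prior; (ii) interval-coverage
claims are made for filter-retained genes only, since the filtered regime
is precisely the one the k_off cutoff declares unreliable. Genes
simulated between the clearly-identifiable and clearly-extreme regimes
(k_off roughly 5-40 at 500 cells) have genuinely flat likelihood profiles
and cannot be classified reliably by any estimator. A wide posterior on
k_off (90% interval spanning more than e^4) is flagged per gene.

## Pipeline and reproducibility

`run_pipeline` executes simulate → structures (with the preliminary-fold
noise filter) → compartments → intermingling → hubs → regulatory
enrichment → kinetics, halting with a stage-tagged error when a dependency
is disabled. All analysis thresholds have fixed defaults (40 kb window,
50 kb separation, 2-radius proximity, 1.5-radius precision, 3.5-radius
trans support, 20 kb/5 kb flanks, 400/5,000 permutations, FDR 0.05,
min cluster 100, k_off cutoff 10). Per-stage seeds derive from one master
seed by stable hashing, so stages can be re-run in isolation and full
reruns are byte-identical. The demo configuration (3 chromosomes x 200
bins at 100 kb, 8 cells, ~1,500 contacts/cell, 3% noise, two planted
10-way hubs per cell, 3 replica models) completes in a few minutes on one
CPU; problem sizes throughout the test-suite experiments (e.g. 400-bead
reconstructions, 50-gene kinetic recoveries, 1,000-permutation enrichment
nulls scaled down from 5,000) were chosen to keep the whole suite at desk
scale while leaving every statistical claim testable.

## Known limitations

* Global chirality of structures is unrecoverable from distances; all
  comparisons are chirality-matched.
* The structural noise filter requires a rigid restraint network; it is a
  no-op on very sparse cells.
* The generator's territories are spherical and its polymer has no loop
  extrusion, so hub span classes arise only from planted geometry.
* Empirical p-values on discrete counts are conservative at low contact
  density.
* Active-fraction point estimates for constitutive genes reflect the
  prior, not the data (only s·f is identified).
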