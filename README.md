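# schichub

Single-cell Hi-C analysis of 3D genome reorganization: restraint-based
polymer structures, chromosome-territory intermingling, multiway
enhancer–promoter hub detection with a permutation null, compartment and
regulatory-element analysis, and Poisson-beta transcriptional bursting
inference — exercised end-to-end on synthetic data with planted ground
truth.

## Who this is for

Computational biologists who want a tested, reusable implementation of the
analysis chain used to characterize the formative pluripotent state in
mouse ES cells: from sparse per-cell contact lists (`chrom pos chrom pos`
text) to 3D models, per-locus intermingling scores, statistically
significant multiway hubs, enhancer–promoter contact enrichment, and
per-gene bursting kinetics.

## The core computations

* **Structures.** Hi-C contacts become flat-bottom distance restraints on
  a particle-on-a-string polymer (one bead per genomic bin); replica
  models are computed by hierarchical simulated annealing (coarse-to-fine
  resolution ladder, underdamped Langevin dynamics, geometric temperature
  schedule) from independent random starts, then rigid-body aligned
  testing both chiralities.
* **Intermingling.** A locus's score is the fraction of beads
  consistently within <2 bead radii of it (in all replica models, both
  loci positionally precise at RMSD < 1.5 radii) that lie on *other*
  chromosomes. Tracks are quantile-normalized across cells, medianed per
  locus, and split into equal-size groups. Trans spatial density is
  `sum(1/d)` over trans beads, background median scaled to 1.00.
* **Hubs.** 40 kb anchor windows (20 kb steps) whose number of long-range
  (>50 kb) contacts is significant against a separation-preserving
  permutation null: each long-range contact is relocated uniformly along
  its chromosome 400 times keeping its separation; empirical
  p = (1+r)/(1+n), BH-FDR within the cell, q < 0.05 kept.
* **Regulatory enrichment.** Elements classified from H3K4me3 / H3K27ac /
  H3K27me3 peaks (active/bivalent promoters; active/emerging/weakening
  enhancers, 3x-change rule); anchor-site category totals tested against
  re-pairings of anchors with other hubs' contact sets within the same
  A/B compartment.
* **Kinetics.** Counts ~ Poisson(s·p), p ~ Beta(k_on, k_off), fitted by
  data-augmented MCMC; genes with posterior-median k_off > 10 are removed
  as unreliable; conditions compared by paired Wilcoxon tests on log fold
  changes.

See `docs/methods.md` for models, parameter defaults and design choices.

## Worked example

Run the demo pipeline (synthetic genome of 3 chromosomes x 20 Mb at
100 kb bins, 8 cells, two planted 10-way hubs per cell) and inspect the
report:

```bash
schichub run --seed 11 --out demo_run
```

```
pipeline complete; report at demo_run/report.json
  simulate: {'n_cells': 8, 'n_planted_hubs': 16, 'contacts_per_cell': [1520, 1520, 1520, 1520, 1520, 1520, 1520, 1520]}
  structure: {'n_models': 3, 'mean_violation_fraction': 0.290074, 'mean_noise_removed_fraction': 0.0}
  compartments: {'label_agreement': 0.995, 'saddle_corners': {'BB': 1.419912, 'AA': 1.353723, 'AB': 0.640696, 'BA': 0.640696}}
  intermingling: {'n_scored_loci': 96}
  hubs: {'n_hubs_detected': 37, 'n_planted_recovered': 16, 'n_planted': 16}
  regulatory: {'n_elements': 74, 'n_typed_pairs': 372, 'n_category_pairs': 20}
  kinetics: {'n_genes_fit': 6, 'n_genes_retained': 6}
```

Reading the report: all 16 planted hub anchors are recovered at FDR
q < 0.05 (plus additional hubs arising from genuine polymer clustering);
the planted A/B checkerboard is labelled almost perfectly (199/200 bins)
and same-compartment saddle corners (AA, BB ≈ 1.35–1.42) exceed
cross-compartment corners (≈ 0.64); the per-cell structures leave a ~29%
restraint-violation fraction, reflecting the sparse, noisy demo contacts; and all six
strongly bursty demo genes pass the k_off > 10 reliability filter.
Outputs
(`cell*.pairs`, `cell*.n3d`, bedGraph tracks, hub and enrichment tables,
kinetic fits) are plain text; reruns with the same seed are
byte-identical.

Individual stages are exposed as subcommands (`schichub structure`,
`compartments`, `intermingle`, `hubs`, `kinetics`) and, more flexibly, as
library functions (`schichub.structure.anneal`,
`schichub.hubs.detect_hubs`, `schichub.kinetics.fit_poisson_beta`, ...).

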