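"""End-to-end pipeline: synthetic cells -> structures -> intermingling ->
hubs -> regulatory enrichment -> kinetics, with one config, per-stage seeds
derived from a master seed, and a summary report.

Every run writes the resolved configuration next to its outputs; reruns
with the same master seed are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import chip  # noqa: F401  (re-exported stage namespace)
from . import compartments as comp
from . import hubs as hubmod
from . import intermingling as inter
from . import kinetics as kin
from . import regulatory as reg
from . import structure as struct
from . import synthetic as synth
from ._utils import stage_seed
from .genome import build_genome
from .io import write_bedgraph, write_contacts, write_run_config, write_structure


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


DEFAULT_CONFIG = {
    "seed": 0,
    "genome": {"n_chroms": 3, "chrom_length": 20_000_000, "bin_size": 100_000},
    "cells": {"n_cells": 8, "n_contacts": 1500, "intermingle_level": 0.5,
              "noise_fraction": 0.03, "hubs_per_cell": 2, "hub_k": 10},
    "stages": {"simulate": True, "structure": True, "compartments": True,
               "intermingling": True, "hubs": True, "regulatory": True,
               "kinetics": True},
    "structure": {"n_models": 3, "n_temps": 10, "steps_per_temp": 120,
                  "quench_steps": 500},
    "thresholds": {
        "hub_window": 40_000, "hub_min_separation": 50_000,
        "proximity_radius": 2.0, "precision_rmsd": 1.5,
        "trans_support_radii": 3.5, "ep_flank": 20_000, "tss_flank": 5_000,
        "n_perm_hubs": 400, "n_perm_enrichment": 5000, "fdr": 0.05,
        "min_cluster_size": 100, "koff_cutoff": 10.0,
    },
    "kinetics": {"n_genes": 6, "n_cells": 200, "n_iter": 1200, "burn_in": 400},
}


def resolve_config(config: dict | None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, value in (config or {}).items():
        if isinstance(value, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


def _planted_hubs(assembly, n_hubs, k, rng):
    hubs = []
    offsets = [-1_500_000, 1_200_000, -900_000, 2_000_000, 800_000,
               -2_400_000, 1_800_000, -700_000, 1_000_000, -1_100_000,
               600_000, -3_000_000]
    for h in range(n_hubs):
        chrom = assembly.names[h % assembly.n_chromosomes]
        length = int(assembly.lengths[chrom])
        anchor = int(rng.integers(4_000_000, length - 4_000_000))
        anchor -= anchor % 20_000
        hubs.append(synth.PlantedHub(chrom, anchor, tuple(offsets[:k])))
    return hubs


def run_pipeline(config: dict | None = None, out_dir="pipeline_out") -> dict:
    cfg = resolve_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_run_config(cfg, out / "resolved_config.yaml")
    stages = cfg["stages"]
    thr = cfg["thresholds"]
    master = int(cfg["seed"])
    report: dict = {"stages": {}, "thresholds": thr}

    if not stages.get("simulate", True):
        raise StageError("simulate", "pipeline requires the simulate stage")

    # --- simulate ------------------------------------------------------
    g = cfg["genome"]
    assembly = build_genome(g["n_chroms"], g["chrom_length"], g["bin_size"])
    cells = cfg["cells"]
    rng = np.random.default_rng(stage_seed(master, "simulate"))
    conformations, contact_lists, planted = [], [], []
    for c in range(cells["n_cells"]):
        conf = synth.simulate_conformation(
            assembly, cells["intermingle_level"], seed=stage_seed(master, f"conf{c}")
        )
        hubs_c = _planted_hubs(assembly, cells["hubs_per_cell"], cells["hub_k"], rng)
        contacts, _ = synth.sample_contacts(
            conf, assembly, cells["n_contacts"],
            noise_fraction=cells["noise_fraction"], planted_hubs=hubs_c,
            seed=stage_seed(master, f"contacts{c}"),
        )
        conformations.append(conf)
        contact_lists.append(contacts)
        planted.append(hubs_c)
        write_contacts(contacts, out / f"cell{c}.pairs")
    compartment_labels = synth.plant_compartments(assembly, block_bins=10)
    report["stages"]["simulate"] = {
        "n_cells": cells["n_cells"],
        "n_planted_hubs": sum(len(h) for h in planted),
        "contacts_per_cell": [len(c) for c in contact_lists],
    }

    # --- structures ----------------------------------------------------
    ensembles = None
    if stages.get("structure", True):
        sc = cfg["structure"]
        schedule = struct.AnnealingSchedule(
            n_temps=sc["n_temps"], steps_per_temp=sc["steps_per_temp"],
            quench_steps=sc["quench_steps"],
        )
        prelim_schedule = struct.AnnealingSchedule(
            n_temps=max(4, sc["n_temps"] // 2),
            steps_per_temp=sc["steps_per_temp"], quench_steps=sc["quench_steps"] // 2,
        )
        # restraint flat bottom consistent with the generator's 2-radius
        # contact capture: anything closer than the capture radius is a
        # legitimate contact distance
        bounds = {"lower": 1.0, "target": 2.0, "upper": 2.5}
        ensembles = []
        violations, noise_removed = [], []
        for c, contacts in enumerate(contact_lists):
            # preliminary single-model fold, then drop contacts the
            # structure cannot support (likely noise)
            prelim_restraints = struct.contacts_to_restraints(contacts, assembly, **bounds)
            prelim = struct.anneal(
                prelim_restraints, assembly, n_models=1,
                schedule=prelim_schedule, seed=stage_seed(master, f"prelim{c}"),
            )
            cleaned, removed = struct.filter_noise_contacts(
                contacts, prelim, assembly, max_distance=4.0
            )
            noise_removed.append(removed)
            restraints = struct.contacts_to_restraints(cleaned, assembly, **bounds)
            ens = struct.anneal(
                restraints, assembly, n_models=sc["n_models"], schedule=schedule,
                seed=stage_seed(master, f"anneal{c}"),
            )
            ens, _ = struct.align_ensemble(ens)
            ensembles.append(ens)
            violations.append(struct.violation_report(ens, restraints)["mean_fraction"])
            write_structure(ens, out / f"cell{c}.n3d")
        pd.DataFrame({"cell": range(len(violations)), "violation_fraction": violations,
                      "noise_removed_fraction": noise_removed}).to_csv(
            out / "violations.tsv", sep="\t", index=False, float_format="%.6f"
        )
        report["stages"]["structure"] = {
            "n_models": sc["n_models"],
            "mean_violation_fraction": round(float(np.mean(violations)), 6),
            "mean_noise_removed_fraction": round(float(np.mean(noise_removed)), 6),
        }

    # --- compartments --------------------------------------------------
    if stages.get("compartments", True):
        chrom = assembly.names[0]
        labels = compartment_labels[chrom]
        matrix = synth.simulate_compartment_matrix(
            labels, seed=stage_seed(master, "compmat")
        )
        normalized = comp.normalize_matrix(matrix)
        track = comp.compartment_scores(normalized, (labels == "A").astype(float))
        sad = comp.saddle(normalized, track["score"].to_numpy(), n_groups=10)
        agreement = float(np.mean(track["label"].to_numpy() == labels))
        bg = pd.DataFrame({
            "chrom": chrom,
            "start": np.arange(labels.size) * assembly.bin_size,
            "end": (np.arange(labels.size) + 1) * assembly.bin_size,
            "value": track["score"],
        })
        write_bedgraph(bg, out / "compartment_scores.bedgraph")
        report["stages"]["compartments"] = {
            "label_agreement": round(agreement, 6),
            "saddle_corners": {k: round(v, 6) for k, v in sad["corners"].items()},
        }

    # --- intermingling -------------------------------------------------
    groups = None
    median_track = None
    if stages.get("intermingling", True):
        if ensembles is None:
            raise StageError("intermingling", "requires the structure stage")
        tracks = np.stack([
            inter.cell_track(
                ens, proximity_radius=thr["proximity_radius"],
                precision_rmsd=thr["precision_rmsd"],
            )
            for ens in ensembles
        ])
        _, median_track, groups = inter.normalize_and_aggregate(tracks, n_groups=10)
        table = assembly.bead_table()
        bg = pd.DataFrame({
            "chrom": [c for c, _ in table],
            "start": [s for _, s in table],
            "end": [s + assembly.bin_size for _, s in table],
            "value": median_track,
        })
        write_bedgraph(bg, out / "intermingling_median.bedgraph")
        report["stages"]["intermingling"] = {
            "n_scored_loci": int(np.sum(~np.isnan(median_track))),
        }

    # --- hubs ----------------------------------------------------------
    hub_tables = None
    if stages.get("hubs", True):
        hub_tables = []
        for c, contacts in enumerate(contact_lists):
            hubs_df = hubmod.detect_hubs(
                contacts, assembly, seed=stage_seed(master, f"hubperm{c}"),
                window=thr["hub_window"], min_separation=thr["hub_min_separation"],
                n_perm=thr["n_perm_hubs"], q_threshold=thr["fdr"], cell_id=f"cell{c}",
            )
            hub_tables.append(hubs_df)
        all_hubs = pd.concat(hub_tables, ignore_index=True)
        flat = all_hubs.copy()
        flat["sites"] = flat["sites"].apply(lambda s: ",".join(map(str, np.atleast_1d(s))))
        flat.to_csv(out / "hubs.tsv", sep="\t", index=False, float_format="%.6g")
        planted_found = 0
        for c, hubs_c in enumerate(planted):
            det = hub_tables[c]
            for ph in hubs_c:
                hit = det[(det["chrom"] == ph.chrom)
                          & (det["start"] < ph.anchor_start + 40_000)
                          & (det["end"] > ph.anchor_start)]
                planted_found += int(len(hit) > 0)
        report["stages"]["hubs"] = {
            "n_hubs_detected": int(len(all_hubs)),
            "n_planted_recovered": planted_found,
            "n_planted": sum(len(h) for h in planted),
        }

    # --- regulatory ----------------------------------------------------
    if stages.get("regulatory", True):
        if hub_tables is None:
            raise StageError("regulatory", "requires the hubs stage")
        all_hubs = pd.concat(hub_tables, ignore_index=True)
        if len(all_hubs) >= 4:
            plan_rng = np.random.default_rng(stage_seed(master, "plan"))
            plan = []
            for i, hub in enumerate(all_hubs.itertuples(index=False)):
                kind = ("active_promoter", "emerging_enhancer",
                        "active_enhancer", "bivalent_promoter")[i % 4]
                center = int((hub.start + hub.end) // 2)
                plan.append(synth.PlannedElement(kind, hub.chrom, center))
                sites = np.atleast_1d(hub.sites)
                if sites.size:
                    site = int(sites[plan_rng.integers(0, sites.size)])
                    site = min(max(site, 1000), int(assembly.lengths[hub.chrom]) - 1000)
                    plan.append(synth.PlannedElement(
                        ("emerging_enhancer", "active_enhancer")[i % 2], hub.chrom, site
                    ))
            tracks_chip, tss = synth.generate_tracks(
                assembly, plan, seed=stage_seed(master, "tracks")
            )
            elements = reg.classify_elements(tracks_chip, tss)
            typed = reg.call_hub_ep_contacts(
                all_hubs, elements, tss, flank=thr["ep_flank"], tss_flank=thr["tss_flank"]
            )
            anchor_labels, site_lists, comps = [], [], []
            offsets = assembly.bin_offsets()
            for h, sub in typed.groupby("hub"):
                first = sub.iloc[0]
                a = first["anchor_classes"][0] if first["anchor_classes"] else "untyped"
                sites = [cl[0] if cl else "untyped" for cl in sub["site_classes"]]
                bin_idx = first["anchor_center"] // assembly.bin_size
                comps.append(compartment_labels[first["chrom"]][bin_idx])
                anchor_labels.append(a)
                site_lists.append(sites)
            enrich = reg.shuffle_and_test(
                anchor_labels, site_lists, comps,
                n_perm=thr["n_perm_enrichment"], seed=stage_seed(master, "shuffle"),
            )
            enrich.to_csv(out / "enrichment.tsv", sep="\t", index=False, float_format="%.6g")
            report["stages"]["regulatory"] = {
                "n_elements": int(len(elements)),
                "n_typed_pairs": int(len(typed)),
                "n_category_pairs": int(len(enrich)),
            }
        else:
            report["stages"]["regulatory"] = {"skipped": "fewer than 4 hubs"}

    # --- kinetics ------------------------------------------------------
    if stages.get("kinetics", True):
        kc = cfg["kinetics"]
        krng = np.random.default_rng(stage_seed(master, "kinetics"))
        # strongly bursty genes: the regime where the rates are identifiable
        truth = pd.DataFrame({
            "gene": [f"g{i}" for i in range(kc["n_genes"])],
            "k_on": krng.uniform(0.3, 1.2, kc["n_genes"]),
            "k_off": krng.uniform(0.4, 2.5, kc["n_genes"]),
            "s": krng.uniform(100, 300, kc["n_genes"]),
        })
        counts = synth.simulate_expression_counts(
            truth, kc["n_cells"], seed=stage_seed(master, "counts")
        )
        settings = kin.McmcSettings(n_iter=kc["n_iter"], burn_in=kc["burn_in"])
        fits = kin.fit_genes(counts, settings=settings, seed=stage_seed(master, "mcmc"))
        table = kin.fits_table(fits)
        table.to_csv(out / "kinetic_fits.tsv", sep="\t", index=False, float_format="%.6g")
        kept = kin.filter_fits(fits, koff_cutoff=thr["koff_cutoff"])
        report["stages"]["kinetics"] = {
            "n_genes_fit": len(fits), "n_genes_retained": len(kept),
        }

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
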