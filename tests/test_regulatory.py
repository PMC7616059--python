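import numpy as np
import pandas as pd
import pytest

from schichub import regulatory as reg
from schichub import synthetic as synth
from schichub.genome import build_genome


@pytest.fixture(scope="module")
def tracks_and_tss():
    asm = build_genome(2, 10_000_000, 100_000)
    plan = [
        synth.PlannedElement("active_promoter", "chr1", 1_000_000, gene="gAct"),
        synth.PlannedElement("bivalent_promoter", "chr1", 3_000_000, gene="gBiv"),
        synth.PlannedElement("active_enhancer", "chr1", 5_000_000),
        synth.PlannedElement("emerging_enhancer", "chr2", 2_000_000),
        synth.PlannedElement("weakening_enhancer", "chr2", 6_000_000),
    ]
    tracks, tss = synth.generate_tracks(asm, plan, seed=6)
    return asm, tracks, tss


class TestClassifyElements:
    def test_planted_classes_recovered(self, tracks_and_tss):
        _, tracks, tss = tracks_and_tss
        elements = reg.classify_elements(tracks, tss)
        classes = dict(zip(elements["gene"].fillna("") + elements["class"], elements["class"]))
        by_class = elements.groupby("class").size().to_dict()
        assert by_class.get("active_promoter") == 1
        assert by_class.get("bivalent_promoter") == 1
        assert by_class.get("active_enhancer") == 1
        assert by_class.get("emerging_enhancer") == 1
        assert by_class.get("weakening_enhancer") == 1

    def test_k27ac_on_k4me3_is_not_an_enhancer(self, tracks_and_tss):
        _, tracks, tss = tracks_and_tss
        elements = reg.classify_elements(tracks, tss)
        enhancers = elements[elements["class"].str.contains("enhancer")]
        # no enhancer call at the promoter positions (K27ac overlapping K4me3)
        assert not ((enhancers.chrom == "chr1") & (enhancers.start < 1_100_000)
                    & (enhancers.end > 900_000)).any()

    def test_long_peaks_trimmed_to_1kb(self, tracks_and_tss):
        _, tracks, tss = tracks_and_tss
        elements = reg.classify_elements(tracks, tss)
        enh = elements[elements["class"].str.contains("enhancer")]
        assert ((enh.end - enh.start) <= 1_000).all()

    def test_insufficient_increase_not_emerging(self):
        """A 48h-only peak below 3x the pseudo-floor stays a plain enhancer."""
        asm = build_genome(1, 10_000_000, 100_000)
        plan = [synth.PlannedElement("active_enhancer", "chr1", 2_000_000)]
        tracks, tss = synth.generate_tracks(asm, plan, seed=1)
        # move the enhancer out of the naive track and shrink its intensity
        weak = tracks[("H3K27ac", "primed")].copy()
        weak[["rep1", "rep2"]] = 0.02  # ~2x floor of the median intensity
        tracks[("H3K27ac", "naive")] = tracks[("H3K27ac", "naive")].iloc[:0]
        tracks[("H3K27ac", "primed")] = weak
        elements = reg.classify_elements(tracks, tss)
        assert (elements["class"] == "active_enhancer").all()

    def test_missing_mark_rejected(self, tracks_and_tss):
        _, tracks, tss = tracks_and_tss
        incomplete = {k: v for k, v in tracks.items() if k != ("H3K27me3", "primed")}
        with pytest.raises(ValueError, match="missing mark"):
            reg.classify_elements(incomplete, tss)


class TestHubContactTyping:
    def _hubs(self):
        return pd.DataFrame([
            {"chrom": "chr1", "start": 1_000_000, "end": 1_040_000,
             "sites": np.array([3_005_000, 5_010_000]), "cell_id": "c0"},
        ])

    def test_flank_rule_inclusive_20kb(self, tracks_and_tss):
        _, tracks, tss = tracks_and_tss
        elements = reg.classify_elements(tracks, tss)
        typed = reg.call_hub_ep_contacts(self._hubs(), elements, tss)
        # anchor center 1,020,000 sits exactly 20 kb from the promoter
        # (inclusive boundary); site 3,005,000 is 5 kb from the bivalent TSS
        assert len(typed) == 2
        first = typed.iloc[0]
        assert "active_promoter" in first.anchor_classes
        assert "bivalent_promoter" in first.site_classes

    def test_element_beyond_flank_not_called(self, tracks_and_tss):
        _, tracks, tss = tracks_and_tss
        elements = reg.classify_elements(tracks, tss)
        hubs = self._hubs()
        hubs.loc[0, "start"] = 1_100_000  # center now 80 kb past the promoter
        hubs.loc[0, "end"] = 1_140_000
        typed = reg.call_hub_ep_contacts(hubs, elements, tss)
        assert all("active_promoter" not in a for a in typed.anchor_classes)

    def test_tss_group_attached_under_5kb(self, tracks_and_tss):
        _, tracks, tss = tracks_and_tss
        elements = reg.classify_elements(tracks, tss)
        tss = tss.copy()
        tss["group"] = ["up", "down"]
        hubs = pd.DataFrame([
            {"chrom": "chr1", "start": 984_000, "end": 1_024_000,
             "sites": np.array([5_000_000]), "cell_id": "c0"},
        ])  # center 1,004,000: 4 kb from gAct TSS
        typed = reg.call_hub_ep_contacts(hubs, elements, tss)
        assert typed.iloc[0].anchor_groups == ["up"]


class TestShuffleAndTest:
    def _random_hubs(self, rng, n_hubs=120, enrich=None):
        anchors = rng.choice(["active_promoter", "bivalent_promoter"], size=n_hubs)
        comps = rng.choice(["A", "B"], size=n_hubs)
        sites = []
        for a in anchors:
            k = int(rng.integers(3, 8))
            probs = np.full(3, 1 / 3)
            if enrich and a == "active_promoter":
                probs = np.array([1 - 2 * enrich / 3, enrich / 3, enrich / 3])
                probs = np.array([enrich, 1, 1], dtype=float)
                probs /= probs.sum()
            sites.append(list(rng.choice(
                ["emerging_enhancer", "active_enhancer", "weakening_enhancer"],
                size=k, p=probs)))
        return anchors, sites, comps

    def test_p_floor_formula(self, rng):
        anchors, sites, comps = self._random_hubs(rng, n_hubs=30)
        res = reg.shuffle_and_test(anchors, sites, comps, n_perm=200, seed=0)
        assert (res["p_up"] >= 1 / 201 - 1e-12).all()

    def test_null_calibration(self):
        """Random labels: log fold changes near zero, ~5% significant."""
        sig = 0
        lfcs = []
        n_tests = 0
        for run in range(10):
            rng = np.random.default_rng(500 + run)
            anchors, sites, comps = self._random_hubs(rng, n_hubs=150)
            res = reg.shuffle_and_test(anchors, sites, comps, n_perm=300, seed=run)
            sig += int((res["p"] < 0.05).sum())
            n_tests += len(res)
            lfcs.extend(res["log2fc"].tolist())
        assert abs(np.mean(lfcs)) < 0.1
        frac = sig / n_tests
        assert frac <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / n_tests)

    def test_planted_excess_detected(self):
        """A 2x promoter-to-emerging-enhancer excess is significant."""
        rng = np.random.default_rng(99)
        anchors, sites, comps = self._random_hubs(rng, n_hubs=150, enrich=2.0)
        res = reg.shuffle_and_test(anchors, sites, comps, n_perm=500, seed=3)
        cell = res[(res.anchor_category == "active_promoter")
                   & (res.site_category == "emerging_enhancer")].iloc[0]
        assert cell.q < 0.05 and cell.log2fc > 0

    def test_observed_totals_order_invariant(self, rng):
        anchors, sites, comps = self._random_hubs(rng, n_hubs=40)
        res1 = reg.shuffle_and_test(anchors, sites, comps, n_perm=50, seed=0)
        perm = rng.permutation(40)
        res2 = reg.shuffle_and_test([anchors[i] for i in perm],
                                    [sites[i] for i in perm],
                                    [comps[i] for i in perm], n_perm=50, seed=0)
        merged = res1.merge(res2, on=["anchor_category", "site_category"])
        assert np.allclose(merged.observed_x, merged.observed_y)


class TestInterchromosomal:
    def test_structure_filter_by_bead_distance(self, assembly, conformation):
        contacts, _ = synth.sample_contacts(conformation, assembly, 500,
                                            capture_radius=2.0, seed=40)
        ens = synth.ensemble_from_truth(assembly, conformation, n_models=3,
                                        jitter=0.01, seed=41)
        kept, dropped = reg.filter_trans_by_structure(contacts, ens, max_distance=3.5)
        n_trans = int((contacts.chrom_a != contacts.chrom_b).sum())
        # proximity-sampled trans contacts are within ~2 radii: all supported
        assert len(kept) + dropped == n_trans
        assert dropped == 0
        # random (unsupported) trans pairs are filtered out
        noise, _ = synth.sample_contacts(conformation, assembly, 500,
                                         noise_fraction=1.0, seed=42)
        kept_noise, dropped_noise = reg.filter_trans_by_structure(noise, ens, max_distance=3.5)
        assert dropped_noise > len(kept_noise)

    def test_enrichment_null_calibrated(self):
        rng = np.random.default_rng(11)
        n_p, n_e, n_c = 40, 40, 400
        res = reg.interchrom_ep_enrichment(
            promoter_idx=rng.integers(0, n_p, n_c),
            enhancer_idx=rng.integers(0, n_e, n_c),
            promoter_labels=rng.choice(["up", "down"], n_p),
            enhancer_labels=rng.choice(["emerging", "weakening"], n_e),
            promoter_compartments=rng.choice(["A", "B"], n_p),
            enhancer_compartments=rng.choice(["A", "B"], n_e),
            n_perm=300, seed=1,
        )
        assert (res["p"] > 0.05).all() or (res["p"] < 0.05).sum() <= 1


class TestHubStateProfiles:
    def test_two_planted_populations_cluster_cleanly(self, assembly, rng):
        n_bins = assembly.total_bins
        active = np.zeros(n_bins)
        polycomb = np.zeros(n_bins)
        active[:60] = 10.0
        polycomb[120:180] = 10.0
        marks = {"H3K27ac": active, "H3K27me3": polycomb}
        hubs = []
        for h in range(20):
            if h % 2 == 0:
                sites = rng.integers(0, 50, size=5) * assembly.bin_size
            else:
                sites = rng.integers(21, 70, size=5) * assembly.bin_size
            hubs.append({"chrom": "chr1" if h % 2 == 0 else "chr2",
                         "start": 100_000, "end": 140_000, "sites": np.array(sites)})
        prof = reg.hub_state_profiles(pd.DataFrame(hubs), marks, assembly)
        labels = (prof["contact_matrix"][:, 0] > prof["contact_matrix"][:, 1])
        # leaves order groups the two populations contiguously
        assert labels[:10].all() != labels[10:].all()
        assert prof["anchor_matrix"].shape == prof["contact_matrix"].shape

    def test_row_alignment_contract(self, assembly, rng):
        marks = {"H3K27ac": rng.uniform(size=assembly.total_bins)}
        hubs = pd.DataFrame([
            {"chrom": "chr1", "start": 0, "end": 40_000,
             "sites": np.array([1_000_000, 2_000_000])},
            {"chrom": "chr1", "start": 5_000_000, "end": 5_040_000,
             "sites": np.array([3_000_000])},
            {"chrom": "chr2", "start": 0, "end": 40_000, "sites": np.array([], dtype=int)},
        ])
        prof = reg.hub_state_profiles(hubs, marks, assembly)
        # hub with no sites is excluded; rows correspond to kept hub ids
        assert set(prof["hubs"]) == {0, 1}
        assert prof["contact_matrix"].shape[0] == 2
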