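import numpy as np
import pandas as pd
import pytest

from schichub import hubs as hub
from schichub import synthetic as synth
from schichub.genome import build_genome
from schichub.io import CONTACT_COLUMNS, canonicalize_contacts


def _contacts(rows):
    return pd.DataFrame(rows, columns=CONTACT_COLUMNS)


def brute_force_scan(contacts, length, window=40_000, step=20_000,
                     min_separation=50_000, min_count=4):
    """Independent oracle: enumerate every window and every contact end."""
    selected = []
    counts = {}
    n_windows = (length - window) // step + 1
    for k in range(n_windows):
        lo, hi = k * step, k * step + window
        count = 0
        for r in contacts.itertuples(index=False):
            if r.chrom_a != r.chrom_b:
                continue
            if abs(r.pos_b - r.pos_a) <= min_separation:
                continue
            for end in (r.pos_a, r.pos_b):
                if lo <= end < hi:
                    count += 1
        if count >= min_count:
            counts[k] = count
    for k in sorted(counts, key=lambda k: (-counts[k], k)):
        if all(abs(k - kk) * step >= window for kk, _ in selected):
            selected.append((k, counts[k]))
    return sorted(selected)


class TestCandidateScan:
    def test_empty_contacts_no_candidates(self, assembly):
        assert hub.find_candidate_anchors(_contacts([]), assembly).empty

    def test_planted_anchor_found_with_count(self, assembly, conformation):
        offsets = (-300_000, 200_000, 500_000, -150_000, 400_000, -250_000, 350_000, 150_000)
        planted = synth.PlantedHub("chr1", 2_000_000, offsets)
        contacts, _ = synth.sample_contacts(conformation, assembly, 50,
                                            planted_hubs=[planted], seed=5)
        cands = hub.find_candidate_anchors(contacts, assembly)
        hit = cands[(cands.chrom == "chr1") & (cands.start <= 2_020_000) & (cands.end > 2_020_000)]
        assert len(hit) == 1 and hit["count"].iloc[0] >= 8

    def test_overlapping_windows_keep_larger_count(self):
        asm = build_genome(1, 1_000_000, 100_000)
        rows = []
        # window at 100k..140k with 6 ends, overlapping window 120k..160k with 9
        for i in range(6):
            rows.append(("chr1", 105_000 + i, "chr1", 500_000 + i))
        for i in range(9):
            rows.append(("chr1", 145_000 + i, "chr1", 700_000 + i))
        contacts = canonicalize_contacts(_contacts(rows))
        cands = hub.find_candidate_anchors(contacts, asm)
        # the count-9 cluster wins its overlap group (leftmost covering
        # window starts at 120k); the count-6 cluster survives separately
        assert 120_000 in set(cands.start)
        assert cands[cands.start == 120_000]["count"].iloc[0] == 9
        assert cands[cands.start == 80_000]["count"].iloc[0] == 6

    @pytest.mark.parametrize("cell_seed", range(8))
    def test_matches_brute_force_enumeration(self, cell_seed):
        """Sliding-window candidates equal an O(n * windows) brute scan."""
        asm = build_genome(1, 5_000_000, 100_000)
        rng = np.random.default_rng(cell_seed)
        n = int(rng.integers(50, 400))
        pos_a = rng.integers(0, 5_000_000, size=n)
        sep = rng.integers(1, 2_000_000, size=n)
        pos_b = np.minimum(pos_a + sep, 4_999_999)
        contacts = canonicalize_contacts(
            pd.DataFrame({"chrom_a": "chr1", "pos_a": pos_a,
                          "chrom_b": "chr1", "pos_b": pos_b})
        )
        expected = brute_force_scan(contacts, 5_000_000, min_count=3)
        got = hub.find_candidate_anchors(contacts, asm, min_count=3)
        got_pairs = sorted((s // 20_000, c) for s, c in zip(got.start, got["count"]))
        assert got_pairs == expected


class TestPermutation:
    def test_separation_multiset_preserved_exactly(self, assembly, contacts):
        permuted = hub.permute_long_range_contacts(contacts, assembly, seed=3)
        for df in (contacts, permuted):
            assert len(df) == len(contacts)
        sep0 = np.sort((contacts.pos_b - contacts.pos_a).abs().to_numpy())
        sep1 = np.sort((permuted.pos_b - permuted.pos_a).abs().to_numpy())
        assert np.array_equal(sep0, sep1)

    def test_single_contact_chromosome_still_one(self):
        asm = build_genome(1, 1_000_000, 100_000)
        contacts = _contacts([("chr1", 10_000, "chr1", 600_000)])
        permuted = hub.permute_long_range_contacts(contacts, asm, seed=0)
        assert len(permuted) == 1
        assert abs(permuted.pos_b[0] - permuted.pos_a[0]) == 590_000

    def test_same_seed_identical(self, assembly, contacts):
        a = hub.permute_long_range_contacts(contacts, assembly, seed=9)
        b = hub.permute_long_range_contacts(contacts, assembly, seed=9)
        assert a.equals(b)


class TestSignificance:
    def test_p_floor_when_observed_beats_all_nulls(self):
        asm = build_genome(1, 10_000_000, 100_000)
        rng = np.random.default_rng(0)
        # sparse background + one overwhelming planted anchor
        pos_a = rng.integers(0, 9_000_000, size=60)
        rows = [("chr1", int(p), "chr1", int(p) + int(s))
                for p, s in zip(pos_a, rng.integers(60_000, 900_000, size=60))]
        for off in range(15):
            rows.append(("chr1", 4_000_000 + off * 100, "chr1", 5_500_000 + off * 1000))
        contacts = canonicalize_contacts(_contacts(rows))
        cands = hub.find_candidate_anchors(contacts, asm)
        res = hub.hub_significance(cands, contacts, asm, n_perm=100, seed=1, keep_all=True)
        top = res.sort_values("count").iloc[-1]
        assert top["count"] >= 15
        assert top["p"] == pytest.approx(1.0 / (top["n_null"] + 1))

    def test_bh_q_at_least_p(self, assembly, contacts):
        cands = hub.find_candidate_anchors(contacts, assembly, min_count=2)
        res = hub.hub_significance(cands, contacts, assembly, n_perm=60, seed=2, keep_all=True)
        if not res.empty:
            assert (res["q"] >= res["p"] - 1e-12).all()

    def test_null_calibration_few_retained(self):
        """Cells generated by the permutation scheme itself retain (almost)
        no windows at q < 0.05."""
        asm = build_genome(1, 10_000_000, 100_000)
        rng = np.random.default_rng(7)
        retained = total_windows = 0
        for cell in range(5):
            sep = rng.integers(60_000, 3_000_000, size=400)
            left = rng.integers(0, 10_000_000 - sep)
            contacts = canonicalize_contacts(pd.DataFrame(
                {"chrom_a": "chr1", "pos_a": left, "chrom_b": "chr1", "pos_b": left + sep}
            ))
            hubs = hub.detect_hubs(contacts, asm, seed=100 + cell, n_perm=100)
            retained += len(hubs)
            total_windows += (10_000_000 - 40_000) // 20_000 + 1
        assert retained / total_windows <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / total_windows)


class TestSpanClass:
    @pytest.mark.parametrize(
        "sites,expected",
        [
            ([1_500_000, 1_200_000], "short"),       # within 0.5 Mb of 1 Mb center
            ([9_000_000], "long"),                     # 8 Mb away
            ([2_000_000], "long"),                     # exactly 1 Mb: half-open
            ([], None),
        ],
    )
    def test_rules(self, sites, expected):
        assert hub.span_class(1_000_000, sites) == expected


class TestAbundanceProfile:
    def test_uniform_hubs_flat_profile(self):
        groups = np.repeat(np.arange(1, 11), 30)
        prof = hub.hub_abundance_by_intermingling(groups, n_bootstrap=50, seed=0)
        assert np.allclose(prof.scaled, 1.0)

    def test_concentrated_hubs(self):
        groups = np.full(40, 3)
        prof = hub.hub_abundance_by_intermingling(groups, n_bootstrap=50, seed=0)
        assert prof.scaled[2] == pytest.approx(10.0)
        assert prof.scaled.sum() == pytest.approx(10.0)

    def test_profile_mean_is_one(self, rng):
        groups = rng.integers(1, 11, size=200)
        prof = hub.hub_abundance_by_intermingling(groups, n_bootstrap=50, seed=1)
        assert prof.scaled.mean() == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            hub.hub_abundance_by_intermingling(np.array([], dtype=int))
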