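import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from schichub import intermingling as inter
from schichub import synthetic as synth
from schichub.genome import build_genome
from schichub.io import StructureEnsemble


def _toy_ensemble(coords_list, chroms, bin_size=100_000):
    coords = np.asarray(coords_list, dtype=float)
    starts = []
    counts = {}
    for c in chroms:
        starts.append(counts.get(c, 0) * bin_size)
        counts[c] = counts.get(c, 0) + 1
    return StructureEnsemble(chroms, starts, coords, bin_size)


class TestProximitySets:
    def test_coincident_beads_are_mutual_neighbors(self):
        base = np.array([[0, 0, 0], [0.5, 0, 0], [10, 10, 10]], dtype=float)
        ens = _toy_ensemble([base, base], ["chr1", "chr2", "chr2"])
        neighbors, valid = inter.proximity_sets(ens)
        assert neighbors[0, 1] and neighbors[1, 0]
        assert not neighbors[0, 2]

    def test_pair_within_radius_in_most_but_not_all_models_excluded(self):
        near = np.array([[0, 0, 0], [1.0, 0, 0]], dtype=float)
        far = np.array([[0, 0, 0], [2.6, 0, 0]], dtype=float)
        ens = _toy_ensemble([near, near, far], ["chr1", "chr2"])
        neighbors, _ = inter.proximity_sets(ens)
        assert not neighbors[0, 1]

    def test_imprecise_bead_is_na(self, rng):
        # bead 1 jumps by 6 radii between models: RMSD >> 1.5
        m1 = np.array([[0, 0, 0], [1.0, 0, 0], [0, 1.0, 0]], dtype=float)
        m2 = m1.copy()
        m2[1] += [6.0, 0, 0]
        ens = _toy_ensemble([m1, m2], ["chr1", "chr1", "chr2"])
        neighbors, valid = inter.proximity_sets(ens)
        assert not valid[1]
        score = inter.intermingling_score(neighbors, valid, ens.chrom_codes())
        assert np.isnan(score[1])


class TestScore:
    @pytest.mark.parametrize(
        "chroms,expected",
        [
            (["chr1", "chr1", "chr1", "chr1", "chr1"], 0.0),
            (["chr1", "chr2", "chr2", "chr2", "chr2"], 1.0),
            (["chr1", "chr2", "chr2", "chr2", "chr1"], 0.75),
        ],
    )
    def test_trans_fraction_of_neighbor_set(self, chroms, expected):
        # bead 0 at origin with 4 beads packed within 2 radii
        coords = np.array(
            [[0, 0, 0], [1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0]], dtype=float
        )
        ens = _toy_ensemble([coords], chroms)
        neighbors, valid = inter.proximity_sets(ens)
        score = inter.intermingling_score(neighbors, valid, ens.chrom_codes())
        assert score[0] == pytest.approx(expected)

    def test_matches_naive_all_pairs_loop(self, small_ensemble):
        """Oracle equivalence on a realistic ensemble via a double loop."""
        neighbors, valid = inter.proximity_sets(small_ensemble)
        score = inter.intermingling_score(neighbors, valid, small_ensemble.chrom_codes())
        from schichub.structure import align_ensemble

        aligned, rmsd = align_ensemble(small_ensemble)
        codes = small_ensemble.chrom_codes()
        n = small_ensemble.n_beads
        for b in range(0, n, 17):  # spot-check a spread of beads
            if rmsd[b] >= 1.5:
                assert np.isnan(score[b])
                continue
            cis = trans = 0
            for c in range(n):
                if c == b or rmsd[c] >= 1.5:
                    continue
                if all(
                    np.linalg.norm(aligned.coords[m, b] - aligned.coords[m, c]) < 2.0
                    for m in range(aligned.n_models)
                ):
                    if codes[b] == codes[c]:
                        cis += 1
                    else:
                        trans += 1
            if cis + trans == 0:
                assert np.isnan(score[b])
            else:
                assert score[b] == pytest.approx(trans / (cis + trans))


class TestNormalizeAggregate:
    def test_equal_group_sizes(self, rng):
        tracks = rng.uniform(size=(3, 100))
        _, _, groups = inter.normalize_and_aggregate(tracks, n_groups=10)
        sizes = np.bincount(groups)[1:]
        assert (sizes == 10).all()

    def test_single_cell_rank_preserved(self, rng):
        track = rng.uniform(size=(1, 50))
        normalized, median, _ = inter.normalize_and_aggregate(track, n_groups=5)
        assert (np.argsort(median) == np.argsort(track[0])).all()

    def test_cell_order_irrelevant(self, rng):
        tracks = rng.uniform(size=(4, 60))
        _, med1, _ = inter.normalize_and_aggregate(tracks, n_groups=5)
        _, med2, _ = inter.normalize_and_aggregate(tracks[::-1], n_groups=5)
        assert np.allclose(med1, med2)

    def test_all_na_locus_ungrouped(self, rng):
        tracks = rng.uniform(size=(2, 20))
        tracks[:, 5] = np.nan
        _, median, groups = inter.normalize_and_aggregate(tracks, n_groups=4)
        assert np.isnan(median[5]) and groups[5] == 0


class TestFeatureEnrichment:
    def test_uniform_features_null_logfc(self, rng):
        med = np.linspace(0, 1, 200)
        feats = np.ones(200)
        res = inter.feature_enrichment(feats, med)
        assert abs(res["log2fc"]) < 1e-9

    def test_top_only_features_capped(self):
        med = np.linspace(0, 1, 100)
        feats = (med >= 0.8).astype(float)
        res = inter.feature_enrichment(feats, med)
        assert res["capped"] and res["log2fc"] == 10.0

    def test_fisher_p_matches_hypergeometric_tail(self):
        """Brute-force hypergeometric sum for the 2x2 table (20,80 / 5,95)."""
        from math import comb

        def exact_two_sided(a, b, c, d):
            n = a + b + c + d
            row1, col1 = a + b, a + c
            def pr(x):
                return comb(col1, x) * comb(n - col1, row1 - x) / comb(n, row1)
            p_obs = pr(a)
            return sum(pr(x) for x in range(max(0, row1 + col1 - n), min(row1, col1) + 1)
                       if pr(x) <= p_obs * (1 + 1e-12))

        from scipy.stats import fisher_exact

        table = [[20, 80], [5, 95]]
        _, p = fisher_exact(table)
        assert p == pytest.approx(exact_two_sided(20, 80, 5, 95), rel=1e-9)


class TestTransDensity:
    def test_hand_computed_reciprocal_sums(self):
        coords = np.array([[0, 0, 0], [2.0, 0, 0], [0, 0, 9], [1.0, 0, 0]], dtype=float)
        ens = _toy_ensemble([coords], ["chr1", "chr2", "chr2", "chr1"])
        res = inter.trans_density(ens)
        # bead 0: trans beads at distances 2 and 9
        assert res["raw"][0] == pytest.approx(1 / 2 + 1 / 9)

    def test_background_median_is_exactly_one(self, small_ensemble):
        res = inter.trans_density(small_ensemble)
        assert np.median(res["scaled"]) == pytest.approx(1.0)

    def test_rigid_motion_invariance(self, small_ensemble):
        rot = Rotation.random(random_state=3).as_matrix()
        moved = StructureEnsemble(
            small_ensemble.chroms, small_ensemble.starts,
            small_ensemble.coords @ rot.T + 7.0, small_ensemble.bin_size,
        )
        a = inter.trans_density(small_ensemble)
        b = inter.trans_density(moved)
        assert np.allclose(a["scaled"], b["scaled"], atol=1e-9)

    def test_matches_naive_double_loop(self, small_ensemble):
        res = inter.trans_density(small_ensemble)
        codes = small_ensemble.chrom_codes()
        n = small_ensemble.n_beads
        for b in range(0, n, 29):
            total = 0.0
            for m in range(small_ensemble.n_models):
                for c in range(n):
                    if codes[c] != codes[b]:
                        d = np.linalg.norm(small_ensemble.coords[m, b] - small_ensemble.coords[m, c])
                        total += 1.0 / d
            assert res["raw"][b] == pytest.approx(total / small_ensemble.n_models)

    def test_per_class_distributions(self, small_ensemble):
        labels = np.array(["A", "B"] * (small_ensemble.n_beads // 2))
        res = inter.trans_density(small_ensemble, class_labels=labels)
        assert set(res["by_class"]) == {"A", "B"}
        assert res["by_class"]["A"].size == (labels == "A").sum()


class TestDiscrimination:
    def test_intermingled_cells_score_higher(self):
        """Cells at intermingle level 1 vs 0 (aggregated per arm) give
        higher per-locus median A-compartment scores by rank-sum test."""
        asm = build_genome(2, 5_000_000, 100_000)
        labels = synth.plant_compartments(asm, block_bins=10)
        a_mask = np.concatenate([labels[c] == "A" for c in asm.names])
        med = {}
        for lvl in (0.0, 1.0):
            tracks = []
            for k in range(6):
                conf = synth.simulate_conformation(asm, lvl, seed=100 + k)
                ens = synth.ensemble_from_truth(asm, conf, n_models=3, jitter=0.05, seed=k)
                tracks.append(inter.cell_track(ens))
            _, med[lvl], _ = inter.normalize_and_aggregate(np.array(tracks), n_groups=5)
        x, y = med[1.0][a_mask], med[0.0][a_mask]
        stat = inter.discrimination_test(x[~np.isnan(x)], y[~np.isnan(y)])
        assert stat.pvalue < 0.01
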