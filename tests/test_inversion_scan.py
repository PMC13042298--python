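"""Masking, Weir-Cockerham Fst, boundary calling, LD screen, PCA calls."""
import numpy as np
import pandas as pd
import pytest

from oracles import anova_wc_fst, exact_het_excess_p
from recland import inversion_scan as iscan
from recland import simdata
from recland.containers import MISSING, GenotypeMatrix


def _gm(genotypes, pos=None, chrom="LG1", dp=None, gq=None, n_alleles=None):
    g = np.asarray(genotypes, dtype=np.int8)
    n_sites, n_samples = g.shape
    return GenotypeMatrix(
        chrom=np.array([chrom] * n_sites, dtype=object),
        pos=np.asarray(pos if pos is not None else np.arange(n_sites) * 1000),
        genotypes=g, samples=[f"s{i}" for i in range(n_samples)],
        dp=None if dp is None else np.asarray(dp),
        gq=None if gq is None else np.asarray(gq),
        n_alleles=None if n_alleles is None else np.asarray(n_alleles))


class TestMasking:
    def test_low_depth_genotype_is_masked(self):
        g = [[1, 1, 1, 1]]
        dp = [[5, 20, 20, 20]]
        gq = [[60] * 4]
        gm = _gm(g, dp=dp, gq=gq)
        masked, report = iscan.mask_genotypes(gm, maf_min=0.0,
                                              depth_cap_sd=100.0)
        assert masked.genotypes[0, 0] == MISSING
        assert report["masked_low_dp"] == 1

    def test_low_gq_genotype_is_masked(self):
        gm = _gm([[1, 1, 1, 1]], dp=[[20] * 4], gq=[[10, 60, 60, 60]])
        masked, _ = iscan.mask_genotypes(gm, maf_min=0.0, depth_cap_sd=100.0)
        assert masked.genotypes[0, 0] == MISSING

    def test_all_het_site_dropped_for_heterozygote_excess(self):
        """200 heterozygotes and no homozygotes: the exact excess
        probability is far below the phred-54.69 threshold."""
        g = np.vstack([np.full((1, 200), 1), np.tile([0, 1, 1, 2], (1, 50))])
        gm = _gm(g, dp=np.full(g.shape, 20), gq=np.full(g.shape, 60))
        masked, report = iscan.mask_genotypes(gm, maf_min=0.0, depth_cap_sd=100.0)
        assert report["dropped_excess_het"] == 1
        assert masked.n_sites == 1

    def test_non_biallelic_site_dropped(self):
        gm = _gm([[0, 1], [1, 1]], dp=np.full((2, 2), 20),
                 gq=np.full((2, 2), 60), n_alleles=[3, 2])
        masked, report = iscan.mask_genotypes(gm, maf_min=0.0, depth_cap_sd=100.0)
        assert report["dropped_not_biallelic"] == 1
        assert masked.n_sites == 1

    def test_missing_dp_gq_skips_masks_with_warning(self):
        gm = _gm([[0, 1, 1, 2]])
        with pytest.warns(UserWarning, match="DP"):
            masked, _ = iscan.mask_genotypes(gm, maf_min=0.0)
        assert masked.n_sites == 1

    @pytest.mark.parametrize("counts", [(0, 200, 0), (50, 100, 50),
                                        (90, 20, 90), (10, 5, 0), (0, 1, 0)])
    def test_excess_het_matches_exact_rational_oracle(self, counts):
        rr, ra, aa = counts
        ours = iscan.excess_het_phred([rr], [ra], [aa])[0]
        oracle = exact_het_excess_p(rr, ra, aa)
        assert ours == pytest.approx(-10 * np.log10(max(oracle, 1e-300)),
                                     rel=1e-9, abs=1e-9)


class TestWindowedFst:
    def test_fixed_differences_give_fst_one(self):
        g = np.column_stack([np.zeros((20, 10)), np.full((20, 10), 2)])
        gm = _gm(g)
        track = iscan.windowed_fst(gm, [f"s{i}" for i in range(10)],
                                   [f"s{i}" for i in range(10, 20)],
                                   window_bp=50_000, step_bp=50_000)
        assert track["fst"].dropna().iloc[0] == pytest.approx(1.0)

    def test_identical_frequencies_give_near_zero_fst(self):
        rng = np.random.default_rng(0)
        g = rng.binomial(2, 0.4, (50, 200)).astype(np.int8)
        gm = _gm(g)
        track = iscan.windowed_fst(gm, [f"s{i}" for i in range(100)],
                                   [f"s{i}" for i in range(100, 200)],
                                   window_bp=100_000, step_bp=100_000)
        assert abs(track["fst"].dropna().iloc[0]) < 0.02

    def test_per_site_components_match_anova_oracle(self):
        rng = np.random.default_rng(1)
        gA = rng.binomial(2, 0.9, (30, 10)).astype(np.int8)
        gB = rng.binomial(2, 0.1, (30, 12)).astype(np.int8)
        gA[rng.random(gA.shape) < 0.05] = MISSING
        a, b, c = iscan.wc_fst_components(gA, gB)
        oracle = anova_wc_fst(gA, gB)
        ok = ~np.isnan(a)
        assert np.allclose(a[ok], oracle[ok, 0], atol=1e-12)
        assert np.allclose(b[ok], oracle[ok, 1], atol=1e-12)
        assert np.allclose(c[ok], oracle[ok, 2], atol=1e-12)

    def test_single_snp_window_equals_per_site_value(self):
        rng = np.random.default_rng(2)
        g = np.column_stack([rng.binomial(2, 0.8, (1, 10)),
                             rng.binomial(2, 0.2, (1, 10))]).astype(np.int8)
        gm = _gm(g, pos=[500])
        a, b, c = iscan.wc_fst_components(g[:, :10], g[:, 10:])
        track = iscan.windowed_fst(gm, [f"s{i}" for i in range(10)],
                                   [f"s{i}" for i in range(10, 20)])
        per_site = a[0] / (a[0] + b[0] + c[0])
        assert track["fst"].dropna().iloc[0] == pytest.approx(per_site, abs=1e-12)

    def test_invariant_to_individual_order(self):
        rng = np.random.default_rng(3)
        g = rng.binomial(2, rng.uniform(0.2, 0.8, (40, 1)), (40, 30)).astype(np.int8)
        gm = _gm(g)
        ga = [f"s{i}" for i in range(15)]
        gb = [f"s{i}" for i in range(15, 30)]
        t1 = iscan.windowed_fst(gm, ga, gb)
        t2 = iscan.windowed_fst(gm, ga[::-1], gb[::-1])
        pd.testing.assert_frame_equal(t1, t2)

    def test_small_group_rejected(self):
        gm = _gm([[0, 1, 2]])
        with pytest.raises(ValueError, match="group"):
            iscan.windowed_fst(gm, ["s0"], ["s1", "s2"])


class TestCallBoundaries:
    def _track(self, fsts, window=100_000):
        return pd.DataFrame({
            "lg": "LG1",
            "start": np.arange(len(fsts)) * window,
            "end": np.arange(1, len(fsts) + 1) * window,
            "fst": fsts, "n_snps": 10})

    def test_hand_walked_example(self):
        track = self._track([0.02, 0.05, 0.30, 0.40, 0.35, 0.10, 0.05])
        assert iscan.call_boundaries(track) == [("LG1", 200_000, 500_000)]

    def test_all_below_threshold_is_none(self):
        assert iscan.call_boundaries(self._track([0.1, 0.05, 0.12, 0.08])) == []

    def test_all_above_threshold_is_whole_extent(self):
        track = self._track([0.3, 0.4, 0.5, 0.4])
        assert iscan.call_boundaries(track) == [("LG1", 0, 400_000)]

    def test_short_gaps_are_merged_long_gaps_split(self):
        merged = self._track([0.3] * 3 + [0.05] * 2 + [0.3] * 3)
        assert iscan.call_boundaries(merged) == [("LG1", 0, 800_000)]
        split = self._track([0.3] * 3 + [0.05] * 3 + [0.3] * 3)
        assert iscan.call_boundaries(split) == [
            ("LG1", 0, 300_000), ("LG1", 600_000, 900_000)]

    def test_invariant_to_flanking_cold_windows(self):
        core = [0.3, 0.4, 0.35]
        a = iscan.call_boundaries(self._track([0.01] * 2 + core + [0.02] * 2))
        b = iscan.call_boundaries(self._track([0.05] * 4 + core + [0.01]))
        assert a[0][2] - a[0][1] == b[0][2] - b[0][1] == 300_000

    def test_runs_shorter_than_minimum_ignored(self):
        track = self._track([0.3, 0.4, 0.05, 0.3, 0.05])
        assert iscan.call_boundaries(track, min_consecutive=3) == []

    def test_empty_track_rejected(self):
        with pytest.raises(ValueError):
            iscan.call_boundaries(pd.DataFrame(columns=["lg", "start", "end",
                                                        "fst", "n_snps"]))


class TestLdScreen:
    def test_duplicated_snp_has_unit_r2(self):
        rng = np.random.default_rng(4)
        row = rng.binomial(2, 0.5, 100).astype(np.int8)
        g = np.vstack([row, row])
        gm = _gm(g, pos=[1_000, 15_000])
        res = iscan.ld_screen(gm, "LG1", maf_min=0.1)
        assert res.r2[0, 1] == pytest.approx(1.0)

    def test_independent_snps_have_mean_r2_about_one_over_n(self):
        rng = np.random.default_rng(5)
        n = 200
        g = rng.binomial(2, 0.5, (80, n)).astype(np.int8)
        gm = _gm(g, pos=np.arange(80) * 12_000)
        res = iscan.ld_screen(gm, "LG1", maf_min=0.1)
        off = res.r2[np.triu_indices(len(res.kept_pos), k=1)]
        se = np.sqrt(2.0) / n / np.sqrt(len(off))   # var(r^2) ~ 2/n^2 under null
        assert abs(off.mean() - 1 / n) < 5 * se + 0.002

    def test_thinning_keeps_first_passing_snp_per_bin(self):
        g = np.array([[0] * 50 + [1] * 50,          # maf 0.25 (dosage mean .5)
                      [0, 1] * 50,
                      [2] * 100], dtype=np.int8)    # monomorphic: maf 0
        gm = _gm(g, pos=[1_000, 2_000, 15_000])
        res = iscan.ld_screen(gm, "LG1", maf_min=0.2)
        assert res.kept_pos.tolist() == [1_000]

    def test_too_few_kept_snps_is_empty(self):
        gm = _gm(np.zeros((3, 20)), pos=[0, 1000, 2000])
        res = iscan.ld_screen(gm, "LG1")
        assert res.blocks == [] and res.r2.size == 0


class TestPcaGenotype:
    def _fixed_difference_panel(self, n=120, n_snps=60, freq=0.4, seed=0):
        """Arrangement haplotypes carry fixed differences: dosage = karyotype."""
        rng = np.random.default_rng(seed)
        k = rng.binomial(2, freq, n)
        g = np.tile(k, (n_snps, 1)).astype(np.int8)
        return _gm(g, pos=np.arange(n_snps) * 1000), k

    def test_fixed_differences_recover_truth_exactly(self):
        gm, truth = self._fixed_difference_panel()
        res = iscan.pca_genotype(gm)
        assert not res.ambiguous
        acc = max(np.mean(res.genotypes == truth),
                  np.mean((2 - res.genotypes) == truth))
        assert acc == 1.0

    def test_diverged_panel_recovers_with_high_accuracy(self):
        spec = simdata.LayoutSpec(n_lg=1, lg_length_bp=2_000_000,
                                  inversions=[("LG1", 400_000, 1_600_000, 0.4)],
                                  seed=6)
        layout = simdata.simulate_genome(spec)
        hits = 0
        for seed in range(8):
            panel = simdata.simulate_population(layout, 240, 0.5, seed=seed,
                                                snps_per_lg=500)
            res = iscan.pca_genotype(panel.genotypes, ("LG1", 400_000, 1_600_000))
            truth = panel.inversion_genotypes_truth["Inv1"].to_numpy()
            if not res.ambiguous:
                acc = max(np.mean(res.genotypes == truth),
                          np.mean((2 - res.genotypes) == truth))
                hits += acc >= 0.99
        assert hits >= 7

    def test_undiverged_panel_is_flagged_ambiguous(self):
        spec = simdata.LayoutSpec(n_lg=1, lg_length_bp=2_000_000,
                                  inversions=[("LG1", 400_000, 1_600_000, 0.4)],
                                  seed=6)
        layout = simdata.simulate_genome(spec)
        flagged = 0
        for seed in range(8):
            panel = simdata.simulate_population(layout, 120, 0.0, seed=seed,
                                                snps_per_lg=300)
            res = iscan.pca_genotype(panel.genotypes, ("LG1", 400_000, 1_600_000))
            flagged += res.ambiguous
        assert flagged >= 7

    def test_too_few_individuals_or_snps_rejected(self):
        with pytest.raises(ValueError, match="individuals"):
            iscan.pca_genotype(_gm(np.zeros((20, 2))))
        with pytest.raises(ValueError, match="SNPs"):
            iscan.pca_genotype(_gm(np.zeros((4, 20))))
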