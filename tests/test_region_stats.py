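"""Region rates, permutation machinery, window densities, sex linkage."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import enumerate_label_perm_p, interval_union_bp
from recland import marey, region_stats


def _linear_marey(rate=5.0, span=10_000_000):
    bp = np.arange(0, span + 1, 100_000)
    return marey.build_marey(bp, bp / 1e6 * rate)


def _regions(records):
    return pd.DataFrame(records, columns=["lg", "start", "end", "label", "name"])


class TestRegionRates:
    def test_rate_is_delta_cm_over_delta_mb(self):
        mm = _linear_marey(rate=5.0)
        reg = _regions([("LG", 2_000_000, 4_000_000, "collinear", "r1")])
        out = region_stats.region_rates(mm, reg)
        assert out["rate_cM_per_Mb"].iloc[0] == pytest.approx(5.0)

    def test_flat_region_rate_is_zero(self):
        bp = np.arange(0, 4_000_001, 100_000)
        cm = np.where(bp < 2_000_000, bp / 1e6 * 10, 20.0)
        mm = marey.build_marey(bp, cm)
        reg = _regions([("LG", 2_000_000, 4_000_000, "inversion", "inv")])
        out = region_stats.region_rates(mm, reg)
        assert out["rate_cM_per_Mb"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_boundary_interpolation_between_markers(self):
        """Markers at (1 Mb, 10 cM) and (2 Mb, 20 cM): a region starting at
        1.5 Mb starts at the interpolated 15 cM."""
        mm = marey.build_marey([0, 1_000_000, 2_000_000], [0.0, 10.0, 20.0])
        reg = _regions([("LG", 1_500_000, 2_000_000, "collinear", "r")])
        out = region_stats.region_rates(mm, reg)
        assert out["rate_cM_per_Mb"].iloc[0] == pytest.approx((20 - 15) / 0.5)

    def test_region_outside_extent_flagged_missing(self):
        mm = _linear_marey(span=1_000_000)
        reg = _regions([("LG", 500_000, 2_000_000, "collinear", "r")])
        out = region_stats.region_rates(mm, reg)
        assert np.isnan(out["rate_cM_per_Mb"].iloc[0])

    def test_rate_is_additive_over_partitions(self):
        rng = np.random.default_rng(2)
        bp = np.sort(rng.choice(10_000_000, 300, replace=False))
        mm = marey.build_marey(bp, np.sort(rng.uniform(0, 50, 300)))
        lo, hi = int(mm.bp[0]) + 1000, int(mm.bp[-1]) - 1000
        cut = (lo + hi) // 2
        whole = region_stats.region_rates(
            mm, _regions([("LG", lo, hi, "c", "w")]))["rate_cM_per_Mb"][0]
        parts = region_stats.region_rates(
            mm, _regions([("LG", lo, cut, "c", "a"), ("LG", cut, hi, "c", "b")]))
        spans = parts["end"] - parts["start"]
        weighted = (parts["rate_cM_per_Mb"] * spans).sum() / spans.sum()
        assert weighted == pytest.approx(whole, rel=1e-9)


class TestLabelPermutation:
    def test_equal_rates_are_never_significant(self):
        rates = pd.DataFrame({
            "label": ["collinear"] * 5 + ["inversion"] * 3,
            "rate_cM_per_Mb": 2.0})
        res = region_stats.label_permutation_test(rates, n_perm=200, seed=1)
        assert res.p_value == 1.0

    def test_complete_separation_matches_exact_enumeration(self):
        vals = [9.0, 8.0, 7.5, 7.0, 1.0, 0.5, 0.2]
        labels = ["collinear"] * 4 + ["inversion"] * 3
        rates = pd.DataFrame({"label": labels, "rate_cM_per_Mb": vals})
        res = region_stats.label_permutation_test(rates, n_perm=5000, seed=2)
        exact = enumerate_label_perm_p(vals, np.array(labels))
        # empirical add-one p converges to the exact enumeration value
        assert res.p_value == pytest.approx(exact, abs=3 * np.sqrt(exact / 5000) + 1e-3)

    def test_single_label_input_rejected(self):
        rates = pd.DataFrame({"label": ["collinear"] * 4,
                              "rate_cM_per_Mb": [1, 2, 3, 4.0]})
        with pytest.raises(ValueError):
            region_stats.label_permutation_test(rates)

    def test_p_values_reproducible_by_seed(self):
        rng = np.random.default_rng(3)
        rates = pd.DataFrame({
            "label": ["collinear"] * 10 + ["inversion"] * 5,
            "rate_cM_per_Mb": rng.uniform(0, 10, 15)})
        a = region_stats.label_permutation_test(rates, n_perm=300, seed=7)
        b = region_stats.label_permutation_test(rates, n_perm=300, seed=7)
        assert a.p_value == b.p_value
        assert np.array_equal(a.null, b.null)


class TestWindowDensity:
    def test_single_feature_half_covers_window(self):
        feats = pd.DataFrame([("LG1", 10_000, 35_000)],
                             columns=["lg", "start", "end"])
        out = region_stats.window_density(feats, {"LG1": 50_000})
        assert out["density"].iloc[0] == pytest.approx(0.5)

    def test_overlapping_features_are_merged(self):
        feats = pd.DataFrame([("LG1", 0, 30_000), ("LG1", 20_000, 50_000)],
                             columns=["lg", "start", "end"])
        out = region_stats.window_density(feats, {"LG1": 50_000})
        assert out["density"].iloc[0] == pytest.approx(1.0)

    def test_empty_track_is_all_zero(self):
        feats = pd.DataFrame(columns=["lg", "start", "end"])
        out = region_stats.window_density(feats, {"LG1": 200_000})
        assert (out["density"] == 0).all()

    @given(st.lists(st.tuples(st.integers(0, 900_000), st.integers(1, 100_000)),
                    max_size=30))
    @settings(deadline=None, max_examples=100)
    def test_density_sums_conserve_union_bases(self, raw):
        intervals = [(s, s + w) for s, w in raw]
        feats = pd.DataFrame([("LG1", s, e) for s, e in intervals],
                             columns=["lg", "start", "end"])
        out = region_stats.window_density(feats, {"LG1": 1_000_000})
        assert out["covered_bp"].sum() == interval_union_bp(intervals)


class TestEnrichment:
    def test_zero_overlap_is_minimal_depletion(self):
        """Features at ~30% density everywhere except inside the inversion:
        the observed inside-fraction is 0, every relocation overlaps some
        feature bases, so the depletion tail p is exactly 1/(n+1)."""
        feats = pd.DataFrame(
            [("LG1", s, s + 3_000) for s in range(0, 10_000_000, 10_000)
             if not (8_000_000 <= s < 9_000_000)],
            columns=["lg", "start", "end"])
        inv = pd.DataFrame([("LG1", 8_000_000, 9_000_000, "Inv1")],
                           columns=["lg", "start", "end", "name"])
        res = region_stats.enrichment_permutation(feats, inv, {"LG1": 10_000_000},
                                                  n_perm=200, seed=0)
        assert res.observed == 0.0
        assert res.direction == "depleted"
        assert res.extra["p_depleted"] == pytest.approx(1 / 201)

    def test_oversized_inversion_rejected(self):
        feats = pd.DataFrame([("LG1", 0, 1000)], columns=["lg", "start", "end"])
        inv = pd.DataFrame([("LG1", 0, 900_000, "big")],
                           columns=["lg", "start", "end", "name"])
        with pytest.raises(ValueError, match="longer"):
            region_stats.enrichment_permutation(feats, inv, {"LG1": 900_000})

    def test_null_seed_reproducibility(self):
        rng = np.random.default_rng(1)
        feats = pd.DataFrame([("LG1", int(s), int(s) + 5_000) for s in
                              rng.choice(1_000_000, 50)],
                             columns=["lg", "start", "end"])
        inv = pd.DataFrame([("LG1", 100_000, 200_000, "Inv1")],
                           columns=["lg", "start", "end", "name"])
        a = region_stats.enrichment_permutation(feats, inv, {"LG1": 1_000_000},
                                                n_perm=100, seed=9)
        b = region_stats.enrichment_permutation(feats, inv, {"LG1": 1_000_000},
                                                n_perm=100, seed=9)
        assert np.array_equal(a.null, b.null)


class TestSexLinkage:
    def _coverage(self, male, female):
        return pd.DataFrame({"contig": [male, male, female, female]},
                            index=["m1", "m2", "f1", "f2"]).T.pipe(
            lambda df: pd.DataFrame(
                {"contig": [male, male, female, female]},
                index=["m1", "m2", "f1", "f2"]))

    def test_half_male_coverage_is_x_linked(self):
        cov = self._coverage(0.5, 1.0)
        sexes = {"m1": "male", "m2": "male", "f1": "female", "f2": "female"}
        out = region_stats.sex_linkage_scan(cov, sexes)
        assert out["classification"].iloc[0] == "X-linked"

    def test_full_coverage_both_sexes_is_autosomal(self):
        cov = self._coverage(1.0, 1.0)
        sexes = {"m1": "male", "m2": "male", "f1": "female", "f2": "female"}
        out = region_stats.sex_linkage_scan(cov, sexes)
        assert out["classification"].iloc[0] == "autosomal"

    def test_half_coverage_both_sexes_stays_ambiguous(self):
        cov = self._coverage(0.5, 0.5)
        sexes = {"m1": "male", "m2": "male", "f1": "female", "f2": "female"}
        out = region_stats.sex_linkage_scan(cov, sexes)
        assert out["classification"].iloc[0] == "ambiguous"

    def test_missing_sex_rejected(self):
        cov = self._coverage(1.0, 1.0)
        with pytest.raises(ValueError):
            region_stats.sex_linkage_scan(cov, {"m1": "male", "m2": "male",
                                                "f1": "male", "f2": "male"})
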