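"""Methylation densities, metagene profiles, error rate and DMR calling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import oryzanc as oz
import oryzanc.simulate as sim
from oryzanc.methylome import binomial_two_sided, call_dmrs

from _oracles import binom_two_sided_oracle


def calls_frame(rows):
    """rows: (chrom, pos0, strand, meth, unmeth, context)"""
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos0", "strand", "count_meth", "count_unmeth", "context"],
    )


def uniform_calls(chrom, positions, level, n_reads, context="CG"):
    m = int(round(level * n_reads))
    return calls_frame(
        [(chrom, p, "+", m, n_reads - m, context) for p in positions]
    )


class TestDensity:
    def test_weighted_level_arithmetic(self):
        feats = pd.DataFrame(
            {"chrom": ["Chr1"], "start": [0], "end": [100], "strand": ["+"]},
            index=["f1"],
        )
        calls = calls_frame(
            [("Chr1", 10, "+", 5, 10, "CG"), ("Chr1", 20, "-", 0, 5, "CG"),
             ("Chr1", 30, "+", 3, 3, "CHG"), ("Chr1", 200, "+", 9, 1, "CG")]
        )
        # inside f1: CG counts 5/15 and 0/5 -> 5 meth of 20 total
        assert oz.feature_methylation_density(calls, feats, "CG")["f1"] == pytest.approx(0.25)
        # no CHH cytosine in the feature -> undefined, not zero
        assert np.isnan(oz.feature_methylation_density(calls, feats, "CHH")["f1"])

    def test_fully_methylated(self):
        feats = pd.DataFrame(
            {"chrom": ["Chr1"], "start": [0], "end": [50], "strand": ["+"]}, index=["f"]
        )
        calls = uniform_calls("Chr1", [5, 25], 1.0, 8)
        assert oz.feature_methylation_density(calls, feats, "CG")["f"] == 1.0


class TestMetageneProfile:
    def test_uniform_level_gives_flat_profile(self):
        positions = np.arange(5, 30_000, 10)
        calls = uniform_calls("Chr1", positions, 0.5, 10)
        feats = pd.DataFrame(
            {"chrom": ["Chr1"] * 3, "start": [2000, 12_000, 22_000],
             "end": [6000, 16_000, 26_000], "strand": ["+", "-", "+"]},
            index=["a", "b", "c"],
        )
        prof = oz.metagene_profile(calls, feats, "CG")
        assert prof.n_features == 3
        assert np.allclose(prof.values, 0.5)

    def test_single_covered_cytosine_single_defined_bin(self):
        calls = calls_frame([("Chr1", 1500, "+", 4, 4, "CG")])
        feats = pd.DataFrame(
            {"chrom": ["Chr1"], "start": [1000], "end": [2000], "strand": ["+"]},
            index=["f"],
        )
        prof = oz.metagene_profile(calls, feats, "CG")
        assert np.sum(~np.isnan(prof.values)) == 1
        assert np.nansum(prof.values) == pytest.approx(0.5)

    def test_flank_boundary_inclusion(self):
        # flank covers [start-1000, start): pos start-1000 is bin 0,
        # pos start-1001 is outside
        feats = pd.DataFrame(
            {"chrom": ["Chr1"], "start": [5000], "end": [6000], "strand": ["+"]},
            index=["f"],
        )
        for flank in (1000, 2000):
            inside = calls_frame([("Chr1", 5000 - flank, "+", 2, 0, "CG")])
            outside = calls_frame([("Chr1", 5000 - flank - 1, "+", 2, 0, "CG")])
            p_in = oz.metagene_profile(inside, feats, "CG", flank_bp=flank)
            p_out = oz.metagene_profile(outside, feats, "CG", flank_bp=flank)
            assert p_in.values[0] == 1.0
            assert np.all(np.isnan(p_out.values))

    def test_strand_symmetry(self):
        # mirrored minus-strand feature sees the reversed profile
        positions = np.arange(0, 10_000, 25)
        levels = np.where(positions < 5000, 0.2, 0.8)
        rows = [
            ("Chr1", int(p), "+", int(10 * l), int(10 * (1 - l)), "CG")
            for p, l in zip(positions, levels)
        ]
        calls = calls_frame(rows)
        plus = pd.DataFrame(
            {"chrom": ["Chr1"], "start": [2000], "end": [8000], "strand": ["+"]},
            index=["f"],
        )
        minus = plus.assign(strand="-")
        p1 = oz.metagene_profile(calls, plus, "CG")
        p2 = oz.metagene_profile(calls, minus, "CG")
        assert np.allclose(p1.values, p2.values[::-1], equal_nan=True)

    def test_stratified_matches_single_profile(self):
        positions = np.arange(5, 10_000, 20)
        calls = uniform_calls("Chr1", positions, 0.3, 10)
        feats = pd.DataFrame(
            {"chrom": ["Chr1"] * 2, "start": [1000, 6000], "end": [3000, 8000],
             "strand": ["+", "+"]},
            index=["a", "b"],
        )
        strata = pd.Series({"a": "one", "b": "one"})
        profs = oz.stratified_profiles(calls, feats, strata, "CG")
        ref = oz.metagene_profile(calls, feats, "CG")
        assert np.allclose(profs["one"].values, ref.values, equal_nan=True)

    def test_empty_stratum_flagged_not_error(self):
        calls = uniform_calls("Chr1", [100], 0.5, 4)
        feats = pd.DataFrame(
            {"chrom": ["Chr1"], "start": [50], "end": [150], "strand": ["+"]},
            index=["a"],
        )
        profs = oz.stratified_profiles(
            calls, feats, pd.Series({"a": "g1", "zz": "g2"}), "CG"
        )
        assert profs["g2"].n_features == 0
        assert np.all(np.isnan(profs["g2"].values))


class TestErrorRate:
    def test_arithmetic(self):
        rows = [("ChrC", i, "+", 0, 1, "CG") for i in range(997)]
        rows += [("ChrC", 2000 + i, "+", 1, 0, "CG") for i in range(3)]
        assert oz.estimate_error_rate(calls_frame(rows), "ChrC") == pytest.approx(0.003)

    def test_zero_methylation(self):
        calls = uniform_calls("ChrC", [1, 2, 3], 0.0, 5)
        assert oz.estimate_error_rate(calls, "ChrC") == 0.0

    def test_no_coverage_raises(self):
        with pytest.raises(ValueError):
            oz.estimate_error_rate(uniform_calls("Chr1", [1], 0.5, 4), "ChrC")

    def test_simulated_rate_within_three_binomial_se(self, config, annotation):
        meth = sim.generate_methylome(config, annotation)
        est = oz.estimate_error_rate(meth["A"], annotation.control_contig)
        sub = meth["A"][meth["A"]["chrom"] == annotation.control_contig]
        total = (sub["count_meth"] + sub["count_unmeth"]).sum()
        se = np.sqrt(config.error_rate * (1 - config.error_rate) / total)
        assert abs(est - config.error_rate) <= 3 * se


class TestBinomialTest:
    def test_matches_exact_enumeration(self):
        rng = np.random.default_rng(3)
        for _ in range(150):
            n = int(rng.integers(1, 31))
            k = int(rng.integers(0, n + 1))
            p0 = float(rng.uniform(0.01, 0.99))
            got = binomial_two_sided(k, n, p0)
            want = binom_two_sided_oracle(k, n, p0)
            assert got == pytest.approx(want, rel=1e-12), (k, n, p0)

    def test_agrees_with_scipy_binomtest(self):
        rng = np.random.default_rng(4)
        for _ in range(60):
            n = int(rng.integers(2, 40))
            k = int(rng.integers(0, n + 1))
            p0 = float(rng.uniform(0.05, 0.95))
            ours = binomial_two_sided(k, n, p0)
            ref = stats.binomtest(k, n, p0, alternative="two-sided").pvalue
            assert ours == pytest.approx(ref, rel=1e-6)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            binomial_two_sided(5, 4, 0.5)
        with pytest.raises(ValueError):
            binomial_two_sided(1, 4, 0.0)


class TestCallDMRs:
    def sample(self, rows):
        return calls_frame(rows)

    def test_strong_site_is_hyper_dmr(self):
        a = self.sample([("Chr1", 100, "+", 9, 1, "CG")])
        b = self.sample([("Chr1", 100, "+", 1, 9, "CG")])
        sites, regions = call_dmrs(a, b, "CG")
        assert sites["is_dmr"].tolist() == [True]
        assert len(regions) == 1 and regions[0].direction == "hyper"
        assert regions[0].level_a == pytest.approx(0.9)
        # p-value equals the exact enumeration at the pooled null
        want = binom_two_sided_oracle(9, 10, 0.5)
        assert sites["p_value"][0] == pytest.approx(want, rel=1e-12)

    def test_spec_null_variant_against_other_sample(self):
        a = self.sample([("Chr1", 100, "+", 9, 1, "CG")])
        b = self.sample([("Chr1", 100, "+", 1, 9, "CG")])
        sites, _ = call_dmrs(a, b, "CG", null="other", error_rate=0.003)
        want = binom_two_sided_oracle(9, 10, 0.1)
        assert sites["p_value"][0] == pytest.approx(want, rel=1e-12)
        assert want == pytest.approx(9.1e-9, rel=0.01)

    def test_small_difference_never_dmr(self):
        a = self.sample([("Chr1", 100, "+", 6, 4, "CG")])
        b = self.sample([("Chr1", 100, "+", 4, 6, "CG")])
        sites, regions = call_dmrs(a, b, "CG")
        assert not sites["is_dmr"].any() and regions == []

    def test_difference_boundary_0_6(self):
        # 24/30 vs 6/30: difference exactly 0.6 -> called ("0.6 or above")
        a = self.sample([("Chr1", 100, "+", 24, 6, "CG")])
        b = self.sample([("Chr1", 100, "+", 6, 24, "CG")])
        sites, _ = call_dmrs(a, b, "CG")
        assert sites["is_dmr"].tolist() == [True]
        # 23/30 vs 7/30: difference ~0.53 -> not called
        a = self.sample([("Chr1", 100, "+", 23, 7, "CG")])
        b = self.sample([("Chr1", 100, "+", 7, 23, "CG")])
        sites, _ = call_dmrs(a, b, "CG")
        assert sites["is_dmr"].tolist() == [False]

    def test_identical_counts_not_dmr(self):
        a = self.sample([("Chr1", 100, "+", 5, 5, "CG")])
        sites, regions = call_dmrs(a, a.copy(), "CG")
        assert not sites["is_dmr"].any()

    def test_min_coverage_and_config_errors(self):
        a = self.sample([("Chr1", 100, "+", 2, 1, "CG")])
        b = self.sample([("Chr1", 100, "+", 0, 3, "CG")])
        sites, _ = call_dmrs(a, b, "CG", min_coverage=4)
        assert len(sites) == 0  # 3 reads < 4: skipped, never imputed
        with pytest.raises(ValueError):
            call_dmrs(a, b, "CG", min_coverage=0)

    def test_region_merging_same_direction_within_gap(self):
        rows_a = [("Chr1", p, "+", 19, 1, "CG") for p in (100, 200, 1000)]
        rows_b = [("Chr1", p, "+", 1, 19, "CG") for p in (100, 200, 1000)]
        sites, regions = call_dmrs(
            self.sample(rows_a), self.sample(rows_b), "CG", merge_gap=200
        )
        assert [(r.start, r.end, r.n_sites) for r in regions] == [
            (100, 201, 2), (1000, 1001, 1),
        ]
        assert regions[0].level_a == pytest.approx(19 / 20)

    def test_opposite_directions_not_merged(self):
        rows_a = [("Chr1", 100, "+", 19, 1, "CG"), ("Chr1", 150, "+", 1, 19, "CG")]
        rows_b = [("Chr1", 100, "+", 1, 19, "CG"), ("Chr1", 150, "+", 19, 1, "CG")]
        _, regions = call_dmrs(self.sample(rows_a), self.sample(rows_b), "CG")
        assert sorted(r.direction for r in regions) == ["hyper", "hypo"]


class TestAnnotateDMRs:
    def test_overlap_counting_and_de_join(self):
        feats = pd.DataFrame(
            {"chrom": ["Chr1", "Chr1"], "start": [0, 150], "end": [200, 400],
             "strand": ["+", "+"]},
            index=["f1", "f2"],
        )
        dmrs = [
            oz.DMR("Chr1", 160, 180, "CG", 0.9, 0.1, 1e-6, "hyper"),  # in both
            oz.DMR("Chr1", 300, 320, "CG", 0.1, 0.9, 1e-6, "hypo"),   # f2 only
            oz.DMR("Chr2", 0, 10, "CG", 0.9, 0.1, 1e-6, "hyper"),     # elsewhere
        ]
        de = pd.DataFrame({"direction": ["Up"]}, index=["f1"])
        out = oz.annotate_dmr_features(dmrs, feats, de)
        assert out.loc["f1"].tolist() == [1, 0, "Up"]
        assert out.loc["f2"].tolist() == [1, 1, "None"]

    def test_no_de_table(self):
        feats = pd.DataFrame(
            {"chrom": ["Chr1"], "start": [0], "end": [10], "strand": ["+"]},
            index=["f"],
        )
        out = oz.annotate_dmr_features([], feats)
        assert out.loc["f", "de_status"] == "None"
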