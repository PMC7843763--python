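"""Generator invariants: determinism, bounds, planted-truth sufficiency."""

import numpy as np
import pandas as pd
import pytest

import oryzanc as oz
import oryzanc.simulate as sim
from oryzanc.io import write_gff3


def small_config(**kw):
    kw.setdefault("seed", 7)
    kw.setdefault("n_chromosomes", 1)
    kw.setdefault("chrom_length", 500_000)
    kw.setdefault("n_genes", 30)
    kw.setdefault("n_te", 40)
    kw.setdefault("n_lncrna", 60)
    kw.setdefault("n_circ", 25)
    kw.setdefault("site_spacing", {"CG": 200, "CHG": 400, "CHH": 400})
    return oz.SimConfig(**kw)


class TestConfigValidation:
    def test_bad_weights(self):
        with pytest.raises(ValueError):
            small_config(te_superfamily_weights={"Gypsy": 0.7})

    def test_bad_probability(self):
        with pytest.raises(ValueError):
            small_config(error_rate=1.5)

    def test_cluster_outside_bounds(self):
        with pytest.raises(ValueError):
            small_config(hot_cluster_spec=[("Chr9", 0, 100, 2.0)])

    def test_dmr_region_validation(self):
        with pytest.raises(ValueError):
            small_config(dmr_spec=[("Chr1", 0, 100, "CXX", 0.9, 0.1)])


class TestAnnotation:
    def test_zero_genes_still_emits_tes(self):
        ann = sim.generate_annotation(small_config(n_genes=0))
        assert ann.genes == {} and len(ann.tes) == 40

    def test_infeasible_packing_raises(self):
        with pytest.raises(ValueError):
            sim.generate_annotation(small_config(n_genes=200))

    def test_degenerate_superfamily_weights(self):
        ann = sim.generate_annotation(
            small_config(te_superfamily_weights={"LTR/Gypsy": 1.0}, n_te=50)
        )
        assert all(t.superfamily == "LTR/Gypsy" for t in ann.tes)

    def test_intervals_within_bounds_and_genes_disjoint(self):
        ann = sim.generate_annotation(small_config())
        for g in ann.genes.values():
            assert 0 <= g.start < g.end <= ann.chromosomes[g.chrom]
        for t in ann.tes:
            assert 0 <= t.start < t.end <= ann.chromosomes[t.chrom]
        by_chrom = {}
        for g in ann.genes.values():
            by_chrom.setdefault(g.chrom, []).append((g.start, g.end))
        for ivs in by_chrom.values():
            ivs.sort()
            assert all(a[1] <= b[0] for a, b in zip(ivs, ivs[1:]))

    def test_gff3_byte_identical_across_runs(self, tmp_path):
        p1, p2 = tmp_path / "a.gff3", tmp_path / "b.gff3"
        write_gff3(sim.generate_annotation(small_config()), p1)
        write_gff3(sim.generate_annotation(small_config()), p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestLncRNAGenerator:
    def test_no_multiplier_means_no_hot_cluster_truth(self):
        cfg = small_config()
        ann = sim.generate_annotation(cfg)
        *_, truth = sim.generate_lncrna_candidates(cfg, ann)
        assert not truth["in_hot_cluster"].any()

    def test_planted_cluster_region_recorded(self):
        cfg = small_config(
            chrom_length=2_000_000, n_genes=40,
            hot_cluster_spec=[("Chr1", 600_000, 1_200_000, 6.0)],
            n_lncrna=300,
        )
        ann = sim.generate_annotation(cfg)
        *_, truth = sim.generate_lncrna_candidates(cfg, ann)
        hot = truth[truth["in_hot_cluster"]]
        assert len(hot) > 0
        assert hot["start"].between(600_000, 1_200_000).all()

    @pytest.mark.parametrize("seed", [0, 7, 12345])
    def test_candidates_within_chromosome_bounds(self, seed):
        cfg = small_config(seed=seed, chrom_length=600_000, n_lncrna=300)
        ann = sim.generate_annotation(cfg)
        cands, *_ = sim.generate_lncrna_candidates(cfg, ann)
        for c in cands:
            assert 0 <= c.start < c.end <= cfg.chrom_length

    def test_all_short_when_fraction_one(self):
        cfg = small_config(fraction_short=1.0, fraction_low_expr=0.0,
                           fraction_coding=0.0, fraction_pfam=0.0)
        ann = sim.generate_annotation(cfg)
        cands, *_, truth = sim.generate_lncrna_candidates(cfg, ann)
        assert (truth["violation"] == "length").all()
        assert all(c.length < 200 for c in cands)

    def test_density_multiplier_raises_bin_rate(self):
        cfg = small_config(
            chrom_length=2_000_000, n_genes=0, n_lncrna=2000,
            hot_cluster_spec=[("Chr1", 0, 1_000_000, 4.0)],
            lnc_class_weights={"intergenic": 1.0},
        )
        ann = sim.generate_annotation(cfg)
        cands, *_ = sim.generate_lncrna_candidates(cfg, ann)
        starts = np.array([c.start for c in cands])
        dense = (starts < 1_000_000).mean()
        assert dense == pytest.approx(0.8, abs=0.05)  # 4:1 placement odds


class TestCircGenerator:
    def test_truth_labels_consistent(self, config, annotation, circ_bundle):
        calls, truth, reads, libs, gene_fpkm = circ_bundle
        genuine = truth[truth["decoy"] == ""]
        by_key = {}
        for tool, rows in calls.items():
            for c in rows:
                by_key.setdefault(c.key, []).append(c)
        for r in genuine.itertuples():
            copies = by_key[(r.chrom, r.start, r.end, r.strand)]
            assert len({c.tool for c in copies}) >= 2
            assert all(c.junction_reads >= 2 for c in copies)
        for r in truth[truth["decoy"] == "one_tool"].itertuples():
            assert len(by_key[(r.chrom, r.start, r.end, r.strand)]) == 1
        for r in truth[truth["decoy"] == "low_reads"].itertuples():
            assert all(
                c.junction_reads == 1
                for c in by_key[(r.chrom, r.start, r.end, r.strand)]
            )
        for r in truth[truth["decoy"] == "long_span"].itertuples():
            assert r.end - r.start > 100_000
        for r in truth[truth["decoy"] == "long_intergenic"].itertuples():
            assert 10_000 < r.end - r.start <= 100_000

    def test_zero_true_circs_only_decoys(self):
        cfg = small_config(n_circ=0)
        ann = sim.generate_annotation(cfg)
        _, truth, *_ = sim.generate_circ_calls(cfg, ann)
        assert (truth["decoy"] != "").all()

    def test_deterministic_tables(self, config, annotation):
        a = sim.generate_circ_calls(config, annotation)
        b = sim.generate_circ_calls(config, annotation)
        assert a[0] == b[0]
        pd.testing.assert_frame_equal(a[1], b[1])


class TestMethylomeGenerator:
    def test_zero_error_rate_control_unmethylated(self):
        cfg = small_config(error_rate=0.0)
        ann = sim.generate_annotation(cfg)
        meth = sim.generate_methylome(cfg, ann)
        control = meth["A"][meth["A"]["chrom"] == "ChrC"]
        assert len(control) > 0 and (control["count_meth"] == 0).all()

    def test_planted_dmr_levels(self):
        cfg = small_config(
            dmr_spec=[("Chr1", 100_000, 140_000, "CG", 0.9, 0.1)],
            site_spacing={"CG": 100, "CHG": 5000, "CHH": 5000},
            tss_dip=(0.0, 1), n_genes=0,
        )
        ann = sim.generate_annotation(cfg)
        meth = sim.generate_methylome(cfg, ann)

        def region_level(df):
            sub = df[(df["chrom"] == "Chr1") & df["pos0"].between(100_000, 139_999)
                     & (df["context"] == "CG")]
            return sub["count_meth"].sum() / (
                sub["count_meth"] + sub["count_unmeth"]
            ).sum()

        assert region_level(meth["A"]) == pytest.approx(0.9, abs=0.02)
        assert region_level(meth["B"]) == pytest.approx(0.1, abs=0.02)
        # expected per-site difference 0.8 on average
        assert region_level(meth["A"]) - region_level(meth["B"]) == pytest.approx(
            0.8, abs=0.03
        )

    def test_zero_dip_depth_flat_near_tss(self):
        cfg = small_config(tss_dip=(0.0, 400))
        ann = sim.generate_annotation(cfg)
        meth = sim.generate_methylome(cfg, ann)
        cg = meth["A"][(meth["A"]["context"] == "CG") & (meth["A"]["chrom"] != "ChrC")]
        lvl = cg["count_meth"].sum() / (cg["count_meth"] + cg["count_unmeth"]).sum()
        assert lvl == pytest.approx(cfg.meth_base_levels["CG"], abs=0.01)


class TestPeaksGenerator:
    def test_zero_peak_fractions_all_no_peak(self):
        cfg = small_config(peak_fraction_interaction=0.0, peak_fraction_only=0.0)
        ann = sim.generate_annotation(cfg)
        peaks, pairs, truth = sim.generate_peaks_interactions(cfg, ann)
        assert (truth["rnapii_class"] == "no_peak").all()
        assert [p for p in peaks if p.mark == "RNAPII"] == [] and pairs == []

    def test_signal_median_split_matches_oracle(self):
        signals = [1.0, 2.0, 3.0, 4.0]
        peaks = [
            oz.Peak("Chr1", i * 100, i * 100 + 50, "RNAPII", s)
            for i, s in enumerate(signals)
        ]
        got = oz.intensity_partition(peaks)
        median = float(np.median(signals))
        assert got == ["strong" if s > median else "weak" for s in signals]


class TestCeRNAGenerator:
    def test_perfect_latent_pcc_gives_sample_pcc_one(self):
        cfg = small_config(triplet_spec=[("miR1", "m1", "lnc1", 1.0)])
        expr, *_ = sim.generate_cerna_inputs(cfg)
        r, _ = oz.pearson_with_p(expr.loc["lnc1"], expr.loc["m1"])
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_decoys_absent_from_truth(self, config):
        _, _, edges, _, truth = sim.generate_cerna_inputs(config)
        truth_ncs = set(truth["ncrna"])
        assert not any(nc.startswith(("dlnc", "clnc")) for nc in truth_ncs)

    def test_eighteen_samples_default(self, config):
        expr, *_ = sim.generate_cerna_inputs(config)
        assert expr.shape[1] == 18
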