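"""ceRNA triplet construction, DE and conservation filters, network export."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import oryzanc as oz
import oryzanc.simulate as sim
from oryzanc.cerna import CeRNATriplet, TargetEdge


class TestExpressionFilter:
    def test_boundaries_and_circ_exemption(self):
        expr = pd.DataFrame(
            {"s1": [0.4, 0.5, 0.01], "s2": [0.4, 0.5, 0.01]},
            index=["lncA", "lncB", "circC"],
        )
        kinds = {"lncA": "lncRNA", "lncB": "mRNA", "circC": "circRNA"}
        assert oz.expression_filter(kinds, expr) == ["lncB", "circC"]


class TestPearson:
    def test_affine_invariance(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        r, p = oz.pearson_with_p(x, 2 * x + 1)
        assert r == pytest.approx(1.0)

    def test_matches_direct_formula(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 2.0, 3.0, 100.0])
        r, p = oz.pearson_with_p(x, y)
        rb = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert r == pytest.approx(rb, abs=1e-12)
        t = rb * np.sqrt((len(x) - 2) / (1 - rb**2))
        assert p == pytest.approx(2 * stats.t.sf(abs(t), len(x) - 2), rel=1e-9)

    def test_zero_variance_is_no_pair(self):
        assert oz.pearson_with_p([1, 1, 1], [1, 2, 3]) is None

    def test_uncorrelated_p_near_one(self):
        x = np.array([1, -1] * 5, dtype=float)
        y = np.array([1.0, 1.0, -1.0, -1.0] * 2 + [1.0, -1.0])
        r, p = oz.pearson_with_p(x, y)
        assert abs(r) < 0.3 and p > 0.3

    def test_p_matches_exact_permutation_at_n6(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([2.0, 1.5, 3.5, 3.0, 5.5, 5.0])
        r_obs, p_t = oz.pearson_with_p(x, y)
        rs = [
            abs(stats.pearsonr(x, perm)[0])
            for perm in itertools.permutations(y)
        ]
        p_perm = np.mean([r >= abs(r_obs) - 1e-12 for r in rs])
        assert abs(p_t - p_perm) < 0.05


from _oracles import brute_force_triplets


class TestBuildTriplets:
    def test_matches_brute_force_on_generator(self, config):
        expr, kinds, edges, _, _ = sim.generate_cerna_inputs(config)
        got = {(t.mirna, t.ncrna, t.mrna) for t in oz.build_triplets(edges, expr)}
        assert got == brute_force_triplets(edges, expr)

    def test_strict_pcc_boundary(self):
        # engineered r = 0.8 (at the threshold) via orthogonal +/-1 designs
        z1 = np.array([1.0, 1.0, -1.0, -1.0] * 4)
        z2 = np.array([1.0, -1.0] * 8)
        assert z1 @ z2 == 0 and abs(z1.sum()) < 1e-12
        y_eq = 4 * z1 + 3 * z2
        r, p = oz.pearson_with_p(z1, y_eq)
        assert r == pytest.approx(0.8, abs=1e-12) and not r > 0.8
        expr = pd.DataFrame(
            {"nc": z1 + 2, "m_eq": y_eq + 8, "m_gt": 4.2 * z1 + 3 * z2 + 8}
        ).T
        expr.columns = [f"s{i}" for i in range(16)]
        edges = [
            TargetEdge("miR1", "nc", "lncRNA", "tf"),
            TargetEdge("miR1", "m_eq", "mRNA", "tf"),
            TargetEdge("miR1", "m_gt", "mRNA", "tf"),
        ]
        got = oz.build_triplets(edges, expr)
        assert [(t.mirna, t.ncrna, t.mrna) for t in got] == [("miR1", "nc", "m_gt")]

    def test_no_shared_mirna_pair_absent(self):
        rng = np.random.default_rng(0)
        z = rng.normal(size=10)
        expr = pd.DataFrame({"nc": z + 5, "m": z + 7}).T
        expr.columns = [f"s{i}" for i in range(10)]
        edges = [
            TargetEdge("miRa", "nc", "lncRNA", "tf"),
            TargetEdge("miRb", "m", "mRNA", "tf"),
        ]
        assert oz.build_triplets(edges, expr) == []

    def test_deterministic_order_and_dedup(self):
        z = np.arange(10.0)
        expr = pd.DataFrame({"nc": z, "m": z + 1}).T
        expr.columns = [f"s{i}" for i in range(10)]
        edges = [
            TargetEdge("miR1", "nc", "lncRNA", "tf"),
            TargetEdge("miR1", "nc", "lncRNA", "ps"),  # duplicate from 2nd predictor
            TargetEdge("miR1", "m", "mRNA", "tf"),
        ]
        got = oz.build_triplets(edges, expr)
        assert len(got) == 1
        assert got == oz.build_triplets(list(reversed(edges)), expr)


class TestDEFilter:
    def test_boundaries(self):
        table = pd.DataFrame(
            {
                "id": ["up", "flat_fc", "high_fdr", "down", "fc_eq2", "fc_eq_half",
                       "fdr_eq"],
                "fc": [3.0, 1.2, 3.0, 0.3, 2.0, 0.5, 3.0],
                "fdr": [0.01, 0.01, 0.2, 0.01, 0.01, 0.01, 0.05],
            }
        )
        out = oz.de_filter(table).set_index("id")["direction"]
        assert out.to_dict() == {
            "up": "Up", "flat_fc": "None", "high_fdr": "None", "down": "Down",
            "fc_eq2": "None", "fc_eq_half": "None", "fdr_eq": "None",
        }

    def test_idempotent_and_order_independent(self):
        rng = np.random.default_rng(1)
        table = pd.DataFrame(
            {"id": [f"f{i}" for i in range(50)],
             "fc": rng.lognormal(0, 1, 50), "fdr": rng.uniform(0, 1, 50)}
        )
        once = oz.de_filter(table)
        twice = oz.de_filter(once)
        assert once["direction"].tolist() == twice["direction"].tolist()
        shuffled = oz.de_filter(table.sample(frac=1, random_state=0)).sort_values("id")
        assert (
            shuffled["direction"].tolist()
            == once.sort_values("id")["direction"].tolist()
        )

    def test_bh_from_raw_pvalues(self):
        table = pd.DataFrame(
            {"id": ["a", "b"], "fc": [3.0, 3.0], "pvalue": [0.001, 0.9]}
        )
        out = oz.de_filter(table)
        assert out["fdr_from_bh"].all()
        ref = stats.false_discovery_control([0.001, 0.9])
        assert out["fdr"].tolist() == pytest.approx(list(ref))


class TestTissueNetwork:
    def trip(self, nc):
        return CeRNATriplet("miR1", nc, "gene1", 0.9, 0.001)

    def test_rules(self):
        de = pd.DataFrame(
            {"direction": ["Up", "Down", "None"]}, index=["gene1", "lncA", "lncB"]
        )
        kinds = {"lncA": "lncRNA", "lncB": "lncRNA", "circA": "circRNA"}
        trips = [self.trip("lncA"), self.trip("lncB"), self.trip("circA")]
        got = oz.tissue_network(trips, de, ncrna_kinds=kinds)
        assert [t.ncrna for t in got] == ["lncA", "circA"]
        # circRNA restricted to the tissue's expressed set
        got = oz.tissue_network(trips, de, ncrna_kinds=kinds, expressed_circs=set())
        assert [t.ncrna for t in got] == ["lncA"]

    def test_non_de_mrna_drops_triplet(self):
        de = pd.DataFrame({"direction": ["None"]}, index=["gene1"])
        assert oz.tissue_network([self.trip("circA")], de,
                                 ncrna_kinds={"circA": "circRNA"}) == []


class TestConservation:
    def hits(self, rows):
        return pd.DataFrame(
            rows, columns=["qseqid", "sseqid", "pident", "gapopen", "evalue"]
        )

    def test_tier_thresholds_both_sides(self):
        rows = [
            ("q80", "g", 80.0, 0, 1e-10),
            ("q79", "g", 79.9, 0, 1e-10),
            ("q50", "g", 50.0, 0, 1e-10),
            ("q49", "g", 49.9, 0, 1e-10),
            ("qev", "g", 99.0, 0, 1e-5),   # e-value not strictly below cutoff
        ]
        conserved, ratio = oz.conservation_filter(self.hits(rows), "oryza")
        assert conserved == {"q80"}
        assert ratio == pytest.approx(1 / 5)
        conserved, _ = oz.conservation_filter(self.hits(rows), "monocot_dicot")
        assert conserved == {"q80", "q79", "q50"}

    def test_junction_tier_gap_rule(self):
        rows = [
            ("ok", "g", 96.0, 1, 1e-10),
            ("gap2", "g", 96.0, 2, 1e-10),
            ("id94", "g", 94.9, 0, 1e-10),
            ("id95", "g", 95.0, 0, 1e-10),
        ]
        conserved, ratio = oz.conservation_filter(self.hits(rows), "junction")
        assert conserved == {"ok", "id95"}

    def test_unknown_tier(self):
        with pytest.raises(ValueError):
            oz.conservation_filter(self.hits([]), "mammals")


class TestExport:
    def test_single_triplet_structure_and_roundtrip(self, tmp_path):
        trips = [CeRNATriplet("miR1", "lncA", "geneB", 0.91, 0.002)]
        prefix = str(tmp_path / "net")
        oz.export_network(trips, prefix, {"lncA": "lncRNA"})
        nodes = pd.read_csv(prefix + ".nodes.tsv", sep="\t")
        edges = pd.read_csv(prefix + ".edges.tsv", sep="\t")
        assert len(nodes) == 3 and len(edges) == 3
        assert set(nodes["kind"]) == {"miRNA", "lncRNA", "mRNA"}
        assert oz.read_network(prefix) == trips

    def test_empty_network(self, tmp_path):
        prefix = str(tmp_path / "empty")
        oz.export_network([], prefix)
        assert oz.read_network(prefix) == []
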