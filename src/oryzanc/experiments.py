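"""Self-contained validation experiments on synthetic data.

Each experiment builds its inputs with :mod:`oryzanc.simulate` under planted,
known signal, runs the corresponding analysis stage, and scores the result
against the planted truth. They are the package's reproducibility harness:
`scripts/acceptance.py` reports their outputs, and the test suite asserts
the recovery properties they measure.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import simulate
from .intervals import IntervalIndex
from .lncrna import detect_hot_clusters
from .methylome import call_dmrs, estimate_error_rate, metagene_profile
from .cerna import build_triplets


def hot_cluster_experiment(
    seed: int, n_seeds: int = 20
) -> dict[str, float]:
    """Recovery of planted lncRNA hot clusters and the uniform null.

    Per seed, one genome carries a 600-kb region (6 consecutive 100-kb bins)
    with placement density x4; a matched genome has uniform placement. The
    cluster density and count are sized so each planted bin sits several
    standard deviations above the detection threshold.
    """
    recovered = 0
    false_on_planted = 0
    seeds_with_false_uniform = 0
    region = ("Chr1", 600_000, 1_200_000, 4.0)
    for i in range(n_seeds):
        cfg = simulate.SimConfig(
            seed=(seed * 1009 + i) % 2**31,
            n_chromosomes=2, chrom_length=2_000_000, n_genes=80,
            n_lncrna=3000, hot_cluster_spec=[region],
            fraction_short=0.0, fraction_low_expr=0.0,
            fraction_coding=0.0, fraction_pfam=0.0,
        )
        ann = simulate.generate_annotation(cfg)
        chrom_lengths = {c: cfg.chrom_length for c in cfg.chrom_names}
        cands, *_ = simulate.generate_lncrna_candidates(cfg, ann)
        clusters = detect_hot_clusters(cands, chrom_lengths)
        hit = [
            c for c in clusters
            if c.chrom == region[0] and c.start < region[2] and region[1] < c.end
        ]
        recovered += bool(hit)
        false_on_planted += len(clusters) - len(hit)

        uni = simulate.SimConfig(
            seed=(seed * 1009 + i) % 2**31,
            n_chromosomes=2, chrom_length=2_000_000, n_genes=80,
            n_lncrna=3000,
            fraction_short=0.0, fraction_low_expr=0.0,
            fraction_coding=0.0, fraction_pfam=0.0,
        )
        ucands, *_ = simulate.generate_lncrna_candidates(
            uni, simulate.generate_annotation(uni)
        )
        seeds_with_false_uniform += bool(detect_hot_clusters(ucands, chrom_lengths))
    return {
        "sensitivity": recovered / n_seeds,
        "extra_clusters_on_planted": false_on_planted,
        "uniform_seeds_with_false_cluster": seeds_with_false_uniform,
        "n_seeds": n_seeds,
    }


def dmr_null_experiment(seed: int, n_sites: int = 10_000) -> dict[str, float]:
    """Calibration under the null: both samples at common CG level 0.5, 20x."""
    cfg = simulate.SimConfig(
        seed=seed, n_chromosomes=1, chrom_length=n_sites * 30,
        n_genes=0, n_te=0, tss_dip=(0.0, 1),
        meth_base_levels={"CG": 0.5, "CHG": 0.5, "CHH": 0.5},
        site_spacing={"CG": 30, "CHG": 10**9, "CHH": 10**9},
    )
    ann = simulate.generate_annotation(cfg)
    meth = simulate.generate_methylome(cfg, ann)
    a = meth["A"][meth["A"]["chrom"] == "Chr1"]
    b = meth["B"][meth["B"]["chrom"] == "Chr1"]
    sites, regions = call_dmrs(a, b, "CG")
    return {
        "n_sites": int(len(sites)),
        "fp_rate_before_difference_filter": float((sites["p_value"] <= 0.05).mean()),
        "n_null_dmrs": int(sites["is_dmr"].sum()),
    }


def dmr_recovery_experiment(seed: int, n_planted: int = 200) -> dict[str, float]:
    """Sensitivity on planted 0.9-vs-0.1 CG DMR sites at 20x coverage."""
    region_end = n_planted * 30
    cfg = simulate.SimConfig(
        seed=seed, n_chromosomes=1, chrom_length=300_000,
        n_genes=0, n_te=0, tss_dip=(0.0, 1),
        dmr_spec=[("Chr1", 0, region_end, "CG", 0.9, 0.1)],
        site_spacing={"CG": 30, "CHG": 10**9, "CHH": 10**9},
    )
    ann = simulate.generate_annotation(cfg)
    meth = simulate.generate_methylome(cfg, ann)
    a = meth["A"][meth["A"]["chrom"] == "Chr1"]
    b = meth["B"][meth["B"]["chrom"] == "Chr1"]
    sites, _ = call_dmrs(a, b, "CG")
    planted = sites["pos0"] < region_end
    called = sites.loc[planted, "is_dmr"]
    return {
        "n_planted": n_planted,
        "sensitivity": float(called.sum() / n_planted),
    }


def tss_dip_experiment(
    seed: int, depth: float = 0.5, n_features: int = 5000
) -> dict[str, float]:
    """Recovery of a planted multiplicative TSS methylation dip.

    5000 genes at 20x CG coverage; the dip (depth ``depth``, half-width
    400 bp) is estimated as 1 - (level in the TSS-proximal flank bins) /
    (level in the gene-body interior), both read-count weighted.
    """
    per_chrom = n_features // 2
    cfg = simulate.SimConfig(
        seed=seed, n_chromosomes=2, chrom_length=per_chrom * 3500,
        n_genes=n_features, gene_length_range=(2000, 3000), n_te=0,
        tss_dip=(depth, 400),
        site_spacing={"CG": 30, "CHG": 10**9, "CHH": 10**9},
    )
    ann = simulate.generate_annotation(cfg)
    meth = simulate.generate_methylome(cfg, ann)
    genes = list(ann.genes.values())
    feats = pd.DataFrame(
        {
            "chrom": [g.chrom for g in genes],
            "start": [g.start for g in genes],
            "end": [g.end for g in genes],
            "strand": [g.strand for g in genes],
        },
        index=[g.id for g in genes],
    )
    prof = metagene_profile(meth["A"], feats, "CG")
    # flank bins 12..19 lie within 400 bp of the TSS (50-bp flank bins)
    dip_lvl = prof.meth[12:20].sum() / prof.total[12:20].sum()
    body = slice(prof.flank_bins + 15, prof.flank_bins + 45)
    baseline = prof.meth[body].sum() / prof.total[body].sum()
    return {
        "planted_depth": depth,
        "recovered_depth": float(1.0 - dip_lvl / baseline),
        "n_features": n_features,
    }


def flat_profile_experiment(seed: int) -> dict[str, float]:
    """Metagene profile under uniform 50% methylation: max per-bin |z|."""
    cfg = simulate.SimConfig(
        seed=seed, n_chromosomes=1, chrom_length=2_000_000, n_genes=200,
        n_te=0, tss_dip=(0.0, 1),
        meth_base_levels={"CG": 0.5, "CHG": 0.12, "CHH": 0.02},
        site_spacing={"CG": 30, "CHG": 10**9, "CHH": 10**9},
    )
    ann = simulate.generate_annotation(cfg)
    meth = simulate.generate_methylome(cfg, ann)
    genes = list(ann.genes.values())
    feats = pd.DataFrame(
        {
            "chrom": [g.chrom for g in genes],
            "start": [g.start for g in genes],
            "end": [g.end for g in genes],
            "strand": [g.strand for g in genes],
        },
        index=[g.id for g in genes],
    )
    prof = metagene_profile(meth["A"], feats, "CG")
    se = np.sqrt(0.25 / prof.total)
    z = np.abs(prof.values - 0.5) / se
    return {"max_abs_z": float(np.nanmax(z)), "n_bins": int(prof.n_bins)}


def error_rate_experiment(seed: int, rate: float = 0.003) -> dict[str, float]:
    """Recovery of the bisulfite non-conversion rate from the control contig."""
    cfg = simulate.SimConfig(
        seed=seed, n_chromosomes=1, chrom_length=400_000, n_genes=0, n_te=0,
        chloroplast_length=300_000, error_rate=rate, tss_dip=(0.0, 1),
        site_spacing={"CG": 30, "CHG": 10**9, "CHH": 10**9},
    )
    ann = simulate.generate_annotation(cfg)
    meth = simulate.generate_methylome(cfg, ann)
    est = estimate_error_rate(meth["A"], cfg.control_contig)
    sub = meth["A"][meth["A"]["chrom"] == cfg.control_contig]
    total = int((sub["count_meth"] + sub["count_unmeth"]).sum())
    return {
        "injected_rate": rate,
        "estimated_rate": float(est),
        "n_sites": int(len(sub)),
        "three_se": float(3 * np.sqrt(rate * (1 - rate) / total)),
    }


def triplet_experiment(seed: int, n_seeds: int = 20) -> dict[str, float]:
    """Planted-triplet recovery (latent PCC 0.95, 18 samples) over seeds."""
    tp = fp = fn = 0
    for i in range(n_seeds):
        cfg = simulate.SimConfig(seed=(seed * 2003 + i) % 2**31)
        expr, kinds, edges, _, truth = simulate.generate_cerna_inputs(cfg)
        found = {(t.mirna, t.ncrna, t.mrna) for t in build_triplets(edges, expr)}
        want = {(r.mirna, r.ncrna, r.mrna) for r in truth.itertuples()}
        tp += len(found & want)
        fp += len(found - want)
        fn += len(want - found)
    return {
        "sensitivity": tp / (tp + fn),
        "false_discovery_proportion": fp / max(tp + fp, 1),
        "n_planted": tp + fn,
        "n_seeds": n_seeds,
    }


def classification_truth_experiment(seed: int) -> dict[str, float]:
    """Agreement of positional classifiers with the generator's planted truth."""
    from .lncrna import classify_lncrna
    from .circrna import CircJunction, classify_circ

    cfg = simulate.SimConfig(seed=seed)
    ann = simulate.generate_annotation(cfg)
    idx = IntervalIndex((g.chrom, g.start, g.end, g) for g in ann.genes.values())

    cands, *_, truth = simulate.generate_lncrna_candidates(cfg, ann)
    labelled = truth[truth["class"] != "unplaced"]
    ok = sum(
        classify_lncrna(t, ann, index=idx) == row["class"]
        for t, (_, row) in zip(cands, truth.iterrows())
        if row["class"] != "unplaced"
    )
    lnc_acc = ok / len(labelled)

    calls, ctruth, *_ = simulate.generate_circ_calls(cfg, ann)
    ok = 0
    for _, r in ctruth.iterrows():
        j = CircJunction(r["chrom"], int(r["start"]), int(r["end"]), r["strand"], "x", 5)
        cls, parent = classify_circ(j, ann, index=idx)
        ok += cls == r["class"] and parent == r["parent_gene"]
    return {
        "lncrna_class_accuracy": float(lnc_acc),
        "n_lncrna": int(len(labelled)),
        "circ_class_accuracy": float(ok / len(ctruth)),
        "n_circ": int(len(ctruth)),
    }
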