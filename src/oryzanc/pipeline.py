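"""End-to-end driver: simulate inputs, run every stage, write all outputs.

Each stage reads only files (or the in-memory objects the previous stage
produced), writes its results as plain-text tables under the output
directory, and logs record counts in/out for every filter so the synthetic
run has the same waterfall shape as a real one. Re-running with the same
config reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import pandas as pd

from . import cerna, circrna, epimarks, io, lncrna, methylome, simulate

log = logging.getLogger("oryzanc")


def run_pipeline(
    config: simulate.SimConfig,
    outdir: str | Path,
    *,
    stages: set[str] | None = None,
) -> dict:
    """Run simulate -> lncrna -> circrna -> methylome -> epimarks -> cerna.

    Returns a manifest dict (also written as ``manifest.json``) with the
    seed, parameters and headline counts of every stage. ``stages``
    restricts execution (the simulate stage always runs, as every other
    stage consumes its outputs).
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    all_stages = {"lncrna", "circrna", "methylome", "epimarks", "cerna"}
    stages = all_stages if stages is None else set(stages)
    unknown = stages - all_stages
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    manifest: dict = {
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "stages": {},
    }

    # --- simulate ---------------------------------------------------------
    ann = simulate.generate_annotation(config)
    io.write_gff3(ann, out / "annotation.gff3")
    io.write_te_bed(ann.tes, out / "te.bed")
    log.info("simulate: %d genes, %d TEs", len(ann.genes), len(ann.tes))

    cands, expr, scores, pfam, lnc_truth = simulate.generate_lncrna_candidates(config, ann)
    io.write_matrix(expr, out / "lncrna_expression.tsv")
    io.write_table(scores, out / "coding_scores.tsv")
    io.write_table(pfam, out / "pfam_hits.tsv")
    io.write_table(lnc_truth, out / "truth_lncrna.tsv")

    calls, circ_truth, circ_reads, lib_sizes, parent_fpkm = simulate.generate_circ_calls(config, ann)
    for tool, rows in calls.items():
        io.write_table(
            pd.DataFrame(
                [
                    (c.chrom, c.start, c.end, c.strand, c.tool, c.junction_reads)
                    for c in rows
                ],
                columns=["chrom", "start", "end", "strand", "tool", "junction_reads"],
            ),
            out / f"circ_calls_{tool}.tsv",
        )
    io.write_table(circ_truth, out / "truth_circ.tsv")

    meth = simulate.generate_methylome(config, ann)
    for sample, df in meth.items():
        io.write_cytosine_report(df, out / f"cytosine_report_{sample}.tsv")

    peaks, pairs, peak_truth = simulate.generate_peaks_interactions(config, ann)
    io.write_bed6(
        [(p.chrom, p.start, p.end, p.mark, p.signal, ".") for p in peaks],
        out / "peaks.bed",
    )
    io.write_bedpe(
        pd.DataFrame(
            [
                (p.chrom1, p.start1, p.end1, p.chrom2, p.start2, p.end2, f"pair{i}", p.score)
                for i, p in enumerate(pairs)
            ],
            columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2", "name", "score"],
        ),
        out / "anchors.bedpe",
    )

    cexpr, kinds, edges, de_table, trip_truth = simulate.generate_cerna_inputs(config)
    io.write_matrix(cexpr, out / "cerna_expression.tsv")
    io.write_table(
        pd.DataFrame(
            [(e.mirna, e.target, e.target_kind, e.source) for e in edges],
            columns=["mirna", "target", "target_kind", "source"],
        ),
        out / "mirna_targets.tsv",
    )
    io.write_table(de_table, out / "de_table.tsv")
    io.write_table(trip_truth, out / "truth_triplets.tsv")

    # --- lncrna -----------------------------------------------------------
    results: dict = {}
    if "lncrna" in stages:
        kept, rejected = lncrna.filter_lncrna_candidates(cands)
        log.info("lncrna filter: %d in, %d kept", len(cands), len(kept))
        gene_idx = None
        from .intervals import IntervalIndex

        gene_idx = IntervalIndex(
            (g.chrom, g.start, g.end, g) for g in ann.genes.values()
        )
        rows = []
        for t in kept:
            cls = lncrna.classify_lncrna(t, ann, index=gene_idx)
            ng, dist = lncrna.nearest_gene(t, ann)
            rows.append(
                (t.chrom, t.start, t.end, f"{t.id}|{cls}", t.mean_fpkm, t.strand,
                 cls, ng, dist, lncrna.expression_tier(t.mean_fpkm))
            )
        lnc_df = pd.DataFrame(
            rows,
            columns=["chrom", "start", "end", "name", "score", "strand",
                     "class", "nearest_gene", "nearest_distance", "tier"],
        )
        io.write_table(lnc_df, out / "lncrna_classified.tsv")
        clusters = lncrna.detect_hot_clusters(
            kept, {c: ann.chromosomes[c] for c in ann.nuclear_chromosomes}
        )
        io.write_table(
            pd.DataFrame(
                [(c.chrom, c.start, c.end, c.n_lncrna) for c in clusters],
                columns=["chrom", "start", "end", "n_lncrna"],
            ),
            out / "lncrna_hot_clusters.tsv",
        )
        sharing = lncrna.tissue_sharing(
            expr.loc[[t.id for t in kept]], config.tissue_columns
        )
        io.write_table(
            sharing.rename_axis("id").reset_index(), out / "lncrna_tissue_sharing.tsv"
        )
        results["lncrna"] = {
            "n_candidates": len(cands),
            "n_lncrna": len(kept),
            "n_rejected": len(rejected),
            "n_hot_clusters": len(clusters),
            "sharing": sharing.value_counts().to_dict(),
        }

    # --- circrna ----------------------------------------------------------
    if "circrna" in stages:
        filtered = {t: circrna.qc_filter(c) for t, c in calls.items()}
        merged = circrna.merge_high_confidence(filtered, {"ciri2", "circexplorer2"})
        log.info("circ merge: %d high-confidence junctions", len(merged))
        from .intervals import IntervalIndex

        gidx = IntervalIndex((g.chrom, g.start, g.end, g) for g in ann.genes.values())
        recs = []
        for j in merged:
            cls, parent = circrna.classify_circ(j, ann, index=gidx)
            recs.append(circrna.CircRNARecord(j, cls, parent))
        recs = circrna.drop_long_intergenic(recs)
        _, as_fraction = circrna.alternative_splicing_summary(recs)
        io.write_table(
            pd.DataFrame(
                [
                    (r.junction.chrom, r.junction.start, r.junction.end,
                     r.junction.strand, r.circ_class, r.parent_gene or "")
                    for r in recs
                ],
                columns=["chrom", "start", "end", "strand", "class", "parent_gene"],
            ),
            out / "circ_classified.tsv",
        )
        results["circrna"] = {
            "n_high_confidence": len(merged),
            "n_after_intergenic_filter": len(recs),
            "by_class": pd.Series([r.circ_class for r in recs]).value_counts().to_dict(),
            "alt_splicing_fraction": as_fraction,
        }

    # --- methylome --------------------------------------------------------
    if "methylome" in stages:
        err = methylome.estimate_error_rate(meth["A"], ann.control_contig)
        genes_df = pd.DataFrame(
            {
                "chrom": [g.chrom for g in ann.genes.values()],
                "start": [g.start for g in ann.genes.values()],
                "end": [g.end for g in ann.genes.values()],
                "strand": [g.strand for g in ann.genes.values()],
            },
            index=list(ann.genes),
        )
        profs = {}
        for ctx in methylome.CONTEXTS:
            prof = methylome.metagene_profile(meth["A"], genes_df, ctx)
            profs[ctx] = prof
        io.write_table(
            pd.DataFrame({ctx: p.values for ctx, p in profs.items()}).rename_axis("bin").reset_index(),
            out / "metagene_profiles.tsv",
        )
        dmr_results = {}
        all_regions = []
        for ctx in methylome.CONTEXTS:
            sites, regions = methylome.call_dmrs(
                meth["A"], meth["B"], ctx, error_rate=max(err, 1e-4)
            )
            dmr_results[ctx] = {"n_sites_tested": len(sites), "n_regions": len(regions)}
            all_regions += regions
        io.write_table(
            pd.DataFrame(
                [
                    (d.chrom, d.start, d.end, d.context, d.level_a, d.level_b,
                     d.p_value, d.direction, d.n_sites)
                    for d in all_regions
                ],
                columns=["chrom", "start", "end", "context", "level_a", "level_b",
                         "p_value", "direction", "n_sites"],
            ),
            out / "dmrs.tsv",
        )
        results["methylome"] = {"error_rate": err, "dmrs": dmr_results}

    # --- epimarks ---------------------------------------------------------
    if "epimarks" in stages:
        gene_feats = sorted(ann.genes.values(), key=lambda g: g.id)
        rnapii = [p for p in peaks if p.mark == "RNAPII"]
        classes = epimarks.rnapii_classify(gene_feats, rnapii, pairs)
        intensity = epimarks.intensity_partition(rnapii)
        te_flags = epimarks.te_associate_lncrna(cands, ann.tes)
        comp = epimarks.te_composition(
            [c for c, f in zip(cands, te_flags) if f], ann.tes
        )
        io.write_table(comp.rename_axis("superfamily").reset_index(), out / "te_composition.tsv")
        io.write_table(
            pd.DataFrame(
                {"gene": [g.id for g in gene_feats], "rnapii_class": classes}
            ),
            out / "rnapii_classes.tsv",
        )
        results["epimarks"] = {
            "rnapii_classes": pd.Series(classes).value_counts().to_dict(),
            "n_strong_peaks": intensity.count("strong"),
            "n_te_associated_lncrna": int(sum(te_flags)),
        }

    # --- cerna ------------------------------------------------------------
    if "cerna" in stages:
        triplets = cerna.build_triplets(edges, cexpr)
        de_calls = cerna.de_filter(de_table).set_index("id")
        tissue_net = cerna.tissue_network(triplets, de_calls, ncrna_kinds=kinds)
        cerna.export_network(triplets, str(out / "cerna_network"), kinds)
        results["cerna"] = {
            "n_triplets": len(triplets),
            "n_tissue_triplets": len(tissue_net),
        }

    manifest["stages"] = results
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
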