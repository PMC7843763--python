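"""Readers and writers for the standard formats the pipeline consumes.

Dialects: GFF3 is 1-based inclusive, BED/BEDPE 0-based half-open, cytosine
reports 1-based. Every reader converts to the internal 0-based half-open
convention exactly once (`pos0` column for per-base records); writers convert
back.
"""

from __future__ import annotations

import os
from typing import Iterable

import gffutils
import pandas as pd

from .annotation import Gene, GenomeAnnotation, TEAnnotation

BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]

CYTOSINE_COLUMNS = ["chrom", "pos", "strand", "count_meth", "count_unmeth", "context"]


# ---------------------------------------------------------------------------
# GFF3 gene annotation

def write_gff3(ann: GenomeAnnotation, path: str | os.PathLike) -> None:
    """Write genes/exons as GFF3; chromosome lengths as ##sequence-region."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, length in ann.chromosomes.items():
            fh.write(f"##sequence-region {chrom} 1 {length}\n")
        if ann.control_contig is not None:
            fh.write(f"#!control-contig {ann.control_contig}\n")
        for gid in sorted(ann.genes):
            g = ann.genes[gid]
            attrs = f"ID={g.id}"
            if g.is_te_gene:
                attrs += ";te_gene=true"
            fh.write(
                f"{g.chrom}\tsim\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chrom}\tsim\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.id}.exon{i};Parent={g.id}\n"
                )


def read_gff3(path: str | os.PathLike) -> GenomeAnnotation:
    """Parse a GFF3 gene annotation back into :class:`GenomeAnnotation`.

    TEs travel separately as BED6 (:func:`read_te_bed`).
    """
    chromosomes: dict[str, int] = {}
    control = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("##sequence-region"):
                _, chrom, _start, end = line.split()
                chromosomes[chrom] = int(end)
            elif line.startswith("#!control-contig"):
                control = line.split()[1]
            elif not line.startswith("#"):
                break
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: dict[str, Gene] = {}
    for f in db.features_of_type("gene"):
        exons = sorted(
            (c.start - 1, c.end) for c in db.children(f, featuretype="exon")
        )
        genes[f.id] = Gene(
            id=f.id,
            chrom=f.seqid,
            start=f.start - 1,
            end=f.end,
            strand=f.strand,
            exons=tuple(exons) if exons else ((f.start - 1, f.end),),
            is_te_gene=f.attributes.get("te_gene", ["false"])[0] == "true",
        )
    if not chromosomes:
        # fall back to feature extents when pragmas are absent
        for g in genes.values():
            chromosomes[g.chrom] = max(chromosomes.get(g.chrom, 0), g.end)
    return GenomeAnnotation(
        chromosomes=chromosomes, genes=genes, control_contig=control
    )


# ---------------------------------------------------------------------------
# BED / BEDPE

def write_bed6(
    records: Iterable[tuple[str, int, int, str, float, str]], path: str | os.PathLike
) -> None:
    """Write (chrom, start, end, name, score, strand) rows as BED6."""
    df = pd.DataFrame(records, columns=["chrom", "start", "end", "name", "score", "strand"])
    df.to_csv(path, sep="\t", header=False, index=False)


def read_bed6(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "name": str},
    )
    if (df["end"] <= df["start"]).any():
        bad = (df["end"] <= df["start"]).idxmax()
        raise ValueError(f"{path}: empty interval at line {bad + 1}")
    return df


def write_te_bed(tes: Iterable[TEAnnotation], path: str | os.PathLike) -> None:
    write_bed6(
        [(t.chrom, t.start, t.end, t.superfamily, 0.0, t.strand) for t in tes], path
    )


def read_te_bed(path: str | os.PathLike) -> list[TEAnnotation]:
    df = read_bed6(path)
    return [
        TEAnnotation(r.chrom, int(r.start), int(r.end), r.strand, r.name)
        for r in df.itertuples()
    ]


def write_bedpe(df: pd.DataFrame, path: str | os.PathLike) -> None:
    cols = ["chrom1", "start1", "end1", "chrom2", "start2", "end2", "name", "score"]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bedpe(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom1", "start1", "end1", "chrom2", "start2", "end2", "name", "score"],
        dtype={"chrom1": str, "chrom2": str, "name": str},
    )


# ---------------------------------------------------------------------------
# Cytosine reports (bisulfite)

def write_cytosine_report(df: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write the internal (0-based ``pos0``) frame as a 1-based report."""
    out = df.copy()
    out["pos"] = out.pop("pos0") + 1
    out[CYTOSINE_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_cytosine_report(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, names=CYTOSINE_COLUMNS, dtype={"chrom": str}
    )
    bad = ~df["context"].isin(["CG", "CHG", "CHH"])
    if bad.any():
        raise ValueError(f"{path}: invalid context at line {int(bad.idxmax()) + 1}")
    df["pos0"] = df.pop("pos") - 1
    return df[["chrom", "pos0", "strand", "count_meth", "count_unmeth", "context"]]


# ---------------------------------------------------------------------------
# Matrices and tables

def write_matrix(df: pd.DataFrame, path: str | os.PathLike) -> None:
    """Feature-by-sample matrix, TSV, first column = feature id."""
    df.to_csv(path, sep="\t", index=True, index_label="id")


def read_matrix(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_blast_tabular(path: str | os.PathLike) -> pd.DataFrame:
    """BLAST outfmt-6 hits with the canonical 12 columns."""
    return pd.read_csv(path, sep="\t", header=None, names=BLAST6_COLUMNS)
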