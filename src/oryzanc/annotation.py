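"""Genome annotation containers: genes with exon/intron structure, TEs, chromosomes.

All coordinates are 0-based half-open internally. Conversion to the 1-based
inclusive GFF3 dialect happens only at the I/O boundary (:mod:`oryzanc.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

Interval = tuple[int, int]


@dataclass(frozen=True)
class Gene:
    """A protein-coding gene model.

    ``exons`` are disjoint, sorted, and contained in ``[start, end)``.
    Introns are the complement of the exons within the gene span.
    """

    id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[Interval, ...]
    is_te_gene: bool = False

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"gene {self.id}: end <= start")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.id}: bad strand {self.strand!r}")
        prev = self.start
        for s, e in self.exons:
            if s < prev or e <= s or e > self.end:
                raise ValueError(f"gene {self.id}: malformed exon ({s},{e})")
            prev = e

    @property
    def tss(self) -> int:
        """Transcription start site (strand-aware 5' position)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def introns(self) -> tuple[Interval, ...]:
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if e1 < s2:
                out.append((e1, s2))
        return tuple(out)


@dataclass(frozen=True)
class TEAnnotation:
    """A transposable-element interval with its superfamily label."""

    chrom: str
    start: int
    end: int
    strand: str
    superfamily: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("TE: end <= start")


@dataclass
class GenomeAnnotation:
    """The coordinate universe every classification rule runs against.

    Parameters
    ----------
    chromosomes
        Mapping chromosome name -> length in bp.
    genes
        Mapping gene id -> :class:`Gene`.
    tes
        Transposable-element intervals.
    control_contig
        Name of the unmethylated control contig (the chloroplast in plants),
        used to estimate the bisulfite non-conversion error rate. ``None``
        if absent.
    """

    chromosomes: dict[str, int]
    genes: dict[str, Gene] = field(default_factory=dict)
    tes: list[TEAnnotation] = field(default_factory=list)
    control_contig: str | None = None

    def __post_init__(self) -> None:
        for g in self.genes.values():
            L = self.chromosomes.get(g.chrom)
            if L is None:
                raise ValueError(f"gene {g.id} on unknown chromosome {g.chrom}")
            if g.start < 0 or g.end > L:
                raise ValueError(f"gene {g.id} outside chromosome bounds")
        for te in self.tes:
            L = self.chromosomes.get(te.chrom)
            if L is None or te.start < 0 or te.end > L:
                raise ValueError("TE outside chromosome bounds")
        if self.control_contig is not None and self.control_contig not in self.chromosomes:
            raise ValueError(f"unknown control contig {self.control_contig}")

    def genes_on(self, chrom: str) -> Iterator[Gene]:
        return (g for g in self.genes.values() if g.chrom == chrom)

    @property
    def nuclear_chromosomes(self) -> list[str]:
        return [c for c in self.chromosomes if c != self.control_contig]
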