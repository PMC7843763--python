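"""circRNA back-splice junction QC, tool merging, classification and profiling.

A circRNA is represented by the genomic span between its two back-splice
junction positions. Calls from several detection tools are merged into a
high-confidence set (a junction must be reported by every required tool at
identical coordinates), filtered for junction-read support (>= 2 reads) and
span (<= 100 kb), classified as exonic / intronic / intergenic against the
gene annotation, and long (> 10 kb) intergenic spans are discarded.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .annotation import GenomeAnnotation
from .intervals import IntervalIndex

MIN_JUNCTION_READS = 2
MAX_SPAN = 100_000
MAX_INTERGENIC_LEN = 10_000


@dataclass(frozen=True)
class CircJunction:
    """One back-splice call: the half-open genomic span between junctions."""

    chrom: str
    start: int
    end: int
    strand: str
    tool: str
    junction_reads: int
    sample: str = ""
    # caller-specific QC evidence; assumed satisfied when a tool does not
    # report it (e.g. breakpoint ambiguity / anchor uniqueness flags)
    breakpoint_unambiguous: bool = True
    unique_anchors: bool = True

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("junction span end <= start")
        if self.junction_reads < 0:
            raise ValueError("negative junction reads")

    @property
    def span(self) -> int:
        return self.end - self.start

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.start, self.end, self.strand)


@dataclass(frozen=True)
class CircRNARecord:
    junction: CircJunction
    circ_class: str
    parent_gene: str | None
    rpm: float = 0.0

    def __post_init__(self) -> None:
        if (self.parent_gene is None) != (self.circ_class == "intergenic"):
            raise ValueError("parent gene present iff not intergenic")


def qc_filter(
    calls: Iterable[CircJunction],
    *,
    min_reads: int = MIN_JUNCTION_READS,
    max_span: int = MAX_SPAN,
) -> list[CircJunction]:
    """Keep calls with >= ``min_reads`` junction reads and span <= ``max_span``.

    Caller-specific boolean QC evidence (unambiguous breakpoint, unique
    anchor alignments) is honoured when the call carries it.
    """
    return [
        c for c in calls
        if c.junction_reads >= min_reads and c.span <= max_span
        and c.breakpoint_unambiguous and c.unique_anchors
    ]


def merge_high_confidence(
    calls_by_tool: Mapping[str, Iterable[CircJunction]],
    required_tools: set[str],
    *,
    tolerance: int = 0,
) -> list[CircJunction]:
    """Intersect per-tool call sets on (chrom, start, end, strand) identity.

    A junction is high-confidence iff every tool in ``required_tools``
    reports it; the merged record carries the maximum junction-read count
    across tools (the same fragments may underlie each tool's count, so
    counts are not summed). Matching is base-exact by default;
    ``tolerance`` allows both junction positions to differ by up to that
    many bp between tools, in which case the coordinates of the
    deepest-covered call are kept.
    """
    missing = required_tools - set(calls_by_tool)
    if missing:
        raise ValueError(f"required tools without call tables: {sorted(missing)}")
    per_tool: dict[str, list[CircJunction]] = {
        t: list(calls_by_tool[t]) for t in required_tools
    }

    def matches(a: CircJunction, b: CircJunction) -> bool:
        return (
            a.chrom == b.chrom
            and a.strand == b.strand
            and abs(a.start - b.start) <= tolerance
            and abs(a.end - b.end) <= tolerance
        )

    out: list[CircJunction] = []
    tools = sorted(required_tools)
    base = tools[0]
    seen: set[tuple] = set()
    for c in per_tool[base]:
        group = [c]
        for other in tools[1:]:
            hit = next((o for o in per_tool[other] if matches(c, o)), None)
            if hit is None:
                group = None
                break
            group.append(hit)
        if group is None:
            continue
        best = max(group, key=lambda x: x.junction_reads)
        if best.key not in seen:
            seen.add(best.key)
            out.append(replace(best, tool="merged"))
    return sorted(out, key=lambda c: c.key)


def classify_circ(
    j: CircJunction,
    ann: GenomeAnnotation,
    *,
    index: IntervalIndex | None = None,
) -> tuple[str, str | None]:
    """Classify one junction span against the gene models.

    exonic: both back-splice ends fall inside exons of one same-strand gene;
    intronic: the whole span lies within a single intron of a same-strand
    gene; otherwise intergenic (including partial or antisense gene
    overlap). Returns ``(circ_class, parent_gene_or_None)``.
    """
    idx = index if index is not None else IntervalIndex(
        (g.chrom, g.start, g.end, g) for g in ann.genes.values()
    )
    left, right = j.start, j.end - 1  # the two junction base positions
    for g in sorted(idx.query(j.chrom, j.start, j.end), key=lambda g: g.id):
        if g.strand != j.strand:
            continue
        left_in = any(s <= left < e for s, e in g.exons)
        right_in = any(s <= right < e for s, e in g.exons)
        if left_in and right_in:
            return "exonic", g.id
    for g in sorted(idx.query(j.chrom, j.start, j.end), key=lambda g: g.id):
        if g.strand != j.strand:
            continue
        if any(s <= j.start and j.end <= e for s, e in g.introns):
            return "intronic", g.id
    return "intergenic", None


def drop_long_intergenic(
    circs: Iterable[CircRNARecord], max_len: int = MAX_INTERGENIC_LEN
) -> list[CircRNARecord]:
    """Remove intergenic circRNAs whose span strictly exceeds ``max_len``."""
    return [
        c for c in circs
        if not (c.circ_class == "intergenic" and c.junction.span > max_len)
    ]


def rpm(junction_reads: float, total_mapped_reads: float) -> float:
    """Reads-per-million normalization of junction read counts."""
    if total_mapped_reads <= 0:
        raise ValueError("total mapped reads must be positive")
    return junction_reads / total_mapped_reads * 1e6


def parental_correlation(
    circ_rpm: Sequence[float], gene_fpkm: Sequence[float]
) -> tuple[float, float, bool]:
    """Pearson correlation between a circRNA and its parental gene.

    Returns ``(r, two_sided_p, significant_positive)`` where the flag is
    ``p < 0.05 and r > 0``. The p-value comes from the t transform with
    n - 2 degrees of freedom.
    """
    x = np.asarray(circ_rpm, dtype=float)
    y = np.asarray(gene_fpkm, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), bool(p < 0.05 and r > 0)


def alternative_splicing_summary(
    circs: Iterable[CircRNARecord],
) -> tuple[Counter, float]:
    """Per-parent circRNA counts and the fraction of parents with > 1 circRNA."""
    counts = Counter(
        c.parent_gene for c in circs if c.parent_gene is not None
    )
    if not counts:
        return counts, 0.0
    multi = sum(1 for v in counts.values() if v > 1)
    return counts, multi / len(counts)


def circ_position_profile(
    circs: Iterable[CircRNARecord],
    ann: GenomeAnnotation,
    n_bins: int = 100,
) -> np.ndarray:
    """Positional density of circRNAs along their (length-normalized) parents.

    Each parental gene body maps to [0, 1) measured from the TSS (minus-strand
    genes are flipped); every bin overlapped by the circRNA's relative span
    gains one count. The summed histogram is divided by the number of
    profiled circRNAs.
    """
    hist = np.zeros(n_bins)
    n = 0
    for c in circs:
        if c.parent_gene is None:
            raise ValueError(f"circRNA at {c.junction.key} has no parent gene")
        g = ann.genes[c.parent_gene]
        L = g.end - g.start
        lo = max(0.0, (c.junction.start - g.start) / L)
        hi = min(1.0, (c.junction.end - g.start) / L)
        if g.strand == "-":
            lo, hi = 1.0 - hi, 1.0 - lo
        b0 = int(np.floor(lo * n_bins))
        b1 = int(np.ceil(hi * n_bins))
        hist[b0: max(b1, b0 + 1)] += 1
        n += 1
    return hist / n if n else hist
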