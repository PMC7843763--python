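"""lncRNA identification and positional characterization.

Candidates that survive the length / expression / coding-potential filters
are placed into one of the five standard positional classes relative to
protein-coding (PC) genes — sense, intronic, antisense, bidirectional,
intergenic — and genome-wide 100-kb binning detects lncRNA "hot clusters":
runs of bins whose lncRNA count exceeds twice the genome-wide bin average,
spanning more than 500 kb in total.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import Gene, GenomeAnnotation
from .intervals import IntervalIndex

LNC_CLASSES = ("sense", "intronic", "antisense", "bidirectional", "intergenic")

# Filter defaults, printed thresholds of the standard pipeline
MIN_LENGTH = 200
MIN_MEAN_FPKM = 0.1
MAX_CODING_PROB = 0.5
PFAM_EVALUE_CUTOFF = 1e-5


@dataclass(frozen=True)
class TranscriptRecord:
    """A transcript candidate with its expression and coding-potential evidence.

    ``pfam_best_evalue`` is the best (smallest) e-value of any protein-domain
    hit, or ``None`` when the transcript hit no domain at all.
    """

    id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...] = ()
    mean_fpkm: float = 0.0
    coding_probability: float = 0.0
    pfam_best_evalue: float | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"{self.id}: end <= start")
        if self.mean_fpkm < 0:
            raise ValueError(f"{self.id}: negative FPKM")
        if not 0.0 <= self.coding_probability <= 1.0:
            raise ValueError(f"{self.id}: coding probability outside [0,1]")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class LncRNARecord:
    transcript: TranscriptRecord
    lnc_class: str
    nearest_gene: str | None
    nearest_distance: int


@dataclass(frozen=True)
class HotCluster:
    chrom: str
    start: int
    end: int
    n_lncrna: int
    bin_counts: tuple[int, ...]


def filter_lncrna_candidates(
    candidates: Iterable[TranscriptRecord],
    known_coding_ids: set[str] | frozenset[str] = frozenset(),
    *,
    min_length: int = MIN_LENGTH,
    min_mean_fpkm: float = MIN_MEAN_FPKM,
    max_coding_prob: float = MAX_CODING_PROB,
    pfam_evalue_cutoff: float = PFAM_EVALUE_CUTOFF,
) -> tuple[list[TranscriptRecord], dict[str, str]]:
    """Apply the lncRNA identification filters.

    A candidate is retained when its length is >= ``min_length`` bp, its mean
    FPKM is >= ``min_mean_fpkm``, it is not a known protein-coding
    transcript, it has no confident protein-domain hit (best e-value absent
    or > ``pfam_evalue_cutoff``), and its coding probability is
    < ``max_coding_prob``.

    Returns ``(kept, rejected)`` where ``rejected`` maps each discarded id to
    the first failing rule (``length`` / ``fpkm`` / ``known_coding`` /
    ``pfam`` / ``coding_probability``).
    """
    kept: list[TranscriptRecord] = []
    rejected: dict[str, str] = {}
    for t in candidates:
        if t.length < min_length:
            rejected[t.id] = "length"
        elif t.mean_fpkm < min_mean_fpkm:
            rejected[t.id] = "fpkm"
        elif t.id in known_coding_ids:
            rejected[t.id] = "known_coding"
        elif t.pfam_best_evalue is not None and t.pfam_best_evalue <= pfam_evalue_cutoff:
            rejected[t.id] = "pfam"
        elif t.coding_probability >= max_coding_prob:
            rejected[t.id] = "coding_probability"
        else:
            kept.append(t)
    return kept, rejected


def _gene_index(ann: GenomeAnnotation) -> IntervalIndex:
    return IntervalIndex(
        (g.chrom, g.start, g.end, g) for g in ann.genes.values()
    )


def classify_lncrna(
    t: TranscriptRecord,
    ann: GenomeAnnotation,
    *,
    bidirectional_window: int = 1000,
    index: IntervalIndex | None = None,
) -> str:
    """Assign one of the five positional classes by fixed precedence.

    sense: >=1 bp same-strand exonic overlap with a PC gene;
    intronic: fully contained in a single intron of a same-strand gene;
    antisense: any opposite-strand overlap;
    bidirectional: no overlap, TSS within ``bidirectional_window`` bp of a PC
    TSS in divergent (head-to-head) orientation;
    otherwise intergenic.
    """
    if t.chrom not in ann.chromosomes:
        raise ValueError(f"unknown chromosome {t.chrom}")
    idx = index if index is not None else _gene_index(ann)
    overlapping: list[Gene] = idx.query(t.chrom, t.start, t.end)

    same = [g for g in overlapping if g.strand == t.strand]
    for g in same:
        if any(s < t.end and t.start < e for s, e in g.exons):
            return "sense"
    for g in same:
        if any(s <= t.start and t.end <= e for s, e in g.introns):
            return "intronic"
    if any(g.strand != t.strand for g in overlapping):
        return "antisense"
    if not overlapping and _is_bidirectional(t, ann, idx, bidirectional_window):
        return "bidirectional"
    return "intergenic"


def _is_bidirectional(
    t: TranscriptRecord, ann: GenomeAnnotation, idx: IntervalIndex, window: int
) -> bool:
    lo = max(0, t.tss - window)
    hi = t.tss + window + 1
    for g in idx.query(t.chrom, lo, hi):
        if g.strand == t.strand:
            continue
        if abs(g.tss - t.tss) > window:
            continue
        # divergent: the two 5' ends point away from each other
        if t.strand == "-" and g.strand == "+" and t.tss <= g.tss:
            return True
        if t.strand == "+" and g.strand == "-" and t.tss >= g.tss:
            return True
    return False


def nearest_gene(
    t: TranscriptRecord, ann: GenomeAnnotation
) -> tuple[str, int]:
    """Gene minimizing edge-to-edge distance; signed, negative = gene on the left.

    Returns ``(gene_id, signed_distance)``; distance 0 iff overlapping.
    Ties are broken by the lexicographically smaller gene id.
    """
    best: tuple[int, str, int] | None = None  # (abs distance, gene id, signed)
    for g in ann.genes.values():
        if g.chrom != t.chrom:
            continue
        if g.end <= t.start:
            d = t.start - g.end
            signed = -d
        elif t.end <= g.start:
            d = g.start - t.end
            signed = d
        else:
            d = 0
            signed = 0
        cand = (d, g.id, signed)
        if best is None or cand[:2] < best[:2]:
            best = cand
    if best is None:
        raise ValueError(f"no genes on chromosome {t.chrom}")
    return best[1], best[2]


def detect_hot_clusters(
    lncrnas: Iterable[TranscriptRecord | LncRNARecord],
    chrom_lengths: Mapping[str, int],
    bin_size: int = 100_000,
    *,
    min_span: int = 500_000,
    fold: float = 2.0,
) -> list[HotCluster]:
    """Detect lncRNA hot clusters by genome-wide 100-kb binning.

    Each lncRNA is assigned to the bin containing its 5' start. Bins whose
    count strictly exceeds ``fold`` x the genome-wide mean bin count are
    merged when consecutive; merged runs with total span strictly greater
    than ``min_span`` are reported. Output order and content are independent
    of input ordering.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    counts = {
        c: np.zeros(int(np.ceil(L / bin_size)), dtype=int)
        for c, L in chrom_lengths.items()
    }
    for r in lncrnas:
        t = r.transcript if isinstance(r, LncRNARecord) else r
        if t.chrom not in counts:
            raise ValueError(f"unknown chromosome {t.chrom}")
        counts[t.chrom][t.tss // bin_size] += 1

    total_bins = sum(len(v) for v in counts.values())
    if total_bins == 0:
        return []
    mean = sum(int(v.sum()) for v in counts.values()) / total_bins
    threshold = fold * mean

    clusters: list[HotCluster] = []
    for chrom in sorted(counts):
        v = counts[chrom]
        hot = v > threshold
        i = 0
        while i < len(v):
            if hot[i]:
                j = i
                while j + 1 < len(v) and hot[j + 1]:
                    j += 1
                start = i * bin_size
                end = min((j + 1) * bin_size, chrom_lengths[chrom])
                if end - start > min_span:
                    clusters.append(
                        HotCluster(
                            chrom=chrom,
                            start=start,
                            end=end,
                            n_lncrna=int(v[i : j + 1].sum()),
                            bin_counts=tuple(int(x) for x in v[i : j + 1]),
                        )
                    )
                i = j + 1
            else:
                i += 1
    return clusters


def expression_tier(fpkm: float) -> str:
    """Three expression tiers: low (<0.5), middle ([0.5, 2]), high (>2)."""
    if fpkm < 0.5:
        return "low"
    if fpkm > 2:
        return "high"
    return "middle"


def tissue_sharing(
    expr: pd.DataFrame,
    tissues: Mapping[str, Sequence[str]],
    expressed_threshold: float = 0.1,
) -> pd.Series:
    """Partition features by the number of tissues expressing them.

    A feature counts as expressed in a tissue when its mean FPKM across that
    tissue's replicate columns is >= ``expressed_threshold``. Categories:
    ``shared`` (all tissues), ``specific`` (exactly one), ``intermediate``
    (more than one but not all), ``none``.
    """
    n_tissues = len(tissues)
    expressed = pd.DataFrame(
        {t: expr[list(cols)].mean(axis=1) >= expressed_threshold for t, cols in tissues.items()}
    )
    n = expressed.sum(axis=1)
    out = pd.Series("intermediate", index=expr.index, name="sharing")
    out[n == 0] = "none"
    out[n == 1] = "specific"
    out[n == n_tissues] = "shared"
    return out
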