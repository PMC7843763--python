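"""TE association, histone/RNAPII peak overlap and interaction stratification.

TE-associated lncRNAs contain a TE site within their boundaries without
being fully contained inside any single TE; TE-associated circRNAs are
those whose parental gene is annotated as a TE-gene. Histone/RNAPII marking
uses the 1-bp overlap rule; RNAPII-bound features split into
peak-with-interaction / peak-only / no-peak classes depending on whether
the bound peak itself touches a chromatin-interaction anchor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import TEAnnotation
from .circrna import CircRNARecord
from .intervals import IntervalIndex

RNAPII_CLASSES = ("peak_with_interaction", "peak_only", "no_peak")


@dataclass(frozen=True)
class Peak:
    chrom: str
    start: int
    end: int
    mark: str
    signal: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("peak end <= start")
        if self.signal < 0:
            raise ValueError("negative peak signal")


@dataclass(frozen=True)
class AnchorPair:
    chrom1: str
    start1: int
    end1: int
    chrom2: str
    start2: int
    end2: int
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.end1 <= self.start1 or self.end2 <= self.start2:
            raise ValueError("anchor end <= start")

    @property
    def anchors(self) -> tuple[tuple[str, int, int], tuple[str, int, int]]:
        return (
            (self.chrom1, self.start1, self.end1),
            (self.chrom2, self.start2, self.end2),
        )


def _feature_tuple(f) -> tuple[str, int, int]:
    """Accept (chrom, start, end[, ...]) tuples or objects with those attrs."""
    if isinstance(f, tuple):
        return f[0], f[1], f[2]
    return f.chrom, f.start, f.end


def te_associate_lncrna(
    features: Sequence, tes: Iterable[TEAnnotation]
) -> list[bool]:
    """TE-associated iff >= 1 bp TE overlap AND not fully inside any single TE."""
    idx = IntervalIndex((t.chrom, t.start, t.end, t) for t in tes)
    flags = []
    for f in features:
        chrom, start, end = _feature_tuple(f)
        hits = idx.query(chrom, start, end)
        contained = any(t.start <= start and end <= t.end for t in hits)
        flags.append(bool(hits) and not contained)
    return flags


def te_associate_circ(
    circs: Sequence[CircRNARecord], te_gene_ids: set[str]
) -> list[bool]:
    """TE-associated iff the parental gene is an annotated TE-gene."""
    return [
        c.parent_gene is not None and c.parent_gene in te_gene_ids for c in circs
    ]


def te_composition(
    features: Sequence, tes: Iterable[TEAnnotation]
) -> pd.DataFrame:
    """Per-superfamily share of TE-associated features, by count and by bp.

    A feature overlapping TEs of two superfamilies counts once in each;
    length is the total overlapped bp per superfamily. Shares are fractions
    of the column totals (length shares sum to 1 when any overlap exists).
    """
    idx = IntervalIndex((t.chrom, t.start, t.end, t) for t in tes)
    count: dict[str, int] = {}
    length: dict[str, int] = {}
    for f in features:
        chrom, start, end = _feature_tuple(f)
        seen: set[str] = set()
        for t in idx.query(chrom, start, end):
            ov = min(end, t.end) - max(start, t.start)
            length[t.superfamily] = length.get(t.superfamily, 0) + ov
            seen.add(t.superfamily)
        for sf in seen:
            count[sf] = count.get(sf, 0) + 1
    if not length:
        return pd.DataFrame(
            columns=["count", "length", "count_share", "length_share"]
        )
    df = pd.DataFrame(
        {"count": pd.Series(count), "length": pd.Series(length)}
    ).fillna(0).astype({"count": int, "length": int}).sort_index()
    df["count_share"] = df["count"] / df["count"].sum()
    df["length_share"] = df["length"] / df["length"].sum()
    return df


def mark_overlap(
    features: Sequence, peaks: Iterable[Peak], mark: str
) -> list[bool]:
    """Marked iff >= 1 bp overlap with any peak of ``mark`` (flag, not count)."""
    idx = IntervalIndex(
        (p.chrom, p.start, p.end, p) for p in peaks if p.mark == mark
    )
    out = []
    for f in features:
        chrom, start, end = _feature_tuple(f)
        out.append(bool(idx.query(chrom, start, end)))
    return out


def rnapii_classify(
    features: Sequence,
    rnapii_peaks: Sequence[Peak],
    anchor_pairs: Iterable[AnchorPair],
    *,
    direct_anchor_overlap: bool = False,
) -> list[str]:
    """Three-way RNAPII stratification per feature.

    ``peak_with_interaction``: the feature overlaps an RNAPII peak that
    itself overlaps (>= 1 bp) an anchor of some interaction pair;
    ``peak_only``: overlaps a peak but no anchored one; else ``no_peak``.
    With ``direct_anchor_overlap`` the feature counts as interacting when it
    touches an anchor directly, bypassing the peak mediation.
    """
    anchor_idx = IntervalIndex(
        (c, s, e, pair)
        for pair in anchor_pairs
        for (c, s, e) in pair.anchors
    )
    anchored = {
        id(p): bool(anchor_idx.query(p.chrom, p.start, p.end))
        for p in rnapii_peaks
    }
    peak_idx = IntervalIndex(
        (p.chrom, p.start, p.end, p) for p in rnapii_peaks
    )
    out = []
    for f in features:
        chrom, start, end = _feature_tuple(f)
        hits = peak_idx.query(chrom, start, end)
        if not hits:
            out.append("no_peak")
        elif any(anchored[id(p)] for p in hits) or (
            direct_anchor_overlap and anchor_idx.query(chrom, start, end)
        ):
            out.append("peak_with_interaction")
        else:
            out.append("peak_only")
    return out


def intensity_partition(
    peaks: Sequence[Peak], *, quantile: float = 0.5
) -> list[str]:
    """Split peaks into weak/strong at the signal quantile (default median).

    Signals strictly above the split point are strong; ties at the split
    (including the all-equal and single-peak cases) are weak, so the
    partition is deterministic.
    """
    if not peaks:
        return []
    signals = np.array([p.signal for p in peaks], dtype=float)
    cut = float(np.quantile(signals, quantile))
    return ["strong" if s > cut else "weak" for s in signals]


def expression_by_group(
    expression: Mapping[str, Sequence[float]],
    groups: tuple[str, str] | None = None,
) -> tuple[pd.DataFrame, float]:
    """Per-group summaries plus a two-sided Wilcoxon rank-sum comparison.

    ``expression`` maps group name -> expression values. ``groups`` names
    the two groups to compare (defaults to the only two present). Uses the
    exact rank-sum distribution for small groups without ties.
    """
    for name, vals in expression.items():
        if len(vals) == 0:
            raise ValueError(f"empty group {name!r}")
    summary = pd.DataFrame(
        {
            name: {
                "n": len(vals),
                "median": float(np.median(vals)),
                "q1": float(np.percentile(vals, 25)),
                "q3": float(np.percentile(vals, 75)),
            }
            for name, vals in expression.items()
        }
    ).T
    if groups is None:
        if len(expression) != 2:
            raise ValueError("specify which two groups to compare")
        groups = tuple(expression)  # type: ignore[assignment]
    a, b = expression[groups[0]], expression[groups[1]]
    method = "exact" if min(len(a), len(b)) <= 8 else "auto"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return summary, float(res.pvalue)
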