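"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as a direct transcription of the rules —
exhaustive scans and exact rational arithmetic — deliberately sharing no
code with the package under test.
"""

from fractions import Fraction
from math import comb


def classify_lncrna_oracle(t, genes, window=1000):
    """Per-gene scan of the five-class precedence rules."""
    ov = [
        g for g in genes
        if g.chrom == t.chrom and g.start < t.end and t.start < g.end
    ]
    for g in ov:
        if g.strand == t.strand and any(
            max(s, t.start) < min(e, t.end) for s, e in g.exons
        ):
            return "sense"
    for g in ov:
        if g.strand != t.strand:
            continue
        for (s1, e1), (s2, e2) in zip(g.exons, g.exons[1:]):
            if e1 <= t.start and t.end <= s2:
                return "intronic"
    if any(g.strand != t.strand for g in ov):
        return "antisense"
    if not ov:
        tss = t.start if t.strand == "+" else t.end - 1
        for g in genes:
            if g.chrom != t.chrom or g.strand == t.strand:
                continue
            gtss = g.start if g.strand == "+" else g.end - 1
            if abs(gtss - tss) > window:
                continue
            if t.strand == "-" and g.strand == "+" and tss <= gtss:
                return "bidirectional"
            if t.strand == "+" and g.strand == "-" and tss >= gtss:
                return "bidirectional"
    return "intergenic"


def classify_circ_oracle(j, genes):
    """Exhaustive exon/intron containment scan for one junction span."""
    left, right = j.start, j.end - 1
    for g in sorted(genes, key=lambda g: g.id):
        if g.chrom != j.chrom or g.strand != j.strand:
            continue
        if any(s <= left < e for s, e in g.exons) and any(
            s <= right < e for s, e in g.exons
        ):
            return "exonic", g.id
    for g in sorted(genes, key=lambda g: g.id):
        if g.chrom != j.chrom or g.strand != j.strand:
            continue
        for (s1, e1), (s2, e2) in zip(g.exons, g.exons[1:]):
            if e1 <= j.start and j.end <= s2:
                return "intronic", g.id
    return "intergenic", None


def te_associate_oracle(feature, tes):
    """Double loop over (feature, TE) pairs."""
    chrom, start, end = feature.chrom, feature.start, feature.end
    overlaps = [
        t for t in tes
        if t.chrom == chrom and t.start < end and start < t.end
    ]
    if not overlaps:
        return False
    return not any(t.start <= start and end <= t.end for t in overlaps)


def mark_overlap_oracle(feature, peaks, mark):
    chrom, start, end = feature.chrom, feature.start, feature.end
    return any(
        p.mark == mark and p.chrom == chrom and p.start < end and start < p.end
        for p in peaks
    )


def interval_query_oracle(records, chrom, start, end):
    """Brute-force half-open overlap scan; returns the payload multiset."""
    return sorted(
        payload
        for c, s, e, payload in records
        if c == chrom and s < end and start < e
    )


def brute_force_triplets(edges, expr, min_fpkm=0.5):
    """Triple loop over all (miRNA, ncRNA, mRNA) combinations."""
    import numpy as np
    from scipy import stats

    mirnas = {e.mirna for e in edges}
    ncs = {e.target for e in edges if e.target_kind in ("lncRNA", "circRNA")}
    mrnas = {e.target for e in edges if e.target_kind == "mRNA"}
    kinds = {e.target: e.target_kind for e in edges}
    pairs = {(e.mirna, e.target) for e in edges}
    out = set()
    for m in mirnas:
        for nc in ncs:
            for g in mrnas:
                if (m, nc) not in pairs or (m, g) not in pairs:
                    continue
                if nc not in expr.index or g not in expr.index:
                    continue
                if any(
                    kinds[fid] != "circRNA" and expr.loc[fid].mean() < min_fpkm
                    for fid in (nc, g)
                ):
                    continue
                x, y = expr.loc[nc].to_numpy(), expr.loc[g].to_numpy()
                if np.ptp(x) == 0 or np.ptp(y) == 0:
                    continue
                r, p = stats.pearsonr(x, y)
                if r > 0.8 and p < 0.05:
                    out.add((m, nc, g))
    return out


def binom_two_sided_oracle(k, n, p0):
    """Exact two-sided binomial p by enumeration in rational arithmetic."""
    p = Fraction(p0)
    q = 1 - p
    pmf = [comb(n, i) * p**i * q ** (n - i) for i in range(n + 1)]
    target = pmf[k]
    return float(min(Fraction(1), sum(x for x in pmf if x <= target)))
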