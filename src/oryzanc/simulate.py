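"""Synthetic-data generator for every input the pipeline consumes.

Emulates an annotation-level view of a rice-like genome: multi-exon
protein-coding genes packed on a few chromosomes plus an unmethylated
chloroplast control contig; TEs drawn from superfamily weights; lncRNA
candidates planted in known positional classes (with controlled fractions
violating each identification filter and optional hot-cluster regions of
elevated placement density); per-tool circRNA back-splice calls with known
decoy classes; per-cytosine bisulfite reports with planted DMRs and a TSS
methylation dip; histone/RNAPII peaks with interaction anchor pairs; and
ceRNA expression/target tables with planted triplets of controlled latent
Pearson correlation.

Every generated record carries a ground-truth label so each downstream
stage can be scored without re-reading generator internals. One RNG stream
per output family is derived from the master seed by a stable label, so
regenerating one file never perturbs another. Identical configs produce
byte-identical outputs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import Gene, GenomeAnnotation, TEAnnotation
from .circrna import CircJunction
from .epimarks import AnchorPair, Peak
from .cerna import TargetEdge
from .lncrna import TranscriptRecord

TOOLS = ("ciri2", "circexplorer2", "findcirc")
CONTEXTS = ("CG", "CHG", "CHH")

# genome-wide TE superfamily proportions, echoing the reported composition
DEFAULT_TE_WEIGHTS = {
    "LTR/Gypsy": 0.46,
    "MITE": 0.22,
    "LTR/Copia": 0.12,
    "DNA/MULE-MuDR": 0.13,
    "RC/Helitron": 0.07,
}

# positional class mix, echoing the reported class frequencies
DEFAULT_CLASS_WEIGHTS = {
    "intergenic": 0.50,
    "antisense": 0.17,
    "sense": 0.15,
    "intronic": 0.09,
    "bidirectional": 0.09,
}

DEFAULT_CIRC_CLASS_WEIGHTS = {"exonic": 0.78, "intronic": 0.06, "intergenic": 0.16}

DEFAULT_METH_LEVELS = {"CG": 0.35, "CHG": 0.12, "CHH": 0.02}
DEFAULT_SITE_SPACING = {"CG": 30, "CHG": 45, "CHH": 15}

TISSUES = ("panicle", "root", "leaf")
VARIETIES = ("MH63", "ZS97", "SY63")


@dataclass
class SimConfig:
    """Knobs of the synthetic study; defaults are the standing conditions."""

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 2_000_000
    chloroplast_length: int = 120_000
    n_genes: int = 160
    gene_length_range: tuple[int, int] = (1_000, 5_000)
    n_te: int = 300
    te_length_range: tuple[int, int] = (100, 3_000)
    te_superfamily_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TE_WEIGHTS)
    )
    fraction_te_genes: float = 0.10
    n_lncrna: int = 400
    lnc_class_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_WEIGHTS)
    )
    lnc_length_range: tuple[int, int] = (300, 2_000)
    hot_cluster_spec: list[tuple[str, int, int, float]] = field(default_factory=list)
    fraction_short: float = 0.05
    fraction_low_expr: float = 0.05
    fraction_coding: float = 0.05
    fraction_pfam: float = 0.05
    # P(expressed in all / exactly one / exactly two tissues)
    tissue_sharing_weights: tuple[float, float, float] = (0.45, 0.30, 0.25)
    n_circ: int = 120
    circ_class_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CIRC_CLASS_WEIGHTS)
    )
    n_circ_decoys_per_class: int = 10
    n_samples: int = 18
    coverage: float = 20.0
    error_rate: float = 0.003
    meth_base_levels: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_METH_LEVELS)
    )
    site_spacing: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SITE_SPACING)
    )
    dmr_spec: list[tuple[str, int, int, str, float, float]] = field(default_factory=list)
    tss_dip: tuple[float, int] = (0.6, 400)
    peak_fraction_interaction: float = 0.25
    peak_fraction_only: float = 0.25
    n_triplets: int = 20
    triplet_pcc: float = 0.95
    triplet_spec: list[tuple[str, str, str, float]] | None = None
    n_decoy_shared_mirna: int = 20
    n_decoy_correlated: int = 10
    n_background_features: int = 60

    def __post_init__(self) -> None:
        for name, p in [
            ("fraction_te_genes", self.fraction_te_genes),
            ("fraction_short", self.fraction_short),
            ("fraction_low_expr", self.fraction_low_expr),
            ("fraction_coding", self.fraction_coding),
            ("fraction_pfam", self.fraction_pfam),
            ("error_rate", self.error_rate),
            ("tss_dip depth", self.tss_dip[0]),
            ("peak_fraction_interaction", self.peak_fraction_interaction),
            ("peak_fraction_only", self.peak_fraction_only),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} outside [0,1]")
        if abs(sum(self.tissue_sharing_weights) - 1.0) > 1e-9 or any(
            w < 0 for w in self.tissue_sharing_weights
        ):
            raise ValueError("tissue_sharing_weights must be nonnegative and sum to 1")
        for weights, label in [
            (self.te_superfamily_weights, "te_superfamily_weights"),
            (self.lnc_class_weights, "lnc_class_weights"),
            (self.circ_class_weights, "circ_class_weights"),
        ]:
            if abs(sum(weights.values()) - 1.0) > 1e-9:
                raise ValueError(f"{label} must sum to 1")
            if any(w < 0 for w in weights.values()):
                raise ValueError(f"{label} must be nonnegative")
        for chrom, start, end, mult in self.hot_cluster_spec:
            if chrom not in self.chrom_names or not (
                0 <= start < end <= self.chrom_length
            ):
                raise ValueError(f"hot cluster region outside bounds: {chrom}:{start}-{end}")
            if mult < 0:
                raise ValueError("density multiplier must be nonnegative")
        for chrom, start, end, ctx, la, lb in self.dmr_spec:
            if ctx not in CONTEXTS:
                raise ValueError(f"bad DMR context {ctx}")
            if not (0 <= la <= 1 and 0 <= lb <= 1):
                raise ValueError("DMR levels outside [0,1]")
            if chrom not in self.chrom_names or not (0 <= start < end <= self.chrom_length):
                raise ValueError(f"DMR region outside bounds: {chrom}:{start}-{end}")

    @property
    def chrom_names(self) -> list[str]:
        return [f"Chr{i + 1}" for i in range(self.n_chromosomes)]

    @property
    def control_contig(self) -> str:
        return "ChrC"

    @property
    def sample_names(self) -> list[str]:
        names = []
        i = 0
        while len(names) < self.n_samples:
            var = VARIETIES[(i // (2 * len(TISSUES))) % len(VARIETIES)]
            tis = TISSUES[(i // 2) % len(TISSUES)]
            names.append(f"{var}_{tis}_rep{i % 2 + 1}")
            i += 1
        return names

    @property
    def tissue_columns(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {t: [] for t in TISSUES}
        for s in self.sample_names:
            out[s.split("_")[1]].append(s)
        return {t: cols for t, cols in out.items() if cols}

    def rng(self, label: str) -> np.random.Generator:
        """Independent, label-stable stream derived from the master seed."""
        return np.random.default_rng(
            [self.seed & 0x7FFFFFFF, zlib.crc32(label.encode())]
        )


# ---------------------------------------------------------------------------
# Annotation

def _gene_exons(rng: np.random.Generator, start: int, length: int) -> tuple:
    """Alternating exon/intron segments covering [start, start+length)."""
    n_ex = int(rng.integers(2, 6))
    k = 2 * n_ex - 1
    min_seg = 40
    if length < k * min_seg:
        n_ex, k = 2, 3
    w = rng.dirichlet(np.ones(k))
    lens = np.maximum(min_seg, (w * (length - min_seg * k)).astype(int) + min_seg)
    lens[-1] += length - int(lens.sum())
    edges = start + np.concatenate([[0], np.cumsum(lens)])
    return tuple((int(edges[i]), int(edges[i + 1])) for i in range(0, k, 2))


def generate_annotation(config: SimConfig) -> GenomeAnnotation:
    """Non-overlapping multi-exon gene models, TEs, and the control contig.

    Genes are packed one per equal-width slot so spacing is bounded below;
    raises when the requested count cannot fit.
    """
    rng = config.rng("annotation")
    chroms = {c: config.chrom_length for c in config.chrom_names}
    chroms[config.control_contig] = config.chloroplast_length

    genes: dict[str, Gene] = {}
    per_chrom = np.full(config.n_chromosomes, config.n_genes // config.n_chromosomes)
    per_chrom[: config.n_genes % config.n_chromosomes] += 1
    margin = 200
    gmin, gmax = config.gene_length_range
    gid = 0
    for chrom, n in zip(config.chrom_names, per_chrom):
        if n == 0:
            continue
        slot = config.chrom_length // int(n)
        if slot < gmax + 2 * margin:
            raise ValueError(
                f"cannot pack {n} genes of up to {gmax} bp into {chrom} "
                f"({config.chrom_length} bp)"
            )
        for i in range(int(n)):
            length = int(rng.integers(gmin, gmax + 1))
            lo = i * slot + margin
            hi = (i + 1) * slot - margin - length
            start = int(rng.integers(lo, hi + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            name = f"gene{gid:04d}"
            genes[name] = Gene(
                id=name,
                chrom=chrom,
                start=start,
                end=start + length,
                strand=strand,
                exons=_gene_exons(rng, start, length),
                is_te_gene=bool(rng.random() < config.fraction_te_genes),
            )
            gid += 1

    tes: list[TEAnnotation] = []
    sf_names = list(config.te_superfamily_weights)
    sf_p = np.array([config.te_superfamily_weights[s] for s in sf_names])
    tmin, tmax = config.te_length_range
    for _ in range(config.n_te):
        chrom = config.chrom_names[int(rng.integers(config.n_chromosomes))]
        length = int(rng.integers(tmin, tmax + 1))
        start = int(rng.integers(0, config.chrom_length - length))
        strand = "+" if rng.random() < 0.5 else "-"
        sf = sf_names[int(rng.choice(len(sf_names), p=sf_p))]
        tes.append(TEAnnotation(chrom, start, start + length, strand, sf))

    return GenomeAnnotation(
        chromosomes=chroms, genes=genes, tes=tes,
        control_contig=config.control_contig,
    )


# ---------------------------------------------------------------------------
# lncRNA candidates

def _bin_weights(config: SimConfig, bin_size: int = 100_000) -> dict[str, np.ndarray]:
    out = {}
    for chrom in config.chrom_names:
        nbins = int(np.ceil(config.chrom_length / bin_size))
        w = np.ones(nbins)
        for c, start, end, mult in config.hot_cluster_spec:
            if c == chrom:
                w[start // bin_size: int(np.ceil(end / bin_size))] = mult
        out[chrom] = w
    return out


def _place_candidate(
    rng: np.random.Generator,
    cls: str,
    chrom: str,
    bin_lo: int,
    bin_hi: int,
    length: int,
    genes_sorted: list[Gene],
    chrom_len: int,
) -> tuple[int, int, str] | None:
    """Coordinates realizing positional class ``cls`` near the chosen bin.

    Returns (start, end, strand) or None when the class cannot be realized
    there (the caller falls back to intergenic placement).
    """
    in_bin = [g for g in genes_sorted if g.start < bin_hi and g.end > bin_lo]

    def gene_free(start: int, end: int, pad: int = 0) -> bool:
        return not any(g.start - pad < end and start < g.end + pad for g in genes_sorted)

    if cls == "sense" and in_bin:
        g = in_bin[int(rng.integers(len(in_bin)))]
        exon = g.exons[int(rng.integers(len(g.exons)))]
        anchor = int(rng.integers(exon[0], exon[1]))
        start = min(max(0, anchor - length // 2), chrom_len - length)
        return start, start + length, g.strand
    if cls == "intronic":
        cands = [
            (g, iv) for g in in_bin for iv in g.introns if iv[1] - iv[0] > length + 2
        ]
        if cands:
            g, (s, e) = cands[int(rng.integers(len(cands)))]
            start = int(rng.integers(s + 1, e - length))
            return start, start + length, g.strand
        return None
    if cls == "antisense" and in_bin:
        g = in_bin[int(rng.integers(len(in_bin)))]
        anchor = int(rng.integers(g.start, g.end))
        start = min(max(0, anchor - length // 2), chrom_len - length)
        return start, start + length, "-" if g.strand == "+" else "+"
    if cls == "bidirectional" and in_bin:
        for g in in_bin:
            if g.strand == "+":
                end = int(g.start - rng.integers(10, 400))
                start = end - length
                if start >= 0 and gene_free(start, end):
                    return start, end, "-"
            else:
                start = int(g.end + rng.integers(10, 400))
                end = start + length
                if end <= chrom_len and gene_free(start, end):
                    return start, end, "+"
        return None
    if cls == "intergenic":
        for _ in range(60):
            start = int(rng.integers(bin_lo, max(bin_lo + 1, bin_hi - length)))
            if gene_free(start, start + length, pad=1100):
                return start, start + length, "+" if rng.random() < 0.5 else "-"
        return None
    return None


def generate_lncrna_candidates(
    config: SimConfig, ann: GenomeAnnotation
) -> tuple[list[TranscriptRecord], pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """lncRNA candidates with planted classes, filter violations and clusters.

    Returns ``(candidates, expression, coding_scores, pfam_hits, truth)``.
    Candidate placement samples a 100-kb bin with probability proportional
    to the hot-cluster density multipliers, then realizes the sampled
    positional class near that bin, so the per-bin placement rate follows
    background x multiplier. The truth table records the planted class,
    hot-cluster membership, and which filter (if any) each candidate was
    built to violate.
    """
    rng = config.rng("lncrna")
    weights = _bin_weights(config)
    bin_size = 100_000
    chrom_p = np.array([weights[c].sum() for c in config.chrom_names], dtype=float)
    chrom_p /= chrom_p.sum()
    genes_by_chrom = {
        c: sorted(
            (g for g in ann.genes.values() if g.chrom == c), key=lambda g: g.start
        )
        for c in config.chrom_names
    }

    n = config.n_lncrna
    # disjoint violation assignment
    order = rng.permutation(n)
    viol = np.array([""] * n, dtype=object)
    k = 0
    for frac, label in [
        (config.fraction_short, "length"),
        (config.fraction_low_expr, "fpkm"),
        (config.fraction_coding, "coding_probability"),
        (config.fraction_pfam, "pfam"),
    ]:
        m = int(round(frac * n))
        viol[order[k: k + m]] = label
        k += m

    classes = list(config.lnc_class_weights)
    class_p = np.array([config.lnc_class_weights[c] for c in classes])
    lmin, lmax = config.lnc_length_range

    records: list[TranscriptRecord] = []
    truth_rows = []
    for i in range(n):
        chrom = config.chrom_names[int(rng.choice(config.n_chromosomes, p=chrom_p))]
        w = weights[chrom]
        b = int(rng.choice(len(w), p=w / w.sum()))
        bin_lo, bin_hi = b * bin_size, min((b + 1) * bin_size, config.chrom_length)
        target_cls = classes[int(rng.choice(len(classes), p=class_p))]
        length = int(rng.integers(lmin, lmax + 1))
        if viol[i] == "length":
            length = int(rng.integers(60, 200))
        placed = _place_candidate(
            rng, target_cls, chrom, bin_lo, bin_hi, length,
            genes_by_chrom[chrom], config.chrom_length,
        )
        cls = target_cls
        if placed is None:
            cls = "intergenic"
            placed = _place_candidate(
                rng, "intergenic", chrom, bin_lo, bin_hi, length,
                genes_by_chrom[chrom], config.chrom_length,
            )
        if placed is None:  # crowded bin: place anywhere, class unknown -> skip truth class
            start = int(rng.integers(bin_lo, max(bin_lo + 1, bin_hi - length)))
            placed = (start, start + length, "+")
            cls = "unplaced"
        start, end, strand = placed
        coding_p = (
            float(rng.uniform(0.5, 1.0))
            if viol[i] == "coding_probability"
            else float(rng.uniform(0.0, 0.45))
        )
        pfam = (
            float(10.0 ** rng.uniform(-10, -5.2))
            if viol[i] == "pfam"
            else (float(10.0 ** rng.uniform(-4.5, 0)) if rng.random() < 0.2 else None)
        )
        records.append(
            TranscriptRecord(
                id=f"lnc{i:04d}",
                chrom=chrom,
                start=start,
                end=end,
                strand=strand,
                exons=((start, end),),
                coding_probability=coding_p,
                pfam_best_evalue=pfam,
            )
        )
        in_hot = any(
            c == chrom and s <= start < e and mult > 1
            for c, s, e, mult in config.hot_cluster_spec
        )
        truth_rows.append(
            {
                "id": f"lnc{i:04d}", "chrom": chrom, "start": start, "end": end,
                "strand": strand, "class": cls, "in_hot_cluster": in_hot,
                "violation": viol[i],
            }
        )

    samples = config.sample_names
    expr = np.empty((n, len(samples)))
    w_all, w_one, w_two = config.tissue_sharing_weights
    tissue_mean = {}
    for i in range(n):
        u = rng.random()
        if u < w_all:
            on = set(TISSUES)
        elif u < w_all + w_one:
            on = {TISSUES[int(rng.integers(len(TISSUES)))]}
        else:
            on = set(rng.choice(TISSUES, size=2, replace=False))
        for t in TISSUES:
            base = float(rng.lognormal(0.3, 1.0))
            tissue_mean[(i, t)] = base if t in on else base * 0.002
    for j, s in enumerate(samples):
        tis = s.split("_")[1]
        for i in range(n):
            expr[i, j] = tissue_mean[(i, tis)] * float(rng.lognormal(0.0, 0.3))
    for i in range(n):
        if viol[i] == "fpkm":
            expr[i] *= 0.05 / max(expr[i].mean(), 1e-12)
    expr_df = pd.DataFrame(expr, index=[r.id for r in records], columns=samples)
    records = [
        replace(r, mean_fpkm=float(expr_df.loc[r.id].mean())) for r in records
    ]
    scores = pd.DataFrame(
        {"id": [r.id for r in records],
         "coding_probability": [r.coding_probability for r in records]}
    )
    pfam = pd.DataFrame(
        {"id": [r.id for r in records],
         "pfam_best_evalue": [r.pfam_best_evalue for r in records]}
    )
    return records, expr_df, scores, pfam, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# circRNA calls

def _intergenic_span(
    rng: np.random.Generator,
    genes_sorted: list[Gene],
    chrom_len: int,
    span_lo: int,
    span_hi: int,
) -> tuple[int, int] | None:
    gaps = []
    prev = 0
    for g in genes_sorted:
        if g.start - prev > span_lo + 2:
            gaps.append((prev, g.start))
        prev = max(prev, g.end)
    if chrom_len - prev > span_lo + 2:
        gaps.append((prev, chrom_len))
    rng.shuffle(gaps)
    for lo, hi in gaps:
        max_span = min(span_hi, hi - lo - 2)
        if max_span <= span_lo:
            continue
        span = int(rng.integers(span_lo + 1, max_span + 1))
        start = int(rng.integers(lo + 1, hi - span))
        return start, start + span
    return None


def generate_circ_calls(
    config: SimConfig, ann: GenomeAnnotation
) -> tuple[dict[str, list[CircJunction]], pd.DataFrame, pd.DataFrame, pd.Series, pd.DataFrame]:
    """Per-tool back-splice call tables with a labelled truth set.

    True circRNAs appear in >= 2 tools with >= 2 junction reads and known
    class/parent; decoys are planted one per failure mode (single tool, one
    read, span > 100 kb, intergenic span > 10 kb). Returns
    ``(calls_by_tool, truth, per_sample_reads, library_sizes, parent_gene_fpkm)``.
    """
    rng = config.rng("circ")
    genes_by_chrom = {
        c: sorted((g for g in ann.genes.values() if g.chrom == c), key=lambda g: g.start)
        for c in config.chrom_names
    }
    classes = list(config.circ_class_weights)
    class_p = np.array([config.circ_class_weights[c] for c in classes])

    rows = []  # (key, class, parent, decoy)
    for i in range(config.n_circ):
        cls = classes[int(rng.choice(len(classes), p=class_p))]
        chrom = config.chrom_names[int(rng.integers(config.n_chromosomes))]
        genes = genes_by_chrom[chrom]
        placed = None
        if cls == "exonic":
            multi = [g for g in genes if len(g.exons) >= 2]
            if multi:
                g = multi[int(rng.integers(len(multi)))]
                a, b = sorted(rng.choice(len(g.exons), size=2, replace=True))
                placed = (g.exons[a][0], g.exons[b][1], g.strand, g.id)
        elif cls == "intronic":
            cands = [(g, iv) for g in genes for iv in g.introns if iv[1] - iv[0] > 80]
            if cands:
                g, (s, e) = cands[int(rng.integers(len(cands)))]
                span = int(rng.integers(60, min(e - s - 2, 2000)))
                start = int(rng.integers(s + 1, e - span))
                placed = (start, start + span, g.strand, g.id)
        else:
            iv = _intergenic_span(rng, genes, config.chrom_length, 200, 9_000)
            if iv:
                placed = (iv[0], iv[1], "+" if rng.random() < 0.5 else "-", None)
        if placed is None:
            continue
        start, end, strand, parent = placed
        cls_eff = cls if parent is not None or cls == "intergenic" else "intergenic"
        rows.append(
            {"chrom": chrom, "start": start, "end": end, "strand": strand,
             "class": cls_eff, "parent_gene": parent, "decoy": ""}
        )

    # decoys, one failure mode each
    for mode in ("one_tool", "low_reads", "long_span", "long_intergenic"):
        for _ in range(config.n_circ_decoys_per_class):
            chrom = config.chrom_names[int(rng.integers(config.n_chromosomes))]
            genes = genes_by_chrom[chrom]
            if mode == "long_span":
                span = int(rng.integers(100_001, 160_000))
                start = int(rng.integers(0, config.chrom_length - span))
                iv = (start, start + span)
            elif mode == "long_intergenic":
                iv = _intergenic_span(rng, genes, config.chrom_length, 10_000, 18_000)
            else:
                iv = _intergenic_span(rng, genes, config.chrom_length, 200, 9_000)
            if iv is None:
                continue
            rows.append(
                {"chrom": chrom, "start": iv[0], "end": iv[1],
                 "strand": "+" if rng.random() < 0.5 else "-",
                 "class": "intergenic", "parent_gene": None, "decoy": mode}
            )

    truth = pd.DataFrame(rows)
    truth = truth.drop_duplicates(subset=["chrom", "start", "end", "strand"]).reset_index(drop=True)
    truth.insert(0, "id", [f"circ{i:04d}" for i in range(len(truth))])

    calls: dict[str, list[CircJunction]] = {t: [] for t in TOOLS}
    abundance = {}
    for r in truth.itertuples():
        lam = float(rng.uniform(3, 25))
        abundance[r.id] = lam
        if r.decoy == "one_tool":
            tools = [TOOLS[int(rng.integers(len(TOOLS)))]]
        else:
            k = 2 if rng.random() < 0.5 else 3
            tools = list(rng.choice(TOOLS, size=k, replace=False))
        for tool in tools:
            reads = 1 if r.decoy == "low_reads" else 2 + int(rng.poisson(lam))
            calls[tool].append(
                CircJunction(
                    chrom=r.chrom, start=int(r.start), end=int(r.end),
                    strand=r.strand, tool=tool, junction_reads=reads,
                )
            )

    samples = config.sample_names
    lib_sizes = pd.Series(
        rng.integers(8_000_000, 12_000_000, size=len(samples)).astype(float),
        index=samples, name="library_size",
    )
    reads = pd.DataFrame(
        rng.poisson(
            np.outer([abundance[i] for i in truth["id"]], np.ones(len(samples)))
        ),
        index=truth["id"], columns=samples,
    )
    parent_ids = sorted({p for p in truth["parent_gene"] if p is not None})
    gene_fpkm = pd.DataFrame(
        rng.lognormal(1.0, 1.0, size=(len(parent_ids), len(samples))),
        index=parent_ids, columns=samples,
    )
    return calls, truth, reads, lib_sizes, gene_fpkm


# ---------------------------------------------------------------------------
# Methylome

def generate_methylome(
    config: SimConfig, ann: GenomeAnnotation
) -> dict[str, pd.DataFrame]:
    """Two bisulfite samples ("A", "B") as per-cytosine report frames.

    Per-context base levels, a multiplicative TSS dip of the configured
    depth within its half-width around every gene TSS, planted DMRs from
    ``dmr_spec`` (sample-specific levels inside the region), and a control
    contig methylated only at the non-conversion error rate. Counts are
    binomial draws at Poisson(coverage) depth; uncovered sites are omitted.
    """
    if ann.control_contig is None:
        raise ValueError("annotation lacks a control contig")
    depth, half_width = config.tss_dip
    tss_by_chrom: dict[str, np.ndarray] = {}
    for g in ann.genes.values():
        tss_by_chrom.setdefault(g.chrom, [])
    for g in ann.genes.values():
        tss_by_chrom[g.chrom].append(g.tss)
    tss_by_chrom = {c: np.sort(np.array(v)) for c, v in tss_by_chrom.items()}

    out: dict[str, pd.DataFrame] = {}
    for sample in ("A", "B"):
        rng = config.rng(f"methylome:{sample}")
        frames = []
        for chrom, L in ann.chromosomes.items():
            is_control = chrom == ann.control_contig
            for ctx in CONTEXTS:
                spacing = config.site_spacing[ctx]
                pos = np.arange(spacing // 2, L, spacing)
                if pos.size == 0:
                    continue
                base = config.error_rate if is_control else config.meth_base_levels[ctx]
                level = np.full(pos.size, base, dtype=float)
                if not is_control:
                    tss = tss_by_chrom.get(chrom, np.array([]))
                    if tss.size and depth > 0:
                        j = np.searchsorted(tss, pos)
                        dist = np.full(pos.size, np.inf)
                        left_ok = j > 0
                        dist[left_ok] = np.abs(pos[left_ok] - tss[j[left_ok] - 1])
                        right_ok = j < tss.size
                        dist[right_ok] = np.minimum(
                            dist[right_ok], np.abs(tss[j[right_ok]] - pos[right_ok])
                        )
                        level[dist <= half_width] *= 1.0 - depth
                    for c, s, e, dctx, la, lb in config.dmr_spec:
                        if c == chrom and dctx == ctx:
                            inside = (pos >= s) & (pos < e)
                            level[inside] = la if sample == "A" else lb
                n = rng.poisson(config.coverage, size=pos.size)
                covered = n > 0
                meth = rng.binomial(n[covered], level[covered])
                strands = np.where(np.arange(covered.sum()) % 2 == 0, "+", "-")
                frames.append(
                    pd.DataFrame(
                        {
                            "chrom": chrom,
                            "pos0": pos[covered],
                            "strand": strands,
                            "count_meth": meth,
                            "count_unmeth": n[covered] - meth,
                            "context": ctx,
                        }
                    )
                )
        df = pd.concat(frames, ignore_index=True)
        out[sample] = df.sort_values(["chrom", "pos0"]).reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# Peaks and interactions

def generate_peaks_interactions(
    config: SimConfig, ann: GenomeAnnotation
) -> tuple[list[Peak], list[AnchorPair], pd.DataFrame]:
    """RNAPII/histone peaks, anchor pairs, and per-gene truth classes.

    Each gene is assigned peak_with_interaction / peak_only / no_peak by the
    configured fractions; RNAPII peaks sit on the promoter of the first two
    classes and anchor pairs join the peaks of interacting genes. Peak
    signals span a weak/strong range. Histone peaks (no truth attached) are
    sprinkled over a random gene subset.
    """
    rng = config.rng("peaks")
    genes = sorted(ann.genes.values(), key=lambda g: (g.chrom, g.start))
    peaks: list[Peak] = []
    pairs: list[AnchorPair] = []
    truth_rows = []
    interacting: list[Peak] = []
    for g in genes:
        u = rng.random()
        if u < config.peak_fraction_interaction:
            cls = "peak_with_interaction"
        elif u < config.peak_fraction_interaction + config.peak_fraction_only:
            cls = "peak_only"
        else:
            cls = "no_peak"
        if cls != "no_peak":
            lo = max(0, g.tss - 150)
            hi = min(ann.chromosomes[g.chrom], g.tss + 250)
            p = Peak(g.chrom, lo, hi, "RNAPII", float(rng.lognormal(1.0, 0.8)))
            peaks.append(p)
            if cls == "peak_with_interaction":
                interacting.append(p)
        truth_rows.append({"gene": g.id, "rnapii_class": cls})
    for a, b in zip(interacting[::2], interacting[1::2]):
        pairs.append(
            AnchorPair(a.chrom, a.start, a.end, b.chrom, b.start, b.end,
                       float(rng.uniform(1, 10)))
        )
    if len(interacting) % 2 == 1 and interacting:
        last = interacting[-1]
        first = interacting[0]
        pairs.append(
            AnchorPair(last.chrom, last.start, last.end,
                       first.chrom, first.start, first.end, 1.0)
        )
    for mark in ("H3K4me3", "H3K27ac", "H3K27me3", "H3K9me2"):
        for g in genes:
            if rng.random() < 0.3:
                lo = max(0, g.start - 100)
                hi = min(ann.chromosomes[g.chrom], g.start + 500)
                peaks.append(Peak(g.chrom, lo, hi, mark, float(rng.lognormal(0.5, 0.8))))
    return peaks, pairs, pd.DataFrame(truth_rows).set_index("gene")


# ---------------------------------------------------------------------------
# ceRNA inputs

def _correlated_pair(
    rng: np.random.Generator, n: int, rho: float
) -> tuple[np.ndarray, np.ndarray]:
    z = rng.normal(size=n)
    a = np.sqrt(rho)
    x = a * z + np.sqrt(1 - rho) * rng.normal(size=n)
    y = a * z + np.sqrt(1 - rho) * rng.normal(size=n)
    return x, y


def _as_fpkm(x: np.ndarray, base: float = 8.0, scale: float = 2.0) -> np.ndarray:
    return np.maximum(base + scale * x, 0.01)


def generate_cerna_inputs(
    config: SimConfig,
) -> tuple[pd.DataFrame, dict[str, str], list[TargetEdge], pd.DataFrame, pd.DataFrame]:
    """Expression matrix, target tables, DE table and planted truth triplets.

    Planted triplets share a latent factor tuned so the sample Pearson
    correlation concentrates near the requested value; both members are
    targets of a common miRNA. Decoys either share a miRNA with near-zero
    correlation or are strongly correlated without a common miRNA. Returns
    ``(expression, kinds, target_edges, de_table, truth_triplets)``.
    """
    rng = config.rng("cerna")
    samples = config.sample_names
    n = len(samples)
    expr: dict[str, np.ndarray] = {}
    kinds: dict[str, str] = {}
    edges: list[TargetEdge] = []
    truth_rows = []

    spec = config.triplet_spec
    if spec is None:
        spec = []
        for i in range(config.n_triplets):
            nc_kind = "lncRNA" if i % 2 == 0 else "circRNA"
            spec.append(
                (f"miR{i:03d}", f"mrna{i:03d}", f"{'lnct' if nc_kind == 'lncRNA' else 'circt'}{i:03d}",
                 config.triplet_pcc)
            )
    predictors = ("targetfinder", "psrnatarget")
    for mirna, mrna, ncrna, rho in spec:
        x, y = _correlated_pair(rng, n, rho)
        expr[ncrna] = _as_fpkm(x)
        expr[mrna] = _as_fpkm(y)
        kinds[ncrna] = "circRNA" if ncrna.startswith("circ") else "lncRNA"
        kinds[mrna] = "mRNA"
        for target, kind in ((ncrna, kinds[ncrna]), (mrna, "mRNA")):
            for src in predictors:
                edges.append(TargetEdge(mirna, target, kind, src))
        truth_rows.append(
            {"mirna": mirna, "ncrna": ncrna, "mrna": mrna, "latent_pcc": rho}
        )

    for i in range(config.n_decoy_shared_mirna):
        mirna, ncrna, mrna = f"dmiR{i:03d}", f"dlnc{i:03d}", f"dmrna{i:03d}"
        expr[ncrna] = _as_fpkm(rng.normal(size=n))
        expr[mrna] = _as_fpkm(rng.normal(size=n))
        kinds[ncrna], kinds[mrna] = "lncRNA", "mRNA"
        edges.append(TargetEdge(mirna, ncrna, "lncRNA", predictors[i % 2]))
        edges.append(TargetEdge(mirna, mrna, "mRNA", predictors[i % 2]))

    for i in range(config.n_decoy_correlated):
        ncrna, mrna = f"clnc{i:03d}", f"cmrna{i:03d}"
        x, y = _correlated_pair(rng, n, config.triplet_pcc)
        expr[ncrna] = _as_fpkm(x)
        expr[mrna] = _as_fpkm(y)
        kinds[ncrna], kinds[mrna] = "lncRNA", "mRNA"
        # targets of *different* miRNAs -> never a triplet
        edges.append(TargetEdge(f"xmiR{i:03d}a", ncrna, "lncRNA", predictors[0]))
        edges.append(TargetEdge(f"xmiR{i:03d}b", mrna, "mRNA", predictors[0]))

    for i in range(config.n_background_features):
        fid = f"bg{i:03d}"
        expr[fid] = np.maximum(rng.lognormal(0.5, 1.0, size=n), 0.01)
        kinds[fid] = "mRNA" if i % 2 == 0 else "lncRNA"

    expr_df = pd.DataFrame(expr, index=samples).T
    expr_df.index.name = "id"

    ids = list(expr_df.index)
    fc = rng.lognormal(0.0, 0.3, size=len(ids))
    fdr = rng.uniform(0.2, 1.0, size=len(ids))
    de_mask = rng.random(len(ids)) < 0.4
    fc[de_mask] = rng.choice([3.0, 6.0, 0.2, 0.3], size=int(de_mask.sum()))
    fdr[de_mask] = rng.uniform(0.0001, 0.01, size=int(de_mask.sum()))
    de = pd.DataFrame({"id": ids, "fc": fc, "fdr": fdr})

    return expr_df, kinds, edges, de, pd.DataFrame(truth_rows)
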