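"""ceRNA (lncRNA/circRNA - miRNA - mRNA) triplet inference and conservation.

A competing triplet joins a non-coding RNA and an mRNA targeted by a common
miRNA whose expressions are strongly co-expressed (Pearson r > 0.8,
P < 0.05 across samples). lncRNAs/mRNAs below mean FPKM 0.5 are excluded
before correlation; circRNAs (RPM-scale) are exempt from that filter.
Tiered BLAST thresholds judge conservation: within the Oryza genus identity
>= 80%, across monocots/dicots >= 50%, and for back-splice junction
sequences >= 95% with at most one gap (e-value < 1e-5 throughout).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from statsmodels.stats.multitest import multipletests

MIN_FPKM = 0.5
PCC_THRESHOLD = 0.8
P_THRESHOLD = 0.05
FC_UP = 2.0
FC_DOWN = 0.5
FDR_THRESHOLD = 0.05

CONSERVATION_TIERS: dict[str, dict[str, float]] = {
    "oryza": {"min_identity": 80.0, "max_evalue": 1e-5},
    "monocot_dicot": {"min_identity": 50.0, "max_evalue": 1e-5},
    "junction": {"min_identity": 95.0, "max_evalue": 1e-5, "max_gaps": 1},
}


@dataclass(frozen=True)
class TargetEdge:
    mirna: str
    target: str
    target_kind: str  # mRNA / lncRNA / circRNA
    source: str = ""


@dataclass(frozen=True)
class CeRNATriplet:
    mirna: str
    ncrna: str
    mrna: str
    pcc: float
    p_value: float


def expression_filter(
    kinds: Mapping[str, str],
    expr: pd.DataFrame,
    min_fpkm: float = MIN_FPKM,
) -> list[str]:
    """Drop lncRNAs/mRNAs with mean FPKM < ``min_fpkm``; circRNAs are exempt.

    ``kinds`` maps feature id -> kind. Features missing from ``expr`` are
    treated as unexpressed (dropped unless circRNA).
    """
    means = expr.mean(axis=1)
    kept = []
    for fid, kind in kinds.items():
        if kind == "circRNA":
            kept.append(fid)
        elif fid in means.index and means[fid] >= min_fpkm:
            kept.append(fid)
    return kept


def pearson_with_p(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float] | None:
    """Pearson r with the two-sided t-based p-value (n - 2 df).

    Returns ``None`` (no pair, never r = 0) when either vector has zero
    variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def build_triplets(
    targets: Iterable[TargetEdge],
    expr: pd.DataFrame,
    *,
    pcc_threshold: float = PCC_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
    min_fpkm: float = MIN_FPKM,
    mirna_allowlist: set[str] | None = None,
    intersect_sources: bool = False,
) -> list[CeRNATriplet]:
    """Enumerate competing triplets from target edges and co-expression.

    For every miRNA, each of its non-coding targets is paired with each of
    its mRNA targets; the pair survives iff both members pass the
    expression filter and their Pearson correlation across the columns of
    ``expr`` satisfies r > ``pcc_threshold`` (strict) and p < ``p_threshold``.
    Edges from multiple predictors are unioned by default;
    ``intersect_sources`` instead requires every predictor that reported
    any edge to report this one. Result is deduplicated and sorted.
    """
    edges = list(targets)
    if mirna_allowlist is not None:
        edges = [e for e in edges if e.mirna in mirna_allowlist]
    if intersect_sources:
        sources = {e.source for e in edges}
        by_pair: dict[tuple[str, str, str], set[str]] = {}
        for e in edges:
            by_pair.setdefault((e.mirna, e.target, e.target_kind), set()).add(e.source)
        edges = [
            TargetEdge(m, t, k, "intersect")
            for (m, t, k), srcs in by_pair.items()
            if srcs == sources
        ]
    kinds = {e.target: e.target_kind for e in edges}
    keep = set(expression_filter(kinds, expr, min_fpkm))

    nc_by_mirna: dict[str, set[str]] = {}
    m_by_mirna: dict[str, set[str]] = {}
    for e in edges:
        if e.target not in keep:
            continue
        if e.target_kind in ("lncRNA", "circRNA"):
            nc_by_mirna.setdefault(e.mirna, set()).add(e.target)
        elif e.target_kind == "mRNA":
            m_by_mirna.setdefault(e.mirna, set()).add(e.target)

    cache: dict[tuple[str, str], tuple[float, float] | None] = {}
    out: set[CeRNATriplet] = set()
    for mirna in sorted(set(nc_by_mirna) & set(m_by_mirna)):
        for nc in sorted(nc_by_mirna[mirna]):
            for mr in sorted(m_by_mirna[mirna]):
                if nc not in expr.index or mr not in expr.index:
                    continue
                key = (nc, mr)
                if key not in cache:
                    cache[key] = pearson_with_p(
                        expr.loc[nc].to_numpy(), expr.loc[mr].to_numpy()
                    )
                rp = cache[key]
                if rp is None:
                    continue
                r, p = rp
                if r > pcc_threshold and p < p_threshold:
                    out.add(CeRNATriplet(mirna, nc, mr, r, p))
    return sorted(out, key=lambda t: (t.mirna, t.ncrna, t.mrna))


def de_filter(table: pd.DataFrame) -> pd.DataFrame:
    """Differential-expression calls from fold change and FDR.

    ``table`` needs columns ``fc`` (raw fold change) and ``fdr`` (or
    ``pvalue``, to which Benjamini-Hochberg is applied, flagged by the
    ``fdr_from_bh`` column). Direction: Up iff FC > 2 and FDR < 0.05, Down
    iff FC < 0.5 and FDR < 0.05, else None. Idempotent and row-order
    independent.
    """
    out = table.copy()
    if "fdr" not in out.columns:
        if "pvalue" not in out.columns:
            raise ValueError("need an 'fdr' or 'pvalue' column")
        out["fdr"] = multipletests(out["pvalue"].to_numpy(), method="fdr_bh")[1]
        out["fdr_from_bh"] = True
    sig = out["fdr"] < FDR_THRESHOLD
    out["direction"] = "None"
    out.loc[sig & (out["fc"] > FC_UP), "direction"] = "Up"
    out.loc[sig & (out["fc"] < FC_DOWN), "direction"] = "Down"
    return out


def tissue_network(
    triplets: Iterable[CeRNATriplet],
    de_calls: pd.DataFrame,
    *,
    ncrna_kinds: Mapping[str, str],
    expressed_circs: set[str] | None = None,
) -> list[CeRNATriplet]:
    """Restrict a triplet set to a tissue's DE genes (circRNAs stay in).

    A triplet is kept iff its mRNA is differentially expressed (direction
    != None in ``de_calls``, indexed by feature id) and its ncRNA is either
    a DE lncRNA or a circRNA (optionally restricted to ``expressed_circs``).
    """
    de = set(de_calls.index[de_calls["direction"] != "None"])
    out = []
    for t in triplets:
        if t.mrna not in de:
            continue
        kind = ncrna_kinds.get(t.ncrna, "lncRNA")
        if kind == "circRNA":
            if expressed_circs is not None and t.ncrna not in expressed_circs:
                continue
        elif t.ncrna not in de:
            continue
        out.append(t)
    return out


def conservation_filter(
    hits: pd.DataFrame,
    tier: str,
    total_queries: int | None = None,
    *,
    gap_column: str = "gapopen",
) -> tuple[set[str], float]:
    """Conserved queries under the tier's identity / e-value / gap thresholds.

    ``hits`` is a BLAST outfmt-6 frame. A query is conserved iff at least
    one hit passes; ratio = conserved / total (``total_queries`` defaults
    to the number of distinct queries in ``hits``).
    """
    if tier not in CONSERVATION_TIERS:
        raise ValueError(f"unknown tier {tier!r}; choose from {sorted(CONSERVATION_TIERS)}")
    th = CONSERVATION_TIERS[tier]
    ok = (hits["pident"] >= th["min_identity"]) & (hits["evalue"] < th["max_evalue"])
    if "max_gaps" in th:
        ok &= hits[gap_column] <= th["max_gaps"]
    conserved = set(hits.loc[ok, "qseqid"])
    total = total_queries if total_queries is not None else hits["qseqid"].nunique()
    ratio = len(conserved) / total if total else 0.0
    return conserved, ratio


# ---------------------------------------------------------------------------
# Network export

def to_graph(triplets: Iterable[CeRNATriplet], kinds: Mapping[str, str]) -> nx.Graph:
    g = nx.Graph()
    for t in triplets:
        g.add_node(t.mirna, kind="miRNA")
        g.add_node(t.ncrna, kind=kinds.get(t.ncrna, "lncRNA"))
        g.add_node(t.mrna, kind="mRNA")
        g.add_edge(t.mirna, t.ncrna, edge_type="mirna-ncrna")
        g.add_edge(t.mirna, t.mrna, edge_type="mirna-mrna")
        g.add_edge(t.ncrna, t.mrna, edge_type="coexpression", pcc=t.pcc, p_value=t.p_value)
    return g


def export_network(
    triplets: Sequence[CeRNATriplet],
    path_prefix: str,
    kinds: Mapping[str, str] | None = None,
) -> None:
    """Write the triplet network as GraphML plus node/edge/triplet TSVs.

    ``<prefix>.graphml``, ``<prefix>.nodes.tsv`` (id, kind),
    ``<prefix>.edges.tsv`` and ``<prefix>.triplets.tsv``; the triplet table
    round-trips losslessly through :func:`read_network`.
    """
    kinds = dict(kinds or {})
    g = to_graph(triplets, kinds)
    nx.write_graphml(g, f"{path_prefix}.graphml")
    nodes = pd.DataFrame(
        [(n, d.get("kind", "")) for n, d in g.nodes(data=True)], columns=["id", "kind"]
    ).sort_values("id")
    nodes.to_csv(f"{path_prefix}.nodes.tsv", sep="\t", index=False)
    edges = pd.DataFrame(
        [
            (u, v, d.get("edge_type", ""), d.get("pcc", np.nan), d.get("p_value", np.nan))
            for u, v, d in g.edges(data=True)
        ],
        columns=["source", "target", "edge_type", "pcc", "p_value"],
    ).sort_values(["source", "target"])
    edges.to_csv(f"{path_prefix}.edges.tsv", sep="\t", index=False)
    trip = pd.DataFrame(
        [(t.mirna, t.ncrna, t.mrna, t.pcc, t.p_value) for t in triplets],
        columns=["mirna", "ncrna", "mrna", "pcc", "p_value"],
    )
    trip.to_csv(f"{path_prefix}.triplets.tsv", sep="\t", index=False)


def read_network(path_prefix: str) -> list[CeRNATriplet]:
    df = pd.read_csv(f"{path_prefix}.triplets.tsv", sep="\t")
    return [
        CeRNATriplet(r.mirna, r.ncrna, r.mrna, float(r.pcc), float(r.p_value))
        for r in df.itertuples()
    ]
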