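"""Context-resolved DNA-methylation analysis from per-cytosine reports.

The in-memory container for a bisulfite sample is a DataFrame with columns
``chrom, pos0, strand, count_meth, count_unmeth, context`` (0-based
positions; contexts CG / CHG / CHH). All levels are weighted methylation
levels, sum(meth) / sum(meth + unmeth), never averages of per-site ratios.

DMRs between two samples are called per cytosine with an exact two-sided
binomial test and a minimum between-sample level difference of 0.6, then
merged into regions. The null proportion defaults to the pooled proportion
of both samples, clamped away from {0, 1} by the bisulfite non-conversion
error rate estimated from the unmethylated chloroplast control contig.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from statsmodels.stats.multitest import multipletests

CONTEXTS = ("CG", "CHG", "CHH")

MIN_DIFF = 0.6
ALPHA = 0.05
DEFAULT_ERROR_RATE = 0.003

_FEATURE_COLS = ["chrom", "start", "end", "strand"]


@dataclass
class MetageneProfile:
    """Coverage-weighted methylation profile over flank / body / flank bins.

    ``values[i]`` is NaN (never silently 0) for bins with no covered
    cytosine; ``meth`` and ``total`` carry the underlying read counts so
    bins can be pooled or given standard errors downstream.
    """

    context: str
    flank_bins: int
    body_bins: int
    values: np.ndarray
    meth: np.ndarray
    total: np.ndarray
    n_features: int

    @property
    def n_bins(self) -> int:
        return 2 * self.flank_bins + self.body_bins


@dataclass(frozen=True)
class DMR:
    chrom: str
    start: int
    end: int
    context: str
    level_a: float
    level_b: float
    p_value: float
    direction: str  # hyper / hypo, sample A relative to B
    n_sites: int = 1


def _check_features(features: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _FEATURE_COLS if c not in features.columns]
    if missing:
        raise ValueError(f"feature frame lacks columns {missing}")
    return features


def feature_methylation_density(
    calls: pd.DataFrame, features: pd.DataFrame, context: str
) -> pd.Series:
    """Weighted methylation level per feature for one context.

    ``features`` is a BED-like frame (chrom, start, end, strand) indexed by
    feature id. Features with no covered cytosine of the context get NaN.
    """
    _check_features(features)
    by_chrom = _context_arrays(calls, context)
    out = pd.Series(np.nan, index=features.index, dtype=float, name=context)
    for fid, row in features.iterrows():
        arr = by_chrom.get(row["chrom"])
        if arr is None:
            continue
        pos, m_arr, u_arr = arr
        i0, i1 = np.searchsorted(pos, [row["start"], row["end"]])
        if i1 > i0:
            m = m_arr[i0:i1].sum()
            u = u_arr[i0:i1].sum()
            if m + u > 0:
                out[fid] = m / (m + u)
    return out


def _context_arrays(
    calls: pd.DataFrame, context: str
) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Per-chromosome (sorted positions, meth, unmeth) arrays for one context."""
    sub = calls[calls["context"] == context]
    out = {}
    for c, g in sub.groupby("chrom"):
        g = g.sort_values("pos0")
        out[c] = (
            g["pos0"].to_numpy(),
            g["count_meth"].to_numpy(dtype=float),
            g["count_unmeth"].to_numpy(dtype=float),
        )
    return out


def metagene_profile(
    calls: pd.DataFrame,
    features: pd.DataFrame,
    context: str,
    *,
    flank_bp: int = 1000,
    body_bins: int = 60,
    flank_bins: int = 20,
) -> MetageneProfile:
    """Average methylation over rescaled feature bodies with fixed-width flanks.

    The body of each feature is rescaled to ``body_bins`` bins; the
    ``flank_bp`` windows up- and downstream are split into ``flank_bins``
    bins each. Minus-strand features are reversed so bin 0 is always the
    distal 5' flank. Bin levels are read-count weighted across features.
    """
    _check_features(features)
    n_bins = 2 * flank_bins + body_bins
    meth = np.zeros(n_bins)
    total = np.zeros(n_bins)
    by_chrom = _context_arrays(calls, context)
    n_features = 0
    for _, row in features.iterrows():
        arr = by_chrom.get(row["chrom"])
        n_features += 1
        if arr is None:
            continue
        start, end = int(row["start"]), int(row["end"])
        pos_all, m_all, u_all = arr
        i0, i1 = np.searchsorted(pos_all, [start - flank_bp, end + flank_bp])
        if i1 == i0:
            continue
        pos = pos_all[i0:i1]
        m = m_all[i0:i1]
        u = u_all[i0:i1]
        L = end - start
        bins = np.empty(pos.size, dtype=int)
        up = pos < start
        down = pos >= end
        body = ~(up | down)
        bins[up] = (pos[up] - (start - flank_bp)) * flank_bins // flank_bp
        bins[body] = flank_bins + (pos[body] - start) * body_bins // L
        bins[down] = (
            flank_bins + body_bins + (pos[down] - end) * flank_bins // flank_bp
        )
        if row["strand"] == "-":
            bins = n_bins - 1 - bins
        np.add.at(meth, bins, m)
        np.add.at(total, bins, m + u)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(total > 0, meth / np.where(total > 0, total, 1), np.nan)
    return MetageneProfile(
        context=context,
        flank_bins=flank_bins,
        body_bins=body_bins,
        values=values,
        meth=meth,
        total=total,
        n_features=n_features,
    )


def stratified_profiles(
    calls: pd.DataFrame,
    features: pd.DataFrame,
    strata: Mapping[str, str] | pd.Series,
    context: str,
    **kwargs,
) -> dict[str, MetageneProfile]:
    """One metagene profile per stratum (e.g. expression tier or quantile)."""
    strata = pd.Series(strata)
    out: dict[str, MetageneProfile] = {}
    for group in sorted(strata.unique()):
        ids = strata.index[strata == group]
        out[group] = metagene_profile(
            calls, features.loc[features.index.intersection(ids)], context, **kwargs
        )
    return out


def estimate_error_rate(calls: pd.DataFrame, control_contig: str) -> float:
    """Bisulfite non-conversion rate from the unmethylated control contig.

    Plant chloroplasts carry no methylation, so any methylated call there is
    a conversion failure: rate = sum(meth) / sum(meth + unmeth).
    """
    sub = calls[calls["chrom"] == control_contig]
    m = float(sub["count_meth"].sum())
    u = float(sub["count_unmeth"].sum())
    if m + u == 0:
        raise ValueError(f"no coverage on control contig {control_contig}")
    return m / (m + u)


@lru_cache(maxsize=200_000)
def binomial_two_sided(k: int, n: int, p0: float) -> float:
    """Exact two-sided binomial p-value by point-probability enumeration.

    Sums P(X = i) over all i with P(X = i) <= P(X = k), where ``p0`` is
    interpreted as the exact rational value of the float. Comparisons that
    float arithmetic cannot settle (within one part in 1e9) are resolved in
    exact rational arithmetic, so near-ties such as pmf(0) vs pmf(1) at
    p0 = 0.1 come out the way exact enumeration does.
    """
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must be in (0, 1)")
    q0 = 1.0 - p0
    pmf = np.array([math.comb(n, i) * p0**i * q0 ** (n - i) for i in range(n + 1)])
    target = pmf[k]
    include = pmf <= target * (1.0 - 1e-9)
    include[k] = True
    borderline = ~include & (pmf <= target * (1.0 + 1e-9))
    if borderline.any():
        p = Fraction(p0)
        q = 1 - p
        exact_target = math.comb(n, k) * p**k * q ** (n - k)
        for i in np.nonzero(borderline)[0]:
            i = int(i)
            if math.comb(n, i) * p**i * q ** (n - i) <= exact_target:
                include[i] = True
    return float(min(1.0, pmf[include].sum()))


def call_dmrs(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    context: str,
    min_coverage: int = 4,
    *,
    error_rate: float = DEFAULT_ERROR_RATE,
    alpha: float = ALPHA,
    min_diff: float = MIN_DIFF,
    merge_gap: int = 200,
    null: str = "pooled",
    symmetric: bool = False,
    bh: bool = False,
) -> tuple[pd.DataFrame, list[DMR]]:
    """Per-cytosine binomial DMR test between two samples, plus region merging.

    For each cytosine of ``context`` covered by >= ``min_coverage`` reads in
    both samples, sample A's methylated count is tested against a null
    proportion with an exact two-sided binomial test; a site is differential
    iff p <= ``alpha`` and the level difference ``|mA - mB| >= min_diff``.
    ``null="pooled"`` (default) uses (kA+kB)/(nA+nB); ``null="other"`` uses
    sample B's observed proportion. Either way the proportion is clamped to
    [error_rate, 1 - error_rate]. With ``symmetric=True`` the mirrored test
    of B against A's proportion must also reach ``alpha``. ``bh=True``
    additionally applies Benjamini-Hochberg across tested sites.

    Returns ``(site_table, regions)``: the per-site table with levels, p and
    DMR flag, and significant sites within ``merge_gap`` bp of each other
    (same direction) merged into :class:`DMR` regions with pooled levels.
    """
    if min_coverage < 1:
        raise ValueError("min_coverage must be >= 1")
    if not 0.0 < error_rate < 0.5:
        raise ValueError("error_rate must be in (0, 0.5)")
    a = calls_a[calls_a["context"] == context]
    b = calls_b[calls_b["context"] == context]
    merged = a.merge(
        b,
        on=["chrom", "pos0", "strand", "context"],
        suffixes=("_a", "_b"),
        how="inner",
    )
    na = (merged["count_meth_a"] + merged["count_unmeth_a"]).to_numpy()
    nb = (merged["count_meth_b"] + merged["count_unmeth_b"]).to_numpy()
    ok = (na >= min_coverage) & (nb >= min_coverage)
    merged = merged.loc[ok].reset_index(drop=True)
    ka = merged["count_meth_a"].to_numpy()
    kb = merged["count_meth_b"].to_numpy()
    na, nb = na[ok], nb[ok]
    ma = ka / na
    mb = kb / nb
    if null == "pooled":
        p0 = (ka + kb) / (na + nb)
    elif null == "other":
        p0 = mb.copy()
    else:
        raise ValueError(f"unknown null {null!r}")
    p0 = np.clip(p0, error_rate, 1.0 - error_rate)
    pvals = np.array(
        [binomial_two_sided(int(k), int(n), float(p)) for k, n, p in zip(ka, na, p0)]
    )
    if symmetric:
        p0r = (ka + kb) / (na + nb) if null == "pooled" else ma.copy()
        p0r = np.clip(p0r, error_rate, 1.0 - error_rate)
        pr = np.array(
            [binomial_two_sided(int(k), int(n), float(p)) for k, n, p in zip(kb, nb, p0r)]
        )
        pvals = np.maximum(pvals, pr)
    sig = pvals <= alpha
    if bh and len(pvals):
        sig &= multipletests(pvals, alpha=alpha, method="fdr_bh")[0]
    d = ma - mb
    is_dmr = sig & (np.abs(d) >= min_diff)

    sites = merged[["chrom", "pos0", "strand", "context"]].copy()
    sites["n_a"] = na
    sites["n_b"] = nb
    sites["level_a"] = ma
    sites["level_b"] = mb
    sites["diff"] = d
    sites["p_value"] = pvals
    sites["is_dmr"] = is_dmr

    regions = _merge_dmr_sites(
        sites.loc[is_dmr], merged.loc[is_dmr], context, merge_gap
    )
    return sites, regions


def _merge_dmr_sites(
    sites: pd.DataFrame, counts: pd.DataFrame, context: str, merge_gap: int
) -> list[DMR]:
    regions: list[DMR] = []
    if sites.empty:
        return regions
    sites = sites.assign(
        _ka=counts["count_meth_a"].to_numpy(),
        _kb=counts["count_meth_b"].to_numpy(),
    ).sort_values(["chrom", "pos0"])
    cur: list[pd.Series] = []

    def flush() -> None:
        if not cur:
            return
        ka = sum(r["_ka"] for r in cur)
        na = sum(r["n_a"] for r in cur)
        kb = sum(r["_kb"] for r in cur)
        nb = sum(r["n_b"] for r in cur)
        regions.append(
            DMR(
                chrom=cur[0]["chrom"],
                start=int(cur[0]["pos0"]),
                end=int(cur[-1]["pos0"]) + 1,
                context=context,
                level_a=ka / na,
                level_b=kb / nb,
                p_value=float(min(r["p_value"] for r in cur)),
                direction="hyper" if cur[0]["diff"] > 0 else "hypo",
                n_sites=len(cur),
            )
        )

    for _, row in sites.iterrows():
        direction = "hyper" if row["diff"] > 0 else "hypo"
        if cur and (
            row["chrom"] != cur[-1]["chrom"]
            or row["pos0"] - cur[-1]["pos0"] > merge_gap
            or direction != ("hyper" if cur[-1]["diff"] > 0 else "hypo")
        ):
            flush()
            cur = []
        cur.append(row)
    flush()
    return regions


def annotate_dmr_features(
    dmrs: Iterable[DMR],
    features: pd.DataFrame,
    de_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Count hyper/hypo DMRs overlapping each feature body, joined to DE status.

    ``de_table`` (optional) is indexed by feature id with a ``direction``
    column in {Up, Down, None}; absent features (or no table) get "None".
    A DMR overlapping two features is counted in both.
    """
    _check_features(features)
    out = pd.DataFrame(
        {"n_hyper": 0, "n_hypo": 0}, index=features.index, dtype=int
    )
    for dmr in dmrs:
        hit = (
            (features["chrom"] == dmr.chrom)
            & (features["start"] < dmr.end)
            & (dmr.start < features["end"])
        )
        col = "n_hyper" if dmr.direction == "hyper" else "n_hypo"
        out.loc[hit, col] += 1
    if de_table is not None and "direction" in de_table.columns:
        out["de_status"] = (
            de_table["direction"].reindex(out.index).fillna("None")
        )
    else:
        out["de_status"] = "None"
    return out
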