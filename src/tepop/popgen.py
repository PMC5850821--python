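"""Population statistics over the strain x site matrix.

Per-strain TE count traits, folded site allele-frequency spectra,
Spearman trait correlations, 10-kb bin enrichment with 95th-percentile
hotspot flags, Tajima's D per bin, size-normalized chi-squared tests of
genomic-class enrichment, and the top-vs-rest Wilcoxon comparison of
Tajima's D.

Conventions: at insertion (``_NR``) sites the *activity allele* is
presence (1); at active reference (``_R``) sites it is the absence (0)
— an excision is the evidence of movement.  MAF folds carrier
frequencies to [0, 0.5].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import SiteMatrix

TOTAL = "total"
SITE_TYPES = ("insertion", "active_reference", "all")


@dataclass
class TraitTable:
    """Per-strain TE counts for each (grouping, site_type) trait.

    ``counts``: strains x traits, columns a MultiIndex
    (grouping, site_type) with grouping in {"total", "type:<class>",
    "family:<name>"}.  ``n_sites``: contributing unique sites per trait.
    ``na_counts``: per cell, how many contributing sites were NA for
    that strain (the NA-exposure used by the mapping filters).
    """

    counts: pd.DataFrame
    n_sites: pd.Series
    na_counts: pd.DataFrame = field(default_factory=pd.DataFrame)

    def trait(self, grouping: str, site_type: str) -> pd.Series:
        return self.counts[(grouping, site_type)]


def _activity_indicator(matrix: SiteMatrix) -> pd.DataFrame:
    """Sites x strains frame: 1 where the strain carries the activity
    allele, 0 where it does not, NaN unknown.  Monomorphic reference
    sites are excluded (no activity observed)."""
    ins = matrix.values.loc[matrix.insertion_ids()]
    act = matrix.values.loc[matrix.active_reference_ids()]
    return pd.concat([ins, 1.0 - act])


def count_traits(matrix: SiteMatrix) -> TraitTable:
    """Count activity alleles per strain for every grouping x site type.

    Insertion counts are 1-values at insertion sites; active-reference
    counts are 0-values (excisions) at active reference sites; ``all``
    is their sum.  NAs never count, but are tallied in ``na_counts``.
    """
    ind = _activity_indicator(matrix)
    meta = matrix.sites.loc[ind.index]
    site_type = np.where(meta["site_type"] == "insertion", "insertion", "active_reference")
    groupings: dict[str, pd.Series] = {TOTAL: pd.Series(True, index=ind.index)}
    for cls in sorted(meta["te_class"].dropna().unique()):
        groupings[f"type:{cls}"] = meta["te_class"] == cls
    for fam in sorted(meta["family"].dropna().unique()):
        groupings[f"family:{fam}"] = meta["family"] == fam

    counts, nas, nsites = {}, {}, {}
    for gname, gmask in groupings.items():
        for st in SITE_TYPES:
            if st == "all":
                mask = gmask.to_numpy()
            else:
                mask = gmask.to_numpy() & (site_type == st)
            block = ind.iloc[mask]
            counts[(gname, st)] = block.sum(axis=0, skipna=True).astype(int)
            nas[(gname, st)] = block.isna().sum(axis=0).astype(int)
            nsites[(gname, st)] = int(mask.sum())
    cols = pd.MultiIndex.from_tuples(counts.keys(), names=["grouping", "site_type"])
    cdf = pd.DataFrame(counts)
    cdf.columns = cols
    ndf = pd.DataFrame(nas)
    ndf.columns = cols
    return TraitTable(counts=cdf, n_sites=pd.Series(nsites).rename_axis(["grouping", "site_type"]),
                      na_counts=ndf)


def site_maf(matrix: SiteMatrix) -> pd.DataFrame:
    """Folded minor allele frequency and singleton flag per segregating site.

    Carrier frequency is the mean activity allele over non-NA strains;
    MAF = min(f, 1-f); a singleton has exactly one carrier.  All-NA
    sites get NaN.
    """
    ind = _activity_indicator(matrix)
    n = ind.notna().sum(axis=1)
    carriers = ind.sum(axis=1, skipna=True)
    with np.errstate(invalid="ignore"):
        f = carriers / n
    maf = np.minimum(f, 1 - f)
    return pd.DataFrame({
        "carrier_freq": f,
        "maf": maf,
        "n_non_na": n,
        "n_carriers": carriers.astype("Int64"),
        "singleton": (carriers == 1),
    })


def correlate_counts(traits: pd.DataFrame | TraitTable, x, y) -> tuple[float, float]:
    """Spearman rank correlation (midrank ties, two-sided p) between two
    trait columns; constant inputs give (nan, nan) with a warning."""
    counts = traits.counts if isinstance(traits, TraitTable) else traits
    xv, yv = counts[x], counts[y]
    ok = xv.notna() & yv.notna()
    xv, yv = xv[ok].to_numpy(float), yv[ok].to_numpy(float)
    if len(xv) < 3:
        raise ValueError("need at least 3 strains")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        warnings.warn("constant trait vector; correlation undefined", stacklevel=2)
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(xv, yv)
    return float(rho), float(p)


def bin_te_counts(
    sites: pd.DataFrame,
    layout: pd.DataFrame,
    bin_size: int = 10_000,
    drop_partial: bool = False,
) -> pd.DataFrame:
    """Unique-site counts per non-overlapping ``bin_size`` window.

    ``top5_flag`` marks bins at or above the 95th percentile of counts
    (linear-interpolation quantile); the flag is suppressed when every
    bin has the same count.  ``ge3_flag`` marks bins with >= 3 sites.
    Terminal partial bins are kept unless ``drop_partial``.
    """
    rows = []
    for _, crow in layout.iterrows():
        length = int(crow["length"])
        edges = np.arange(0, length, bin_size)
        for start in edges:
            end = min(start + bin_size, length)
            if drop_partial and end - start < bin_size:
                continue
            rows.append((str(crow["chrom"]), int(start), int(end)))
    bins = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    counts = np.zeros(len(bins), dtype=int)
    bin_lookup = {c: g for c, g in bins.groupby("chrom")}
    for chrom, grp in sites.groupby("chrom"):
        b = bin_lookup.get(chrom)
        if b is None:
            continue
        idx = (grp["position"].to_numpy() - 1) // bin_size
        idx = np.clip(idx, 0, len(b) - 1)
        np.add.at(counts, b.index.to_numpy()[idx.astype(int)], 1)
    bins["te_count"] = counts
    if counts.max() == counts.min():
        bins["top5_flag"] = False
    else:
        q95 = float(np.quantile(counts, 0.95))
        bins["top5_flag"] = counts >= q95
    bins["ge3_flag"] = counts >= 3
    return bins


@dataclass
class TajimaDComponents:
    n: int
    S: int
    pi: float
    theta_w: float
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float
    D: float


def tajimas_d(genotypes: np.ndarray | pd.DataFrame) -> TajimaDComponents:
    """Tajima's D for haploid-coded biallelic genotypes (strains x sites).

    pi is the mean number of pairwise differences (missing entries
    excluded pairwise per site), theta_w = S / a1, and D their
    normalized difference with the standard Tajima (1989) constants.
    D is NaN when S = 0 or fewer than 4 sequences are present.
    """
    G = np.asarray(genotypes, dtype=float)
    if G.ndim != 2:
        raise ValueError("genotypes must be 2-D (strains x sites)")
    n = G.shape[0]
    nan_cc = TajimaDComponents(n, 0, 0.0, 0.0, *([np.nan] * 8), np.nan)
    if n < 4:
        warnings.warn("Tajima's D needs at least 4 sequences", stacklevel=2)
        return nan_cc

    non_missing = (~np.isnan(G)).sum(axis=0)
    with np.errstate(invalid="ignore"):
        ones = np.nansum(G, axis=0)
    segregating = (ones > 0) & (ones < non_missing) & (non_missing >= 2)
    S = int(segregating.sum())

    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)

    if S == 0:
        return TajimaDComponents(n, 0, 0.0, 0.0, a1, a2, b1, b2, c1, c2, e1, e2, np.nan)

    # mean pairwise differences, per site: 2*j*(m-j) / (m choose 2)
    m = non_missing[segregating]
    j = ones[segregating]
    pi = float(np.sum(j * (m - j) / (m * (m - 1) / 2.0)))
    theta_w = S / a1
    D = (pi - theta_w) / np.sqrt(e1 * S + e2 * S * (S - 1))
    return TajimaDComponents(n, S, pi, theta_w, a1, a2, b1, b2, c1, c2, e1, e2, float(D))


def tajimas_d_per_bin(
    genotypes: pd.DataFrame, markers: pd.DataFrame, bins: pd.DataFrame
) -> pd.Series:
    """Tajima's D for the SNVs falling in each bin (NaN when empty/S=0)."""
    out = np.full(len(bins), np.nan)
    mpos = markers.set_index("marker")
    for i, (_, b) in enumerate(bins.iterrows()):
        in_bin = mpos[(mpos["chrom"] == b["chrom"])
                      & (mpos["position"] > b["start"])
                      & (mpos["position"] <= b["end"])].index
        if len(in_bin) == 0:
            continue
        out[i] = tajimas_d(genotypes[in_bin].to_numpy(float)).D
    return pd.Series(out, index=bins.index, name="tajima_d")


def chisq_size_normalized(
    observed: dict[str, int] | pd.Series, sizes: dict[str, float] | pd.Series
) -> tuple[float, float, int]:
    """Pearson chi-squared of observed class counts against expectations
    proportional to class sizes in bp; returns (chi2, p, df)."""
    obs = pd.Series(observed, dtype=float)
    siz = pd.Series(sizes, dtype=float).reindex(obs.index)
    if (siz <= 0).any():
        raise ValueError("class sizes must be positive")
    total = obs.sum()
    if total <= 0:
        raise ValueError("total observed count must be positive")
    expected = total * siz / siz.sum()
    if (expected < 1).any():
        warnings.warn("expected cell count below 1; chi-squared unreliable", stacklevel=2)
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = len(obs) - 1
    p = float(stats.chi2.sf(chi2, df))
    return chi2, p, df


def compare_bin_selection(d_top: pd.Series, d_rest: pd.Series) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney, midranks) of Tajima's D
    in top-5% bins vs the rest; NaNs are dropped first."""
    a = pd.Series(d_top).dropna().to_numpy(float)
    b = pd.Series(d_rest).dropna().to_numpy(float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups need at least one non-NA value")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# printed-summary helpers


def pct(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """Percentage rounded to ``ndigits`` (the form used in reports)."""
    if denominator == 0:
        raise ValueError("denominator must be non-zero")
    return round(100.0 * numerator / denominator, ndigits)


def breakdown_pct(counts: dict[str, float], ndigits: int = 1) -> dict[str, float]:
    """Each category as a percentage of the total, rounded."""
    total = sum(counts.values())
    return {k: pct(v, total, ndigits) for k, v in counts.items()}
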