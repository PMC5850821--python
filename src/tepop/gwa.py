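"""Kinship-corrected association mapping of TE-count traits.

The scan is the classic single-marker linear mixed model for inbred
panels: y = mu + x*beta + g + e with g ~ N(0, sigma_g^2 K) and
e ~ N(0, sigma_e^2 I).  The variance ratio delta = sigma_g^2/sigma_e^2
is estimated once on the null (intercept-only) model by REML via the
eigendecomposition of K, then every marker is tested by generalized
least squares with those variance components fixed (the
population-parameters-previously-determined scheme).  Downstream, the
trait filters, Bonferroni threshold, 300-SNV peak grouping, +/-50-marker
intervals, cis-proximity and median-split filters, and Spearman
fine-mapping reproduce the TE-count QTL protocol.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .matrix import SiteMatrix
from .popgen import TraitTable, count_traits

# ---------------------------------------------------------------------------
# trait construction and filters


def prune_outlier_strains(values: pd.Series, max_fraction: float = 0.05,
                          gap_bins: int = 2) -> pd.Index:
    """Strains whose counts lie beyond a gap of >= ``gap_bins`` empty
    integer bins from the main mass, provided they are fewer than
    ``max_fraction`` of strains.  Returns the index of pruned strains."""
    v = values.dropna().astype(int)
    if v.empty:
        return pd.Index([])
    histogram = v.value_counts().sort_index()
    occupied = histogram.index.to_numpy()
    # connected components of occupied counts, split at gaps >= gap_bins+1
    comp_break = np.diff(occupied) > gap_bins
    comp_id = np.concatenate(([0], np.cumsum(comp_break)))
    comp_mass = {c: int(histogram[occupied[comp_id == c]].sum()) for c in np.unique(comp_id)}
    main = max(comp_mass, key=comp_mass.get)
    pruned = []
    for c, mass in comp_mass.items():
        if c != main and mass < max_fraction * len(v):
            bad_vals = set(occupied[comp_id == c])
            pruned.extend(v.index[v.isin(bad_vals)])
    return pd.Index(pruned)


def build_trait_table(
    matrix: SiteMatrix,
    max_site_na_frac: float = 0.10,
    max_strain_na_frac: float = 0.10,
    min_diff_frac: float = 0.05,
    prune_outliers: bool = True,
) -> tuple[TraitTable, dict[str, list]]:
    """TE-count traits ready for mapping, with the attrition log.

    Filters, in order: (a) drop sites NA in >= 10% of strains; (b) per
    trait, mask strains NA at >= 10% of that trait's sites; (c) drop
    all-zero traits; (d) drop traits where < 5% of strains differ from
    the modal count; (e) prune outlier strains beyond a gap in the count
    distribution when they are < 5% of strains.
    """
    n_strains = len(matrix.strains)
    na_frac = matrix.values.isna().sum(axis=1) / n_strains
    bad_sites = matrix.sites.index[na_frac >= max_site_na_frac]
    log: dict[str, list] = {"sites_dropped_na": list(bad_sites)}
    kept = matrix.subset(matrix.sites.index.difference(bad_sites, sort=False))

    table = count_traits(kept)
    counts = table.counts.astype(float)

    # (b) strain NA exposure per trait
    with np.errstate(invalid="ignore"):
        exposure = table.na_counts / table.n_sites.replace(0, np.nan)
    masked = exposure >= max_strain_na_frac
    counts = counts.mask(masked)
    log["strain_masks"] = [
        (col, list(counts.index[masked[col]])) for col in counts.columns if masked[col].any()
    ]

    drop_cols = []
    for col in counts.columns:
        v = counts[col].dropna()
        if v.empty or (v == 0).all():
            drop_cols.append((col, "all_zero"))
            continue
        modal = v.mode().iloc[0]
        if (v != modal).sum() < min_diff_frac * n_strains:
            drop_cols.append((col, "low_variation"))
    log["traits_dropped"] = drop_cols
    counts = counts.drop(columns=[c for c, _ in drop_cols])

    if prune_outliers:
        pruned_log = []
        for col in counts.columns:
            pruned = prune_outlier_strains(counts[col])
            if len(pruned):
                counts.loc[pruned, col] = np.nan
                pruned_log.append((col, list(pruned)))
        log["outliers_pruned"] = pruned_log

    if counts.shape[1] == 0:
        raise ValueError(f"no traits survive filtering; attrition: {log}")
    return (
        TraitTable(counts=counts, n_sites=table.n_sites[counts.columns],
                   na_counts=table.na_counts[counts.columns]),
        log,
    )


# ---------------------------------------------------------------------------
# kinship and the mixed-model scan


def kinship_matrix(genotypes: pd.DataFrame) -> pd.DataFrame:
    """Additive realized-relationship matrix K = Z Z' / c from {0,1}
    genotypes, with Z column-centered and c chosen so mean(diag(K)) = 1."""
    Z = genotypes.to_numpy(float)
    Z = Z - Z.mean(axis=0, keepdims=True)
    K = Z @ Z.T
    c = np.trace(K) / K.shape[0]
    if c <= 0:
        raise ValueError("genotypes have no variance; kinship undefined")
    K /= c
    return pd.DataFrame(K, index=genotypes.index, columns=genotypes.index)


def _reml_delta(y_rot: np.ndarray, x0_rot: np.ndarray, lam: np.ndarray,
                bounds: tuple[float, float] = (-12.0, 12.0)) -> float:
    """REML estimate of delta = sigma_g^2 / sigma_e^2 on the null model."""
    n, q = len(y_rot), x0_rot.shape[1]

    def neg_restricted_ll(log_delta: float) -> float:
        d = np.exp(log_delta) * lam + 1.0
        w = 1.0 / d
        xtwx = (x0_rot * w[:, None]).T @ x0_rot
        beta = np.linalg.solve(xtwx, (x0_rot * w[:, None]).T @ y_rot)
        resid = y_rot - x0_rot @ beta
        rss = float(np.sum(w * resid**2))
        sigma_e2 = rss / (n - q)
        _, logdet_xtwx = np.linalg.slogdet(xtwx)
        return 0.5 * ((n - q) * np.log(sigma_e2) + np.sum(np.log(d)) + logdet_xtwx)

    res = optimize.minimize_scalar(neg_restricted_ll, bounds=bounds, method="bounded",
                                   options={"xatol": 1e-8})
    if not res.success:
        raise RuntimeError(f"REML variance-ratio optimization failed: {res.message}")
    return float(np.exp(res.x))


def mixed_model_scan(
    trait: pd.Series,
    genotypes: pd.DataFrame,
    markers: pd.DataFrame,
    kinship: pd.DataFrame | None = None,
    maf_min: float = 0.05,
) -> pd.DataFrame:
    """Single-marker mixed-model association scan.

    ``trait``: per-strain counts (NaN strains are dropped);
    ``genotypes``: strains x markers in {0, 1}; ``markers``: metadata
    frame with columns (marker, chrom, position) in genome order.
    Returns one row per tested marker with effect, se, p and -log10 p.
    """
    y = trait.dropna()
    strains = y.index.intersection(genotypes.index)
    if y[strains].std() == 0:
        raise ValueError("trait is constant; nothing to map")
    y = y[strains].to_numpy(float)
    G = genotypes.loc[strains]
    if kinship is None:
        K = kinship_matrix(G).to_numpy()
    else:
        K = kinship.loc[strains, strains].to_numpy(float)

    freq = G.mean(axis=0)
    maf = np.minimum(freq, 1 - freq)
    tested = G.columns[maf >= maf_min]
    X = G[tested].to_numpy(float)
    n = len(y)

    lam, U = np.linalg.eigh(K)
    lam = np.clip(lam, 0.0, None)
    y_rot = U.T @ y
    ones_rot = U.T @ np.ones(n)
    delta = _reml_delta(y_rot, ones_rot[:, None], lam)
    w = 1.0 / (delta * lam + 1.0)

    X_rot = U.T @ X
    a11 = float(np.sum(w * ones_rot**2))
    a12 = (w * ones_rot) @ X_rot
    a22 = np.sum(w[:, None] * X_rot**2, axis=0)
    b1 = float(np.sum(w * ones_rot * y_rot))
    b2 = (w * y_rot) @ X_rot
    yy = float(np.sum(w * y_rot**2))
    det = a11 * a22 - a12**2
    with np.errstate(divide="ignore", invalid="ignore"):
        beta1 = (a22 * b1 - a12 * b2) / det
        beta2 = (a11 * b2 - a12 * b1) / det
        rss = yy - (beta1 * b1 + beta2 * b2)
        sigma2 = rss / (n - 2)
        se = np.sqrt(sigma2 * a11 / det)
        tstat = beta2 / se
    p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    out = markers.set_index("marker").loc[tested].rename_axis("marker").reset_index()
    out["effect"] = beta2
    out["se"] = se
    out["p"] = p
    with np.errstate(divide="ignore"):
        out["neglog10p"] = -np.log10(p)
    out["maf"] = maf[tested].to_numpy()
    out["delta"] = delta
    return out


# ---------------------------------------------------------------------------
# QTL definition and filters


@dataclass
class QTLResult:
    trait: object
    chrom: str
    peak_marker: str
    peak_index: int  # genome-order index into the tested-marker list
    peak_p: float
    peak_neglog10p: float
    sig_markers: list[str]
    sig_indices: list[int]
    interval_index: tuple[int, int]
    interval_bp: tuple[int, int]
    flags: dict = field(default_factory=dict)
    finemap: pd.DataFrame | None = None


def define_qtl(
    scan: pd.DataFrame,
    alpha: float = 0.05,
    group_snvs: int = 300,
    interval_markers: int = 50,
    trait: object = None,
) -> list[QTLResult]:
    """Group Bonferroni-significant markers into QTL.

    Threshold = alpha / n tested markers; significant markers on one
    chromosome join a peak when their genome-order index separation is
    < ``group_snvs``; the interval spans first-to-last significant
    marker extended by ``interval_markers`` indices each side, clipped
    at the chromosome.
    """
    n_tested = len(scan)
    if n_tested == 0:
        return []
    threshold = alpha / n_tested
    scan = scan.reset_index(drop=True)
    sig = scan.index[scan["p"] < threshold]
    results: list[QTLResult] = []
    if len(sig) == 0:
        return results
    for chrom in scan.loc[sig, "chrom"].unique():
        chrom_all = scan.index[scan["chrom"] == chrom]
        lo_idx, hi_idx = int(chrom_all.min()), int(chrom_all.max())
        csig = np.array([i for i in sig if scan.loc[i, "chrom"] == chrom])
        breaks = np.diff(csig) >= group_snvs
        gid = np.concatenate(([0], np.cumsum(breaks)))
        for g in np.unique(gid):
            members = csig[gid == g]
            sub = scan.loc[members]
            peak = sub.loc[sub["neglog10p"].idxmax()]
            left = max(int(members.min()) - interval_markers, lo_idx)
            right = min(int(members.max()) + interval_markers, hi_idx)
            results.append(QTLResult(
                trait=trait,
                chrom=str(chrom),
                peak_marker=str(peak["marker"]),
                peak_index=int(sub["neglog10p"].idxmax()),
                peak_p=float(peak["p"]),
                peak_neglog10p=float(peak["neglog10p"]),
                sig_markers=[str(m) for m in sub["marker"]],
                sig_indices=[int(i) for i in members],
                interval_index=(left, right),
                interval_bp=(int(scan.loc[left, "position"]), int(scan.loc[right, "position"])),
            ))
    return results


def sites_to_marker_indices(
    site_positions: pd.DataFrame, scan: pd.DataFrame
) -> list[int]:
    """Map TE site positions onto the tested-marker index scale (nearest
    marker on the same chromosome)."""
    scan = scan.reset_index(drop=True)
    out = []
    for chrom, grp in site_positions.groupby("chrom"):
        cmarkers = scan[scan["chrom"] == chrom]
        if cmarkers.empty:
            continue
        mpos = cmarkers["position"].to_numpy()
        midx = cmarkers.index.to_numpy()
        for pos in grp["position"]:
            j = np.searchsorted(mpos, pos)
            cand = [k for k in (j - 1, j) if 0 <= k < len(mpos)]
            best = min(cand, key=lambda k: abs(mpos[k] - pos))
            out.append(int(midx[best]))
    return out


def cis_proximity_filter(
    qtl: QTLResult, te_marker_indices: list[int], cis_markers: int = 100
) -> bool:
    """True (flag: likely cis / linked to the counted sites themselves)
    iff the peak lies within ``cis_markers`` marker indices of any
    high-density TE site of the mapped trait's family and site type."""
    flag = any(abs(qtl.peak_index - i) <= cis_markers for i in te_marker_indices)
    qtl.flags["cis_proximal"] = flag
    return flag


def median_split_filter(
    qtl: QTLResult, trait: pd.Series, peak_genotype: pd.Series
) -> bool:
    """True (QTL removed) iff the median trait value is identical in the
    two peak-marker genotype groups."""
    strains = trait.dropna().index.intersection(peak_genotype.index)
    g = peak_genotype[strains]
    groups = sorted(g.unique())
    if len(groups) < 2:
        raise ValueError("peak marker is monomorphic among phenotyped strains")
    medians = [trait[strains][g == a].median() for a in groups]
    removed = bool(medians[0] == medians[1])
    qtl.flags["median_split_fail"] = removed
    return removed


def finemap_correlations(
    qtl: QTLResult,
    variants: pd.DataFrame,
    variant_genotypes: pd.DataFrame,
    trait: pd.Series,
    effects: tuple[str, ...] = ("moderate", "severe"),
    quantile: float = 0.90,
) -> pd.DataFrame:
    """Spearman correlation of the trait with every moderate/severe
    variant in the QTL interval; |rho| strictly above the 90th
    percentile of computed |rho| is marked ``reported``."""
    lo, hi = qtl.interval_bp
    inside = variants[
        (variants["chrom"] == qtl.chrom)
        & (variants["position"] >= lo)
        & (variants["position"] <= hi)
        & (variants["effect"].isin(effects))
    ]
    rows = []
    strains = trait.dropna().index
    for _, v in inside.iterrows():
        g = variant_genotypes[v["variant_id"]].reindex(strains)
        ok = g.notna()
        if g[ok].nunique() < 2:
            rho = np.nan
        else:
            rho = float(stats.spearmanr(trait[strains][ok], g[ok])[0])
        rows.append((v["variant_id"], v["gene"], v["effect"], rho))
    fm = pd.DataFrame(rows, columns=["variant_id", "gene", "effect", "rho"])
    if len(fm) < 2:
        warnings.warn("fewer than 2 variants in interval; all reported", stacklevel=2)
        fm["reported"] = True
    else:
        cut = float(np.nanquantile(fm["rho"].abs(), quantile))
        fm["reported"] = fm["rho"].abs() > cut
    qtl.finemap = fm
    return fm


def pirna_in_interval(
    qtl: QTLResult, pirna_positions: pd.DataFrame, has_variation: pd.Series
) -> list[str]:
    """piRNAs inside the QTL interval that vary across the strain set.

    ``pirna_positions``: frame (pirna_id, chrom, position);
    ``has_variation``: boolean per pirna_id."""
    lo, hi = qtl.interval_bp
    inside = pirna_positions[
        (pirna_positions["chrom"] == qtl.chrom)
        & (pirna_positions["position"] >= lo)
        & (pirna_positions["position"] <= hi)
    ]
    return [pid for pid in inside["pirna_id"] if bool(has_variation.get(pid, False))]
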