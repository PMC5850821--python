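"""Rare-variant correlation with extreme TE copy-number strains.

Association scans only see common variation; a strain whose TE count is
wildly elevated because of a private defect in a transposon-control
gene is invisible to them.  This module flags strains at least
``k_sd`` (default 4) sample standard deviations above the trait mean,
collects rare (AF <= 10%) predicted-deleterious variants those strains
carry in TE-control and piRNA genes, and grades the non-synonymous ones
with Grantham scores.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .grantham import GranthamResult, grantham_category, grantham_score  # noqa: F401
from .popgen import TraitTable

logger = logging.getLogger(__name__)

OUTLIER_COLUMNS = ["trait", "strain", "count", "mean", "sd", "threshold"]


def detect_outlier_strains(
    traits: TraitTable | pd.DataFrame,
    n_sites: pd.Series | None = None,
    k_sd: float = 4.0,
) -> pd.DataFrame:
    """Strains with trait count >= mean + k_sd * sd (one-sided upper).

    Mean and sd (n-1 denominator) are taken over non-NA strains.  Traits
    backed by fewer than 2 TE sites are skipped — a 4-sd cutoff on a
    single site is uninformative.  sd = 0 yields no outliers.
    """
    if isinstance(traits, TraitTable):
        counts, n_sites = traits.counts, traits.n_sites
    else:
        counts = traits
    rows = []
    for col in counts.columns:
        if n_sites is not None and n_sites.get(col, 2) < 2:
            continue
        v = counts[col].dropna().astype(float)
        if len(v) < 2:
            continue
        mean, sd = v.mean(), v.std(ddof=1)
        if sd == 0:
            logger.info("trait %s has zero variance; no outliers", col)
            continue
        threshold = mean + k_sd * sd
        for strain, count in v[v >= threshold].items():
            rows.append((col, strain, count, mean, sd, threshold))
    return pd.DataFrame(rows, columns=OUTLIER_COLUMNS)


def rare_variant_filter(
    variants: pd.DataFrame,
    variant_genotypes: pd.DataFrame,
    outliers: pd.DataFrame,
    gene_list: pd.DataFrame,
    rare_af_max: float = 0.10,
    effects: tuple[str, ...] = ("moderate", "severe"),
) -> pd.DataFrame:
    """Rare, predicted-deleterious variants carried by outlier strains.

    Keeps variants with AF <= ``rare_af_max``, effect in ``effects``
    (piRNA-class genes bypass the severity filter: piRNA loci have no
    protein-effect prediction), gene in ``gene_list`` (columns gene,
    gene_class), and at least one flagged outlier strain carrying the
    alternate allele.
    """
    if gene_list.empty:
        raise ValueError("gene list is empty")
    classes = gene_list.set_index("gene")["gene_class"]
    outlier_strains = set(outliers["strain"])
    keep = []
    for _, v in variants.iterrows():
        if v["gene"] not in classes.index:
            continue
        if v["af"] > rare_af_max:
            continue
        if classes[v["gene"]] != "pirna" and v["effect"] not in effects:
            continue
        g = variant_genotypes[v["variant_id"]]
        carriers = set(g.index[g == 1])
        hit = carriers & outlier_strains
        if hit:
            row = v.to_dict()
            row["outlier_carriers"] = sorted(hit)
            row["gene_class"] = classes[v["gene"]]
            keep.append(row)
    return pd.DataFrame(keep)


def build_outlier_report(
    outliers: pd.DataFrame, rare_variants: pd.DataFrame
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Join outlier strains to their rare variants with Grantham grades.

    Returns the long report (one row per trait x strain x variant) and
    the percentage histogram of Grantham categories over all distinct
    non-synonymous variants in the report.
    """
    rows = []
    for _, o in outliers.iterrows():
        if rare_variants.empty:
            continue
        mine = rare_variants[[o["strain"] in c for c in rare_variants["outlier_carriers"]]]
        for _, v in mine.iterrows():
            score, category = np.nan, pd.NA
            if (
                pd.notna(v.get("ref_aa"))
                and pd.notna(v.get("alt_aa"))
                and v.get("gene_class") != "pirna"
            ):
                g = grantham_score(v["ref_aa"], v["alt_aa"])
                score, category = g.score, g.category
            rows.append({
                "trait": o["trait"], "strain": o["strain"], "count": o["count"],
                "gene": v["gene"], "gene_class": v["gene_class"], "variant_id": v["variant_id"],
                "effect": v["effect"], "af": v["af"],
                "grantham_score": score, "grantham_category": category,
            })
    report = pd.DataFrame(rows)
    histogram: dict[str, float] = {}
    if not report.empty:
        graded = report.dropna(subset=["grantham_score"]).drop_duplicates("variant_id")
        if len(graded):
            fractions = graded["grantham_category"].value_counts(normalize=True)
            histogram = {k: round(100.0 * v, 1) for k, v in fractions.items()}
    return report, histogram
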