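"""Genomic-feature annotation of TE sites.

Every site gets exactly one feature label by the priority order
CDS > UTR > promoter > intron > intergenic (a position inside the CDS
of one isoform and the intron of another is a CDS hit), the biotype of
the gene supplying the winning label, an arm/center label from the
chromosome's recombination-domain breakpoints, and an essential-gene
flag for CDS hits in genes whose RNAi phenotype contains any of the
canonical severity keywords.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .synth.genome import ESSENTIAL_KEYWORDS, GeneModels

FEATURE_PRIORITY = {"CDS": 0, "UTR": 1, "promoter": 2, "intron": 3}
INTERGENIC = "intergenic"

ANNOTATION_COLUMNS = ["feature", "gene_id", "biotype", "arm_center", "essential_flag"]

PROMOTER_BP = 2000


def derive_promoters(genes: pd.DataFrame, layout: pd.DataFrame) -> pd.DataFrame:
    """Promoter = up to 2 kb upstream of the gene start on its strand,
    truncated at the nearest gene boundary (either strand) when closer,
    and clipped at chromosome ends.  Returns (gene_id, chrom, start, end);
    genes whose promoter space is fully occupied yield no row."""
    chrom_len = dict(zip(layout["chrom"], layout["length"]))
    rows = []
    for chrom, grp in genes.groupby("chrom"):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        for gid, g in grp.iterrows():
            if g["strand"] == "+":
                upstream_ends = ends[ends < g["start"]]
                floor = int(upstream_ends.max()) + 1 if len(upstream_ends) else 1
                lo = max(g["start"] - PROMOTER_BP, floor, 1)
                hi = g["start"] - 1
            else:
                downstream_starts = starts[starts > g["end"]]
                ceil_ = int(downstream_starts.min()) - 1 if len(downstream_starts) else chrom_len[chrom]
                hi = min(g["end"] + PROMOTER_BP, ceil_, chrom_len[chrom])
                lo = g["end"] + 1
            if lo <= hi:
                rows.append((gid, chrom, int(lo), int(hi)))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])


def _feature_trees(
    gene_models: GeneModels, promoters: pd.DataFrame
) -> dict[str, IntervalTree]:
    """One interval tree per chromosome; payload (priority, gene_start,
    gene_id, pooled_label)."""
    trees: dict[str, IntervalTree] = {}
    gene_start = gene_models.genes["start"]

    def add(chrom, start, end, label, gid):
        pooled = "UTR" if label.endswith("UTR") else label
        trees.setdefault(chrom, IntervalTree()).addi(
            int(start), int(end) + 1, (FEATURE_PRIORITY[pooled], int(gene_start[gid]), gid, pooled)
        )

    for _, f in gene_models.features.iterrows():
        if f["feature"] in ("CDS", "intron") or f["feature"].endswith("UTR"):
            add(f["chrom"], f["start"], f["end"], f["feature"], f["gene_id"])
    for _, p in promoters.iterrows():
        add(p["chrom"], p["start"], p["end"], "promoter", p["gene_id"])
    return trees


def assign_features(
    sites: pd.DataFrame,
    gene_models: GeneModels,
    layout: pd.DataFrame,
    promoters: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Feature + biotype assignment for sites (columns chrom, position).

    Returns a frame aligned to ``sites.index`` with ``feature``,
    ``gene_id`` (NA when intergenic) and ``biotype`` (gene biotype, NA
    when intergenic).
    """
    if promoters is None:
        promoters = derive_promoters(gene_models.genes, layout)
    chrom_len = dict(zip(layout["chrom"], layout["length"]))
    trees = _feature_trees(gene_models, promoters)
    biotype = gene_models.genes["biotype"] if len(gene_models.genes) else pd.Series(dtype=object)
    feats, gids, bios = [], [], []
    for _, row in sites.iterrows():
        chrom, pos = row["chrom"], int(row["position"])
        if chrom not in chrom_len or not 1 <= pos <= chrom_len[chrom]:
            raise ValueError(f"position {chrom}:{pos} outside chromosome bounds")
        hits = trees.get(chrom, IntervalTree())[pos]
        if not hits:
            feats.append(INTERGENIC)
            gids.append(pd.NA)
            bios.append(pd.NA)
            continue
        prio, _, gid, label = min(h.data for h in hits)  # (priority, gene_start, ...) tie-break
        feats.append(label)
        gids.append(gid)
        bios.append(biotype[gid])
    return pd.DataFrame(
        {"feature": feats, "gene_id": gids, "biotype": bios}, index=sites.index
    )


def classify_arm_center(sites: pd.DataFrame, layout: pd.DataFrame) -> pd.Series:
    """'arm' iff position <= arm_left_end or position > center_end."""
    lay = layout.set_index("chrom")
    aL = lay["arm_left_end"].reindex(sites["chrom"]).to_numpy()
    cE = lay["center_end"].reindex(sites["chrom"]).to_numpy()
    pos = sites["position"].to_numpy()
    is_arm = (pos <= aL) | (pos > cE)
    return pd.Series(np.where(is_arm, "arm", "center"), index=sites.index, name="arm_center")


def flag_essential_insertions(
    assignments: pd.DataFrame, genes: pd.DataFrame, keywords=ESSENTIAL_KEYWORDS
) -> pd.Series:
    """True for CDS-feature sites in genes whose phenotype string contains
    any severity keyword (case-insensitive substring)."""
    phen = genes["phenotype"].fillna("").str.lower() if len(genes) else pd.Series(dtype=object)

    def is_essential(row) -> bool:
        if row["feature"] != "CDS" or pd.isna(row["gene_id"]):
            return False
        text = phen.get(row["gene_id"], "")
        return any(k in text for k in keywords)

    return assignments.apply(is_essential, axis=1).rename("essential_flag")


def annotate_sites(
    sites: pd.DataFrame, gene_models: GeneModels, layout: pd.DataFrame
) -> pd.DataFrame:
    """Full annotation: feature, gene, biotype, arm/center, essential flag."""
    promoters = derive_promoters(gene_models.genes, layout)
    out = assign_features(sites, gene_models, layout, promoters)
    out["arm_center"] = classify_arm_center(sites, layout)
    out["essential_flag"] = flag_essential_insertions(out, gene_models.genes)
    return out[ANNOTATION_COLUMNS]
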