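"""Readers and writers for the pipeline's on-disk formats.

Plain-text only: TSV tables, BED (0-based half-open; internal
coordinates are 1-based inclusive), GFF3 gene models and FASTA
sequences.  Every writer has a matching reader that round-trips the
in-memory objects.
"""

from __future__ import annotations

import os
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .calls import CALL_COLUMNS, empty_calls
from .coverage import DEFAULT_WINDOW
from .matrix import SiteMatrix
from .synth.genome import LAYOUT_COLUMNS, GeneModels
from .synth.population import REF_ANNOTATION_COLUMNS

# --- layout ----------------------------------------------------------------


def write_layout(layout: pd.DataFrame, path) -> None:
    layout[LAYOUT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_layout(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


# --- TE families -----------------------------------------------------------


def write_families(families: pd.DataFrame, tsv_path, fasta_path) -> None:
    families.drop(columns="consensus").to_csv(tsv_path, sep="\t")
    records = [
        SeqRecord(Seq(row["consensus"]), id=str(name), description="")
        for name, row in families.iterrows()
    ]
    SeqIO.write(records, fasta_path, "fasta")


def read_families(tsv_path, fasta_path) -> pd.DataFrame:
    fam = pd.read_csv(tsv_path, sep="\t", index_col="family")
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    fam["consensus"] = pd.Series(seqs).reindex(fam.index)
    return fam


# --- gene models (GFF3) ----------------------------------------------------

_GFF_TYPE = {"CDS": "CDS", "five_prime_UTR": "five_prime_UTR",
             "three_prime_UTR": "three_prime_UTR", "intron": "intron"}


def write_gff3(models: GeneModels, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gid, g in models.genes.iterrows():
            attrs = f"ID={gid};biotype={g['biotype']}"
            if g["phenotype"]:
                attrs += f";phenotype={g['phenotype']}"
            fh.write("\t".join([
                str(g["chrom"]), "tepop", "gene", str(g["start"]), str(g["end"]),
                ".", g["strand"], ".", attrs,
            ]) + "\n")
            tid = f"{gid}.t1"
            fh.write("\t".join([
                str(g["chrom"]), "tepop", "mRNA", str(g["start"]), str(g["end"]),
                ".", g["strand"], ".", f"ID={tid};Parent={gid}",
            ]) + "\n")
            feats = models.features[models.features["gene_id"] == gid]
            for k, (_, f) in enumerate(feats.iterrows()):
                fh.write("\t".join([
                    str(f["chrom"]), "tepop", _GFF_TYPE[f["feature"]],
                    str(f["start"]), str(f["end"]), ".", g["strand"], ".",
                    f"ID={tid}.f{k};Parent={tid}",
                ]) + "\n")


def read_gff3(path) -> GeneModels:
    db = gffutils.create_db(str(path), dbfn=":memory:", force=True, keep_order=True,
                            merge_strategy="create_unique")
    gene_rows, feat_rows = {}, []
    for gene in db.features_of_type("gene"):
        gid = gene.id
        gene_rows[gid] = (
            gene.seqid, gene.start, gene.end, gene.strand,
            gene.attributes.get("biotype", ["protein_coding"])[0],
            gene.attributes.get("phenotype", [""])[0],
        )
        for tr in db.children(gene, featuretype="mRNA"):
            for f in db.children(tr):
                if f.featuretype in _GFF_TYPE.values():
                    feat_rows.append((gid, f.seqid, f.start, f.end, f.featuretype))
    genes = pd.DataFrame.from_dict(
        gene_rows, orient="index",
        columns=["chrom", "start", "end", "strand", "biotype", "phenotype"],
    )
    genes.index.name = "gene_id"
    features = pd.DataFrame(feat_rows, columns=["gene_id", "chrom", "start", "end", "feature"])
    return GeneModels(genes=genes, features=features)


# --- reference TE annotation (BED) -----------------------------------------


def write_reference_bed(ref_annotation: pd.DataFrame, path) -> None:
    """BED with 0-based half-open coordinates; name = family."""
    bed = pd.DataFrame({
        "chrom": ref_annotation["chrom"],
        "start": ref_annotation["position"] - 1,
        "end": ref_annotation["position"] - 1 + ref_annotation["length"],
        "name": ref_annotation["family"],
        "score": 0,
        "strand": "+",
    })
    bed.to_csv(path, sep="\t", index=False, header=False)


def read_reference_bed(path, families: pd.DataFrame | None = None) -> pd.DataFrame:
    bed = pd.read_csv(path, sep="\t", header=None,
                      names=["chrom", "start", "end", "name", "score", "strand"],
                      dtype={"chrom": str})
    out = pd.DataFrame({
        "chrom": bed["chrom"],
        "position": bed["start"] + 1,
        "family": bed["name"],
        "length": bed["end"] - bed["start"],
    })
    if families is not None:
        out["te_class"] = families["te_class"].reindex(out["family"]).fillna("unknown").to_numpy()
    else:
        out["te_class"] = "unknown"
    return out[REF_ANNOTATION_COLUMNS]


# --- calls and coverage ----------------------------------------------------


def write_calls(calls_by_strain: dict[str, pd.DataFrame], directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for strain, df in calls_by_strain.items():
        df[CALL_COLUMNS].to_csv(directory / f"{strain}.tsv", sep="\t", index=False)


def read_calls(directory) -> dict[str, pd.DataFrame]:
    out = {}
    for name in sorted(os.listdir(directory)):
        if not name.endswith(".tsv"):
            continue
        df = pd.read_csv(Path(directory) / name, sep="\t", dtype={"chrom": str})
        out[name[:-4]] = df if len(df) else empty_calls()
    return out


def write_coverage(tracks: dict[str, dict[str, np.ndarray]], directory,
                   window: int = DEFAULT_WINDOW) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for strain, per_chrom in tracks.items():
        rows = []
        for chrom, depth in per_chrom.items():
            starts = np.arange(len(depth)) * window
            rows.append(pd.DataFrame({"chrom": chrom, "start": starts,
                                      "end": starts + window, "depth": depth}))
        pd.concat(rows, ignore_index=True).to_csv(
            directory / f"{strain}.tsv", sep="\t", index=False)


def read_coverage(directory) -> dict[str, dict[str, np.ndarray]]:
    out: dict[str, dict[str, np.ndarray]] = {}
    for name in sorted(os.listdir(directory)):
        if not name.endswith(".tsv"):
            continue
        df = pd.read_csv(Path(directory) / name, sep="\t", dtype={"chrom": str})
        out[name[:-4]] = {
            chrom: grp.sort_values("start")["depth"].to_numpy()
            for chrom, grp in df.groupby("chrom")
        }
    return out


# --- genotypes and piRNAs ---------------------------------------------------


def write_genotypes(genotypes: pd.DataFrame, markers: pd.DataFrame,
                    genotype_path, marker_path) -> None:
    genotypes.rename_axis("strain").to_csv(genotype_path, sep="\t")
    markers.to_csv(marker_path, sep="\t", index=False)


def read_genotypes(genotype_path, marker_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    genotypes = pd.read_csv(genotype_path, sep="\t", index_col="strain")
    markers = pd.read_csv(marker_path, sep="\t", dtype={"chrom": str})
    return genotypes, markers


def write_pirnas(pirnas: pd.DataFrame, path) -> None:
    records = [
        SeqRecord(Seq(row["sequence"]), id=str(pid), description="")
        for pid, row in pirnas.iterrows()
    ]
    SeqIO.write(records, path, "fasta")


def read_pirnas(path) -> pd.Series:
    return pd.Series({rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")},
                     name="sequence")


# --- site matrix ------------------------------------------------------------


def write_site_matrix(matrix: SiteMatrix, path) -> None:
    """Rows = _NR/_R-suffixed site ids, columns = strains, values 0/1/NA."""
    out = matrix.values.copy()
    out.insert(0, "family", matrix.sites["family"])
    out.rename_axis("site_id").to_csv(path, sep="\t", na_rep="NA")


def read_site_matrix(path, families: pd.DataFrame | None = None) -> SiteMatrix:
    df = pd.read_csv(path, sep="\t", index_col="site_id", na_values="NA")
    family = df.pop("family")
    parts = pd.Series(df.index, index=df.index).str.rsplit("_", n=3)
    sites = pd.DataFrame({
        "chrom": parts.str[0],
        "position": parts.str[1].astype(int),
        "family": family,
        "site_type": np.where(parts.str[3] == "NR", "insertion", "reference"),
    }, index=df.index)
    if families is not None:
        sites["te_class"] = families["te_class"].reindex(sites["family"]).fillna("unknown").to_numpy()
    else:
        sites["te_class"] = "unknown"
    vals = df.astype(float)
    ref = sites["site_type"] == "reference"
    has_zero = (vals == 0.0).any(axis=1)
    ref_class = np.where(has_zero, "active", "monomorphic").astype(object)
    ref_class[~ref.to_numpy()] = np.nan
    sites["ref_class"] = ref_class
    return SiteMatrix(sites[["chrom", "position", "family", "te_class", "site_type",
                             "ref_class"]], vals)
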