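"""Synthetic genome scaffolds: chromosome layout, TE families, gene models.

The layout mimics the holocentric nematode chromosome organisation used
throughout the pipeline: each chromosome is split into two gene-poor,
high-recombination *arms* flanking a gene-dense *center*, with the arm
fraction configurable.  TE families carry a class (cut-and-paste DNA
transposon, copy-and-paste retrotransposon, or unknown), a consensus
sequence and the length of the longest known element of the family —
the quantity the harmonizer's redundant-call collapse rule depends on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CHROM_NAMES = ["I", "II", "III", "IV", "V", "X"]

TE_CLASSES = ("dna", "retro", "unknown")

#: RNAi-phenotype keywords that mark a gene as essential downstream.
ESSENTIAL_KEYWORDS = ("arrest", "lethal", "sterile", "slow growth", "sick", "severe")

_BENIGN_PHENOTYPES = ("dumpy", "uncoordinated", "roller", "long", "clear")
_SEVERE_PHENOTYPES = (
    "embryonic lethal",
    "larval arrest",
    "sterile progeny",
    "slow growth",
    "sick",
    "larval lethal",
)

LAYOUT_COLUMNS = ["chrom", "length", "arm_left_end", "center_end"]


def _chrom_names(n: int) -> list[str]:
    if n <= len(CHROM_NAMES):
        return CHROM_NAMES[:n]
    return CHROM_NAMES + [f"chr{i}" for i in range(len(CHROM_NAMES) + 1, n + 1)]


def make_genome_layout(
    n_chrom: int, lengths: list[int], arm_fraction: float = 0.5, seed: int = 0
) -> pd.DataFrame:
    """Build a chromosome table with arm/center breakpoints.

    Arms are ``[1, arm_left_end]`` and ``(center_end, length]``; jointly
    they cover ``arm_fraction`` of each chromosome (to rounding).
    Deterministic; ``seed`` is accepted for interface uniformity.
    """
    if not 0 < arm_fraction < 1:
        raise ValueError("arm_fraction must be in (0, 1)")
    if len(lengths) != n_chrom:
        raise ValueError("lengths must have n_chrom entries")
    rows = []
    for name, length in zip(_chrom_names(n_chrom), lengths):
        length = int(length)
        if length <= 0:
            raise ValueError(f"chromosome length must be positive, got {length}")
        arm_bp = int(round(length * arm_fraction))
        left = arm_bp // 2
        right = arm_bp - left
        arm_left_end = max(1, left)
        center_end = min(length - 1, length - right)
        if not 1 <= arm_left_end < center_end <= length:
            raise ValueError("chromosome too short for the requested arm fraction")
        rows.append((name, length, arm_left_end, center_end))
    return pd.DataFrame(rows, columns=LAYOUT_COLUMNS)


def arm_bp(layout_row: pd.Series) -> int:
    """Base pairs covered by the two arms of one chromosome."""
    return int(layout_row["arm_left_end"]) + int(layout_row["length"] - layout_row["center_end"])


def make_te_families(
    n_families: int,
    class_mix: dict[str, float],
    length_range: tuple[int, int] = (100, 2000),
    seed: int = 0,
) -> pd.DataFrame:
    """Draw TE families with random consensus sequences.

    Returns a frame indexed by family name with columns ``te_class``,
    ``consensus`` and ``longest_element_length``.  Consensus lengths are
    uniform in ``length_range``; families shorter than 100 bp are
    disallowed because short elements cannot be called reliably.
    """
    if abs(sum(class_mix.values()) - 1.0) > 1e-9:
        raise ValueError("class_mix proportions must sum to 1")
    unknown = set(class_mix) - set(TE_CLASSES)
    if unknown:
        raise ValueError(f"unknown TE classes: {sorted(unknown)}")
    lo, hi = length_range
    if lo < 100:
        raise ValueError("consensus length lower bound must be >= 100 bp")
    rng = np.random.default_rng(seed)
    classes = list(class_mix)
    probs = np.array([class_mix[c] for c in classes], dtype=float)
    drawn = rng.choice(classes, size=n_families, p=probs)
    alphabet = np.array(list("ACGT"))
    rows = {}
    for i, te_class in enumerate(drawn):
        length = int(rng.integers(lo, hi + 1))
        consensus = "".join(rng.choice(alphabet, size=length))
        rows[f"fam{i:03d}"] = (te_class, consensus, length)
    fam = pd.DataFrame.from_dict(
        rows, orient="index", columns=["te_class", "consensus", "longest_element_length"]
    )
    fam.index.name = "family"
    return fam


@dataclass
class GeneModels:
    """Gene spans plus per-transcript sub-features.

    ``genes`` is indexed by gene id with columns ``chrom, start, end,
    strand, biotype, phenotype``; ``features`` holds one row per CDS /
    UTR / intron interval (1-based inclusive coordinates).
    """

    genes: pd.DataFrame
    features: pd.DataFrame = field(default_factory=pd.DataFrame)


_FEATURE_COLUMNS = ["gene_id", "chrom", "start", "end", "feature"]


def _gene_structure(start: int, end: int, rng: np.random.Generator) -> list[tuple[int, int, str]]:
    """Split a gene span into 5'UTR, CDS, intron, CDS, 3'UTR (plus-strand order)."""
    length = end - start + 1
    utr5 = max(30, int(0.06 * length))
    utr3 = max(30, int(0.08 * length))
    body = length - utr5 - utr3
    intron = max(40, int(body * rng.uniform(0.2, 0.4)))
    cds1 = (body - intron) // 2
    cds2 = body - intron - cds1
    pos = start
    parts = []
    for span, label in [
        (utr5, "five_prime_UTR"),
        (cds1, "CDS"),
        (intron, "intron"),
        (cds2, "CDS"),
        (utr3, "three_prime_UTR"),
    ]:
        parts.append((pos, pos + span - 1, label))
        pos += span
    return parts


def make_gene_models(
    layout: pd.DataFrame,
    gene_density: float,
    seed: int = 0,
    essential_fraction: float = 0.15,
    biotype_probs: dict[str, float] | None = None,
    max_tries: int = 50,
) -> GeneModels:
    """Place non-overlapping stranded genes at ``gene_density`` genes/Mb.

    A fraction of protein-coding genes is tagged with an RNAi-phenotype
    keyword string (e.g. "embryonic lethal") so the annotation module's
    essential-gene flagging is exercisable; the rest get benign
    phenotype strings or none.
    """
    if gene_density < 0:
        raise ValueError("gene density must be >= 0")
    if biotype_probs is None:
        biotype_probs = {"protein_coding": 0.85, "pseudogene": 0.10, "other": 0.05}
    rng = np.random.default_rng(seed)
    biotypes = list(biotype_probs)
    bprobs = np.array([biotype_probs[b] for b in biotypes], dtype=float)
    gene_rows: dict[str, tuple] = {}
    feat_rows: list[tuple] = []
    idx = 0
    for _, chrom_row in layout.iterrows():
        chrom, length = chrom_row["chrom"], int(chrom_row["length"])
        n_genes = int(round(gene_density * length / 1e6))
        if n_genes == 0:
            continue
        for attempt in range(max_tries):
            sizes = rng.integers(1500, 6000, size=n_genes)
            gap = 200  # room so promoters/intergenic space exist
            if sizes.sum() + gap * (n_genes + 1) > length:
                if attempt == max_tries - 1:
                    raise RuntimeError(
                        f"cannot place {n_genes} non-overlapping genes on {chrom} "
                        f"({length} bp) at density {gene_density}/Mb"
                    )
                continue
            free = length - int(sizes.sum()) - gap * (n_genes + 1)
            cuts = np.sort(rng.integers(0, free + 1, size=n_genes))
            starts = cuts + gap + np.concatenate(([0], np.cumsum(sizes[:-1] + gap))) + 1
            break
        for size, start in zip(sizes, starts):
            gene_id = f"gene{idx:04d}"
            idx += 1
            end = int(start + size - 1)
            strand = "+" if rng.random() < 0.5 else "-"
            biotype = str(rng.choice(biotypes, p=bprobs))
            if biotype == "protein_coding" and rng.random() < essential_fraction:
                phenotype = str(rng.choice(_SEVERE_PHENOTYPES))
            elif rng.random() < 0.5:
                phenotype = str(rng.choice(_BENIGN_PHENOTYPES))
            else:
                phenotype = ""
            gene_rows[gene_id] = (chrom, int(start), end, strand, biotype, phenotype)
            parts = _gene_structure(int(start), end, rng)
            if strand == "-":  # mirror labels so the 5' UTR sits at the high end
                labels = [p[2] for p in parts][::-1]
                parts = [(s, e, lab) for (s, e, _), lab in zip(parts, labels)]
            for s, e, lab in parts:
                feat_rows.append((gene_id, chrom, s, e, lab))
    genes = pd.DataFrame.from_dict(
        gene_rows, orient="index", columns=["chrom", "start", "end", "strand", "biotype", "phenotype"]
    )
    genes.index.name = "gene_id"
    features = pd.DataFrame(feat_rows, columns=_FEATURE_COLUMNS)
    return GeneModels(genes=genes, features=features)
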