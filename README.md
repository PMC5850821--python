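# tepop

Transposable-element (TE) population genomics for inbred nematode
panels: from raw TE-caller output to presence/absence genotypes,
population statistics and TE-count QTL.

## The problem

Wild *Caenorhabditis elegans* isolates differ widely in how many
transposons they carry and where those transposons sit.  Split-read
callers (TEMP / TE-Locate style) emit per-strain tables of *insertion*
calls (a TE present in the strain but not the reference genome),
*reference* calls (an annotated reference TE confirmed present) and
*absence* calls (a reference TE excised).  That raw output is noisy:
positions jitter by a few base pairs, reference calls land up to a
kilobase from the annotated element, one deletion call can span several
adjacent TEs, and the reference and absence callers regularly contradict
each other at the same site.  `tepop` turns those tables into a clean
strains × sites matrix with values 1 / 0 / NA and then asks the
population-genetic questions that matrix supports: how rare are
insertions, where do they land, which genomic regions are TE hotspots,
what common and rare genetic variation modulates TE copy number, and
which piRNAs could be silencing which TE families.

The package is aimed at statistical-genetics users working with selfing
(isotype) panels, where every strain is effectively homozygous and
genotypes are coded {0, 1}.

## What is inside

| module | does |
| --- | --- |
| `tepop.synth` | generates every input — genome layout with arm/center domains, TE families with consensus sequences, gene models (GFF3), truth TE landscapes with a calibrated site-frequency spectrum, noisy caller output, coverage tracks, structured SNV panels with planted QTL, piRNA sets with planted complements |
| `tepop.harmonize` | collapse / position-adjust / span-split / filter / dedupe / contradiction-resolve per strain, 50-bp single-linkage merge across strains, 8×-coverage NA scoring, active vs monomorphic reference classification |
| `tepop.benchmark` | nearest-event truth matching, TPR/FDR, threshold sweeps, filter-impact percentages |
| `tepop.annotate` | promoter derivation (2 kb, truncated at the nearest gene), feature priority CDS > UTR > promoter > intron > intergenic, biotype, arm/center, essential-gene flags |
| `tepop.popgen` | per-strain count traits, folded MAF and singleton flags, Spearman correlations, 10-kb hotspot bins (95th-percentile flag), Tajima's D, bp-normalized chi-squared, Wilcoxon rank-sum |
| `tepop.gwa` | kinship matrix, EMMA-style mixed-model scan (one REML fit of δ = σ²g/σ²e on the null model via the eigendecomposition of K, then per-marker GLS Wald tests), Bonferroni threshold, <300-SNV peak grouping, ±50-marker intervals, cis-proximity / median-split filters, Spearman fine-mapping, piRNA-in-interval lookup |
| `tepop.pirna` | exhaustive sliding-window Hamming scan of 21-nt piRNAs against TE consensus sequences, both orientations, ≤5 mismatches |
| `tepop.rarevar` | mean + 4·sd outlier strains, rare-variant (AF ≤ 10%) filters, Grantham (1974) substitution scoring and classes |

The model at the core of the association scan is the standard mixed
model for inbred panels,

    y = 1·μ + x·β + g + e,   g ~ N(0, σ²g·K),  e ~ N(0, σ²e·I),

with K the realized relationship matrix Z·Zᵀ/c (Z column-centered
genotypes, mean diagonal 1).  δ = σ²g/σ²e is estimated once by REML on
the null model through the eigendecomposition of K; each marker is then
tested by generalized least squares with those variance components
fixed, with p-values from a t reference distribution (n − 2 df).

## Worked example

`examples/06_map_te_qtl.py` plants one causal variant (effect 3× the
residual sd) modulating a TE count in a structured 150-strain panel of
2,000 SNVs and maps it:

```
markers tested (MAF >= 5%): 1968; Bonferroni P < 2.54e-05
variance ratio (genetic/residual): 0.77
QTL on chr1: peak snv00900 (-log10 P = 17.0), 1 significant markers, interval markers (835, 935)
  median-split filter: kept
fine-mapping: 8 moderate/severe variants in interval, 1 above the 90th |rho| percentile
  strongest: var0084 in gene0063 (rho = 0.26)
causal marker snv00900 inside interval: True
```

The scan recovers the planted marker as the peak, the ±50-marker
interval brackets it, the median-split filter confirms the two peak
genotype groups differ, and fine-mapping reports the variant whose
|Spearman rho| with the trait exceeds the interval's 90th percentile.

The other examples cover simulation (`01`), harmonization of noisy
calls (`02`), caller benchmarking (`03`), site annotation (`04`),
population statistics (`05`), piRNA complementarity (`07`) and
rare-variant outliers (`08`); each prints a few numbers and a one-line
reading of them.

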