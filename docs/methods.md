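# Methods

This note records the models, rules and numerical choices the package
implements, what the synthetic-data generator does and does not
emulate, and where the design was genuinely open.

## Coordinates and containers

All internal coordinates are 1-based inclusive; BED output converts to
0-based half-open.  Calls, sites and annotations live in pandas
DataFrames with fixed schemas (`tepop.calls.CALL_COLUMNS`,
`tepop.matrix.SITE_COLUMNS`).  The central container is
`SiteMatrix`: site metadata plus a strains × sites frame of
1 (present) / 0 (absent) / NaN (no evidence).  Site ids are
`<chrom>_<pos>_<family>_NR` for insertion sites and `..._R` for
reference sites.  Only start positions are tracked; element footprints
matter only for deletion-span containment and BED output.

## Harmonization rules

Applied per strain, in order:

1. **Collapse** — same-family insertion calls on one chromosome whose
   successive gaps are each *strictly less* than the family's longest
   element length form one run; the member with the highest read
   support survives (ties: smallest position).  The strict `<` follows
   the rule's "separated by a length less than" reading, in contrast to
   the inclusive `<= 50` of the cross-strain merge ("within 50 bp").
2. **Reference position adjustment** — reference calls snap to the
   nearest annotated same-family reference TE within 1 kb; calls with
   no such element are dropped (dropping is the contract, not an
   error).
3. **Span splitting** — an absence call whose deletion span contains k
   annotated reference TEs becomes k point absence calls at the
   annotated positions, each inheriting the span's read support; spans
   containing none are dropped with a warning.
4. **Filters** — insertion calls need both-end support, read support ≥ 3
   (wild-isolate protocol; `HarmonizeConfig.simulation_protocol()`
   uses 8, the stricter benchmarking setting) and per-call frequency
   *strictly greater* than 0.25.  Reference/absence calls need support
   ≥ 3.  The per-call frequency is treated as an opaque float in [0, 1]
   (a caller-internal per-sample estimate); nothing downstream depends
   on its interpretation.
5. **Dedupe** — among same-kind, same-family calls at one position the
   highest support survives; equal supports keep the first in input
   order (a deterministic, stable tie-break).
6. **Contradictions** — where a strain has both a reference and an
   absence call at one (chrom, position, family), the higher-support
   call wins; ties keep the absence call.  The count of resolved
   contradictions is reported.

Across strains, insertion calls are **single-linkage clustered** per
(chromosome, family) with link distance ≤ 50 bp; each cluster becomes
one unique site at the arithmetic mean member position, rounded
half-up.  Single-linkage (chains allowed) was chosen because it is
order-independent; a pairwise "within 50 bp of another strain's call"
reading would depend on processing order.

**Scoring**: a strain scores 1 at an insertion site it carries; a
non-carrier scores NA when its mean coverage over the ±25 bp window is
below 8×, else 0.  The coverage test uses the *mean* over the 51-bp
window (the rule names the window and the 8× threshold but not the
aggregation; minimum would be the conservative alternative and differs
only when coverage changes inside 51 bp).  Reference sites score 1 with
a reference call, 0 with an absence call, NA with neither; sites never
observed present anywhere are dropped (no usable reference evidence),
and the remainder classify as *active* (≥1 zero and ≥1 one — an
excision is the evidence of movement) or *monomorphic* (no zero; NA is
not evidence of excision).

## Benchmarking

Calls match their *nearest* truth event on the same chromosome by
start-position distance (ties to the earlier position) and count as
true positives only when that nearest event shares the family and lies
within the cutoff — nearest-first, then family test, mirroring a
closest-interval join followed by family comparison.  TPR is counted
over truth events (an event found by several calls counts once), FDR
over calls; 0-call FDR and 0-truth TPR are NA.  Counting TPR over
events rather than calls is an interpretation choice; with deduplicated
calls the two rarely differ.

## Annotation

Promoters are up to 2,000 bp upstream of the gene start on the gene's
strand, truncated at the nearest gene *boundary* on either strand when
that gene is closer, and clipped at chromosome ends.  Every site gets
exactly one feature by the priority CDS > UTR > promoter > intron >
intergenic across all genes and isoforms; ties at equal priority go to
the gene with the leftmost start.  5′ and 3′ UTR are pooled into "UTR"
for reporting (sub-labels are retained in the gene models).  Genic
sites inherit the host gene's biotype; intergenic sites have biotype
NA.  Arm/center: a position is "arm" iff ≤ `arm_left_end` or >
`center_end`.  Essential-gene flagging is a case-insensitive substring
match of the RNAi-phenotype keywords (arrest, lethal, sterile, slow
growth, sick, severe) and applies to CDS hits only — an intron hit in
an essential gene is not counted.  Interval queries use an interval
tree; the tests check the priority logic against a naive enumeration of
all overlaps.

## Population statistics

The *activity allele* is presence (1) at insertion sites and absence
(0) at active reference sites; monomorphic sites never contribute.
Count traits are tallied per strain for every grouping (total, by TE
class, by family) × site type (insertion, active_reference, all), with
NAs excluded but recorded as per-cell NA exposure.  MAF is the folded
carrier frequency over non-NA strains; a singleton has exactly one
carrier.  Hotspot bins are non-overlapping 10-kb windows; the top-5%
flag marks counts at or above the 95th percentile
(linear-interpolation quantile, the numpy default; "at or above"
resolves the open boundary question), suppressed when all bins tie;
terminal partial bins are kept by default (configurable) so the genome
is fully tiled.  Tajima's D follows the standard 1989 constants with
strains treated as haploid sequences (fully inbred isotypes); S = 0 or
n < 4 gives NA, and missing genotypes are excluded pairwise in π.  The
size-normalized chi-squared uses expected counts proportional to
class sizes in bp; the hotspot-selection comparison is a two-sided
Mann–Whitney with midranks.

## Association mapping

Trait filters, in order: sites NA in ≥ 10% of strains are dropped; per
trait, strains NA at ≥ 10% of the trait's contributing sites are
masked; all-zero traits and traits where fewer than 5% of strains
differ from the modal count are dropped; outlier strains are pruned
when they lie beyond a gap of ≥ 2 empty integer count bins from the
main mass and make up < 5% of strains (integer bins because the traits
are counts; the "main mass" is the heaviest connected component).

The scan is the population-parameters-previously-determined scheme:
eigendecompose K once, fit δ = σ²g/σ²e by REML on the intercept-only
model (bounded scalar optimization of the restricted likelihood over
log δ ∈ [−12, 12]), then test every MAF ≥ 5% marker by GLS with δ
fixed.  Wald statistics use a t reference with n − 2 df, which keeps
null p-values uniform at n ≈ 150 (the normal reference is slightly
anti-conservative there).  Raw counts are mapped untransformed.
Bonferroni uses α = 0.05 over tested markers.  Significant markers on
one chromosome group into a QTL when their genome-order index
separation is < 300; the interval spans the first-to-last significant
marker of the group ± 50 marker indices, clipped at the chromosome (the
span reading, rather than anchoring on the last significant variant
alone).  The cis filter flags peaks within 100 marker indices of a
high-density TE site of the mapped trait's own family and site type,
where "high density" reuses the top-5% 10-kb bins.  The median-split
filter removes QTL whose peak-genotype groups have identical trait
medians.  Fine-mapping computes Spearman rho between the trait and
every moderate/severe variant in the interval and reports |rho|
strictly above the interval's 90th percentile.

## piRNA search

21-nt piRNAs are scanned against every family consensus by an
exhaustive full-length sliding-window Hamming comparison in both
orientations (sense = matches the consensus strand, antisense = matches
its reverse complement; silencing is antisense-guided but strand
handling is left to the caller, so both are always searched).  At 21 nt
and ≤ 5 mismatches an ungapped substitution-only scan dominates gapped
alignment and is exactly reproducible, unlike a heuristic seed-and-
extend search.  One best record per (piRNA, family, orientation); ties
go to the smallest forward-strand offset; ambiguous bases never match.
Summaries count each (piRNA, family) pair once at its minimal level.
Pairings are reported per family, not per element copy.

## Rare variants

Outlier strains are ≥ mean + 4·sd (sample sd, n − 1) above the trait
mean, one-sided upper; traits backed by a single TE site are skipped.
Rare variants have AF ≤ 10% (inclusive), predicted moderate/severe
effect, sit in a supplied TE-control/piRNA gene list, and are carried
by ≥ 1 flagged strain.  piRNA-class genes bypass the severity filter —
piRNA loci are non-coding, so protein-effect predictions do not apply
to them.  Grantham classes use the conventional boundaries ≤ 50 /
≤ 100 / ≤ 150 / > 150; the full 1974 distance matrix is embedded and
checked for symmetry, zero diagonal and spot values in the tests.

## The synthetic-data generator

What it emulates, and the defaults it fixes:

- **Genome**: a handful of chromosomes with two arms jointly covering
  `arm_fraction` (default 0.5) of each chromosome; sites land on arms
  with probability `arm_bias` (default 0.8), reflecting the observed
  arm excess of TE insertions.
- **Frequency spectrum**: per-site carrier counts are
  1 + BetaBinomial(n − 1, α = `sfs_skew`, β = 3).  The singleton
  fraction has a closed form (`expected_singleton_fraction`), and
  `solve_sfs_skew` inverts it, so panels can be calibrated to the
  ~67% private-insertion fraction seen in wild isolates.  No generative
  model is implied by the analysis itself; the shifted Beta-binomial is
  a stand-in with a tunable singleton weight.
- **Reference sites**: an `active_fraction` (default 0.385, the
  active share of usable reference TEs in wild panels) receives 1 to
  n − 1 excisions — by definition an active reference site retains the
  element in at least one strain.
- **Caller noise** (`ErrorModel`): Gaussian position jitter on
  insertion calls; reference-call offsets up to ±900 bp; per-call
  false-negative dropping; false positives per Mb with read support
  drawn at a quarter of the true-call distribution (stray-read
  artifacts); contradictory reference+absence pairs at a per-site
  rate, with the spurious call's support at a third of the true call's
  (so support-based resolution usually, not always, restores the
  truth); and deletion spans merging *adjacent* excised reference TEs
  at `spanning_rate`.  Read support is constant or Poisson; call
  frequencies are uniform on (0.3, 1.0), above the 0.25 filter, so the
  frequency filter's bite is exercised by dedicated tests rather than
  by random attrition.
- **Coverage**: piecewise-constant per 25-bp window, Gaussian around
  `coverage_mean`, floored at 0 — exactly the granularity the 8×/±25 bp
  NA rule needs.
- **SNV panels**: Balding–Nichols-style subpopulation divergence
  (`fst_like`), {0, 1} inbred coding, traits = baseline (default 20) +
  planted marker effects + optional structure term + Gaussian noise,
  rounded to non-negative counts.
- **piRNAs**: planted 21-mers cut from a named consensus (either
  strand) with exactly k substitutions, verified by brute-force scan to
  sit at minimal distance k; background 21-mers are rejection-sampled
  to be > 5 mismatches from every family.
- **Truth-site spacing**: same-family sites on a chromosome are kept at
  least (longest element + 2 kb) apart and any two sites at least
  500 bp apart, so distinct truth sites can never be collapsed, merged,
  mis-snapped or swallowed by a deletion span.  This is what makes the
  zero-noise round trip exact rather than approximate.

What it does **not** emulate: read-level data (no FASTQ/BAM), sequence
evolution or family phylogenies, recombination maps, linkage
disequilibrium beyond subpopulation structure, coverage-dependent call
quality, and isotype grouping.  Passing round-trip and power tests
therefore validate the *rules and statistics*, not caller performance
on real alignments; real-data TPR/FDR depends on the upstream callers
and cannot be established here.

## Problem sizes in tests and the acceptance script

The suites run on deliberately small instances chosen to keep every
stochastic check comfortably inside its statistical tolerance: 20
round-trip configurations with 4–16 strains and 10–70 sites on 0.15–0.7
Mb genomes; 100 random instances per brute-force oracle; 100 random
Tajima matrices (n ≤ 20, ≤ 50 sites); mapping panels of 150 strains ×
1,000–2,000 markers with 50 power replicates.  Tolerances: oracle and
round-trip checks are exact; Tajima agreement is 1e−10; the
null-calibration KS test uses α = 0.01; power must reach 90% with the
peak within 20 marker indices of the planted variant.

## Known limitations

- The mixed-model scan reuses null-model variance components for every
  marker (per-marker REML would be exact but is ~100× slower and
  changes little at these effect sizes).
- `resolve_contradictions` assumes at most one reference and one
  absence call per site per strain — guaranteed after dedupe, which is
  why the pipeline orders dedupe first.
- Grantham scoring covers the 20 standard amino acids; indels,
  stop-gains and non-coding variants carry no score and are excluded
  from category histograms.
- The per-call frequency is filtered but never modeled; panels whose
  callers report a differently-scaled frequency need the threshold
  adjusted, not the code.
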