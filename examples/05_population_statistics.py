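"""Population statistics of TE activity.

Per-strain count traits, the folded allele-frequency spectrum, the
insertion vs active-reference correlation, 10-kb hotspot bins and
Tajima's D in hotspot vs background bins.
"""

from tepop.popgen import (
    bin_te_counts,
    compare_bin_selection,
    correlate_counts,
    count_traits,
    site_maf,
    tajimas_d_per_bin,
)
from tepop.synth import (
    make_genome_layout,
    make_te_families,
    simulate_population_tes,
    simulate_snv_genotypes,
    solve_sfs_skew,
)

layout = make_genome_layout(2, [1_000_000, 800_000], 0.5, seed=11)
families = make_te_families(10, {"dna": 0.7, "retro": 0.2, "unknown": 0.1},
                            (150, 900), seed=11)
skew = solve_sfs_skew(80, 0.67)
_, _, truth = simulate_population_tes(
    layout, families, n_strains=80, n_ref_sites=120, n_novel_sites=300,
    sfs_skew=skew, seed=12,
)

traits = count_traits(truth)
ins = traits.trait("total", "insertion")
act = traits.trait("total", "active_reference")
print(f"insertions per strain      : mean {ins.mean():.2f} (range {ins.min()}-{ins.max()})")
print(f"active references per strain: mean {act.mean():.2f} (range {act.min()}-{act.max()})")

rho, p = correlate_counts(traits, ("total", "insertion"), ("total", "active_reference"))
print(f"Spearman insertion vs active-reference: rho = {rho:.3f}, P = {p:.2e}")

maf = site_maf(truth)
print(f"singleton sites: {100 * maf['singleton'].mean():.1f}%  "
      f"(median MAF {maf['maf'].median():.3f})")

bins = bin_te_counts(truth.sites, layout)
G, markers, _, _ = simulate_snv_genotypes(80, 3000, fst_like=0.05, layout=layout, seed=13)
d = tajimas_d_per_bin(G, markers, bins)
top, rest = d[bins["top5_flag"]], d[~bins["top5_flag"]]
W, wp = compare_bin_selection(top, rest)
print(f"hotspot bins (top 5%): {int(bins['top5_flag'].sum())} of {len(bins)}; "
      f"Tajima's D hotspots vs rest: W = {W:.0f}, P = {wp:.3f}")
# in real panels insertion and excision counts correlate (cut-and-paste
# movement); this generator draws them independently, so rho ~ 0 here,
# and the SNVs are neutral, so the Tajima's D comparison is flat too
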