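"""Map a TE count trait with the kinship-corrected mixed-model scan.

Plants one causal variant modulating a TE count in a structured panel,
runs the scan, groups significant markers into QTL, and applies the
median-split and fine-mapping steps.
"""

import numpy as np

from tepop.gwa import (
    define_qtl,
    finemap_correlations,
    median_split_filter,
    mixed_model_scan,
)
from tepop.synth import make_variant_effects, simulate_snv_genotypes

n_strains, n_markers, causal = 150, 2000, 900
G, markers, traits, _ = simulate_snv_genotypes(
    n_strains, n_markers, n_subpops=3, fst_like=0.1,
    causal_spec=[(causal, 3.0, "te_count")], trait_noise_sd=1.0, seed=14,
)
y = traits["te_count"]

scan = mixed_model_scan(y, G, markers)
threshold = 0.05 / len(scan)
print(f"markers tested (MAF >= 5%): {len(scan)}; Bonferroni P < {threshold:.2e}")
print(f"variance ratio (genetic/residual): {scan['delta'].iloc[0]:.2f}")

qtl = define_qtl(scan, trait="te_count")
for q in qtl:
    print(f"QTL on {q.chrom}: peak {q.peak_marker} "
          f"(-log10 P = {q.peak_neglog10p:.1f}), "
          f"{len(q.sig_markers)} significant markers, "
          f"interval markers {q.interval_index}")
    removed = median_split_filter(q, y, G[q.peak_marker])
    print(f"  median-split filter: {'removed' if removed else 'kept'}")

variants, vgeno = make_variant_effects(markers, G, n_variants=200, seed=15)
fm = finemap_correlations(qtl[0], variants, vgeno, y)
print(f"fine-mapping: {len(fm)} moderate/severe variants in interval, "
      f"{int(fm['reported'].sum())} above the 90th |rho| percentile")
best = fm.loc[fm["rho"].abs().idxmax()]
print(f"  strongest: {best['variant_id']} in {best['gene']} (rho = {best['rho']:.2f})")
print(f"causal marker snv{causal:05d} inside interval: "
      f"{qtl[0].interval_index[0] <= causal <= qtl[0].interval_index[1]}")
# the planted variant should be the peak (or in tight linkage with it)
# and the interval should bracket it
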