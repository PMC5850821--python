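"""Link extreme TE copy-number strains to rare deleterious variants.

Flags strains more than 4 standard deviations above the mean of a TE
count trait, collects rare (AF <= 10%) moderate/severe variants they
carry in TE-control and piRNA genes, and grades substitutions with
Grantham scores.
"""

import numpy as np
import pandas as pd

from tepop.rarevar import (
    build_outlier_report,
    detect_outlier_strains,
    rare_variant_filter,
)

rng = np.random.default_rng(18)
strains = [f"ST{i:03d}" for i in range(152)]

# a Tc1-like insertion count trait with one extreme strain
counts = pd.DataFrame({("family:Tc1", "insertion"): rng.poisson(7.0, 152).astype(float)},
                      index=strains)
counts.iloc[151] = 120.0  # the outlier
outliers = detect_outlier_strains(counts, n_sites=pd.Series({("family:Tc1", "insertion"): 40}))
print(outliers[["trait", "strain", "count", "threshold"]].to_string(index=False))

variants = pd.DataFrame({
    "variant_id": ["v0", "v1", "v2"],
    "gene": ["wago-like-1", "wago-like-1", "21ur-sim0007"],
    "chrom": ["IV", "IV", "IV"],
    "position": [1_200_000, 1_250_000, 1_400_000],
    "effect": ["moderate", "severe", "low"],
    "ref_aa": ["C", "L", np.nan],
    "alt_aa": ["Y", "I", np.nan],
    "af": [0.02, 0.30, 0.05],
})
genotypes = pd.DataFrame(0, index=strains, columns=variants["variant_id"])
genotypes.loc[strains[151], ["v0", "v2"]] = 1
gene_list = pd.DataFrame({"gene": ["wago-like-1", "21ur-sim0007"],
                          "gene_class": ["te_control", "pirna"]})

rare = rare_variant_filter(variants, genotypes, outliers, gene_list)
report, histogram = build_outlier_report(outliers, rare)
print(report[["strain", "gene", "variant_id", "effect", "af",
              "grantham_score", "grantham_category"]].to_string(index=False))
print("Grantham category histogram (%):", histogram)
# v1 is too common (AF 0.30) and not carried by the outlier; the
# cysteine-to-tyrosine change scores 194 = radical, the kind of private
# defect in an Argonaute-pathway gene that can release TE silencing
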