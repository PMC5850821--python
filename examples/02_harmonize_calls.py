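"""Harmonize noisy caller output into a presence/absence matrix.

Emulates split-read caller noise (position jitter, false and dropped
calls, contradictory reference+absence pairs, multi-TE deletion spans),
then runs the full cleaning protocol and scores every strain at every
unique site.
"""

import numpy as np

from tepop.harmonize import harmonize_population
from tepop.synth import (
    ErrorModel,
    emulate_caller_output,
    make_coverage_tracks,
    make_genome_layout,
    make_te_families,
    simulate_population_tes,
)

layout = make_genome_layout(2, [600_000, 500_000], 0.5, seed=3)
families = make_te_families(8, {"dna": 0.7, "retro": 0.3}, (150, 900), seed=3)
ref, _, truth = simulate_population_tes(
    layout, families, n_strains=25, n_ref_sites=50, n_novel_sites=100,
    sfs_skew=0.3, seed=4,
)

model = ErrorModel(
    position_jitter_sd=2.0, fp_rate_per_mb=2.0, fn_rate=0.03,
    contradiction_rate=0.05, spanning_rate=0.2, ref_offset_sd=150.0,
    read_support_dist=("poisson", 30.0), coverage_mean=60.0, coverage_sd=15.0,
)
calls = emulate_caller_output(truth, layout, model, seed=5)
coverage = make_coverage_tracks(layout, truth.strains, model, seed=5)

matrix, stats = harmonize_population(calls, coverage, ref, families)

n_cells = matrix.values.size
print(f"raw calls               : {sum(len(df) for df in calls.values())}")
print(f"contradictions resolved : {stats['n_contradictions']}")
print(f"unique sites scored     : {len(matrix.sites)} "
      f"(truth had {len(truth.sites)})")
print(f"  insertion sites       : {len(matrix.insertion_ids())}")
print(f"  active reference      : {len(matrix.active_reference_ids())}")
print(f"  monomorphic reference : {len(matrix.monomorphic_ids())}")
print(f"NA cells                : {100 * np.isnan(matrix.values.to_numpy()).mean():.1f}%")
# extra sites beyond the truth are surviving false-positive calls; NA
# cells mark strains with insufficient coverage or no usable call
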