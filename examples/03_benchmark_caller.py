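"""Score emulated calls against the simulation truth (TPR/FDR).

Matches every insertion call to its nearest truth event, sweeps the
distance cutoff, and measures how much a read-support filter costs in
true positives versus what it removes in false positives.
"""

import pandas as pd

from tepop.benchmark import compute_tpr_fdr, filter_impact, match_calls_to_truth
from tepop.calls import INSERTION
from tepop.synth import (
    ErrorModel,
    emulate_caller_output,
    make_genome_layout,
    make_te_families,
    simulate_population_tes,
)

layout = make_genome_layout(1, [1_000_000], 0.5, seed=6)
families = make_te_families(6, {"dna": 0.8, "retro": 0.2}, (150, 800), seed=6)
_, events, truth = simulate_population_tes(
    layout, families, n_strains=2, n_ref_sites=0, n_novel_sites=150,
    sfs_skew=5.0, seed=7,
)
model = ErrorModel(position_jitter_sd=3.0, fp_rate_per_mb=40.0,
                   read_support_dist=("poisson", 10.0))
# benchmark one strain's raw calls against that strain's truth events
strain = truth.strains[0]
calls = emulate_caller_output(truth, layout, model, seed=8)[strain]
calls = calls[calls["kind"] == INSERTION]
truth_events = events[(events["kind"] == "novel_insertion") & (events["strain"] == strain)]

for cutoff in (1, 10, 50):
    m = match_calls_to_truth(calls, truth_events, cutoff)
    r = compute_tpr_fdr(m, truth_events, calls)
    print(f"cutoff {cutoff:>2} bp: TPR {r.tpr:5.1f}%  FDR {r.fdr:5.1f}%  "
          f"({r.n_called} calls vs {r.n_true} truth events)")

pre = match_calls_to_truth(calls, truth_events, 50)
filtered = calls[calls["read_support"] >= 8]
post = match_calls_to_truth(filtered, truth_events, 50)
tp_cost, fp_gain = filter_impact(pre, post)
print(f"support >= 8 filter: removes {tp_cost:.1f}% of TPs, {fp_gain:.1f}% of FPs")
# TPR rises with a looser distance cutoff (jitter forgiveness); a good
# support filter removes far more false than true calls
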