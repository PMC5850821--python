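"""Search piRNA-TE complementarity with a mismatch-bounded scan.

Plants 21-mers cut from TE consensus sequences at known mismatch
levels among random background piRNAs, then recovers them with the
exhaustive sliding-window Hamming scan (both orientations, up to 5
mismatches).
"""

from tepop.pirna import align_pirnas, cumulative_pairings, pairing_summary
from tepop.synth import make_pirna_set, make_te_families

families = make_te_families(6, {"dna": 0.7, "retro": 0.3}, (200, 1200), seed=16)
planted = [
    (families.index[0], 0, "sense"),
    (families.index[0], 0, "antisense"),
    (families.index[1], 1, "antisense"),
    (families.index[2], 3, "sense"),
    (families.index[3], 5, "antisense"),
]
pirnas = make_pirna_set(families, n_background=40, planted=planted, seed=17)

pairings = align_pirnas(pirnas["sequence"], families, max_mismatch=5)
summary = pairing_summary(pairings)
print("pairings per minimal mismatch level:")
print(summary.to_string())
print("cumulative (allowing up to k mismatches):")
print(cumulative_pairings(summary).to_string())
for _, row in pairings.sort_values("mismatches").head(3).iterrows():
    print(f"  {row['pirna_id']} ~ {row['te_family']} "
          f"({row['orientation']}, {row['mismatches']} mm, offset {row['te_offset']})")
# only the planted piRNAs pair (background is rejection-sampled clear of
# all families), each at exactly its planted mismatch level
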