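import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tepop.calls import as_calls
from tepop.harmonize import (
    adjust_reference_positions,
    collapse_adjacent_insertions,
    dedupe_same_position,
    filter_calls,
    harmonize_population,
    harmonize_strain_calls,
    merge_insertions_across_strains,
    resolve_contradictions,
    split_spanning_absences,
)

from _oracles import brute_collapse, brute_contained, brute_merge

TC_FAMILIES = pd.DataFrame(
    {"te_class": ["dna"], "consensus": ["A" * 1610], "longest_element_length": [1610]},
    index=pd.Index(["Tc1x"], name="family"),
)


def ins(strain, pos, support, family="Tc1x", freq=0.9, both=True, chrom="I"):
    return dict(strain=strain, chrom=chrom, position=pos, family=family,
                kind="insertion", read_support=support, both_end=both, call_freq=freq)


def refcall(strain, pos, support, family="Tc1x", chrom="I"):
    return dict(strain=strain, chrom=chrom, position=pos, family=family,
                kind="reference", read_support=support, both_end=True)


def abscall(strain, pos, support, family="Tc1x", chrom="I", span=None):
    row = dict(strain=strain, chrom=chrom, position=pos, family=family,
               kind="absence", read_support=support, both_end=True)
    if span:
        row.update(span_start=float(span[0]), span_end=float(span[1]))
    return row


ANNOT = pd.DataFrame({
    "chrom": ["I", "I", "I"],
    "position": [6_000, 8_000, 10_000],
    "family": ["Tc1x", "Tc1x", "Tc1x"],
    "te_class": ["dna"] * 3,
    "length": [200] * 3,
})


class TestCollapse:
    def test_single_call_unchanged(self):
        calls = as_calls([ins("s", 1000, 5)])
        out = collapse_adjacent_insertions(calls, TC_FAMILIES)
        pd.testing.assert_frame_equal(out, calls)

    def test_gap_below_longest_element_collapses_to_best_support(self):
        calls = as_calls([ins("s", 1000, 5), ins("s", 1300, 9)])
        out = collapse_adjacent_insertions(calls, TC_FAMILIES)
        assert len(out) == 1
        assert out.iloc[0]["position"] == 1300 and out.iloc[0]["read_support"] == 9

    def test_different_families_not_collapsed(self):
        fams = pd.concat([TC_FAMILIES, pd.DataFrame(
            {"te_class": ["retro"], "consensus": ["C" * 400], "longest_element_length": [400]},
            index=pd.Index(["CER9x"], name="family"))])
        calls = as_calls([ins("s", 1000, 5), ins("s", 1010, 5, family="CER9x")])
        assert len(collapse_adjacent_insertions(calls, fams)) == 2

    def test_unknown_family_raises(self):
        calls = as_calls([ins("s", 1000, 5, family="nope")])
        with pytest.raises(KeyError, match="nope"):
            collapse_adjacent_insertions(calls, TC_FAMILIES)

    def test_gap_equal_to_longest_element_kept_separate(self):
        calls = as_calls([ins("s", 1000, 5), ins("s", 2610, 9)])
        assert len(collapse_adjacent_insertions(calls, TC_FAMILIES)) == 2

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.tuples(st.integers(1, 20_000), st.integers(1, 40)),
                    min_size=1, max_size=40))
    def test_matches_brute_force_union_find(self, records):
        calls = as_calls([ins("s", p, r) for p, r in records])
        out = collapse_adjacent_insertions(
            calls.sort_values(["chrom", "position"], kind="stable"), TC_FAMILIES
        )
        got = sorted(zip(out["position"], out["read_support"]))
        assert got == brute_collapse(records, 1610)


class TestAdjustReference:
    def test_snaps_within_1kb(self):
        out = adjust_reference_positions(as_calls([refcall("s", 10_480, 5)]), ANNOT)
        assert list(out["position"]) == [10_000]

    def test_beyond_1kb_dropped(self):
        out = adjust_reference_positions(as_calls([refcall("s", 11_500, 5)]), ANNOT)
        # 11,500 is 1,500 bp from the nearest Tc1x at 10,000
        assert out.empty

    def test_exact_position_unchanged(self):
        out = adjust_reference_positions(as_calls([refcall("s", 8_000, 5)]), ANNOT)
        assert list(out["position"]) == [8_000]

    def test_wrong_family_dropped(self):
        calls = as_calls([refcall("s", 10_010, 5, family="ghost")])
        assert adjust_reference_positions(calls, ANNOT).empty


class TestSplitSpanningAbsence:
    def test_span_over_two_tes_splits(self):
        calls = as_calls([abscall("s", 5_000, 7, span=(5_000, 9_000))])
        out = split_spanning_absences(calls, ANNOT)
        assert sorted(out["position"]) == [6_000, 8_000]
        assert (out["read_support"] == 7).all()

    def test_span_over_one_te(self):
        calls = as_calls([abscall("s", 5_500, 4, span=(5_500, 6_500))])
        out = split_spanning_absences(calls, ANNOT)
        assert list(out["position"]) == [6_000]

    def test_span_over_none_dropped(self):
        calls = as_calls([abscall("s", 1, 4, span=(1, 500))])
        assert split_spanning_absences(calls, ANNOT).empty

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.integers(1, 11_000), st.integers(0, 6_000))
    def test_containment_matches_brute_force(self, lo, width):
        hi = lo + width
        calls = as_calls([abscall("s", lo, 3, span=(lo, hi))])
        out = split_spanning_absences(calls, ANNOT)
        assert sorted(out["position"]) == brute_contained((lo, hi), ANNOT["position"])


class TestFilterCalls:
    def test_insertion_at_thresholds_kept(self):
        calls = as_calls([ins("s", 100, 3, freq=0.30)])
        assert len(filter_calls(calls)) == 1

    def test_frequency_boundary_is_strict(self):
        calls = as_calls([ins("s", 100, 10, freq=0.25)])
        assert filter_calls(calls).empty

    def test_low_support_absence_dropped(self):
        calls = as_calls([abscall("s", 100, 2)])
        assert filter_calls(calls).empty

    def test_single_end_insertion_dropped(self):
        calls = as_calls([ins("s", 100, 10, both=False)])
        assert filter_calls(calls).empty


class TestDedupe:
    def test_keeps_highest_support(self):
        calls = as_calls([ins("s", 100, 4), ins("s", 100, 9)])
        out = dedupe_same_position(calls)
        assert list(out["read_support"]) == [9]

    def test_single_call_unchanged(self):
        calls = as_calls([ins("s", 100, 4)])
        pd.testing.assert_frame_equal(dedupe_same_position(calls), calls)

    def test_tie_keeps_first_in_input_order(self):
        calls = as_calls([ins("s", 100, 5, freq=0.41), ins("s", 100, 5, freq=0.77)])
        out = dedupe_same_position(calls)
        assert out.iloc[0]["call_freq"] == pytest.approx(0.41)


class TestResolveContradictions:
    def test_higher_support_reference_wins(self):
        calls = as_calls([refcall("s", 6_000, 10), abscall("s", 6_000, 3)])
        out, n = resolve_contradictions(calls)
        assert n == 1 and list(out["kind"]) == ["reference"]

    def test_tie_keeps_absence(self):
        calls = as_calls([refcall("s", 6_000, 4), abscall("s", 6_000, 4)])
        out, n = resolve_contradictions(calls)
        assert n == 1 and list(out["kind"]) == ["absence"]

    def test_disjoint_positions_untouched(self):
        calls = as_calls([refcall("s", 6_000, 4), abscall("s", 8_000, 4)])
        out, n = resolve_contradictions(calls)
        assert n == 0 and len(out) == 2


class TestMergeAcrossStrains:
    def test_two_strains_within_50bp_merge_to_mean(self):
        calls = as_calls([ins("A", 500, 5), ins("B", 540, 5)])
        sites, carriers = merge_insertions_across_strains(calls)
        assert list(sites["position"]) == [520]
        assert carriers[sites.index[0]] == ["A", "B"]

    def test_beyond_50bp_stay_separate(self):
        calls = as_calls([ins("A", 500, 5), ins("B", 560, 5)])
        sites, _ = merge_insertions_across_strains(calls)
        assert len(sites) == 2

    def test_chaining_single_linkage(self):
        calls = as_calls([ins("A", 500, 5), ins("B", 540, 5), ins("C", 585, 5)])
        sites, carriers = merge_insertions_across_strains(calls)
        assert list(sites["position"]) == [542]  # mean 541.67 rounds half-up
        assert carriers[sites.index[0]] == ["A", "B", "C"]

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.tuples(st.integers(1, 5_000), st.sampled_from("ABCD")),
                    min_size=1, max_size=40))
    def test_matches_brute_force_single_linkage(self, records):
        calls = as_calls([ins(s, p, 5) for p, s in records])
        sites, carriers = merge_insertions_across_strains(calls)
        got = sorted(
            (int(pos), frozenset(carriers[sid]))
            for sid, pos in sites["position"].items()
        )
        assert got == brute_merge(records)


class TestEndToEnd:
    def test_noiseless_round_trip(self, population, noiseless_calls, families):
        _, _, truth = population
        calls, coverage = noiseless_calls
        ref_annotation = truth.sites[truth.sites["site_type"] == "reference"]
        matrix, stats = harmonize_population(
            calls, coverage,
            ref_annotation.reset_index()[["chrom", "position", "family", "te_class"]]
            .assign(length=200),
            families,
        )
        assert stats["n_contradictions"] == 0
        assert matrix.equals(truth)

    def test_idempotent_on_own_output(self, population, noiseless_calls, families):
        ref, _, truth = population
        calls, _ = noiseless_calls
        strain = truth.strains[0]
        once, _ = harmonize_strain_calls(calls[strain], ref, families)
        twice, n = harmonize_strain_calls(once, ref, families)
        assert n == 0
        pd.testing.assert_frame_equal(
            once.sort_values(["chrom", "position", "kind"]).reset_index(drop=True),
            twice.sort_values(["chrom", "position", "kind"]).reset_index(drop=True),
        )

    def test_low_coverage_non_carrier_scored_na(self, layout, families):
        from tepop.coverage import constant_tracks
        from tepop.harmonize import score_site_matrix

        sites = pd.DataFrame({"chrom": ["I"], "position": [1000], "family": ["fam000"]},
                             index=pd.Index(["I_1000_fam000_NR"], name="site_id"))
        carriers = {"I_1000_fam000_NR": ["A"]}
        calls = as_calls([ins("A", 1000, 9, family="fam000")])
        annot = pd.DataFrame(columns=["chrom", "position", "family", "te_class", "length"])
        low = constant_tracks(layout, ["B"], depth=7.9)
        high = constant_tracks(layout, ["A", "C"], depth=30.0)
        coverage = {**low, **high}
        m = score_site_matrix(sites, carriers, calls, coverage, annot, families,
                              strains=["A", "B", "C"])
        row = m.values.iloc[0]
        assert row["A"] == 1.0 and np.isnan(row["B"]) and row["C"] == 0.0

    def test_reference_site_classification(self, layout, families):
        from tepop.coverage import constant_tracks
        from tepop.harmonize import score_site_matrix

        annot = pd.DataFrame({"chrom": ["I", "I", "I"], "position": [1000, 3000, 5000],
                              "family": ["fam000"] * 3, "te_class": ["dna"] * 3,
                              "length": [200] * 3})
        calls = as_calls(
            # site 1000: all reference -> monomorphic
            [refcall(s, 1000, 5, family="fam000") for s in "ABC"]
            # site 3000: mixed -> active
            + [refcall("A", 3000, 5, family="fam000"),
               abscall("B", 3000, 5, family="fam000")]
            # site 5000: absences only -> excluded
            + [abscall(s, 5000, 5, family="fam000") for s in "ABC"]
        )
        coverage = constant_tracks(layout, list("ABC"), 30.0)
        m = score_site_matrix(pd.DataFrame(columns=["chrom", "position", "family"]),
                              {}, calls, coverage, annot, families, strains=list("ABC"))
        assert list(m.monomorphic_ids()) == ["I_1000_fam000_R"]
        assert list(m.active_reference_ids()) == ["I_3000_fam000_R"]
        assert "I_5000_fam000_R" not in m.sites.index

    def test_na_when_neither_call(self, layout, families):
        from tepop.coverage import constant_tracks
        from tepop.harmonize import score_site_matrix

        annot = pd.DataFrame({"chrom": ["I"], "position": [1000], "family": ["fam000"],
                              "te_class": ["dna"], "length": [200]})
        calls = as_calls([refcall("A", 1000, 5, family="fam000"),
                          abscall("B", 1000, 5, family="fam000")])
        coverage = constant_tracks(layout, list("ABC"), 30.0)
        m = score_site_matrix(pd.DataFrame(columns=["chrom", "position", "family"]),
                              {}, calls, coverage, annot, families, strains=list("ABC"))
        assert np.isnan(m.values.loc["I_1000_fam000_R", "C"])

    def test_missing_coverage_track_raises(self, layout, families):
        from tepop.coverage import constant_tracks
        from tepop.harmonize import score_site_matrix

        sites = pd.DataFrame({"chrom": ["I"], "position": [1000], "family": ["fam000"]},
                             index=pd.Index(["I_1000_fam000_NR"], name="site_id"))
        annot = pd.DataFrame(columns=["chrom", "position", "family", "te_class", "length"])
        with pytest.raises(KeyError, match="coverage"):
            score_site_matrix(sites, {}, as_calls([]), constant_tracks(layout, ["A"], 30),
                              annot, families, strains=["A", "B"])


class TestConservation:
    def test_every_filtered_call_lands_in_one_cell(self, population, noiseless_calls, families):
        ref, _, truth = population
        calls, coverage = noiseless_calls
        matrix, _ = harmonize_population(calls, coverage, ref, families)
        n_cells_called = int((matrix.values == 1.0).sum().sum()
                             + (matrix.values.loc[matrix.reference_ids()] == 0.0).sum().sum())
        n_input = sum(len(df) for df in calls.values())
        assert n_cells_called == n_input  # zero-noise: one call per scored cell
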