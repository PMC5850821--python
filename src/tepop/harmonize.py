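"""Harmonize raw per-strain TE caller output into a strain x site matrix.

The cleaning protocol, applied per strain and then across strains:

1.  *Collapse* runs of same-family insertion calls closer than the
    family's longest element (redundant split-read hits on one element),
    keeping the best-supported member.
2.  *Adjust* reference-caller positions to the nearest annotated
    reference TE of the same family within 1 kb; unmatched calls drop.
3.  *Split* absence (deletion) calls whose span covers several annotated
    reference TEs into one absence call per covered element.
4.  *Filter*: insertion calls need both-end support, a minimum read
    support and a per-call frequency strictly above a cutoff; reference
    and absence calls need a minimum read support.
5.  *Dedupe* identical-position calls, keeping the highest support.
6.  *Resolve contradictions* where one strain has both a reference and
    an absence call at a site: higher support wins, ties go to absence.
7.  *Merge* insertion calls across strains by single-linkage clustering
    (link distance 50 bp) into unique sites at the mean position.
8.  *Score* every strain at every unique site as present / absent / NA
    (NA when coverage around an insertion site is below 8x, or when a
    reference site has neither a reference nor an absence call).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calls import ABSENCE, CALL_COLUMNS, INSERTION, REFERENCE, concat_calls, empty_calls
from .matrix import SiteMatrix, make_site_id
from .matrix import INSERTION as SITE_INSERTION
from .matrix import REFERENCE as SITE_REFERENCE
from .coverage import mean_coverage

logger = logging.getLogger(__name__)


@dataclass
class HarmonizeConfig:
    """Thresholds of the cleaning protocol.

    The wild-isolate protocol keeps insertion calls with >= 3 supporting
    reads; the stricter simulation/benchmarking protocol uses 8.
    """

    insertion_min_reads: int = 3
    insertion_min_freq: float = 0.25
    ref_abs_min_reads: int = 3
    merge_bp: int = 50
    na_coverage: float = 8.0
    flank_bp: int = 25
    adjust_bp: int = 1000

    @classmethod
    def simulation_protocol(cls) -> "HarmonizeConfig":
        return cls(insertion_min_reads=8)


# ---------------------------------------------------------------------------
# per-strain steps


def collapse_adjacent_insertions(calls: pd.DataFrame, families: pd.DataFrame) -> pd.DataFrame:
    """Collapse same-family insertion runs with successive gaps strictly
    below the family's longest element length; the best-supported member
    survives (ties: smallest position)."""
    ins = calls[calls["kind"] == INSERTION]
    unknown = set(ins["family"]) - set(families.index)
    if unknown:
        raise KeyError(f"unknown TE families in calls: {sorted(unknown)}")
    keep_idx: list = []
    for (_, _, family), grp in ins.groupby(["strain", "chrom", "family"], sort=False):
        limit = int(families.loc[family, "longest_element_length"])
        grp = grp.sort_values(["position", "read_support"], kind="stable")
        pos = grp["position"].to_numpy()
        run_break = np.diff(pos) >= limit
        run_id = np.concatenate(([0], np.cumsum(run_break)))
        for rid in np.unique(run_id):
            members = grp.iloc[run_id == rid]
            best = members.sort_values(
                ["read_support", "position"], ascending=[False, True], kind="stable"
            ).index[0]
            keep_idx.append(best)
    out = pd.concat([calls[calls["kind"] != INSERTION], calls.loc[keep_idx]])
    return out.sort_index().reset_index(drop=True)


def _nearest_annotated(positions: np.ndarray, annotated: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """For each position, nearest annotated coordinate and distance."""
    order = np.argsort(annotated)
    ann = annotated[order]
    right = np.searchsorted(ann, positions)
    left = np.clip(right - 1, 0, len(ann) - 1)
    right = np.clip(right, 0, len(ann) - 1)
    d_left = np.abs(positions - ann[left])
    d_right = np.abs(positions - ann[right])
    use_left = d_left <= d_right
    nearest = np.where(use_left, ann[left], ann[right])
    dist = np.where(use_left, d_left, d_right)
    return nearest, dist


def adjust_reference_positions(
    calls: pd.DataFrame, ref_annotation: pd.DataFrame, max_distance: int = 1000
) -> pd.DataFrame:
    """Snap reference calls to the nearest annotated same-family reference
    TE within ``max_distance``; calls with no such element are dropped.
    Non-reference calls pass through untouched."""
    ref = calls[calls["kind"] == REFERENCE].copy()
    rest = calls[calls["kind"] != REFERENCE]
    if ref.empty:
        return calls.reset_index(drop=True)
    ref["_keep"] = False
    ann_groups = ref_annotation.groupby(["chrom", "family"])["position"]
    for (chrom, family), grp in ref.groupby(["chrom", "family"], sort=False):
        try:
            ann = ann_groups.get_group((chrom, family)).to_numpy()
        except KeyError:
            continue
        nearest, dist = _nearest_annotated(grp["position"].to_numpy(), ann)
        ok = dist <= max_distance
        ref.loc[grp.index, "position"] = nearest
        ref.loc[grp.index, "_keep"] = ok
    out = pd.concat([rest, ref[ref["_keep"]].drop(columns="_keep")])
    return out.sort_index().reset_index(drop=True)


def split_spanning_absences(calls: pd.DataFrame, ref_annotation: pd.DataFrame) -> pd.DataFrame:
    """Expand absence spans covering k annotated reference TEs into k
    point absence calls at the annotated positions (inheriting read
    support); spans covering none are dropped with a warning."""
    absent = calls[calls["kind"] == ABSENCE]
    rest = calls[calls["kind"] != ABSENCE]
    ann_by_chrom = {c: g.sort_values("position") for c, g in ref_annotation.groupby("chrom")}
    new_rows = []
    n_dropped = 0
    for _, call in absent.iterrows():
        lo = call["span_start"] if pd.notna(call["span_start"]) else call["position"]
        hi = call["span_end"] if pd.notna(call["span_end"]) else call["position"]
        ann = ann_by_chrom.get(call["chrom"])
        if ann is None:
            n_dropped += 1
            continue
        inside = ann[(ann["position"] >= lo) & (ann["position"] <= hi)]
        if inside.empty:
            n_dropped += 1
            continue
        for _, te in inside.iterrows():
            row = call.to_dict()
            row.update(position=int(te["position"]), family=te["family"],
                       span_start=np.nan, span_end=np.nan)
            new_rows.append(row)
    if n_dropped:
        logger.warning("dropped %d absence calls spanning no annotated reference TE", n_dropped)
    out = concat_calls([rest, pd.DataFrame(new_rows, columns=CALL_COLUMNS)])
    return out.reset_index(drop=True)


def filter_calls(
    calls: pd.DataFrame,
    insertion_min_reads: int = 3,
    insertion_min_freq: float = 0.25,
    ref_abs_min_reads: int = 3,
) -> pd.DataFrame:
    """Support/frequency filters: insertions need both-end support,
    ``read_support >= insertion_min_reads`` and ``call_freq >`` (strict)
    ``insertion_min_freq``; reference/absence calls need
    ``read_support >= ref_abs_min_reads``."""
    is_ins = calls["kind"] == INSERTION
    keep_ins = (
        is_ins
        & calls["both_end"]
        & (calls["read_support"] >= insertion_min_reads)
        & (calls["call_freq"] > insertion_min_freq)
    )
    keep_other = ~is_ins & (calls["read_support"] >= ref_abs_min_reads)
    return calls[keep_ins | keep_other].reset_index(drop=True)


def dedupe_same_position(calls: pd.DataFrame) -> pd.DataFrame:
    """Among same-kind same-family calls at one position in one strain,
    keep the highest read support; equal supports keep the first in
    input order (stable)."""
    ranked = calls.sort_values("read_support", ascending=False, kind="stable")
    kept = ranked.drop_duplicates(subset=["strain", "chrom", "position", "family", "kind"])
    n_ties = len(calls) - len(kept)
    if n_ties:
        logger.debug("dedupe removed %d duplicate-position calls", n_ties)
    return kept.sort_index().reset_index(drop=True)


def resolve_contradictions(calls: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Where a strain has both a reference and an absence call at one
    (chrom, position, family), keep the higher-support call; ties keep
    the absence call.  Returns the resolved calls and the number of
    contradictions."""
    ra = calls[calls["kind"].isin([REFERENCE, ABSENCE])]
    rest = calls[~calls["kind"].isin([REFERENCE, ABSENCE])]
    key = ["strain", "chrom", "position", "family"]
    drop_idx = []
    n = 0
    for _, pair in ra.groupby(key, sort=False):
        kinds = set(pair["kind"])
        if len(kinds) < 2:
            continue
        n += 1
        ref_row = pair[pair["kind"] == REFERENCE].iloc[0]
        abs_row = pair[pair["kind"] == ABSENCE].iloc[0]
        if ref_row["read_support"] > abs_row["read_support"]:
            drop_idx.append(abs_row.name)
        else:  # absence wins ties
            drop_idx.append(ref_row.name)
    if n == 0:
        return calls.reset_index(drop=True), 0
    out = pd.concat([rest, ra.drop(index=drop_idx)])
    return out.sort_index().reset_index(drop=True), n


# ---------------------------------------------------------------------------
# cross-strain steps


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def merge_insertions_across_strains(
    calls: pd.DataFrame, merge_bp: int = 50
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Single-linkage cluster same-family insertion calls across strains
    (link distance <= merge_bp); each cluster becomes one unique site at
    the mean member position (rounded half-up).

    Returns a site table (site_id, chrom, position, family) and a map
    site_id -> carrier strains.
    """
    ins = calls[calls["kind"] == INSERTION]
    site_rows = {}
    carriers: dict[str, list[str]] = {}
    for (chrom, family), grp in ins.groupby(["chrom", "family"], sort=True):
        grp = grp.sort_values("position", kind="stable")
        pos = grp["position"].to_numpy()
        breaks = np.diff(pos) > merge_bp
        cluster = np.concatenate(([0], np.cumsum(breaks)))
        for cid in np.unique(cluster):
            members = grp.iloc[cluster == cid]
            mean_pos = _round_half_up(members["position"].mean())
            sid = make_site_id(chrom, mean_pos, family, SITE_INSERTION)
            site_rows[sid] = (chrom, mean_pos, family)
            carriers[sid] = sorted(set(members["strain"]))
    sites = pd.DataFrame.from_dict(site_rows, orient="index",
                                   columns=["chrom", "position", "family"])
    sites.index.name = "site_id"
    return sites, carriers


def classify_reference_sites(matrix: SiteMatrix) -> tuple[pd.Index, pd.Index]:
    """Partition reference sites into (active, monomorphic)."""
    return matrix.active_reference_ids(), matrix.monomorphic_ids()


def score_site_matrix(
    insertion_sites: pd.DataFrame,
    carriers: dict[str, list[str]],
    calls: pd.DataFrame,
    coverage: dict[str, dict[str, np.ndarray]],
    ref_annotation: pd.DataFrame,
    families: pd.DataFrame,
    strains: list[str],
    na_coverage: float = 8.0,
    flank_bp: int = 25,
) -> SiteMatrix:
    """Score every strain at every unique site.

    Insertion sites: 1 for carriers; non-carriers are NA when mean
    coverage over the +/- ``flank_bp`` window is below ``na_coverage``,
    else 0.  Reference sites: 1 with a reference call, 0 with an absence
    call, NA with neither; sites never observed present are dropped, and
    the rest are classified active/monomorphic.
    """
    missing = [s for s in strains if s not in coverage]
    if missing:
        raise KeyError(f"coverage track missing for strains: {missing}")

    meta_rows: dict[str, tuple] = {}
    value_rows: dict[str, np.ndarray] = {}
    s_index = {s: i for i, s in enumerate(strains)}

    for sid, srow in insertion_sites.iterrows():
        vec = np.zeros(len(strains))
        carry = set(carriers.get(sid, []))
        for s in strains:
            if s in carry:
                vec[s_index[s]] = 1.0
            else:
                cov = mean_coverage(coverage[s], srow["chrom"], int(srow["position"]), flank_bp)
                vec[s_index[s]] = np.nan if cov < na_coverage else 0.0
        te_class = families.loc[srow["family"], "te_class"] if srow["family"] in families.index else "unknown"
        meta_rows[sid] = (srow["chrom"], int(srow["position"]), srow["family"], te_class,
                          SITE_INSERTION, np.nan)
        value_rows[sid] = vec

    ra = calls[calls["kind"].isin([REFERENCE, ABSENCE])]
    ra_lookup: dict[tuple, str] = {
        (r["strain"], r["chrom"], r["position"], r["family"]): r["kind"]
        for _, r in ra.iterrows()
    }
    for _, ann in ref_annotation.iterrows():
        vec = np.full(len(strains), np.nan)
        for s in strains:
            kind = ra_lookup.get((s, ann["chrom"], ann["position"], ann["family"]))
            if kind == REFERENCE:
                vec[s_index[s]] = 1.0
            elif kind == ABSENCE:
                vec[s_index[s]] = 0.0
        if not (vec == 1.0).any():
            continue  # never observed present: no usable reference call
        has_zero = (vec == 0.0).any()
        ref_class = "active" if has_zero else "monomorphic"
        sid = make_site_id(ann["chrom"], int(ann["position"]), ann["family"], SITE_REFERENCE)
        te_class = families.loc[ann["family"], "te_class"] if ann["family"] in families.index else "unknown"
        meta_rows[sid] = (ann["chrom"], int(ann["position"]), ann["family"], te_class,
                          SITE_REFERENCE, ref_class)
        value_rows[sid] = vec

    sites = pd.DataFrame.from_dict(
        meta_rows, orient="index",
        columns=["chrom", "position", "family", "te_class", "site_type", "ref_class"],
    )
    sites.index.name = "site_id"
    values = pd.DataFrame.from_dict(value_rows, orient="index", columns=strains)
    values.index.name = "site_id"
    return SiteMatrix(sites, values).sorted()


# ---------------------------------------------------------------------------
# orchestration


def harmonize_strain_calls(
    calls: pd.DataFrame,
    ref_annotation: pd.DataFrame,
    families: pd.DataFrame,
    config: HarmonizeConfig | None = None,
) -> tuple[pd.DataFrame, int]:
    """Run the per-strain cleaning steps; returns (calls, n_contradictions)."""
    cfg = config or HarmonizeConfig()
    calls = calls.sort_values(["chrom", "position"], kind="stable").reset_index(drop=True)
    calls = collapse_adjacent_insertions(calls, families)
    calls = adjust_reference_positions(calls, ref_annotation, cfg.adjust_bp)
    calls = split_spanning_absences(calls, ref_annotation)
    calls = filter_calls(calls, cfg.insertion_min_reads, cfg.insertion_min_freq,
                         cfg.ref_abs_min_reads)
    calls = dedupe_same_position(calls)
    return resolve_contradictions(calls)


def harmonize_population(
    calls_by_strain: dict[str, pd.DataFrame],
    coverage: dict[str, dict[str, np.ndarray]],
    ref_annotation: pd.DataFrame,
    families: pd.DataFrame,
    config: HarmonizeConfig | None = None,
) -> tuple[SiteMatrix, dict]:
    """Full harmonization: per-strain cleaning, cross-strain merge, scoring.

    Returns the scored :class:`SiteMatrix` and a stats dict with the
    total contradiction count.
    """
    cfg = config or HarmonizeConfig()
    cleaned = []
    n_contra = 0
    for strain, df in calls_by_strain.items():
        if len(df) == 0:
            cleaned.append(empty_calls())
            continue
        out, n = harmonize_strain_calls(df, ref_annotation, families, cfg)
        n_contra += n
        cleaned.append(out)
    allcalls = concat_calls(cleaned)
    sites, carriers = merge_insertions_across_strains(allcalls, cfg.merge_bp)
    matrix = score_site_matrix(
        sites, carriers, allcalls, coverage, ref_annotation, families,
        strains=list(calls_by_strain), na_coverage=cfg.na_coverage, flank_bp=cfg.flank_bp,
    )
    return matrix, {"n_contradictions": n_contra}
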