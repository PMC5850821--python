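"""Simulate a population of TE sites and noisy caller output.

``simulate_population_tes`` draws the ground truth: annotated reference
TE positions (a subset of which are *active*, i.e. excised in at least
one strain) and novel insertion sites segregating at a skewed site
frequency spectrum, both preferentially placed on chromosome arms.

``emulate_caller_output`` then degrades the truth into per-strain raw
call tables the way split-read TE callers do: position jitter on
insertion calls, reference calls reported up to ~1 kb from the
annotated element, dropped calls, injected false positives,
contradictory reference+absence call pairs at the same site, and
single absence calls spanning several adjacent reference TEs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..calls import ABSENCE, INSERTION, REFERENCE, as_calls, empty_calls
from ..coverage import mean_coverage  # noqa: F401  (re-exported for convenience)
from ..matrix import SiteMatrix, make_site_id
from ..matrix import INSERTION as SITE_INSERTION
from ..matrix import REFERENCE as SITE_REFERENCE
from .sfs import draw_carrier_counts

REF_ANNOTATION_COLUMNS = ["chrom", "position", "family", "te_class", "length"]
TRUTH_EVENT_COLUMNS = ["strain", "chrom", "position", "family", "kind"]


def _segment_bounds(row: pd.Series) -> dict[str, list[tuple[int, int]]]:
    aL, cE, L = int(row["arm_left_end"]), int(row["center_end"]), int(row["length"])
    return {"arm": [(1, aL), (cE + 1, L)], "center": [(aL + 1, cE)]}


def _sample_site_positions(
    layout: pd.DataFrame,
    families: pd.DataFrame,
    n_sites: int,
    arm_bias: float,
    rng: np.random.Generator,
    taken: dict[tuple[str, str], list[int]],
) -> pd.DataFrame:
    """Place sites on arm/center segments, keeping same-family sites on a
    chromosome far enough apart that distinct truth sites can never be
    collapsed or merged into each other downstream."""
    if not 0.5 <= arm_bias <= 1.0:
        raise ValueError("arm_bias must be in [0.5, 1]")
    chrom_probs = layout["length"] / layout["length"].sum()
    fam_names = list(families.index)
    rows = []
    max_tries = 200 * max(n_sites, 1)
    tries = 0
    while len(rows) < n_sites:
        tries += 1
        if tries > max_tries:
            raise RuntimeError("could not place TE sites with required spacing; genome too small")
        crow = layout.iloc[int(rng.choice(len(layout), p=chrom_probs))]
        segs = _segment_bounds(crow)
        kind = "arm" if rng.random() < arm_bias else "center"
        spans = segs[kind]
        weights = np.array([hi - lo + 1 for lo, hi in spans], dtype=float)
        lo, hi = spans[int(rng.choice(len(spans), p=weights / weights.sum()))]
        pos = int(rng.integers(lo, hi + 1))
        family = fam_names[int(rng.integers(len(fam_names)))]
        chrom = str(crow["chrom"])
        # same-family spacing: beyond the collapse window and the 1-kb
        # reference-matching window; any-family spacing: beyond a deletion span.
        min_gap = int(families.loc[family, "longest_element_length"]) + 2000
        if any(abs(p - pos) < min_gap for p in taken.get((chrom, family), [])):
            continue
        if any(abs(p - pos) < 500 for p in taken.get((chrom, "*"), [])):
            continue
        taken.setdefault((chrom, family), []).append(pos)
        taken.setdefault((chrom, "*"), []).append(pos)
        rows.append((chrom, pos, family))
    return pd.DataFrame(rows, columns=["chrom", "position", "family"])


def simulate_population_tes(
    layout: pd.DataFrame,
    families: pd.DataFrame,
    n_strains: int,
    n_ref_sites: int,
    n_novel_sites: int,
    sfs_skew: float,
    arm_bias: float = 0.8,
    active_fraction: float = 0.385,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, SiteMatrix]:
    """Draw the ground-truth TE landscape of a strain panel.

    Returns ``(ref_annotation, truth_events, truth_matrix)``.  Novel
    sites are carried by 1..n strains (shifted Beta-binomial carrier
    counts); reference sites split into active (1..n-1 excisions, so the
    reference allele survives somewhere) and monomorphic.  The truth
    matrix has no NAs.
    """
    if n_strains < 2:
        raise ValueError("need at least 2 strains")
    rng = np.random.default_rng(seed)
    strains = [f"ST{i:03d}" for i in range(n_strains)]
    taken: dict[tuple[str, str], list[int]] = {}

    ref_sites = _sample_site_positions(layout, families, n_ref_sites, arm_bias, rng, taken)
    novel_sites = _sample_site_positions(layout, families, n_novel_sites, arm_bias, rng, taken)

    ref_annotation = ref_sites.copy()
    ref_annotation["te_class"] = families.loc[ref_annotation["family"], "te_class"].to_numpy()
    ref_annotation["length"] = (
        families.loc[ref_annotation["family"], "consensus"].str.len().to_numpy()
    )
    ref_annotation = ref_annotation[REF_ANNOTATION_COLUMNS].sort_values(
        ["chrom", "position"], ignore_index=True
    )

    site_meta: dict[str, tuple] = {}
    values: dict[str, np.ndarray] = {}
    events: list[tuple] = []

    # Novel insertions: carriers get 1, everyone else 0.
    if n_novel_sites:
        counts = draw_carrier_counts(n_novel_sites, n_strains, sfs_skew, rng)
        for (_, row), k in zip(novel_sites.iterrows(), counts):
            sid = make_site_id(row["chrom"], row["position"], row["family"], SITE_INSERTION)
            carriers = rng.choice(n_strains, size=k, replace=False)
            vec = np.zeros(n_strains)
            vec[carriers] = 1.0
            te_class = families.loc[row["family"], "te_class"]
            site_meta[sid] = (row["chrom"], row["position"], row["family"], te_class,
                              SITE_INSERTION, np.nan)
            values[sid] = vec
            for ci in carriers:
                events.append((strains[ci], row["chrom"], row["position"], row["family"],
                               "novel_insertion"))

    # Reference sites: active ones lose the element in 1..n-1 strains.
    n_active = int(round(active_fraction * n_ref_sites))
    active_idx = set(rng.choice(n_ref_sites, size=n_active, replace=False)) if n_ref_sites else set()
    if n_active:
        excision_counts = iter(
            draw_carrier_counts(n_active, n_strains, sfs_skew, rng, max_carriers=n_strains - 1)
        )
    for i, (_, row) in enumerate(ref_sites.iterrows()):
        sid = make_site_id(row["chrom"], row["position"], row["family"], SITE_REFERENCE)
        vec = np.ones(n_strains)
        ref_class = "monomorphic"
        if i in active_idx:
            k = next(excision_counts)
            excised = rng.choice(n_strains, size=k, replace=False)
            vec[excised] = 0.0
            ref_class = "active"
            for ci in excised:
                events.append((strains[ci], row["chrom"], row["position"], row["family"],
                               "reference_excision"))
        te_class = families.loc[row["family"], "te_class"]
        site_meta[sid] = (row["chrom"], row["position"], row["family"], te_class,
                          SITE_REFERENCE, ref_class)
        values[sid] = vec

    sites = pd.DataFrame.from_dict(
        site_meta, orient="index",
        columns=["chrom", "position", "family", "te_class", "site_type", "ref_class"],
    )
    sites.index.name = "site_id"
    vals = pd.DataFrame.from_dict(values, orient="index", columns=strains)
    vals.index.name = "site_id"
    truth_events = pd.DataFrame(events, columns=TRUTH_EVENT_COLUMNS)
    return ref_annotation, truth_events, SiteMatrix(sites, vals).sorted()


@dataclass
class ErrorModel:
    """Parametric caller-noise model.

    ``read_support_dist`` is ``("constant", c)`` or ``("poisson", mu)``
    (floored at 1 read).  ``spanning_rate`` is the chance that an
    absence call is merged with the next adjacent excised reference TE
    into one deletion span; ``ref_offset_sd`` jitters reference-call
    positions (callers report them up to ~1 kb off the annotation).
    """

    position_jitter_sd: float = 0.0
    fp_rate_per_mb: float = 0.0
    fn_rate: float = 0.0
    contradiction_rate: float = 0.0
    read_support_dist: tuple = ("poisson", 30.0)
    coverage_mean: float = 60.0
    coverage_sd: float = 0.0
    spanning_rate: float = 0.0
    ref_offset_sd: float = 0.0
    call_freq_range: tuple[float, float] = (0.3, 1.0)

    def __post_init__(self) -> None:
        for name in ("fp_rate_per_mb", "fn_rate", "contradiction_rate", "spanning_rate"):
            v = getattr(self, name)
            if name != "fp_rate_per_mb" and not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
            if v < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.position_jitter_sd < 0 or self.ref_offset_sd < 0:
            raise ValueError("jitter must be >= 0")
        kind = self.read_support_dist[0]
        if kind not in ("constant", "poisson"):
            raise ValueError(f"unknown read_support_dist kind {kind!r}")

    @classmethod
    def noiseless(cls, coverage_mean: float = 60.0) -> "ErrorModel":
        return cls(read_support_dist=("constant", 30), coverage_mean=coverage_mean)


def _draw_support(model: ErrorModel, rng: np.random.Generator, size: int) -> np.ndarray:
    kind, param = model.read_support_dist
    if kind == "constant":
        return np.full(size, int(param), dtype=int)
    return np.maximum(1, rng.poisson(param, size=size))


def _draw_freq(model: ErrorModel, rng: np.random.Generator, size: int) -> np.ndarray:
    lo, hi = model.call_freq_range
    return rng.uniform(lo, hi, size=size)


def make_coverage_tracks(
    layout: pd.DataFrame,
    strains: list[str],
    model: ErrorModel,
    seed: int = 0,
    window: int = 25,
) -> dict[str, dict[str, np.ndarray]]:
    """Piecewise-constant fold-coverage per ``window``-bp bin, Gaussian
    around ``coverage_mean`` and floored at 0."""
    rng = np.random.default_rng(seed)
    tracks: dict[str, dict[str, np.ndarray]] = {}
    for strain in strains:
        per_chrom = {}
        for _, row in layout.iterrows():
            n_win = int(np.ceil(row["length"] / window))
            if model.coverage_sd == 0:
                depth = np.full(n_win, float(model.coverage_mean))
            else:
                depth = np.maximum(
                    0.0, rng.normal(model.coverage_mean, model.coverage_sd, size=n_win)
                )
            per_chrom[str(row["chrom"])] = depth
        tracks[strain] = per_chrom
    return tracks


def emulate_caller_output(
    truth: SiteMatrix,
    layout: pd.DataFrame,
    model: ErrorModel,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Degrade a truth matrix into per-strain raw call tables.

    With a zero error model, harmonizing the output reproduces the truth
    matrix exactly (the round-trip property the tests rely on).
    """
    rng = np.random.default_rng(seed)
    chrom_len = dict(zip(layout["chrom"], layout["length"]))
    ins_ids = truth.insertion_ids()
    ref_ids = truth.reference_ids()
    ins_meta = truth.sites.loc[ins_ids]
    ref_meta = truth.sites.loc[ref_ids].sort_values(["chrom", "position"])
    # TE element length: reuse position spacing info via family consensus length if
    # present in metadata; fall back to a nominal length.
    fam_names = list(truth.sites["family"].unique())
    genome_mb = layout["length"].sum() / 1e6

    out: dict[str, pd.DataFrame] = {}
    for strain in truth.strains:
        rows: list[dict] = []
        vals = truth.values[strain]

        # --- insertion calls ---
        carried = ins_meta.index[vals.loc[ins_ids] == 1.0]
        for sid in carried:
            if rng.random() < model.fn_rate:
                continue
            meta = ins_meta.loc[sid]
            pos = int(meta["position"])
            if model.position_jitter_sd > 0:
                pos += int(round(rng.normal(0, model.position_jitter_sd)))
            pos = int(np.clip(pos, 1, chrom_len[meta["chrom"]]))
            rows.append(dict(strain=strain, chrom=meta["chrom"], position=pos,
                             family=meta["family"], kind=INSERTION,
                             read_support=int(_draw_support(model, rng, 1)[0]),
                             both_end=True, call_freq=float(_draw_freq(model, rng, 1)[0])))

        # --- false-positive insertion calls ---
        n_fp = rng.poisson(model.fp_rate_per_mb * genome_mb) if model.fp_rate_per_mb else 0
        for _ in range(n_fp):
            crow = layout.iloc[int(rng.integers(len(layout)))]
            # spurious calls come from few stray reads: support well below
            # the true-call distribution, so support filters can bite
            rows.append(dict(strain=strain, chrom=str(crow["chrom"]),
                             position=int(rng.integers(1, crow["length"] + 1)),
                             family=fam_names[int(rng.integers(len(fam_names)))],
                             kind=INSERTION,
                             read_support=max(1, int(_draw_support(model, rng, 1)[0] // 4)),
                             both_end=bool(rng.random() < 0.7),
                             call_freq=float(_draw_freq(model, rng, 1)[0])))

        # --- reference / absence calls ---
        absence_by_site: dict[str, dict] = {}
        for sid, meta in ref_meta.iterrows():
            present = vals.loc[sid] == 1.0
            pos = int(meta["position"])
            chrom = meta["chrom"]
            te_len = 200  # nominal element footprint for deletion spans
            if present:
                if rng.random() >= model.fn_rate:
                    off = int(round(rng.normal(0, model.ref_offset_sd))) if model.ref_offset_sd else 0
                    off = int(np.clip(off, -900, 900))
                    call_pos = int(np.clip(pos + off, 1, chrom_len[chrom]))
                    rows.append(dict(strain=strain, chrom=chrom, position=call_pos,
                                     family=meta["family"], kind=REFERENCE,
                                     read_support=int(_draw_support(model, rng, 1)[0]),
                                     both_end=True, call_freq=np.nan))
                if rng.random() < model.contradiction_rate:
                    rows.append(dict(strain=strain, chrom=chrom, position=pos,
                                     family=meta["family"], kind=ABSENCE,
                                     read_support=max(1, int(_draw_support(model, rng, 1)[0] // 3)),
                                     both_end=True, call_freq=np.nan,
                                     span_start=float(max(1, pos - 20)),
                                     span_end=float(pos + te_len + 20)))
            else:
                if rng.random() >= model.fn_rate:
                    absence_by_site[sid] = dict(
                        strain=strain, chrom=chrom, position=pos,
                        family=meta["family"], kind=ABSENCE,
                        read_support=int(_draw_support(model, rng, 1)[0]),
                        both_end=True, call_freq=np.nan,
                        span_start=float(max(1, pos - 20)), span_end=float(pos + te_len + 20))
                if rng.random() < model.contradiction_rate:
                    rows.append(dict(strain=strain, chrom=chrom, position=pos,
                                     family=meta["family"], kind=REFERENCE,
                                     read_support=max(1, int(_draw_support(model, rng, 1)[0] // 3)),
                                     both_end=True, call_freq=np.nan))

        # --- merge adjacent excisions into one spanning deletion call ---
        if model.spanning_rate > 0 and absence_by_site:
            order_idx = {sid: i for i, sid in enumerate(ref_meta.index)}
            ordered = [sid for sid in ref_meta.index if sid in absence_by_site]
            merged: set[str] = set()
            for a, b in zip(ordered, ordered[1:]):
                if a in merged or b in merged:
                    continue
                if ref_meta.loc[a, "chrom"] != ref_meta.loc[b, "chrom"]:
                    continue
                if order_idx[b] - order_idx[a] != 1:
                    continue  # only genuinely adjacent reference TEs share a span
                if rng.random() < model.spanning_rate:
                    ca, cb = absence_by_site[a], absence_by_site[b]
                    ca["span_end"] = cb["span_end"]
                    ca["read_support"] = max(ca["read_support"], cb["read_support"])
                    merged.add(b)
            for sid in merged:
                absence_by_site.pop(sid)
        rows.extend(absence_by_site.values())

        df = as_calls(rows) if rows else empty_calls()
        out[strain] = df.sort_values(["chrom", "position"], kind="stable", ignore_index=True)
    return out
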