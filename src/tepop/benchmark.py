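"""Benchmark TE calls against a simulated truth set (TPR / FDR).

Matching follows the closest-interval recipe: each call is paired with
its nearest truth event on the same chromosome (by start-position
distance) and counts as a true positive only when that nearest event
has the same family and lies within the cutoff distance.  TPR is
counted over truth events (an event detected by several calls counts
once); FDR over calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MATCH_COLUMNS = ["chrom", "position", "family", "truth_index", "distance", "is_tp"]


@dataclass
class BenchmarkResult:
    tpr: float  # percent of truth events recovered (NaN when no truth)
    fdr: float  # percent of calls that are false (NaN when no calls)
    n_true: int
    n_called: int
    n_matched: int
    read_support_min: int | None = None
    freq_min: float | None = None
    cutoff_distance: int | None = None


def match_calls_to_truth(
    calls: pd.DataFrame, truth: pd.DataFrame, cutoff_distance: int
) -> pd.DataFrame:
    """Annotate each call with its nearest truth event and TP status.

    ``calls`` and ``truth`` need columns ``chrom, position, family``.
    Nearest is by absolute start distance; ties resolve to the earlier
    truth position.  Calls on chromosomes without truth never match.
    """
    if cutoff_distance < 0:
        raise ValueError("cutoff_distance must be >= 0")
    truth = truth.reset_index(drop=True)
    out = calls[["chrom", "position", "family"]].copy().reset_index(drop=True)
    out["truth_index"] = -1
    out["distance"] = np.inf
    out["is_tp"] = False
    for chrom, tgrp in truth.groupby("chrom"):
        cmask = out["chrom"] == chrom
        if not cmask.any():
            continue
        order = np.argsort(tgrp["position"].to_numpy(), kind="stable")
        tpos = tgrp["position"].to_numpy()[order]
        tidx = tgrp.index.to_numpy()[order]
        cpos = out.loc[cmask, "position"].to_numpy()
        right = np.searchsorted(tpos, cpos)
        left = np.clip(right - 1, 0, len(tpos) - 1)
        right = np.clip(right, 0, len(tpos) - 1)
        d_left = np.abs(cpos - tpos[left])
        d_right = np.abs(cpos - tpos[right])
        use_left = d_left <= d_right  # tie -> earlier truth position
        nearest = np.where(use_left, tidx[left], tidx[right])
        dist = np.where(use_left, d_left, d_right)
        out.loc[cmask, "truth_index"] = nearest
        out.loc[cmask, "distance"] = dist
    matched = out["truth_index"] >= 0
    fam_of_truth = truth["family"].reindex(out.loc[matched, "truth_index"]).to_numpy()
    same_family = out.loc[matched, "family"].to_numpy() == fam_of_truth
    out.loc[matched, "is_tp"] = same_family & (out.loc[matched, "distance"] <= cutoff_distance)
    return out


def compute_tpr_fdr(
    matches: pd.DataFrame, truth: pd.DataFrame, calls: pd.DataFrame, **context
) -> BenchmarkResult:
    """Summarise matched calls into TPR/FDR percentages."""
    n_true = len(truth)
    n_called = len(calls)
    tp_truth = matches.loc[matches["is_tp"], "truth_index"].nunique()
    n_fp = int((~matches["is_tp"]).sum())
    tpr = np.nan if n_true == 0 else 100.0 * tp_truth / n_true
    fdr = np.nan if n_called == 0 else 100.0 * n_fp / n_called
    return BenchmarkResult(
        tpr=tpr, fdr=fdr, n_true=n_true, n_called=n_called, n_matched=int(tp_truth), **context
    )


def sweep_thresholds(
    calls: pd.DataFrame,
    truth: pd.DataFrame,
    read_support_grid: list[int],
    freq_grid: list[float],
    distance_grid: list[int],
) -> pd.DataFrame:
    """TPR/FDR over a grid of read-support, frequency and distance cutoffs.

    Calls are filtered by ``read_support >= s`` and ``call_freq > f``
    (missing frequencies pass) before matching at each distance cutoff.
    """
    if not (len(read_support_grid) and len(freq_grid) and len(distance_grid)):
        raise ValueError("threshold grids must be non-empty")
    rows = []
    for s in read_support_grid:
        for f in freq_grid:
            kept = calls[
                (calls["read_support"] >= s)
                & (calls["call_freq"].isna() | (calls["call_freq"] > f))
            ]
            for d in distance_grid:
                m = match_calls_to_truth(kept, truth, d)
                r = compute_tpr_fdr(m, truth, kept,
                                    read_support_min=s, freq_min=f, cutoff_distance=d)
                rows.append(vars(r))
    return pd.DataFrame(rows)


def filter_impact(pre: pd.DataFrame, post: pd.DataFrame) -> tuple[float, float]:
    """Percent of TP and FP calls a filter eliminated.

    ``pre`` and ``post`` are matched call tables (from
    :func:`match_calls_to_truth`) against the same truth; 0/0 counts as
    0 removed.
    """
    def pct_removed(n_pre: int, n_post: int) -> float:
        if n_pre == 0:
            return 0.0
        return 100.0 * (n_pre - n_post) / n_pre

    tp_pre, tp_post = int(pre["is_tp"].sum()), int(post["is_tp"].sum())
    fp_pre, fp_post = int((~pre["is_tp"]).sum()), int((~post["is_tp"]).sum())
    return pct_removed(tp_pre, tp_post), pct_removed(fp_pre, fp_post)
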