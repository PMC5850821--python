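"""Fold-coverage tracks: piecewise-constant depth per fixed-width window.

A track is ``dict[chrom -> numpy array of window depths]``; windows are
``window`` bp wide (default 25), matching the granularity needed by the
8x / +/-25 bp missing-data rule used when scoring insertion sites.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DEFAULT_WINDOW = 25


def constant_tracks(
    layout: pd.DataFrame, strains: list[str], depth: float, window: int = DEFAULT_WINDOW
) -> dict[str, dict[str, np.ndarray]]:
    """Uniform-depth tracks for every strain (handy in tests)."""
    per_chrom = {
        str(r["chrom"]): np.full(int(np.ceil(r["length"] / window)), float(depth))
        for _, r in layout.iterrows()
    }
    return {s: {c: d.copy() for c, d in per_chrom.items()} for s in strains}


def mean_coverage(
    track: dict[str, np.ndarray],
    chrom: str,
    position: int,
    flank: int = 25,
    window: int = DEFAULT_WINDOW,
) -> float:
    """Base-weighted mean depth over [position - flank, position + flank],
    clipped at chromosome ends."""
    depth = track[chrom]
    lo = max(1, position - flank)
    hi = min(len(depth) * window, position + flank)
    total = 0.0
    for widx in range((lo - 1) // window, (hi - 1) // window + 1):
        wlo, whi = widx * window + 1, (widx + 1) * window
        overlap = min(hi, whi) - max(lo, wlo) + 1
        total += overlap * depth[widx]
    return total / (hi - lo + 1)
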