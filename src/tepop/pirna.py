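"""Mismatch-bounded complementarity search of 21-nt piRNAs against TE consensus.

piRNAs are 21-nt germline small RNAs that can silence transposons via
base-pairing.  The search here is an exhaustive, ungapped full-length
scan: for every (piRNA, TE family) pair and each orientation it finds
the 21-bp consensus window at minimal Hamming distance and reports the
pair when that distance is at most ``max_mismatch`` (default 5).  At
this length and mismatch budget an exhaustive substitution-only scan is
strictly more sensitive than a heuristic seed-and-extend aligner, and
is fully reproducible.

Orientation convention: *sense* means the piRNA sequence matches the
consensus strand directly; *antisense* means it matches the reverse
complement.  Offsets are always reported on the forward consensus
strand (0-based position of the window start).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

PIRNA_LENGTH = 21

PAIRING_COLUMNS = ["pirna_id", "te_family", "orientation", "mismatches", "te_offset"]

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


_ACGT = _encode("ACGT")


def min_hamming_window(query: str, subject: str) -> tuple[int, int]:
    """Minimal Hamming distance of ``query`` over all full-length windows
    of ``subject`` and the (first) offset achieving it.

    Ambiguous bases (anything outside ACGT) never match, on either side.
    """
    q = _encode(query)
    s = _encode(subject)
    if len(s) < len(q):
        raise ValueError("subject shorter than query")
    windows = np.lib.stride_tricks.sliding_window_view(s, len(q))
    valid = np.isin(q, _ACGT)
    matches = (windows == q) & valid & np.isin(windows, _ACGT)
    mism = len(q) - matches.sum(axis=1)
    off = int(np.argmin(mism))
    return int(mism[off]), off


def align_pirnas(
    pirnas: pd.Series | dict[str, str],
    families: pd.DataFrame,
    max_mismatch: int = 5,
) -> pd.DataFrame:
    """Scan every piRNA against every family consensus in both orientations.

    ``pirnas`` maps id -> 21-nt sequence; ``families`` is indexed by
    family name with a ``consensus`` column.  One best record per
    (piRNA, family, orientation) with ``mismatches <= max_mismatch``;
    ties in distance go to the smallest forward-strand offset.
    """
    if isinstance(pirnas, dict):
        pirnas = pd.Series(pirnas)
    rows = []
    for pid, seq in pirnas.items():
        if len(seq) != PIRNA_LENGTH:
            raise ValueError(f"piRNA {pid} is {len(seq)} nt; expected {PIRNA_LENGTH}")
        rc = revcomp(seq)
        for fam, cons in families["consensus"].items():
            if len(cons) < PIRNA_LENGTH:
                raise ValueError(f"consensus of {fam} shorter than {PIRNA_LENGTH} nt")
            # antisense match of the piRNA == forward match of its reverse
            # complement, so offsets from both scans are forward-strand.
            for orientation, query in (("sense", seq), ("antisense", rc)):
                mm, off = min_hamming_window(query, cons)
                if mm <= max_mismatch:
                    rows.append((pid, fam, orientation, mm, off))
    return pd.DataFrame(rows, columns=PAIRING_COLUMNS)


def pairing_summary(pairings: pd.DataFrame, max_mismatch: int = 5) -> pd.Series:
    """Histogram of pairings per minimal mismatch level 0..max_mismatch.

    A (piRNA, family) pair counts once, at its minimal mismatch level
    across orientations.
    """
    levels = pd.Index(range(max_mismatch + 1), name="mismatches")
    if pairings.empty:
        return pd.Series(0, index=levels, name="n_pairings")
    best = pairings.groupby(["pirna_id", "te_family"])["mismatches"].min()
    counts = best.value_counts().reindex(levels, fill_value=0).sort_index()
    return counts.rename("n_pairings")


def cumulative_pairings(summary: pd.Series) -> pd.Series:
    """Pairings discovered when up to k mismatches are allowed."""
    return summary.cumsum().rename("n_cumulative")
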