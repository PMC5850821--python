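"""Schema for raw TE caller records.

One row per call: an *insertion* (novel TE detected by split reads), a
*reference* call (annotated reference TE confirmed present), or an
*absence* call (annotated reference TE excised).  Absence calls may
carry a (span_start, span_end) deletion span; a single span can cover
several adjacent reference TEs and is split by the harmonizer.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

INSERTION = "insertion"
REFERENCE = "reference"
ABSENCE = "absence"

KINDS = (INSERTION, REFERENCE, ABSENCE)

CALL_COLUMNS = [
    "strain",
    "chrom",
    "position",
    "family",
    "kind",
    "read_support",
    "both_end",
    "call_freq",
    "span_start",
    "span_end",
]

_DTYPES = {
    "strain": object,
    "chrom": object,
    "position": np.int64,
    "family": object,
    "kind": object,
    "read_support": np.int64,
    "both_end": bool,
    "call_freq": float,
    "span_start": float,  # float so missing spans are NaN
    "span_end": float,
}


def empty_calls() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=t) for c, t in _DTYPES.items()})


def as_calls(rows: list[dict]) -> pd.DataFrame:
    """Build a call table from row dicts, filling optional fields."""
    if not rows:
        return empty_calls()
    df = pd.DataFrame(rows)
    for col in CALL_COLUMNS:
        if col not in df:
            if col == "read_support":
                df[col] = 0
            elif col == "both_end":
                df[col] = True
            else:
                df[col] = np.nan
    return df[CALL_COLUMNS].astype({k: v for k, v in _DTYPES.items() if k in df})


def concat_calls(frames) -> pd.DataFrame:
    frames = [f for f in frames if len(f)]
    if not frames:
        return empty_calls()
    return pd.concat(frames, ignore_index=True)
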