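"""Generate piRNA sets with planted TE complements.

Planted piRNAs are 21-mers cut from a named family consensus (or its
reverse complement) with exactly ``k`` substitutions applied, verified
by brute-force scan so the minimal Hamming distance to that family
really is ``k``.  Background piRNAs are random 21-mers rejection-sampled
so that no family is within 5 mismatches in either orientation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..pirna import PIRNA_LENGTH, min_hamming_window, revcomp

_BASES = "ACGT"

PIRNA_META_COLUMNS = ["sequence", "planted_family", "planted_mismatches", "orientation"]


def _min_distance_to_family(seq: str, consensus: str) -> int:
    mm_s, _ = min_hamming_window(seq, consensus)
    mm_a, _ = min_hamming_window(revcomp(seq), consensus)
    return min(mm_s, mm_a)


def _substitute(seq: str, k: int, rng: np.random.Generator) -> str:
    chars = list(seq)
    for i in rng.choice(len(chars), size=k, replace=False):
        alternatives = [b for b in _BASES if b != chars[i]]
        chars[i] = alternatives[int(rng.integers(3))]
    return "".join(chars)


def make_pirna_set(
    families: pd.DataFrame,
    n_background: int,
    planted: list[tuple[str, int, str]] | None = None,
    seed: int = 0,
    max_tries: int = 200,
) -> pd.DataFrame:
    """Build a piRNA table (indexed by id, columns ``sequence``,
    ``planted_family``, ``planted_mismatches``, ``orientation``).

    ``planted`` entries are ``(family, k, orientation)`` with k in 0..5
    and orientation ``sense``/``antisense``.
    """
    planted = planted or []
    rng = np.random.default_rng(seed)
    rows: dict[str, tuple] = {}
    idx = 0
    for family, k, orientation in planted:
        if not 0 <= k <= 5:
            raise ValueError("planted mismatch count must be in 0..5")
        if orientation not in ("sense", "antisense"):
            raise ValueError(f"unknown orientation {orientation!r}")
        cons = families.loc[family, "consensus"]
        if len(cons) < PIRNA_LENGTH:
            raise ValueError(f"consensus of {family} shorter than {PIRNA_LENGTH} nt")
        for _ in range(max_tries):
            off = int(rng.integers(0, len(cons) - PIRNA_LENGTH + 1))
            window = cons[off : off + PIRNA_LENGTH]
            seq = window if orientation == "sense" else revcomp(window)
            seq = _substitute(seq, k, rng)
            # another window (or the other strand) may lie closer by chance;
            # resample until the minimal distance is exactly k
            if _min_distance_to_family(seq, cons) == k:
                break
        else:
            raise RuntimeError(f"could not plant a clean {k}-mismatch piRNA in {family}")
        rows[f"21ur-sim{idx:04d}"] = (seq, family, k, orientation)
        idx += 1
    for _ in range(n_background):
        for _ in range(max_tries):
            seq = "".join(rng.choice(list(_BASES), size=PIRNA_LENGTH))
            if all(_min_distance_to_family(seq, c) > 5 for c in families["consensus"]):
                break
        else:
            raise RuntimeError("could not sample a background piRNA clear of all families")
        rows[f"21ur-sim{idx:04d}"] = (seq, np.nan, np.nan, np.nan)
        idx += 1
    out = pd.DataFrame.from_dict(rows, orient="index", columns=PIRNA_META_COLUMNS)
    out.index.name = "pirna_id"
    return out
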