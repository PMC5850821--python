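"""Naive reference implementations used as independent oracles.

Everything here is deliberately O(n^2)-ish and written from the rule
definitions, not from the package code paths it checks.
"""

from __future__ import annotations

import numpy as np


def union_find_components(positions, link, strict: bool) -> list[list[int]]:
    """Single-linkage components over 1-D positions via all-pairs union."""
    n = len(positions)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            d = abs(positions[i] - positions[j])
            if (d < link) if strict else (d <= link):
                parent[find(i)] = find(j)
    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)
    return list(comps.values())


def brute_collapse(records, limit: int):
    """records: list of (position, read_support).  Returns surviving
    (position, read_support) per component: max support, tie -> smallest
    position.  Components use strict < linkage."""
    if not records:
        return []
    pos = [r[0] for r in records]
    out = []
    for comp in union_find_components(pos, limit, strict=True):
        members = [records[i] for i in comp]
        best = max(members, key=lambda r: (r[1], -r[0]))
        out.append(best)
    return sorted(out)


def brute_merge(records, link: int = 50):
    """records: list of (position, strain).  Returns sorted list of
    (mean_position_rounded_half_up, carrier set) with <= linkage."""
    if not records:
        return []
    pos = [r[0] for r in records]
    out = []
    for comp in union_find_components(pos, link, strict=False):
        members = [records[i] for i in comp]
        mean = sum(m[0] for m in members) / len(members)
        out.append((int(np.floor(mean + 0.5)), frozenset(m[1] for m in members)))
    return sorted(out)


def brute_nearest_match(call_pos, call_fam, truth, cutoff):
    """truth: list of (position, family).  True positive iff the nearest
    truth event (ties -> earlier position) shares the family and lies
    within cutoff."""
    if not truth:
        return False
    best = min(truth, key=lambda t: (abs(t[0] - call_pos), t[0]))
    return best[1] == call_fam and abs(best[0] - call_pos) <= cutoff


def brute_contained(span, annotated):
    """Annotated positions inside [span_start, span_end], inclusive."""
    lo, hi = span
    return sorted(p for p in annotated if lo <= p <= hi)


def brute_min_hamming(query: str, subject: str):
    """Minimal mismatches of query over all full windows of subject;
    non-ACGT on either side never matches."""
    acgt = set("ACGT")
    best, best_off = len(query) + 1, -1
    for off in range(len(subject) - len(query) + 1):
        window = subject[off : off + len(query)]
        mm = sum(
            1
            for a, b in zip(query, window)
            if a not in acgt or b not in acgt or a != b
        )
        if mm < best:
            best, best_off = mm, off
    return best, best_off


def brute_tajimas_d(G: np.ndarray):
    """Independent Tajima's D: explicit pairwise-difference loops and
    freshly derived constants.  G: strains x sites in {0,1} (complete)."""
    n, L = G.shape
    S = 0
    for j in range(L):
        col = G[:, j]
        if 0 < col.sum() < n:
            S += 1
    if S == 0 or n < 4:
        return float("nan")
    diffs = []
    for i in range(n):
        for k in range(i + 1, n):
            diffs.append(int(np.sum(G[i] != G[k])))
    pi = sum(diffs) / len(diffs) * 1.0  # mean pairwise differences
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (pi - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))
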