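"""Independent reference implementations used only to check the package.

These deliberately avoid the code paths they verify: edit distance is a
NumPy row-DP rather than edlib; coordinate projection walks a per-base map;
genotype likelihoods are evaluated directly.
"""

from __future__ import annotations

import math

import numpy as np


def levenshtein(a: str, b: str) -> int:
    """Classic DP edit distance, vectorized one row at a time."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    bb = np.frombuffer(b.encode(), dtype=np.uint8)
    jj = np.arange(len(b), dtype=np.int64)
    prev = np.arange(len(b) + 1, dtype=np.int64)
    for i, ca in enumerate(a.encode()):
        # without the left-neighbour (insertion) term:
        m = np.minimum(prev[:-1] + (bb != ca), prev[1:] + 1)
        # closure over insertions: cur[j+1] = min(min_{k<=j} m[k] + (j-k),
        #                                         cur[0] + (j+1))
        chain = np.minimum.accumulate(m - jj) + jj
        cur = np.empty(len(b) + 1, dtype=np.int64)
        cur[0] = i + 1
        cur[1:] = np.minimum(chain, (i + 2) + jj)
        prev = cur
    return int(prev[-1])


def per_base_map(cigar: list[tuple[str, int]], target_start: int) -> dict[int, int]:
    """target position -> query position for every aligned (=/X) column."""
    t, q = target_start, 0
    mapping: dict[int, int] = {}
    for op, n in cigar:
        if op in "=X":
            for i in range(n):
                mapping[t + i] = q + i
            t += n
            q += n
        elif op == "D":
            t += n
        elif op in "IS":
            q += n
    return mapping


def project_interval_by_map(
    mapping: dict[int, int], start: int, end: int
) -> tuple[int, int] | None:
    hits = [mapping[p] for p in range(start, end) if p in mapping]
    if not hits:
        return None
    return min(hits), max(hits) + 1


def genotype_gq(n_ref: int, n_alt: int, error_rate: float) -> tuple[str, float]:
    """Direct evaluation of the three diploid genotype likelihoods."""
    e = error_rate
    ll = {
        "RR": n_alt * math.log10(e) + n_ref * math.log10(1 - e),
        "RA": (n_ref + n_alt) * math.log10(0.5),
        "AA": n_ref * math.log10(e) + n_alt * math.log10(1 - e),
    }
    best, second = sorted(ll.values(), reverse=True)[:2]
    gt = max(ll, key=ll.get)
    return gt, min(99.0, 10.0 * (best - second))
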