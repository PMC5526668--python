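"""Exhaustive brute-force direct-repeat oracle for equivalence testing.

Independent of the seeded search in the package: every diagonal of the
self-comparison matrix is scanned in full, so a seeding bug in the
implementation cannot hide here. A window on diagonal ``d`` pairs
``[lo, hi)`` with ``[lo + d, hi + d)``; a window is reported iff

* it starts and ends with a match,
* it contains at most ``max_mismatch`` mismatches,
* it is maximal: not contained in any other window satisfying the first two
  conditions (for each left end the longest admissible window is taken; since
  that right end is non-decreasing in the left end, containment arises exactly
  between windows sharing a right end, where the leftmost survives),
* its length and gap satisfy the search criteria.
"""

from __future__ import annotations

import numpy as np


def brute_force_direct_repeats(
    sequence: str,
    min_len: int,
    max_mismatch: int,
    max_gap: int,
    min_gap: int,
) -> set[tuple[int, int, int, int]]:
    """Return ``{(start1, start2, length, hamming)}`` for every qualifying
    maximal forward-repeat pair (linear sequence)."""
    a = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    n = len(a)
    h = max_mismatch
    out: set[tuple[int, int, int, int]] = set()
    for d in range(min_len + min_gap, n - min_len + 1):
        m = n - d
        neq = a[:m] != a[d:]
        mis = np.flatnonzero(neq)
        cum = np.concatenate(([0], np.cumsum(neq)))
        match = ~neq
        # candidate left ends: match positions at 0 or right after a mismatch
        prev_is_mis = np.concatenate(([True], neq[:-1]))
        lefts = np.flatnonzero(match & prev_is_mis)
        if lefts.size == 0:
            continue
        # right boundary before the (h+1)-th mismatch after each left end
        t = cum[lefts] + h
        hi0 = np.where(t < len(mis), mis[np.minimum(t, len(mis) - 1)], m)
        # trim trailing mismatches: end at the last match before hi0
        match_idx = np.where(match, np.arange(m), -1)
        last_match_upto = np.maximum.accumulate(match_idx)
        hi = last_match_upto[np.maximum(hi0 - 1, 0)] + 1
        # containment: hi is non-decreasing in the left end, so among windows
        # sharing a right end only the leftmost (first) is maximal
        keep = np.concatenate(([True], hi[1:] > hi[:-1]))
        lo_k, hi_k = lefts[keep], hi[keep]
        counts = cum[hi_k] - cum[lo_k]
        lengths = hi_k - lo_k
        gaps = d - lengths
        ok = (
            (hi_k > lo_k)
            & (lengths >= min_len)
            & (gaps >= min_gap)
            & (gaps <= max_gap)
        )
        for lo, hi_i, c in zip(lo_k[ok], hi_k[ok], counts[ok]):
            out.add((int(lo), int(lo + d), int(hi_i - lo), int(c)))
    return out
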