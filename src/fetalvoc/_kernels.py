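"""Numba-jitted inner loops shared by the state-coding, overlap, and DTW code.

These kernels exist because the permutation null reruns the overlap pairing
tens of thousands of times and template matching evaluates dynamic programs
over ~10^4-cell lattices per profile pair.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def greedy_pairs(onsets, offsets, kinds):
    """Pair overlapping units of opposite kinds, first-overlapper-wins.

    Inputs are merged streams sorted by (onset, kind). Two units of opposite
    kind pair when they share an onset frame, or when the later unit's onset
    falls strictly inside the earlier unit's interval (at least one frame
    after its onset and strictly before its offset). Each unit joins at most
    one pair; a unit overlapping several others pairs with the earliest.

    Returns an int64 array ``partner`` with ``partner[i]`` the merged-stream
    index of unit i's pair mate, or -1 if unpaired.
    """
    n = onsets.size
    partner = np.full(n, -1, dtype=np.int64)
    for i in range(n):
        if partner[i] >= 0:
            continue
        for j in range(i + 1, n):
            if onsets[j] > onsets[i] and onsets[j] >= offsets[i]:
                break  # sorted onsets: no later unit can overlap i
            if kinds[j] == kinds[i] or partner[j] >= 0:
                continue
            if onsets[j] == onsets[i] or onsets[j] < offsets[i]:
                # same onset frame, or strictly inside (onsets[j] > onsets[i]
                # is guaranteed by the sort and the break above)
                partner[i] = j
                partner[j] = i
                break
    return partner


@njit(cache=True)
def dtw_cost_kernel(a, b):
    """Minimal cumulative |a_i - b_j| over monotone warping paths.

    Steps {(1,0), (0,1), (1,1)}, both endpoint pairs matched, no path-length
    normalization. O(len(a) * len(b)) time, O(len(b)) memory.
    """
    n = a.size
    m = b.size
    prev = np.empty(m, dtype=np.float64)
    cur = np.empty(m, dtype=np.float64)
    prev[0] = abs(a[0] - b[0])
    for j in range(1, m):
        prev[j] = prev[j - 1] + abs(a[0] - b[j])
    for i in range(1, n):
        cur[0] = prev[0] + abs(a[i] - b[0])
        for j in range(1, m):
            best = prev[j]
            if prev[j - 1] < best:
                best = prev[j - 1]
            if cur[j - 1] < best:
                best = cur[j - 1]
            cur[j] = abs(a[i] - b[j]) + best
        prev, cur = cur, prev
    return prev[m - 1]


@njit(cache=True)
def dtw_matrix(a, b):
    """Full accumulated-cost matrix for the same recursion as dtw_cost_kernel."""
    n = a.size
    m = b.size
    acc = np.empty((n, m), dtype=np.float64)
    acc[0, 0] = abs(a[0] - b[0])
    for j in range(1, m):
        acc[0, j] = acc[0, j - 1] + abs(a[0] - b[j])
    for i in range(1, n):
        acc[i, 0] = acc[i - 1, 0] + abs(a[i] - b[0])
        for j in range(1, m):
            best = acc[i - 1, j]
            if acc[i - 1, j - 1] < best:
                best = acc[i - 1, j - 1]
            if acc[i, j - 1] < best:
                best = acc[i, j - 1]
            acc[i, j] = abs(a[i] - b[j]) + best
    return acc
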