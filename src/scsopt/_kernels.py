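"""Numba kernels for the hot inner loops.

All kernels operate on int64 arrays: a candidate supersequence ``cand``
(1-D) and an instance given as a zero-padded matrix ``strs`` of shape
(n, k_max) with true row lengths in ``lens``. Padding values are never
read because every scan is bounded by ``lens``.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def greedy_match_counts(cand, strs, lens):
    """Per-string count of characters matched by a greedy left-to-right
    scan of ``cand``."""
    n = strs.shape[0]
    out = np.empty(n, np.int64)
    for j in range(n):
        p = 0
        lj = lens[j]
        for i in range(cand.shape[0]):
            if p < lj and cand[i] == strs[j, p]:
                p += 1
        out[j] = p
    return out


@njit(cache=True)
def is_subseq(s, t):
    p = 0
    ls = s.shape[0]
    for i in range(t.shape[0]):
        if p < ls and t[i] == s[p]:
            p += 1
    return p == ls


@njit(cache=True)
def trim_pass(cand, strs, lens):
    """One deterministic left-to-right deletion pass.

    Position i is dropped iff the string formed by the kept prefix plus
    the untouched suffix cand[i+1:] is still a common supersequence.
    The test uses the identity: s is a subsequence of u+v  iff
    (forward greedy match of s in u) + (backward greedy match of s in v)
    covers all of s. Backward matches over every suffix are precomputed
    once, so the whole pass is O(n * len(cand)).
    """
    L = cand.shape[0]
    n = strs.shape[0]
    # G[i, j]: chars of string j matched greedily from its END by cand[i:]
    G = np.zeros((L + 1, n), np.int64)
    for i in range(L - 1, -1, -1):
        for j in range(n):
            g = G[i + 1, j]
            if g < lens[j] and cand[i] == strs[j, lens[j] - g - 1]:
                G[i, j] = g + 1
            else:
                G[i, j] = g
    keep = np.zeros(L, np.bool_)
    f = np.zeros(n, np.int64)  # forward greedy match over kept prefix
    for i in range(L):
        deletable = True
        for j in range(n):
            if f[j] + G[i + 1, j] < lens[j]:
                deletable = False
                break
        if deletable:
            continue
        keep[i] = True
        for j in range(n):
            if f[j] < lens[j] and cand[i] == strs[j, f[j]]:
                f[j] += 1
    return cand[keep]


@njit(cache=True)
def majority_merge_append(cand, strs, lens, nsym):
    """Append characters to ``cand`` until it is a common supersequence.

    Greedy-match each string against cand first, then repeatedly emit the
    code whose emission advances the most pending strings (ties broken by
    the lowest code), advancing their pointers, until none are pending.
    """
    n = strs.shape[0]
    f = np.zeros(n, np.int64)
    for i in range(cand.shape[0]):
        for j in range(n):
            if f[j] < lens[j] and cand[i] == strs[j, f[j]]:
                f[j] += 1
    rem = 0
    for j in range(n):
        rem += lens[j] - f[j]
    out = np.empty(cand.shape[0] + rem, np.int64)
    out[: cand.shape[0]] = cand
    pos = cand.shape[0]
    counts = np.zeros(nsym, np.int64)
    while True:
        done = True
        for c in range(nsym):
            counts[c] = 0
        for j in range(n):
            if f[j] < lens[j]:
                done = False
                counts[strs[j, f[j]]] += 1
        if done:
            break
        best = 0
        for c in range(1, nsym):
            if counts[c] > counts[best]:
                best = c
        out[pos] = best
        pos += 1
        for j in range(n):
            if f[j] < lens[j] and strs[j, f[j]] == best:
                f[j] += 1
    return out[:pos]
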