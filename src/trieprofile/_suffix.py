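"""Suffix-array and LCP primitives used by the empirical profiler.

The suffix array is built by prefix doubling over numpy ``lexsort``
passes.  Each round sorts by the rank pair ``(rank[i], rank[i+h])`` and
terminates as soon as all ranks are distinct — for texts whose longest
repeat has length ``L`` that happens once ``h > L``, i.e. after
``O(log L)`` rounds, which makes the construction fast on random
sequences (where ``L`` is a few dozen even at millions of characters).

Adjacent LCPs come from Kasai's linear-time algorithm, JIT-compiled with
numba since it is an inherently sequential scan.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["suffix_array", "lcp_array"]


def suffix_array(text: np.ndarray) -> np.ndarray:
    """Suffix array of an integer text (any comparable dtype).

    Returns ``sa`` with ``sa[j]`` = start of the j-th smallest suffix.
    The caller is responsible for sentinels; ties between a suffix and a
    proper prefix of it cannot occur when the text ends with a unique
    smallest symbol.
    """
    text = np.ascontiguousarray(text)
    n = text.size
    if n == 0:
        return np.empty(0, dtype=np.int64)
    # initial ranks: dense codes of the single characters
    uniq, rank = np.unique(text, return_inverse=True)
    rank = rank.astype(np.int64)
    order = np.argsort(rank, kind="stable")
    if uniq.size == n:
        return order
    h = 1
    while h < n:
        key2 = np.full(n, -1, dtype=np.int64)
        key2[: n - h] = rank[h:]
        order = np.lexsort((key2, rank))
        r1 = rank[order]
        r2 = key2[order]
        changed = np.empty(n, dtype=np.int64)
        changed[0] = 0
        changed[1:] = (r1[1:] != r1[:-1]) | (r2[1:] != r2[:-1])
        new_rank = np.cumsum(changed)
        rank = np.empty(n, dtype=np.int64)
        rank[order] = new_rank
        if new_rank[-1] == n - 1:
            break
        h *= 2
    return order


@njit(cache=True)
def _kasai(text: np.ndarray, sa: np.ndarray, rank: np.ndarray) -> np.ndarray:
    n = text.size
    lcp = np.zeros(n, dtype=np.int64)  # lcp[j] = LCP(suffix sa[j-1], suffix sa[j])
    h = 0
    for i in range(n):
        r = rank[i]
        if r > 0:
            j = sa[r - 1]
            while i + h < n and j + h < n and text[i + h] == text[j + h]:
                h += 1
            lcp[r] = h
            if h > 0:
                h -= 1
        else:
            h = 0
    return lcp


def lcp_array(text: np.ndarray, sa: np.ndarray) -> np.ndarray:
    """Adjacent-LCP array in suffix-array order (``lcp[0] = 0``)."""
    text = np.ascontiguousarray(text, dtype=np.int64)
    sa = np.ascontiguousarray(sa, dtype=np.int64)
    rank = np.empty(text.size, dtype=np.int64)
    rank[sa] = np.arange(text.size, dtype=np.int64)
    return _kasai(text, sa, rank)
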