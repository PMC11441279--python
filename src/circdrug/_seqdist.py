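"""Numba kernels for pairwise sequence comparison.

Sequences are passed as uint8 code arrays.  Two distances are provided:

* ``lcs_len`` — longest common subsequence length; the "ratio" similarity
  (edit distance with substitution cost 2) is 2*LCS/(|a|+|b|).
* ``levenshtein`` — plain unit-cost edit distance.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def lcs_len(a: np.ndarray, b: np.ndarray) -> int:
    la, lb = a.size, b.size
    prev = np.zeros(lb + 1, dtype=np.int64)
    curr = np.zeros(lb + 1, dtype=np.int64)
    for i in range(1, la + 1):
        ai = a[i - 1]
        for j in range(1, lb + 1):
            if ai == b[j - 1]:
                curr[j] = prev[j - 1] + 1
            elif prev[j] >= curr[j - 1]:
                curr[j] = prev[j]
            else:
                curr[j] = curr[j - 1]
        prev, curr = curr, prev
    return prev[lb]


@njit(cache=True)
def levenshtein(a: np.ndarray, b: np.ndarray) -> int:
    la, lb = a.size, b.size
    prev = np.arange(lb + 1)
    curr = np.zeros(lb + 1, dtype=np.int64)
    for i in range(1, la + 1):
        curr[0] = i
        ai = a[i - 1]
        for j in range(1, lb + 1):
            cost = 0 if ai == b[j - 1] else 1
            d = prev[j - 1] + cost
            if prev[j] + 1 < d:
                d = prev[j] + 1
            if curr[j - 1] + 1 < d:
                d = curr[j - 1] + 1
            curr[j] = d
        prev, curr = curr, prev
    return prev[lb]


def encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
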