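"""Numba kernel for the quadratic sample-entropy template search."""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def sampen_counts(x: np.ndarray, m: int, r: float):
    """Template-match counts (A, B) for sample entropy.

    B counts pairs of length-m templates within Chebyshev distance r
    (self-matches excluded, templates restricted so the m+1 extension
    exists); A counts the same pairs still matching at length m+1.
    """
    n = x.shape[0]
    nt = n - m
    A = 0
    B = 0
    for i in range(nt - 1):
        for j in range(i + 1, nt):
            ok = True
            for k in range(m):
                if abs(x[i + k] - x[j + k]) > r:
                    ok = False
                    break
            if ok:
                B += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    A += 1
    return A, B
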