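"""Dynamic time warping between dominant-frequency contours.

Standard unconstrained DTW with the symmetric step pattern
(diagonal, horizontal and vertical moves all weighted 1) and absolute
difference as the local cost.  No warping window, no endpoint slack:
dist(a, a) = 0 and dist(a, b) = dist(b, a).
"""

from __future__ import annotations

import numpy as np

__all__ = ["dtw_distance", "pairwise_dtw"]


def dtw_distance(a, b) -> float:
    """DTW distance between two 1-D sequences (e.g. contours in kHz)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("DTW requires non-empty contours")
    n, m = a.size, b.size
    cost = np.abs(a[:, None] - b[None, :])
    D = np.full((n + 1, m + 1), np.inf)
    D[0, 0] = 0.0
    for i in range(1, n + 1):
        row = D[i]
        prev = D[i - 1]
        ci = cost[i - 1]
        for j in range(1, m + 1):
            row[j] = ci[j - 1] + min(prev[j], prev[j - 1], row[j - 1])
    return float(D[n, m])


def pairwise_dtw(contours) -> np.ndarray:
    """Symmetric zero-diagonal matrix of DTW distances over all contours."""
    n = len(contours)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = dtw_distance(contours[i], contours[j])
            out[i, j] = out[j, i] = d
    return out
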