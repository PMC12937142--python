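"""Independent brute-force oracles used only by the tests.

These deliberately avoid the production code paths: template matching is
done with full pairwise Chebyshev distance matrices
(scipy.spatial.distance.cdist) instead of the numba loop kernels, and the
step-up FDR is a literal transcription of the procedure's definition.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.spatial.distance import cdist


def sampen_counts_oracle(x: np.ndarray, m: int, r: float) -> tuple[int, int]:
    """Unordered template-pair counts (A, B) by exhaustive enumeration."""
    x = np.asarray(x, dtype=float)
    nt = x.size - m
    Xm = sliding_window_view(x, m)[:nt]
    Xm1 = sliding_window_view(x, m + 1)
    dm = cdist(Xm, Xm, "chebyshev")
    dm1 = cdist(Xm1, Xm1, "chebyshev")
    b = int(((dm <= r).sum() - nt) // 2)
    a = int(((dm1 <= r).sum() - nt) // 2)
    return a, b


def sampen_oracle(x: np.ndarray, m: int, r: float) -> float:
    a, b = sampen_counts_oracle(x, m, r)
    if a == 0 or b == 0:
        return float("nan")
    return -float(np.log(a / b))


def xsampen_oracle(u: np.ndarray, v: np.ndarray, m: int, r: float) -> float:
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nt = u.size - m
    Um = sliding_window_view(u, m)[:nt]
    Vm = sliding_window_view(v, m)[:nt]
    Um1 = sliding_window_view(u, m + 1)
    Vm1 = sliding_window_view(v, m + 1)
    b = int((cdist(Um, Vm, "chebyshev") <= r).sum())
    a = int((cdist(Um1, Vm1, "chebyshev") <= r).sum())
    if a == 0 or b == 0:
        return float("nan")
    return -float(np.log(a / b))


def bh_oracle(pvals: np.ndarray) -> np.ndarray:
    """Step-up Benjamini–Hochberg: q_i = min_{j: rank_j ≥ rank_i} p_j·n/rank_j."""
    p = np.asarray(pvals, dtype=float)
    n = p.size
    order = np.argsort(p, kind="mergesort")
    q = np.empty(n)
    running = np.inf
    for pos in range(n - 1, -1, -1):
        i = order[pos]
        running = min(running, p[i] * n / (pos + 1))
        q[i] = min(running, 1.0)
    return q
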