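"""Approximate-entropy template counting kernels.

Classic Pincus ApEn: ApEn(m, r) = Phi^m(r) - Phi^{m+1}(r), where Phi^m(r) is
the mean over templates of log(C_i / n_templates) and C_i counts templates
within Chebyshev distance r of template i, self-match included.

The numba kernel counts matches for embedding dimensions m and m+1 in one
O(N^2) pass over template pairs (the m+1 check reuses the m-prefix
distance). A pure-numpy chunked fallback covers environments where numba
is unavailable.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - import guard
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _apen_counts_py(x: np.ndarray, m: int, r: float) -> tuple[np.ndarray, np.ndarray]:
    """Chunked numpy pairwise Chebyshev counts; self-matches included."""
    n = x.shape[0]
    nm1 = n - m + 1
    nm2 = n - m
    emb1 = np.lib.stride_tricks.sliding_window_view(x, m)  # (nm1, m)
    emb2 = np.lib.stride_tricks.sliding_window_view(x, m + 1)  # (nm2, m+1)
    cm = np.zeros(nm1)
    cm1 = np.zeros(nm2)
    chunk = max(1, int(2e7) // max(n, 1))
    for s in range(0, nm1, chunk):
        block = emb1[s:s + chunk, None, :] - emb1[None, :, :]
        d = np.abs(block).max(axis=2)
        cm[s:s + chunk] = (d <= r).sum(axis=1)
    for s in range(0, nm2, chunk):
        block = emb2[s:s + chunk, None, :] - emb2[None, :, :]
        d = np.abs(block).max(axis=2)
        cm1[s:s + chunk] = (d <= r).sum(axis=1)
    return cm, cm1


if _HAVE_NUMBA:

    @njit(cache=False)
    def _apen_counts_nb(x, m, r):  # pragma: no cover - compiled
        n = x.shape[0]
        nm1 = n - m + 1
        nm2 = n - m
        cm = np.ones(nm1)
        cm1 = np.ones(nm2)
        for i in range(nm1):
            for j in range(i + 1, nm1):
                d = 0.0
                for k in range(m):
                    dd = abs(x[i + k] - x[j + k])
                    if dd > d:
                        d = dd
                if d <= r:
                    cm[i] += 1.0
                    cm[j] += 1.0
                    if j < nm2:
                        dd = abs(x[i + m] - x[j + m])
                        if dd > d:
                            d = dd
                        if d <= r:
                            cm1[i] += 1.0
                            cm1[j] += 1.0
        return cm, cm1


def apen_counts(x: np.ndarray, m: int, r: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-template match counts for dimensions m and m+1 (self-matches in)."""
    x = np.ascontiguousarray(x, dtype=np.float64)
    if _HAVE_NUMBA:
        return _apen_counts_nb(x, m, r)
    return _apen_counts_py(x, m, r)
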