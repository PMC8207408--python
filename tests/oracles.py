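"""From-definition brute-force oracles, kept independent of the package's
vectorized implementations."""

import numpy as np


def nodf_bruteforce(A: np.ndarray) -> float:
    """NODF straight from the paired definition: for each unordered pair of
    rows with strictly decreasing positive totals, 100 * overlap / smaller
    total; zero on ties or empty partners; same over columns; averaged over
    all row and column pairs."""
    A = np.asarray(A)
    n, m = A.shape
    total = 0.0
    for M in (A, A.T):
        r = M.shape[0]
        k = M.sum(axis=1)
        for i in range(r):
            for j in range(i + 1, r):
                if k[i] == k[j]:
                    continue
                hi, lo = (i, j) if k[i] > k[j] else (j, i)
                if k[lo] == 0:
                    continue
                overlap = int(np.sum(M[hi] & M[lo]))
                total += 100.0 * overlap / k[lo]
    return total / (n * (n - 1) / 2 + m * (m - 1) / 2)


def barber_q_bruteforce(A: np.ndarray, g: np.ndarray, h: np.ndarray) -> float:
    """Q_B as the literal double sum over all cells."""
    A = np.asarray(A, dtype=float)
    F = A.sum()
    k = A.sum(axis=1)
    d = A.sum(axis=0)
    q = 0.0
    for i in range(A.shape[0]):
        for j in range(A.shape[1]):
            if g[i] == h[j]:
                q += A[i, j] - k[i] * d[j] / F
    return q / F
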