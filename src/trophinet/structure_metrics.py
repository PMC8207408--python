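"""Whole-network structure metrics: connectance, degree statistics, NODF
nestedness, and a correspondence-analysis ordination of the incidence matrix.

NODF follows the original paired overlap-and-decreasing-fill definition: for
every ordered pair of rows (i, j) with strictly decreasing positive marginal
totals k_i > k_j > 0 the pair contributes ``100 * |row_i AND row_j| / k_j``,
and zero on marginal ties or empty partners; likewise over column pairs.  The
metric is the mean over all n(n-1)/2 + m(m-1)/2 pairs, so it lies in
[0, 100] and needs no pre-sorting of the matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .network_core import BipartiteNetwork

__all__ = [
    "connectance",
    "DegreeSummary",
    "degree_summary",
    "nodf",
    "CAResult",
    "correspondence_analysis",
    "summarize",
]


def _as_matrix(net: BipartiteNetwork | np.ndarray) -> np.ndarray:
    if isinstance(net, BipartiteNetwork):
        return net.A
    A = np.asarray(net)
    if A.ndim != 2:
        raise ValueError("expected a 2-D incidence matrix")
    return A


def connectance(net: BipartiteNetwork | np.ndarray) -> float:
    """Fraction of possible links realized, C = F / (n * m)."""
    A = _as_matrix(net)
    n, m = A.shape
    if n * m == 0:
        raise ValueError("empty matrix")
    return float(A.sum() / (n * m))


@dataclass(frozen=True)
class DegreeSummary:
    """Degree-distribution descriptors of a consumer-resource network."""

    consumer_degrees: np.ndarray
    resource_degrees: np.ndarray
    mean_degree: float  #: mean consumer degree F / n
    frac_low: float  #: fraction of consumers with degree <= 2
    frac_high: float  #: fraction of consumers with degree > 5
    resource_share: np.ndarray  #: per-resource fraction of all interactions


def degree_summary(net: BipartiteNetwork | np.ndarray) -> DegreeSummary:
    A = _as_matrix(net)
    k = A.sum(axis=1).astype(np.int64)
    d = A.sum(axis=0).astype(np.int64)
    F = int(k.sum())
    return DegreeSummary(
        consumer_degrees=k,
        resource_degrees=d,
        mean_degree=F / A.shape[0],
        frac_low=float(np.mean(k <= 2)),
        frac_high=float(np.mean(k > 5)),
        resource_share=d / F if F else np.zeros_like(d, dtype=float),
    )


def nodf(net: BipartiteNetwork | np.ndarray) -> float:
    """NODF nestedness in [0, 100] (strict decreasing-fill convention)."""
    A = _as_matrix(net).astype(np.int64)
    n, m = A.shape
    n_pairs = n * (n - 1) // 2 + m * (m - 1) // 2
    if n_pairs == 0:
        raise ValueError("NODF needs at least two rows or two columns")
    total = 0.0
    for M in (A, A.T):
        k = M.sum(axis=1)
        overlap = M @ M.T  # |row_i AND row_j|
        # pair (i, j) counts when k_i > k_j > 0; term = 100 * overlap / k_j
        ki = k[:, None]
        kj = k[None, :]
        valid = (ki > kj) & (kj > 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(valid, overlap / np.where(kj > 0, kj, 1), 0.0)
        total += 100.0 * terms.sum()
    return float(total / n_pairs)


@dataclass(frozen=True)
class CAResult:
    """Correspondence-analysis ordination (symmetric scaling)."""

    row_coords: np.ndarray  #: n x n_axes
    col_coords: np.ndarray  #: m x n_axes
    inertia: np.ndarray  #: per-axis principal inertia (singular value squared)
    total_inertia: float  #: chi-square statistic of the table divided by F


def correspondence_analysis(
    net: BipartiteNetwork | np.ndarray, n_axes: int = 2
) -> CAResult:
    """Correspondence analysis of the incidence matrix treated as a
    contingency table.

    Coordinates come from the SVD of the standardized residual matrix
    ``D_r^{-1/2} (P - r c^T) D_c^{-1/2}`` with P = A/F; symmetric scaling
    assigns both rows and columns principal-like coordinates scaled by the
    square root of the singular values.  Fewer axes than requested are
    returned on rank-deficient tables.
    """
    A = _as_matrix(net).astype(float)
    if (A.sum(axis=1) == 0).any() or (A.sum(axis=0) == 0).any():
        raise ValueError("correspondence analysis requires no all-zero rows or columns")
    F = A.sum()
    P = A / F
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, Vt = linalg.svd(S, full_matrices=False)
    keep = sv > 1e-12
    U, sv, Vt = U[:, keep], sv[keep], Vt[keep]
    n_axes = min(n_axes, sv.size)
    U, sv, Vt = U[:, :n_axes], sv[:n_axes], Vt[:n_axes]
    srt = np.sqrt(sv)
    row = (U / np.sqrt(r)[:, None]) * srt[None, :]
    col = (Vt.T / np.sqrt(c)[:, None]) * srt[None, :]
    total = float((S**2).sum())  # chi-square / F
    return CAResult(row_coords=row, col_coords=col, inertia=sv**2, total_inertia=total)


def summarize(net: BipartiteNetwork) -> dict:
    """One-row structural summary: species/resource richness, mean degree,
    connectance, NODF (module counts and modularity are added by the
    pipeline, which owns the optimizer seed)."""
    ds = degree_summary(net)
    return {
        "S": net.n_consumers,
        "R": net.n_resources,
        "links": net.n_links,
        "SD": ds.mean_degree,
        "C": connectance(net),
        "N": nodf(net),
    }
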