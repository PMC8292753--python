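"""Bivariate local Moran's I on gridded time-series matrices.

The light and temperature matrices (rows = observation days in a fixed
order, columns = time slots) are treated as spatially organized grids.
Joint structure is detected with the local bivariate statistic

    I_i = z_x[i] * sum_j w[i, j] * z_y[j]

where z_x, z_y are the matrices standardized over all cells and w is a
row-standardized queen-contiguity weight structure accumulated over orders
1..8, i.e. every cell within Chebyshev distance 8 is a neighbour. Because
a cumulative queen ball on a regular grid is a square of side 2m+1, the
spatial lag is computed with summed-area tables in O(cells) rather than a
sparse weights matrix.

Significance uses the conditional permutation test standard for LISA
statistics: for each cell, the y values of all *other* cells are permuted
(by uniform resampling of neighbour sets), and the two-sided pseudo
p-value is ``(count(|I*| >= |I_i|) + 1) / (n_perm + 1)``.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError

DEFAULT_ORDER = 8
DEFAULT_N_PERM = 999
DEFAULT_ALPHA = 0.05

CLUSTER_LABELS = ("high-high", "low-low", "high-low", "low-high", "ns")


def queen_neighbor_counts(n_rows: int, n_cols: int, max_order: int = DEFAULT_ORDER):
    """Number of queen neighbours (orders 1..max_order) for every cell.

    The cumulative order-m queen neighbourhood of (r, c) is all cells with
    Chebyshev distance <= m, excluding (r, c) itself; at the grid edges the
    ball is clipped, so counts vary by position.
    """
    r = np.arange(n_rows)
    c = np.arange(n_cols)
    height = np.minimum(r + max_order, n_rows - 1) - np.maximum(r - max_order, 0) + 1
    width = np.minimum(c + max_order, n_cols - 1) - np.maximum(c - max_order, 0) + 1
    return np.outer(height, width) - 1


def queen_neighbors(r: int, c: int, n_rows: int, n_cols: int, max_order: int = DEFAULT_ORDER):
    """Explicit neighbour list of one cell (used by tests and small grids)."""
    out = []
    for rr in range(max(0, r - max_order), min(n_rows, r + max_order + 1)):
        for cc in range(max(0, c - max_order), min(n_cols, c + max_order + 1)):
            if (rr, cc) != (r, c):
                out.append((rr, cc))
    return out


def _box_sum(mat: np.ndarray, m: int) -> np.ndarray:
    """Sum of mat over the (2m+1)-square around each cell, edge-clipped."""
    n_rows, n_cols = mat.shape
    S = np.zeros((n_rows + 1, n_cols + 1))
    np.cumsum(np.cumsum(mat, axis=0), axis=1, out=S[1:, 1:])
    r = np.arange(n_rows)
    c = np.arange(n_cols)
    r0 = np.maximum(r - m, 0)
    r1 = np.minimum(r + m, n_rows - 1) + 1
    c0 = np.maximum(c - m, 0)
    c1 = np.minimum(c + m, n_cols - 1) + 1
    return S[np.ix_(r1, c1)] - S[np.ix_(r0, c1)] - S[np.ix_(r1, c0)] + S[np.ix_(r0, c0)]


def spatial_lag(z: np.ndarray, max_order: int = DEFAULT_ORDER) -> np.ndarray:
    """Row-standardized queen lag: mean of z over each cell's neighbours."""
    counts = queen_neighbor_counts(*z.shape, max_order=max_order)
    return (_box_sum(z, max_order) - z) / counts


def _standardize(a: np.ndarray, name: str) -> np.ndarray:
    sd = a.std()
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateInputError(f"{name} matrix has zero variance")
    return (a - a.mean()) / sd


@dataclass
class MoranResult:
    """Local statistics, standardized inputs, pseudo p-values and labels."""

    I: np.ndarray
    z_x: np.ndarray
    z_y: np.ndarray
    lag_y: np.ndarray
    pseudo_p: np.ndarray
    labels: np.ndarray  # object array of CLUSTER_LABELS
    alpha: float
    order: int
    n_perm: int


def bivariate_local_moran(
    x: np.ndarray,
    y: np.ndarray,
    max_order: int = DEFAULT_ORDER,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    alpha: float = DEFAULT_ALPHA,
) -> MoranResult:
    """Bivariate local Moran's I of x against the spatial lag of y.

    Both matrices are z-standardized over all cells. The permutation test
    holds each cell's x fixed and redraws its neighbours' y values from all
    other cells, the conditional randomization usual for LISA maps.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("matrices must be complete (impute/bridge first)")
    z_x = _standardize(x, "x")
    z_y = _standardize(y, "y")

    lag_y = spatial_lag(z_y, max_order)
    I = z_x * lag_y

    counts = queen_neighbor_counts(*x.shape, max_order=max_order).ravel()
    zx_f = z_x.ravel()
    zy_f = z_y.ravel()
    absI = np.abs(I.ravel())
    n_cells = zx_f.size
    rng = np.random.default_rng(seed)

    p = np.empty(n_cells)
    chunk = max(1, int(2e6 // max(n_perm, 1)))
    for start in range(0, n_cells, chunk):
        stop = min(start + chunk, n_cells)
        for i in range(start, stop):
            k = counts[i]
            draw = rng.integers(0, n_cells - 1, size=(n_perm, k))
            draw[draw >= i] += 1  # exclude the cell itself
            lag_star = zy_f[draw].mean(axis=1)
            exceed = np.abs(zx_f[i] * lag_star) >= absI[i]
            p[i] = (exceed.sum() + 1.0) / (n_perm + 1.0)

    pseudo_p = p.reshape(x.shape)
    labels = classify_clusters(z_x, lag_y, pseudo_p, alpha)
    return MoranResult(
        I=I, z_x=z_x, z_y=z_y, lag_y=lag_y, pseudo_p=pseudo_p,
        labels=labels, alpha=alpha, order=max_order, n_perm=n_perm,
    )


def classify_clusters(z_x, lag_y, pseudo_p, alpha: float = DEFAULT_ALPHA) -> np.ndarray:
    """Cluster labels by the sign pair (z_x, lagged z_y) at significant cells.

    (+,+) high-high; (-,-) low-low; (+,-) high-low (high light / low
    temperature); (-,+) low-high. Non-significant cells are "ns".
    """
    labels = np.full(z_x.shape, "ns", dtype=object)
    sig = pseudo_p <= alpha
    labels[sig & (z_x > 0) & (lag_y > 0)] = "high-high"
    labels[sig & (z_x < 0) & (lag_y < 0)] = "low-low"
    labels[sig & (z_x > 0) & (lag_y < 0)] = "high-low"
    labels[sig & (z_x < 0) & (lag_y > 0)] = "low-high"
    return labels
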