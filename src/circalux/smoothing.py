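"""Natural cubic smoothing spline with GCV-chosen penalty.

Implements the classic Reinsch formulation: the fitted values of the
smoothing spline minimizing ``RSS + lam * integral(f'')^2`` over natural
cubic splines with knots at the data sites are ``(I + lam*K)^{-1} y`` with
``K = D' W^{-1} D`` built from the second-difference matrix D and the
tridiagonal Gram matrix W of the second-derivative basis (Green & Silverman
Ch. 2). A one-time symmetric eigendecomposition of K (Demmler-Reinsch) makes
the whole lambda path cheap, so the generalized cross-validation score

    GCV(lam) = n * RSS(lam) / (n - tr S(lam))^2

is minimized by direct search over a wide log-spaced grid. The
decomposition depends only on the abscissae, which for this pipeline are
always the fixed 288-slot day grid, and is cached per grid.
"""
from __future__ import annotations

import numpy as np

_LAMBDA_GRID = np.logspace(-3, 10, 79)
_cache: dict = {}


def _reinsch_penalty(x: np.ndarray) -> np.ndarray:
    n = len(x)
    h = np.diff(x)
    D = np.zeros((n - 2, n))
    W = np.zeros((n - 2, n - 2))
    idx = np.arange(n - 2)
    D[idx, idx] = 1.0 / h[:-1]
    D[idx, idx + 1] = -1.0 / h[:-1] - 1.0 / h[1:]
    D[idx, idx + 2] = 1.0 / h[1:]
    W[idx, idx] = (h[:-1] + h[1:]) / 3.0
    W[idx[:-1], idx[:-1] + 1] = h[1:-1] / 6.0
    W[idx[:-1] + 1, idx[:-1]] = h[1:-1] / 6.0
    return D.T @ np.linalg.solve(W, D)


def _eigenbasis(x: np.ndarray):
    key = (len(x), float(x[0]), float(x[-1]))
    if key not in _cache:
        d, U = np.linalg.eigh(_reinsch_penalty(x))
        _cache[key] = (np.clip(d, 0.0, None), U)
    return _cache[key]


def smooth_spline(x, y, lam: float | None = None):
    """Fitted smoothing-spline values at the data sites.

    Parameters
    ----------
    x : array
        Strictly increasing abscissae (slot minutes).
    y : array
        Observations; must be complete (impute first).
    lam : float, optional
        Penalty. Default: chosen by generalized cross-validation.

    Returns
    -------
    fitted : numpy.ndarray
        Smoothed values on ``x``.
    info : dict
        ``lam`` used, effective degrees of freedom ``df``, and ``gcv`` score.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.isnan(y).any():
        raise ValueError("smooth_spline requires complete data; impute first")
    n = len(y)
    d, U = _eigenbasis(x)
    yt = U.T @ y
    if lam is not None:
        shrink = 1.0 / (1.0 + lam * d)
        fitted = U @ (shrink * yt)
        return fitted, {"lam": float(lam), "df": float(shrink.sum()), "gcv": np.nan}

    best = None
    for lam_c in _LAMBDA_GRID:
        shrink = 1.0 / (1.0 + lam_c * d)
        df = shrink.sum()
        rss = float((((1.0 - shrink) * yt) ** 2).sum())
        gcv = n * rss / (n - df) ** 2
        if best is None or gcv < best[0]:
            best = (gcv, lam_c, shrink, df)
    gcv, lam_b, shrink, df = best
    fitted = U @ (shrink * yt)
    return fitted, {"lam": float(lam_b), "df": float(df), "gcv": float(gcv)}
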