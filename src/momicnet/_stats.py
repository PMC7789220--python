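"""Shared statistical helpers: cross-correlation, t-based p-values, BH."""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests


def rank_transform(x: np.ndarray) -> np.ndarray:
    """Column-wise midranks (Spearman preprocessing)."""
    return np.apply_along_axis(stats.rankdata, 0, np.asarray(x, dtype=float))


def cross_correlation(
    x: np.ndarray, y: np.ndarray, method: str = "pearson"
) -> np.ndarray:
    """Correlation between every column of ``x`` and every column of ``y``.

    Columns with zero variance yield NaN correlations rather than raising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape[0] != y.shape[0]:
        raise ValueError("x and y must share the sample dimension")
    if method == "spearman":
        x, y = rank_transform(x), rank_transform(y)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    sx = np.sqrt((xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc.T @ yc) / np.outer(sx, sy)
    return np.clip(r, -1.0, 1.0, out=r)  # NaN passes through clip


def correlation_pvalues(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for H0: rho=0, from t = r*sqrt(n-2)/sqrt(1-r^2), n-2 df."""
    if n < 3:
        raise ValueError("need n >= 3 samples for a correlation test")
    r = np.asarray(r, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r**2)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isclose(np.abs(r), 1.0), 0.0, p)
    return np.where(np.isnan(r), np.nan, np.minimum(p, 1.0))


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg q-values; NaN entries are passed through."""
    p = np.asarray(p, dtype=float)
    q = np.full(p.shape, np.nan)
    mask = np.isfinite(p)
    if mask.any():
        q[mask] = multipletests(p[mask].ravel(), method="fdr_bh")[1]
    return q
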