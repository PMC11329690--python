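"""Survey-weighted moment and quantile helpers.

All estimators use the population convention (denominator ``sum(w)``, not
``sum(w) - 1``), so that unit weights reproduce the plain population moments
and integer weights are exactly equivalent to row replication.
"""

from __future__ import annotations

import numpy as np


def as_weights(w, n: int) -> np.ndarray:
    """Validate a weight vector: positive, finite, length ``n``."""
    if w is None:
        return np.ones(n)
    w = np.asarray(w, dtype=float)
    if w.shape != (n,):
        raise ValueError(f"weights have shape {w.shape}, expected ({n},)")
    if not np.all(np.isfinite(w)) or np.any(w <= 0):
        raise ValueError("weights must be positive and finite")
    return w


def wmean(x, w) -> float | np.ndarray:
    """Weighted mean along axis 0 (works on 1-D and 2-D arrays)."""
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    if x.ndim == 1:
        return float(np.sum(w * x) / np.sum(w))
    return np.sum(w[:, None] * x, axis=0) / np.sum(w)


def wvar(x, w) -> float | np.ndarray:
    """Weighted population variance along axis 0."""
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    m = wmean(x, w)
    if x.ndim == 1:
        return float(np.sum(w * (x - m) ** 2) / np.sum(w))
    return np.sum(w[:, None] * (x - m) ** 2, axis=0) / np.sum(w)


def wsd(x, w):
    return np.sqrt(wvar(x, w))


def wcov(x, y, w) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    mx, my = wmean(x, w), wmean(y, w)
    return float(np.sum(w * (x - mx) * (y - my)) / np.sum(w))


def wcorr(x, y, w) -> float:
    """Weighted Pearson correlation; 0 if either side is constant."""
    sx, sy = wsd(x, w), wsd(y, w)
    if sx == 0.0 or sy == 0.0:
        return 0.0
    return wcov(x, y, w) / (sx * sy)


def wquantile(x, q, w) -> np.ndarray:
    """Weighted quantiles by inverse of the right-continuous weighted ECDF.

    Returns, for each level in ``q``, the smallest data value whose
    cumulative weight share is >= q.  With unit weights this is the
    inverted-CDF (type-1) sample quantile.
    """
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    q = np.atleast_1d(np.asarray(q, dtype=float))
    if np.any((q < 0) | (q > 1)):
        raise ValueError("quantile levels must be in [0, 1]")
    order = np.argsort(x, kind="stable")
    xs, ws = x[order], w[order]
    cum = np.cumsum(ws) / np.sum(ws)
    idx = np.searchsorted(cum, q, side="left")
    idx = np.clip(idx, 0, len(xs) - 1)
    return xs[idx]


def normalize_mean_one(w) -> np.ndarray:
    """Rescale weights to mean 1 so weighted counts stay on the n scale."""
    w = np.asarray(w, dtype=float)
    return w * (len(w) / np.sum(w))
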