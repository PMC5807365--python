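"""Locally weighted polynomial smoothing of methylation along coordinates.

The smoother is loess with degree-2 local polynomials and tricube
weights over the ceil(span * n) nearest neighbors by coordinate
distance (span 0.4 by default, no robustness iterations).  The standard
deviation band is the square root of the same smoother applied to the
squared residuals, floored at zero — the band drawn behind genomic
methylation tracks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SmoothedTrack", "loess_smooth"]


@dataclass
class SmoothedTrack:
    positions: np.ndarray
    fitted: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        if not np.isfinite(self.fitted).all():
            raise ValueError("fitted values must be finite")
        if (self.sd < 0).any():
            raise ValueError("sd band must be non-negative")


def _loess_fit(x: np.ndarray, y: np.ndarray, k: int, degree: int) -> np.ndarray:
    """Evaluate the tricube-weighted degree-``degree`` local fit at every x."""
    n = len(x)
    fitted = np.empty(n)
    for i in range(n):
        d = np.abs(x - x[i])
        # k nearest neighbors by coordinate distance (ties kept by partition)
        if k < n:
            idx = np.argpartition(d, k - 1)[:k]
        else:
            idx = np.arange(n)
        dmax = d[idx].max()
        if dmax == 0:
            fitted[i] = y[idx].mean()
            continue
        w = (1.0 - (d[idx] / dmax) ** 3) ** 3
        w = np.clip(w, 0.0, None)
        if w.sum() == 0:
            w = np.ones_like(w)
        # center x at the evaluation point for conditioning; the fit value
        # at x[i] is then the intercept
        xc = (x[idx] - x[i]) / dmax
        design = np.vander(xc, degree + 1, increasing=True)
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(design * sw[:, None], y[idx] * sw, rcond=None)
        fitted[i] = coef[0]
    return fitted


def loess_smooth(
    positions: np.ndarray,
    levels: np.ndarray,
    span: float = 0.4,
    degree: int = 2,
) -> SmoothedTrack:
    """Smooth per-CpG levels along genomic coordinates.

    Parameters
    ----------
    positions, levels
        Coordinates (need not be sorted; returned sorted ascending) and
        the value at each.  At least max(5, degree + 2) points required.
    span
        Fraction of points in each local neighborhood, in (0, 1].
    """
    if not 0.0 < span <= 1.0:
        raise ValueError(f"span must be in (0, 1], got {span}")
    positions = np.asarray(positions, dtype=float)
    levels = np.asarray(levels, dtype=float)
    if positions.shape != levels.shape or positions.ndim != 1:
        raise ValueError("positions and levels must be 1-D and equal length")
    n = len(positions)
    if n < max(5, degree + 2):
        raise ValueError(f"need at least {max(5, degree + 2)} points, got {n}")
    if len(np.unique(positions)) != n:
        raise ValueError("positions must be unique")
    order = np.argsort(positions)
    x, y = positions[order], levels[order]
    k = int(np.ceil(span * n))
    k = max(k, degree + 2)  # enough points for a determined fit
    fitted = _loess_fit(x, y, k, degree)
    resid_sq = (y - fitted) ** 2
    sd = np.sqrt(np.maximum(0.0, _loess_fit(x, resid_sq, k, degree)))
    return SmoothedTrack(positions=x, fitted=fitted, sd=sd)
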