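"""Gaussian kernel density estimation of discriminant scores and the
balanced-error classification threshold.

Each cohort's score distribution is estimated as an equal-weight mixture of
Gaussians centered on the reference scores.  The null hypothesis for
classification states that a participant is typically developing (TD); with
ASD on the positive score axis, the Type I error at a threshold θ is the TD
density mass above θ (a TD participant called ASD) and the Type II error is
the ASD mass below θ (an ASD participant called TD).  The threshold H0 is
placed where |Type I − Type II| is minimized over the evaluation grid.

Bandwidths default to Silverman's rule of thumb
``0.9 * min(sd, IQR/1.34) * n**(-1/5)``; densities are tabulated on a fixed
grid and renormalized to unit trapezoidal mass so all tail masses are
deterministic and free of edge-truncation bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

#: Number of grid points for density tabulation.
GRID_POINTS = 2048
#: Grid half-extension beyond the pooled score range, in bandwidths.
GRID_PAD_BANDWIDTHS = 4.0


def silverman_bandwidth(scores: np.ndarray) -> float:
    """Silverman's rule of thumb: 0.9 * min(sd, IQR/1.34) * n^(-1/5).

    Falls back to the non-zero alternative of sd/IQR when one vanishes, and
    to a small positive constant for a degenerate (single or constant) set.
    """
    x = np.asarray(scores, dtype=float)
    n = x.size
    if n == 0:
        raise ValueError("empty score set")
    sd = x.std(ddof=1) if n > 1 else 0.0
    q75, q25 = np.percentile(x, [75, 25])
    iqr = (q75 - q25) / 1.34
    candidates = [c for c in (sd, iqr) if c > 0]
    spread = min(candidates) if candidates else 1.0
    return float(0.9 * spread * n ** (-0.2))


@dataclass
class DensityModel:
    """KDE of one score set, tabulated on an ordered grid."""

    scores: np.ndarray
    bandwidth: float
    grid: np.ndarray
    density: np.ndarray  # renormalized to unit trapezoidal mass on the grid

    def tail_mass(self, threshold: float, side: str) -> float:
        """Renormalized trapezoidal mass below or above a threshold.

        Thresholds beyond the grid give 0 or 1; below + above == 1 exactly.
        """
        if side not in ("below", "above"):
            raise ValueError("side must be 'below' or 'above'")
        below = self._mass_below(threshold)
        return below if side == "below" else 1.0 - below

    def _mass_below(self, threshold: float) -> float:
        g, d = self.grid, self.density
        if threshold <= g[0]:
            return 0.0
        if threshold >= g[-1]:
            return 1.0
        cum = cumulative_trapezoid(d, g, initial=0.0)
        j = np.searchsorted(g, threshold)
        if j < g.size and g[j] == threshold:
            # exact grid hit: return the tabulated cumulative, no interpolation
            return float(cum[j])
        return float(np.interp(threshold, g, cum))


def fit_kde(scores: np.ndarray, bandwidth: float | None = None,
            grid: np.ndarray | None = None) -> DensityModel:
    """Equal-weight Gaussian mixture centered on each reference score.

    If no grid is supplied one is built spanning the score range padded by
    four bandwidths, with 2048 points.  The tabulated density is renormalized
    to unit trapezoidal mass.
    """
    x = np.asarray(scores, dtype=float)
    if x.size == 0:
        raise ValueError("empty score set")
    if not np.all(np.isfinite(x)):
        raise ValueError("scores must be finite")
    h = silverman_bandwidth(x) if bandwidth is None else float(bandwidth)
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    if grid is None:
        lo = x.min() - GRID_PAD_BANDWIDTHS * h
        hi = x.max() + GRID_PAD_BANDWIDTHS * h
        grid = np.linspace(lo, hi, GRID_POINTS)
    else:
        grid = np.asarray(grid, dtype=float)
    z = (grid[:, None] - x[None, :]) / h
    dens = np.exp(-0.5 * z * z).sum(axis=1) / (x.size * h * np.sqrt(2.0 * np.pi))
    mass = np.trapezoid(dens, grid)
    if mass <= 0:
        raise ValueError("density has zero mass on the supplied grid")
    return DensityModel(scores=x, bandwidth=h, grid=grid, density=dens / mass)


def common_grid(td_scores: np.ndarray, asd_scores: np.ndarray,
                n_points: int = GRID_POINTS) -> np.ndarray:
    """Evaluation grid spanning the pooled score range padded by 4 bandwidths.

    The pad uses the larger of the two cohorts' Silverman bandwidths, so each
    cohort's density is fully covered by the shared grid.
    """
    h = max(silverman_bandwidth(td_scores), silverman_bandwidth(asd_scores))
    pooled = np.concatenate([np.asarray(td_scores, float), np.asarray(asd_scores, float)])
    lo = pooled.min() - GRID_PAD_BANDWIDTHS * h
    hi = pooled.max() + GRID_PAD_BANDWIDTHS * h
    return np.linspace(lo, hi, n_points)


@dataclass
class ThresholdedDensities:
    """TD and ASD densities with the balanced-error threshold H0."""

    td: DensityModel
    asd: DensityModel
    h0: float
    type_i: float
    type_ii: float

    def report(self) -> dict:
        return {
            "h0": self.h0,
            "type_i": self.type_i,
            "type_ii": self.type_ii,
            "td_bandwidth": self.td.bandwidth,
            "asd_bandwidth": self.asd.bandwidth,
            "grid": {
                "lo": float(self.td.grid[0]),
                "hi": float(self.td.grid[-1]),
                "n": int(self.td.grid.size),
            },
        }


def find_threshold(td: DensityModel, asd: DensityModel) -> ThresholdedDensities:
    """Place H0 where |TypeI(θ) − TypeII(θ)| is minimized over the grid.

    TypeI(θ) = TD mass above θ (non-increasing in θ); TypeII(θ) = ASD mass
    below θ (non-decreasing), so the balance point is essentially unique.
    Ties are broken by taking the median tying grid point.
    """
    if td.grid.shape != asd.grid.shape or not np.allclose(td.grid, asd.grid):
        raise ValueError("density models must share a common grid")
    g = td.grid
    cum_td = cumulative_trapezoid(td.density, g, initial=0.0)
    cum_asd = cumulative_trapezoid(asd.density, g, initial=0.0)
    type_i = 1.0 - cum_td      # TD mass above θ
    type_ii = cum_asd          # ASD mass below θ
    gap = np.abs(type_i - type_ii)
    ties = np.flatnonzero(gap == gap.min())
    idx = int(ties[len(ties) // 2])
    return ThresholdedDensities(
        td=td, asd=asd,
        h0=float(g[idx]),
        type_i=float(type_i[idx]),
        type_ii=float(type_ii[idx]),
    )


def estimate_thresholded(td_scores: np.ndarray, asd_scores: np.ndarray) -> ThresholdedDensities:
    """Convenience: common grid, per-cohort KDEs, balanced-error threshold."""
    grid = common_grid(td_scores, asd_scores)
    return find_threshold(fit_kde(td_scores, grid=grid), fit_kde(asd_scores, grid=grid))
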