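"""Dipole extraction and circular correlation analysis.

A *dipole* is an ON/OFF pair of cells closer than a distance d; its implied
preferred orientation is orthogonal to the ON→OFF vector.  Spatial
correlations between dipole orientations use the plain circular statistic
C = <cos 2Δθ> (orientation is π-periodic), the same statistic applied to
OPM pixel pairs in :func:`rgcdipoles.opm.opm_autocorrelation`.
"""
from __future__ import annotations

import warnings
from typing import List, Sequence

import numpy as np
import pandas as pd
from scipy.special import ive

from .core import BinnedCorrelation, Dipole, PointMosaic
from .opm import OrientationField

__all__ = [
    "dipole_orientation",
    "extract_dipoles",
    "dipole_table",
    "dipole_correlation",
    "bootstrap_ci",
    "cross_correlation",
    "analytic_cross_correlation",
]


def dipole_orientation(on, off) -> float:
    """Preferred orientation of an ON/OFF pair, in [0, π).

    θ = (direction angle of off − on) + π/2, reduced modulo π; orthogonal to
    the connecting vector and therefore invariant under swapping the two
    endpoints.
    """
    on = np.asarray(on, dtype=float)
    off = np.asarray(off, dtype=float)
    dx, dy = off[0] - on[0], off[1] - on[1]
    if dx == 0.0 and dy == 0.0:
        raise ValueError("coincident points have no defined dipole orientation")
    return float((np.arctan2(dy, dx) + 0.5 * np.pi) % np.pi)


def _extract_arrays(on: np.ndarray, off: np.ndarray, d: float):
    """Vectorized extraction: (on_idx, off_idx, midpoints, separations, thetas)."""
    if on.shape[0] == 0 or off.shape[0] == 0:
        empty = np.zeros(0)
        return empty.astype(int), empty.astype(int), np.zeros((0, 2)), empty, empty
    dx = off[None, :, 0] - on[:, None, 0]
    dy = off[None, :, 1] - on[:, None, 1]
    sep = np.hypot(dx, dy)
    ii, jj = np.nonzero(sep < d)
    mid = 0.5 * (on[ii] + off[jj])
    theta = (np.arctan2(dy[ii, jj], dx[ii, jj]) + 0.5 * np.pi) % np.pi
    return ii, jj, mid, sep[ii, jj], theta


def extract_dipoles(mosaic: PointMosaic, d: float) -> List[Dipole]:
    """All ON/OFF pairs with separation strictly smaller than *d*.

    A cell may appear in many dipoles; the result is ordered by (ON index,
    OFF index).  An empty list is a valid result.
    """
    if not d > 0:
        raise ValueError("dipole distance d must be > 0")
    ii, jj, mid, sep, theta = _extract_arrays(mosaic.on_points, mosaic.off_points, d)
    return [
        Dipole(int(i), int(j), (float(m[0]), float(m[1])), float(s), float(t))
        for i, j, m, s, t in zip(ii, jj, mid, sep, theta)
    ]


def dipole_table(dipoles: Sequence[Dipole]) -> pd.DataFrame:
    """Dipole list as a table (on_index, off_index, mid_x, mid_y, separation_um, theta_rad)."""
    return pd.DataFrame(
        {
            "on_index": [d.on_index for d in dipoles],
            "off_index": [d.off_index for d in dipoles],
            "mid_x": [d.midpoint[0] for d in dipoles],
            "mid_y": [d.midpoint[1] for d in dipoles],
            "separation_um": [d.separation for d in dipoles],
            "theta_rad": [d.orientation for d in dipoles],
        }
    )


def _dipole_mid_theta(dipoles: Sequence[Dipole]):
    mid = np.array([d.midpoint for d in dipoles], dtype=float).reshape(-1, 2)
    theta = np.array([d.orientation for d in dipoles], dtype=float)
    return mid, theta


def _correlation_arrays(mid: np.ndarray, theta: np.ndarray, n_bins: int, max_r: float):
    """Binned <cos 2Δθ> over unordered midpoint pairs (i ≠ j)."""
    n = mid.shape[0]
    i, j = np.triu_indices(n, k=1)
    d = np.hypot(mid[i, 0] - mid[j, 0], mid[i, 1] - mid[j, 1])
    c = np.cos(2.0 * (theta[i] - theta[j]))
    inside = d < max_r
    which = np.floor(d[inside] / (max_r / n_bins)).astype(int)
    counts = np.bincount(which, minlength=n_bins)
    sums = np.bincount(which, weights=c[inside], minlength=n_bins)
    values = np.full(n_bins, np.nan)
    np.divide(sums, counts, out=values, where=counts > 0)
    return values, counts


def dipole_correlation(dipoles: Sequence[Dipole], n_bins: int, max_r: float) -> BinnedCorrelation:
    """Distance-binned circular correlation of dipole orientations.

    For each bin of midpoint separations, C is the mean of cos 2(θᵢ − θⱼ)
    over unordered pairs i ≠ j; bins without pairs are undefined (NaN).
    At least 2 dipoles are required.
    """
    if len(dipoles) < 2:
        raise ValueError("need at least 2 dipoles for a correlation function")
    if n_bins < 1 or not max_r > 0:
        raise ValueError("n_bins must be >= 1 and max_r > 0")
    mid, theta = _dipole_mid_theta(dipoles)
    values, counts = _correlation_arrays(mid, theta, n_bins, max_r)
    edges = np.linspace(0.0, max_r, n_bins + 1)
    return BinnedCorrelation(edges, values, counts)


def bootstrap_ci(dipoles: Sequence[Dipole], n_bins: int, max_r: float,
                 n_boot: int, seed: int = 0) -> BinnedCorrelation:
    """Correlation function with 95% bootstrap confidence bounds per bin.

    Dipoles are resampled with replacement *n_boot* times (n_boot ≥ 100);
    per bin the CI is the 2.5th–97.5th percentile of the resampled C
    values.  Bins undefined in the point estimate propagate as undefined
    CIs.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    base = dipole_correlation(dipoles, n_bins, max_r)
    mid, theta = _dipole_mid_theta(dipoles)
    n = mid.shape[0]
    rng = np.random.default_rng(seed)
    boots = np.full((n_boot, n_bins), np.nan)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boots[b], _ = _correlation_arrays(mid[idx], theta[idx], n_bins, max_r)
    with warnings.catch_warnings():
        # bins undefined in every resample are reported as NaN CIs below
        warnings.simplefilter("ignore", RuntimeWarning)
        lo = np.nanpercentile(boots, 2.5, axis=0)
        hi = np.nanpercentile(boots, 97.5, axis=0)
    lo[~base.defined] = np.nan
    hi[~base.defined] = np.nan
    return BinnedCorrelation(base.bin_edges, base.values, base.pair_counts,
                            ci_low=lo, ci_high=hi)


def cross_correlation(dipoles: Sequence[Dipole], opm: OrientationField) -> float:
    """Mean alignment <cos 2(θᵢ − ϑ(midpointᵢ))> between dipoles and an OPM."""
    if len(dipoles) == 0:
        raise ValueError("need at least 1 dipole for a cross-correlation")
    mid, theta = _dipole_mid_theta(dipoles)
    local = opm.sample(mid)
    return float(np.mean(np.cos(2.0 * (theta - local))))


def analytic_cross_correlation(beta: float) -> float:
    """Expected OPM/dipole cross-correlation under the von-Mises kernel.

    With pair placement density ∝ exp(β cos 2Δ) the expectation of cos 2Δ
    is the Bessel ratio I₁(β)/I₀(β): 0 at β = 0 and → 1 as β → ∞.
    Evaluated with exponentially scaled Bessel functions for stability.
    """
    if not beta >= 0:
        raise ValueError("beta must be >= 0")
    if beta == 0:
        return 0.0
    return float(ive(1, beta) / ive(0, beta))
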