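"""Core domain types shared across the package.

All coordinates are retinal micrometres (µm).  Cortical lengths enter the
analysis only through the linear magnification factor M (mm of cortex per mm
of retina), see :mod:`rgcdipoles.opm`.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "MosaicFormatError",
    "PointMosaic",
    "PairRepulsion",
    "InteractionParams",
    "MPIPPConfig",
    "Dipole",
    "BinnedCorrelation",
    "as_point_array",
    "validate_window",
]

#: axis-aligned rectangle (x_min, x_max, y_min, y_max) in µm
Window = Tuple[float, float, float, float]


class MosaicFormatError(ValueError):
    """Raised when a mosaic text file cannot be parsed."""


def as_point_array(points) -> np.ndarray:
    """Coerce *points* to a float ``(n, 2)`` array of finite positions."""
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        return pts.reshape(0, 2)
    if pts.ndim == 1 and pts.shape[0] == 2:
        pts = pts.reshape(1, 2)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError(f"expected an (n, 2) array of positions, got shape {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise ValueError("positions must be finite real numbers")
    return pts


def validate_window(window) -> Window:
    """Validate and normalize an (x_min, x_max, y_min, y_max) window."""
    try:
        x0, x1, y0, y1 = (float(v) for v in window)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"window must be 4 numbers (x_min, x_max, y_min, y_max): {window!r}") from exc
    if not all(np.isfinite(v) for v in (x0, x1, y0, y1)):
        raise ValueError("window bounds must be finite")
    if x1 <= x0 or y1 <= y0:
        raise ValueError(f"degenerate window {window!r}: require x_min < x_max and y_min < y_max")
    return (x0, x1, y0, y1)


@dataclass
class PointMosaic:
    """ON and OFF cell positions inside a rectangular observation window.

    Parameters
    ----------
    on_points, off_points : array_like, shape (n, 2)
        Positions of ON- and OFF-centre cells in retinal µm.
    window : tuple of float
        Axis-aligned observation rectangle (x_min, x_max, y_min, y_max) in µm.
        Densities are always computed relative to this window's area.
    """

    on_points: np.ndarray
    off_points: np.ndarray
    window: Window

    def __post_init__(self) -> None:
        self.on_points = as_point_array(self.on_points)
        self.off_points = as_point_array(self.off_points)
        self.window = validate_window(self.window)
        x0, x1, y0, y1 = self.window
        for name, pts in (("on", self.on_points), ("off", self.off_points)):
            if pts.size and (
                pts[:, 0].min() < x0 or pts[:, 0].max() > x1
                or pts[:, 1].min() < y0 or pts[:, 1].max() > y1
            ):
                raise ValueError(f"{name} points fall outside the window {self.window}")

    @property
    def n_on(self) -> int:
        return self.on_points.shape[0]

    @property
    def n_off(self) -> int:
        return self.off_points.shape[0]

    @property
    def area(self) -> float:
        """Window area in µm²."""
        x0, x1, y0, y1 = self.window
        return (x1 - x0) * (y1 - y0)

    @property
    def diagonal(self) -> float:
        """Window diagonal in µm (the natural range for correlation bins)."""
        x0, x1, y0, y1 = self.window
        return float(np.hypot(x1 - x0, y1 - y0))

    def points(self, polarity: str) -> np.ndarray:
        if polarity == "on":
            return self.on_points
        if polarity == "off":
            return self.off_points
        raise ValueError(f"polarity must be 'on' or 'off', got {polarity!r}")

    @classmethod
    def from_points(cls, on_points, off_points, window=None, pad: float = 0.0) -> "PointMosaic":
        """Build a mosaic, defaulting the window to the padded bounding box."""
        on = as_point_array(on_points)
        off = as_point_array(off_points)
        if window is None:
            allpts = np.vstack([on, off]) if on.size or off.size else np.zeros((0, 2))
            if allpts.size == 0:
                raise ValueError("cannot infer a window for an empty mosaic")
            x0, x1 = allpts[:, 0].min() - pad, allpts[:, 0].max() + pad
            y0, y1 = allpts[:, 1].min() - pad, allpts[:, 1].max() + pad
            # collinear points give a degenerate bounding box; open it minimally
            if x1 <= x0:
                x0, x1 = x0 - 0.5, x1 + 0.5
            if y1 <= y0:
                y0, y1 = y0 - 0.5, y1 + 0.5
            window = (x0, x1, y0, y1)
        return cls(on, off, window)


@dataclass(frozen=True)
class PairRepulsion:
    """Parametric soft repulsion for one pair type.

    ``delta`` is the hard exclusion radius in µm (for ON–OFF, the soma
    diameter); ``phi`` (µm) the repulsion range; ``alpha`` the dimensionless
    shape exponent.  ON–OFF interactions use the pure step form, in which
    case ``phi`` and ``alpha`` are None.
    """

    delta: float
    phi: Optional[float] = None
    alpha: Optional[float] = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.delta) or self.delta < 0:
            raise ValueError(f"delta must be >= 0, got {self.delta}")
        if self.phi is not None and not self.phi > 0:
            raise ValueError(f"phi must be > 0, got {self.phi}")
        if self.alpha is not None and not self.alpha > 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")


@dataclass(frozen=True)
class InteractionParams:
    """Interaction parameters per pair type {ON–ON, OFF–OFF, ON–OFF}."""

    on_on: PairRepulsion
    off_off: PairRepulsion
    on_off: PairRepulsion

    def __post_init__(self) -> None:
        for name in ("on_on", "off_off"):
            pr = getattr(self, name)
            if pr.phi is None or pr.alpha is None:
                raise ValueError(f"{name} interaction requires phi and alpha")

    @property
    def soma_diameter(self) -> float:
        """Hard-core distance of the ON–OFF step interaction (µm)."""
        return self.on_off.delta

    def pair(self, polarity: str) -> PairRepulsion:
        return self.on_on if polarity == "on" else self.off_off


@dataclass(frozen=True)
class MPIPPConfig:
    """Configuration of the (modulated) pairwise interacting point process.

    Parameters
    ----------
    beta : float
        Modulation strength β ≥ 0.  β = 0 recovers the plain PIPP.
    d_mod : float
        Modulation / dipole distance d in µm: ON/OFF pairs closer than this
        are treated as dipoles and subject to orientation modulation.
    n_sweeps : int
        Number of full Monte-Carlo update iterations (each sweeps all ON
        cells, then all OFF cells).
    magnification : float
        Cortical magnification M, mm cortex per mm retina.
    seed : int
        Seed for the simulation RNG.
    """

    beta: float = 0.0
    d_mod: float = 80.0
    n_sweeps: int = 20
    magnification: float = 1.7
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.beta >= 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if not self.d_mod > 0:
            raise ValueError(f"d_mod must be > 0, got {self.d_mod}")
        if not (isinstance(self.n_sweeps, (int, np.integer)) and self.n_sweeps >= 1):
            raise ValueError(f"n_sweeps must be an integer >= 1, got {self.n_sweeps}")
        if not self.magnification > 0:
            raise ValueError(f"magnification must be > 0, got {self.magnification}")


@dataclass(frozen=True)
class Dipole:
    """A nearby ON/OFF cell pair with its implied preferred orientation.

    The preferred orientation θ ∈ [0, π) is orthogonal to the ON→OFF vector
    (direction angle + π/2, reduced mod π); the midpoint is the arithmetic
    mean of the two endpoints.
    """

    on_index: int
    off_index: int
    midpoint: Tuple[float, float]
    separation: float
    orientation: float

    def __post_init__(self) -> None:
        if not self.separation > 0:
            raise ValueError("dipole separation must be positive (coincident cells)")
        if not (0.0 <= self.orientation < np.pi):
            raise ValueError(f"orientation must lie in [0, pi), got {self.orientation}")


@dataclass
class BinnedCorrelation:
    """Distance-binned circular correlation C(r) with pair counts.

    Bins with ``pair_counts == 0`` are undefined and carry NaN values (never
    zero).  Optional ``ci_low``/``ci_high`` hold 95% bootstrap bounds.
    """

    bin_edges: np.ndarray
    values: np.ndarray
    pair_counts: np.ndarray
    ci_low: Optional[np.ndarray] = None
    ci_high: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.pair_counts = np.asarray(self.pair_counts, dtype=int)
        if self.bin_edges.ndim != 1 or self.bin_edges.size < 2:
            raise ValueError("bin_edges must be a 1-d array of at least 2 edges")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin_edges must be strictly increasing")
        n = self.bin_edges.size - 1
        if self.values.shape != (n,) or self.pair_counts.shape != (n,):
            raise ValueError("values and pair_counts must have len(bin_edges) - 1 entries")
        if np.any(self.pair_counts < 0):
            raise ValueError("pair counts must be non-negative")
        defined = self.pair_counts > 0
        if np.any(np.isnan(self.values[defined])):
            raise ValueError("defined bins (pair_count > 0) must carry finite values")
        if not np.all(np.isnan(self.values[~defined])):
            raise ValueError("bins with pair_count == 0 must be NaN (undefined), not a number")
        vals = self.values[defined]
        if vals.size and (vals.min() < -1 - 1e-9 or vals.max() > 1 + 1e-9):
            raise ValueError("correlation values must lie in [-1, 1]")
        for ci in (self.ci_low, self.ci_high):
            if ci is not None:
                ci = np.asarray(ci, dtype=float)
                if ci.shape != (n,):
                    raise ValueError("CI arrays must match the number of bins")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def defined(self) -> np.ndarray:
        """Boolean mask of bins that contain at least one pair."""
        return self.pair_counts > 0

    def to_frame(self) -> pd.DataFrame:
        """Export as a table with columns r_lo, r_hi, C, n_pairs[, ci_lo, ci_hi]."""
        data = {
            "r_lo": self.bin_edges[:-1],
            "r_hi": self.bin_edges[1:],
            "C": self.values,
            "n_pairs": self.pair_counts,
        }
        if self.ci_low is not None:
            data["ci_lo"] = self.ci_low
        if self.ci_high is not None:
            data["ci_hi"] = self.ci_high
        return pd.DataFrame(data)
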