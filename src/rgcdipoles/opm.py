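"""Orientation-preference fields: synthesis, filtering, and summaries.

An orientation preference map (OPM) assigns to every position a preferred
stimulus orientation ϑ ∈ [0, π).  Measured maps have a single dominant
column spacing Λ and an essentially uniform orientation histogram; the
synthesizer here emulates both by bandpass-filtering complex white noise
around the wavenumber 2π/Λ and taking half the phase angle.  Fields live in
retinal coordinates; a cortical map of column spacing Λ_cortex seen through
a linear retinotopy with magnification M appears on the retina with spacing
Λ_cortex / M.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy.special import expit

from .core import BinnedCorrelation, validate_window

__all__ = [
    "OrientationField",
    "fermi_bandpass",
    "synthesize_opm",
    "synthesize_opm_for_window",
    "opm_autocorrelation",
    "cortex_to_retina",
    "retina_to_cortex",
]


@dataclass
class OrientationField:
    """A gridded preferred-orientation map ϑ(x) ∈ [0, π).

    Parameters
    ----------
    angles : ndarray, shape (ny, nx)
        Preferred orientations in radians, row index = y.
    pixel_size : float
        µm per pixel in retinal coordinates.
    column_spacing : float
        Dominant column spacing Λ in retinal µm (after magnification
        scaling).
    magnification : float
        Cortical magnification M (mm cortex / mm retina) used to map the
        field into retinal coordinates.
    origin : tuple of float
        Retinal position (µm) of the field's lower-left corner; pixel (0, 0)
        covers ``[origin, origin + pixel_size)`` in both axes.
    """

    angles: np.ndarray
    pixel_size: float
    column_spacing: float
    magnification: float = 1.7
    origin: Tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.ndim != 2:
            raise ValueError("angles must be a 2-d grid")
        if not np.all(np.isfinite(self.angles)):
            raise ValueError("angles must be finite")
        if self.angles.min() < 0 or self.angles.max() >= np.pi:
            raise ValueError("angles must lie in [0, pi)")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")
        if not self.column_spacing > 0:
            raise ValueError("column_spacing must be > 0")
        if not self.magnification > 0:
            raise ValueError("magnification must be > 0")
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    @property
    def shape(self) -> Tuple[int, int]:
        return self.angles.shape

    @property
    def extent(self) -> Tuple[float, float, float, float]:
        """Retinal footprint (x_min, x_max, y_min, y_max) in µm."""
        ny, nx = self.angles.shape
        x0, y0 = self.origin
        return (x0, x0 + nx * self.pixel_size, y0, y0 + ny * self.pixel_size)

    def covers(self, window) -> bool:
        x0, x1, y0, y1 = validate_window(window)
        fx0, fx1, fy0, fy1 = self.extent
        eps = 1e-9 * self.pixel_size
        return fx0 <= x0 + eps and fx1 >= x1 - eps and fy0 <= y0 + eps and fy1 >= y1 - eps

    def sample(self, points) -> np.ndarray:
        """Preferred orientation at *points* via nearest-pixel lookup.

        Out-of-footprint positions are evaluated at the nearest in-bounds
        pixel (indices are clipped).
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        ny, nx = self.angles.shape
        ix = np.clip(((pts[:, 0] - self.origin[0]) / self.pixel_size).astype(int), 0, nx - 1)
        iy = np.clip(((pts[:, 1] - self.origin[1]) / self.pixel_size).astype(int), 0, ny - 1)
        return self.angles[iy, ix]


def fermi_bandpass(field, k_low: float, k_high: float, steepness: float,
                   pixel_size: float = 1.0) -> np.ndarray:
    """Fermi bandpass filter of a complex 2-d field.

    Multiplies the Fourier transform by

        F(k) = 1/(1 + exp((k - k_low)/steepness)) * [1 - 1/(1 + exp((k - k_high)/steepness))]

    where k = |k| is the angular wavenumber (1/µm given *pixel_size* in µm):
    a smooth low-pass shoulder at ``k_low`` and high-pass shoulder at
    ``k_high`` (0 < k_high < k_low).  The mean (k = 0) component is removed.
    The filter is linear.
    """
    arr = np.asarray(field, dtype=complex)
    if arr.ndim != 2:
        raise ValueError("field must be a 2-d grid")
    if not np.all(np.isfinite(arr.real)) or not np.all(np.isfinite(arr.imag)):
        raise ValueError("field values must be finite")
    if not (0 < k_high < k_low):
        raise ValueError("require 0 < k_high < k_low (high-pass cutoff below low-pass cutoff)")
    if not steepness > 0:
        raise ValueError("steepness must be > 0")
    ny, nx = arr.shape
    ky = 2 * np.pi * np.fft.fftfreq(ny, d=pixel_size)
    kx = 2 * np.pi * np.fft.fftfreq(nx, d=pixel_size)
    k = np.hypot(ky[:, None], kx[None, :])
    # expit keeps the sigmoids overflow-free
    transfer = expit((k_low - k) / steepness) * expit((k - k_high) / steepness)
    spec = np.fft.fft2(arr) * transfer
    spec[0, 0] = 0.0
    return np.fft.ifft2(spec)


def synthesize_opm(nx: int, ny: int, pixel_size: float, column_spacing: float,
                   rel_bandwidth: float = 0.3, seed: int = 0,
                   magnification: float = 1.7,
                   origin: Tuple[float, float] = (0.0, 0.0)) -> OrientationField:
    """Synthesize a bandpass (Fermi-filtered) orientation field.

    Complex Gaussian white noise is bandpass-filtered around the wavenumber
    k0 = 2π/Λ (band edges k0·(1 ± rel_bandwidth), steepness k0/10) and the
    orientation taken as half the phase of the filtered field, which yields
    a field with a single dominant column spacing Λ and a uniform
    orientation marginal.  Deterministic given *seed*.
    """
    if nx < 4 or ny < 4:
        raise ValueError("grid must be at least 4x4 pixels")
    if not 0 < rel_bandwidth < 1:
        raise ValueError("rel_bandwidth must lie in (0, 1)")
    if column_spacing < 2 * pixel_size:
        raise ValueError(
            f"column spacing {column_spacing} µm below 2 pixels "
            f"({2 * pixel_size} µm): the field would be aliased"
        )
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((ny, nx)) + 1j * rng.standard_normal((ny, nx))
    k0 = 2 * np.pi / column_spacing
    z = fermi_bandpass(noise, k_low=k0 * (1 + rel_bandwidth),
                       k_high=k0 * (1 - rel_bandwidth),
                       steepness=k0 / 10, pixel_size=pixel_size)
    angles = (np.angle(z) % (2 * np.pi)) / 2.0
    # guard against the half-open interval: angle == 2π would fold to π
    angles[angles >= np.pi] = 0.0
    return OrientationField(angles, pixel_size=pixel_size,
                            column_spacing=column_spacing,
                            magnification=magnification, origin=origin)


def synthesize_opm_for_window(window, pixel_size: float,
                              column_spacing_cortex_mm: float = 1.0,
                              magnification: float = 1.7,
                              rel_bandwidth: float = 0.3,
                              seed: int = 0) -> OrientationField:
    """Synthesize a field whose retinal footprint covers *window*.

    The cortical column spacing (mm) is mapped to retinal µm through the
    magnification M: Λ_retina = 1000 · Λ_cortex / M.
    """
    x0, x1, y0, y1 = validate_window(window)
    spacing_um = 1000.0 * cortex_to_retina(column_spacing_cortex_mm, magnification)
    nx = int(np.ceil((x1 - x0) / pixel_size))
    ny = int(np.ceil((y1 - y0) / pixel_size))
    return synthesize_opm(nx, ny, pixel_size, spacing_um,
                          rel_bandwidth=rel_bandwidth, seed=seed,
                          magnification=magnification, origin=(x0, y0))


def opm_autocorrelation(field: OrientationField, n_bins: int, max_r: float,
                        max_pixels: int = 2000, seed: int = 0) -> BinnedCorrelation:
    """Circular spatial autocorrelation C(r) = <cos 2(ϑ₁ − ϑ₂)> of a field.

    Pixel pairs are binned by distance; for large grids a seeded random
    subsample of at most *max_pixels* pixels is used (all pairs among the
    subsample).  Bins without pairs are undefined (NaN).
    """
    ny, nx = field.angles.shape
    diag = np.hypot(nx * field.pixel_size, ny * field.pixel_size)
    if max_r > diag / 2 + 1e-9:
        raise ValueError(f"max_r {max_r} exceeds half the field diagonal {diag / 2:.1f}")
    iy, ix = np.mgrid[0:ny, 0:nx]
    pos = np.column_stack([(ix.ravel() + 0.5), (iy.ravel() + 0.5)]) * field.pixel_size
    ang = field.angles.ravel()
    if pos.shape[0] > max_pixels:
        rng = np.random.default_rng(seed)
        keep = rng.choice(pos.shape[0], size=max_pixels, replace=False)
        pos, ang = pos[keep], ang[keep]
    i, j = np.triu_indices(pos.shape[0], k=1)
    d = np.hypot(pos[i, 0] - pos[j, 0], pos[i, 1] - pos[j, 1])
    c = np.cos(2.0 * (ang[i] - ang[j]))
    edges = np.linspace(0.0, max_r, n_bins + 1)
    inside = d < max_r
    which = np.floor(d[inside] / (max_r / n_bins)).astype(int)
    counts = np.bincount(which, minlength=n_bins)
    sums = np.bincount(which, weights=c[inside], minlength=n_bins)
    values = np.full(n_bins, np.nan)
    np.divide(sums, counts, out=values, where=counts > 0)
    return BinnedCorrelation(edges, values, counts)


def cortex_to_retina(length_cortex, magnification: float):
    """Map a cortical length to a retinal length: length / M.

    Units are preserved (mm→mm or µm→µm); M is mm cortex per mm retina.
    Vectorized over *length_cortex*.
    """
    if not magnification > 0:
        raise ValueError("magnification must be > 0")
    out = np.asarray(length_cortex, dtype=float) / magnification
    return float(out) if out.ndim == 0 else out


def retina_to_cortex(length_retina, magnification: float):
    """Inverse of :func:`cortex_to_retina`: length · M."""
    if not magnification > 0:
        raise ValueError("magnification must be > 0")
    out = np.asarray(length_retina, dtype=float) * magnification
    return float(out) if out.ndim == 0 else out
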