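"""Monte-Carlo hypothesis tests and statistical power for dipole correlations.

The machinery compares an observed dipole-orientation correlation function
against an ensemble of simulated ones through band-summed deviation
statistics (T for ensemble members, S for the observed function), rank
Monte-Carlo p-values, a (β, magnification) consistency scan, and a
simulation-based false-negative-rate (power) estimate for detecting OPM-like
angular correlations in mosaics of a given number and size.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Union

import numpy as np

from .core import BinnedCorrelation, InteractionParams, MPIPPConfig, PointMosaic
from .dipoles import _correlation_arrays, _extract_arrays
from .opm import OrientationField, synthesize_opm_for_window
from .pipp import simulate_mpipp
from .presets import (
    CAT_BETA_INTERACTIONS,
    CAT_COLUMN_SPACING_CORTEX_MM,
    CAT_MAGNIFICATION,
    DIPOLE_DISTANCE,
    M623_DENSITY_OFF,
    M623_DENSITY_ON,
    OPM_PIXEL_SIZE,
)
from .spatial import g_function, l_function, voronoi_disorder

__all__ = [
    "MonteCarloTest",
    "PowerGrid",
    "distance_band",
    "positive_correlation_band",
    "t_statistic",
    "s_statistic",
    "monte_carlo_pvalue",
    "local_stats_pvalue",
    "beta_magnification_scan",
    "estimate_false_negative_rate",
    "power_grid",
    "synthetic_opm_sampler",
]

#: distance range (µm) of the local positive-correlation band (first bins)
LOCAL_BAND_R_MAX = 100.0
#: distance range (µm) of the anticorrelation band
ANTI_BAND = (200.0, 400.0)


@dataclass
class MonteCarloTest:
    """Result of a rank-based Monte-Carlo test.

    ``t_values`` is the ensemble statistic distribution (length m ≥ 99),
    ``s_value`` the observed statistic and ``p_value`` the rank probability
    on the lattice {1/(m+1), ..., 1}.
    """

    t_values: np.ndarray
    s_value: float
    p_value: float
    alternative: str

    def __post_init__(self) -> None:
        self.t_values = np.asarray(self.t_values, dtype=float)
        if self.t_values.size < 99:
            raise ValueError("need an ensemble of at least 99 statistic values")
        if not 0 < self.p_value <= 1:
            raise ValueError("p_value must lie in (0, 1]")
        if self.alternative not in ("lower", "upper", "two-sided"):
            raise ValueError(f"unknown alternative {self.alternative!r}")


@dataclass
class PowerGrid:
    """False-negative-rate surface over (β, N, area)."""

    beta_values: np.ndarray
    n_values: np.ndarray
    area_values: np.ndarray
    fnr: np.ndarray
    band: str

    def __post_init__(self) -> None:
        self.beta_values = np.asarray(self.beta_values, dtype=float)
        self.n_values = np.asarray(self.n_values, dtype=int)
        self.area_values = np.asarray(self.area_values, dtype=float)
        self.fnr = np.asarray(self.fnr, dtype=float)
        expected = (self.beta_values.size, self.n_values.size, self.area_values.size)
        if self.fnr.shape != expected:
            raise ValueError(f"fnr grid must have shape {expected}")
        finite = np.isfinite(self.fnr)
        if np.any((self.fnr[finite] < 0) | (self.fnr[finite] > 1)):
            raise ValueError("false-negative rates must lie in [0, 1]")
        if self.band not in ("local", "anticorrelation"):
            raise ValueError(f"unknown band {self.band!r}")


def _corr_like(obj: Union[BinnedCorrelation, np.ndarray]) -> np.ndarray:
    if isinstance(obj, BinnedCorrelation):
        return obj.values
    return np.asarray(obj, dtype=float)


def distance_band(bin_edges, r_min: float, r_max: float) -> np.ndarray:
    """Mask of bins whose centers lie in [r_min, r_max)."""
    edges = np.asarray(bin_edges, dtype=float)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return (centers >= r_min) & (centers < r_max)


def positive_correlation_band(ensemble_mean, threshold: float = 0.1) -> np.ndarray:
    """Mask of bins where the ensemble mean correlation exceeds *threshold*."""
    return _corr_like(ensemble_mean) > threshold


def t_statistic(corr, ensemble_mean, band) -> float:
    """Band-summed deviation T = Σ over masked bins of (C(r_k) − C̄(r_k)).

    Both arguments may be :class:`BinnedCorrelation` objects (whose bin
    grids must match) or plain value arrays; *band* is a boolean bin mask.
    Undefined (NaN) bins inside the band are an error.
    """
    c = _corr_like(corr)
    cbar = _corr_like(ensemble_mean)
    band = np.asarray(band, dtype=bool)
    if isinstance(corr, BinnedCorrelation) and isinstance(ensemble_mean, BinnedCorrelation):
        if not np.allclose(corr.bin_edges, ensemble_mean.bin_edges):
            raise ValueError("correlation functions live on different bin grids")
    if c.shape != cbar.shape or band.shape != c.shape:
        raise ValueError("correlation, ensemble mean and band must share the bin grid")
    if not band.any():
        raise ValueError("band mask selects no bins")
    dev = c[band] - cbar[band]
    if np.any(np.isnan(dev)):
        raise ValueError("undefined (NaN) bins inside the band")
    return float(dev.sum())


def s_statistic(data_corr, ensemble_mean, band) -> float:
    """T-type statistic of the *observed* correlation function (Eq.-8 role).

    Identical computation to :func:`t_statistic`, applied to the measured
    correlation function instead of an ensemble member.
    """
    return t_statistic(data_corr, ensemble_mean, band)


def monte_carlo_pvalue(t_values, s_value: float, alternative: str = "lower") -> float:
    """Rank-based Monte-Carlo p-value of an observed statistic.

    p = (1 + #{ensemble values at least as extreme as s}) / (m + 1), where
    extremeness follows *alternative* ('lower', 'upper' or 'two-sided').
    With m = 99 and an observed value more extreme than the whole ensemble
    this gives exactly p = 0.01; ties are counted as extreme, so the value
    never drops below 1/(m+1).
    """
    t = np.asarray(t_values, dtype=float)
    if t.ndim != 1 or t.size < 99:
        raise ValueError("need an ensemble of at least 99 statistic values")
    if np.any(np.isnan(t)) or np.isnan(s_value):
        raise ValueError("statistic values must not be NaN")
    m = t.size
    p_low = (1 + int(np.sum(t <= s_value))) / (m + 1)
    p_high = (1 + int(np.sum(t >= s_value))) / (m + 1)
    if alternative == "lower":
        return p_low
    if alternative == "upper":
        return p_high
    if alternative == "two-sided":
        return min(1.0, 2.0 * min(p_low, p_high))
    raise ValueError(f"unknown alternative {alternative!r}")


# ---------------------------------------------------------------------------
# goodness-of-fit p-values for local spatial statistics

def _measure_curves(point_sets, window, measure: str, eval_r: np.ndarray) -> np.ndarray:
    if measure == "g":
        return np.vstack([g_function(p, window, eval_r) for p in point_sets])
    if measure == "l":
        return np.vstack([l_function(p, window, eval_r) for p in point_sets])
    raise ValueError(f"unknown measure {measure!r}")


def local_stats_pvalue(observed: PointMosaic, model: Callable[[int], PointMosaic],
                       measure: str, m: int = 99, polarity: str = "off",
                       eval_r: Optional[np.ndarray] = None,
                       seed: int = 0) -> MonteCarloTest:
    """Monte-Carlo goodness-of-fit p-value for a local spatial statistic.

    The observed mosaic and m model simulations are each scored against the
    mean of the others: for the curves G and L the score is the integrated
    squared deviation, for μ₂ the squared deviation of the scalar.  The
    rank of the observed score in the simulated score distribution gives
    the p-value (upper tail: large scores mean misfit); p ≤ 0.05 signals
    that the model does not fit.

    ``model(seed_i)`` must return a :class:`PointMosaic`; *measure* is one
    of ``"g"``, ``"l"`` or ``"mu2"``.
    """
    if m < 99:
        raise ValueError("need at least 99 model simulations")
    if measure not in ("g", "l", "mu2"):
        raise ValueError("measure must be 'g', 'l' or 'mu2'")
    seeds = np.random.SeedSequence(seed).generate_state(m) % (2**31)
    sims = [model(int(s)) for s in seeds]
    n_obs = observed.points(polarity).shape[0]
    n_sim = np.mean([mos.points(polarity).shape[0] for mos in sims[:10]])
    if n_obs and abs(n_sim - n_obs) > 0.2 * n_obs:
        warnings.warn(
            f"model density ({n_sim:.0f} {polarity} cells) differs from the observed "
            f"mosaic ({n_obs}) by more than 20%", stacklevel=2,
        )
    window = observed.window
    point_sets = [observed.points(polarity)] + [mos.points(polarity) for mos in sims]
    if measure == "mu2":
        vals = np.array([voronoi_disorder(p, window) for p in point_sets])
        total = vals.sum()
        loo_mean = (total - vals) / (vals.size - 1)
        scores = (vals - loo_mean) ** 2
    else:
        if eval_r is None:
            x0, x1, y0, y1 = window
            r_hi = min(x1 - x0, y1 - y0) / 4.0
            eval_r = np.linspace(r_hi / 50.0, r_hi, 50)
        curves = _measure_curves(point_sets, window, measure, np.asarray(eval_r, dtype=float))
        total = curves.sum(axis=0)
        loo_mean = (total[None, :] - curves) / (curves.shape[0] - 1)
        scores = ((curves - loo_mean) ** 2).sum(axis=1)
    s_obs, t_sims = scores[0], scores[1:]
    p = monte_carlo_pvalue(t_sims, s_obs, alternative="upper")
    return MonteCarloTest(t_sims, float(s_obs), p, "upper")


# ---------------------------------------------------------------------------
# dipole-correlation ensembles

def synthetic_opm_sampler(column_spacing_cortex_mm: float = CAT_COLUMN_SPACING_CORTEX_MM,
                          pixel_size: float = OPM_PIXEL_SIZE,
                          rel_bandwidth: float = 0.3) -> Callable:
    """Factory for OPM region samplers backed by the field synthesizer.

    The returned callable ``sampler(seed, window, magnification)`` produces
    an independent synthetic OPM covering *window*, with the cortical
    column spacing mapped into retinal µm by the magnification.
    """

    def sampler(seed: int, window, magnification: float) -> OrientationField:
        return synthesize_opm_for_window(
            window, pixel_size=pixel_size,
            column_spacing_cortex_mm=column_spacing_cortex_mm,
            magnification=magnification, rel_bandwidth=rel_bandwidth, seed=seed,
        )

    return sampler


def _corr_values_for_mosaic(mosaic: PointMosaic, d: float, edges: np.ndarray) -> np.ndarray:
    """Correlation-function values of a mosaic's dipoles on a fixed bin grid."""
    _, _, mid, _, theta = _extract_arrays(mosaic.on_points, mosaic.off_points, d)
    n_bins = edges.size - 1
    if mid.shape[0] < 2:
        return np.full(n_bins, np.nan)
    values, _ = _correlation_arrays(mid, theta, n_bins, float(edges[-1]))
    return values


def _simulate_corr_ensemble(n_real: int, window, n_on: int, n_off: int,
                            params: InteractionParams, beta: float, d: float,
                            magnification: float, opm_source: Optional[Callable],
                            n_sweeps: int, edges: np.ndarray,
                            seed_seq: np.random.SeedSequence) -> np.ndarray:
    """Correlation functions of n_real independent (m)PIPP realizations."""
    sim_seeds = seed_seq.generate_state(2 * n_real) % (2**31)
    out = np.empty((n_real, edges.size - 1))
    for k in range(n_real):
        opm = None
        if beta > 0:
            if opm_source is None:
                raise ValueError("an OPM sampler is required for beta > 0")
            opm = opm_source(int(sim_seeds[2 * k]), window, magnification)
        cfg = MPIPPConfig(beta=beta, d_mod=d, n_sweeps=n_sweeps,
                          magnification=magnification, seed=int(sim_seeds[2 * k + 1]))
        mosaic = simulate_mpipp(window, n_on, n_off, params, opm=opm, cfg=cfg)
        out[k] = _corr_values_for_mosaic(mosaic, d, edges)
    return out


def beta_magnification_scan(observed_corr: BinnedCorrelation, opm_source: Callable,
                            beta_grid: Sequence[float], magnification_grid: Sequence[float],
                            n_real: int = 100, d: float = DIPOLE_DISTANCE,
                            params: InteractionParams = CAT_BETA_INTERACTIONS, *,
                            window, n_on: int, n_off: int,
                            r_cut: float = LOCAL_BAND_R_MAX, n_sweeps: int = 20,
                            alternative: str = "two-sided", seed: int = 0) -> np.ndarray:
    """Monte-Carlo consistency p-values over a (β, magnification) grid.

    For each grid cell, *n_real* mPIPP realizations (each modulated by an
    independently sampled OPM region) provide the T distribution of the
    band-summed correlation statistic; S comes from the observed
    correlation function over the bins below *r_cut*.  Small p-values mean
    the observed correlations are unlikely under that (β, M); the default
    two-sided alternative flags data that is either less or more locally
    correlated than the model ensemble.
    """
    beta_grid = np.asarray(beta_grid, dtype=float)
    magnification_grid = np.asarray(magnification_grid, dtype=float)
    if beta_grid.size == 0 or magnification_grid.size == 0:
        raise ValueError("parameter grids must be non-empty")
    edges = observed_corr.bin_edges
    band = distance_band(edges, 0.0, r_cut) & observed_corr.defined
    if not band.any():
        raise ValueError(f"no defined bins below the distance cutoff {r_cut} µm")
    pmat = np.empty((beta_grid.size, magnification_grid.size))
    root = np.random.SeedSequence(seed)
    for a, beta in enumerate(beta_grid):
        for b, mag in enumerate(magnification_grid):
            child = np.random.SeedSequence(entropy=seed, spawn_key=(a, b))
            ens = _simulate_corr_ensemble(n_real, window, n_on, n_off, params,
                                          float(beta), d, float(mag), opm_source,
                                          n_sweeps, edges, child)
            if np.isnan(ens[:, band]).any():
                raise ValueError("ensemble produced undefined bins inside the band")
            cbar = ens.mean(axis=0)
            t_vals = (ens[:, band] - cbar[band]).sum(axis=1)
            s_val = s_statistic(observed_corr.values, cbar, band)
            pmat[a, b] = monte_carlo_pvalue(t_vals, s_val, alternative=alternative)
    del root
    return pmat


# ---------------------------------------------------------------------------
# statistical power (false-negative rate)

def _band_mask(edges: np.ndarray, band: str) -> np.ndarray:
    if band == "local":
        mask = distance_band(edges, 0.0, LOCAL_BAND_R_MAX)
    elif band == "anticorrelation":
        mask = distance_band(edges, *ANTI_BAND)
    else:
        raise ValueError("band must be 'local' or 'anticorrelation'")
    if not mask.any():
        raise ValueError(f"the {band!r} band is undefined for this bin grid")
    return mask


def estimate_false_negative_rate(beta: float, n_mosaics: int, area_mm2: float,
                                 band: str,
                                 params: InteractionParams = CAT_BETA_INTERACTIONS,
                                 opm_source: Optional[Callable] = None,
                                 n_pipp: int = 500, n_draws: int = 100,
                                 n_repeats: int = 1000, alpha: float = 0.05, *,
                                 density_on: float = M623_DENSITY_ON,
                                 density_off: float = M623_DENSITY_OFF,
                                 d: float = DIPOLE_DISTANCE, n_bins: int = 20,
                                 n_sweeps: int = 20,
                                 magnification: float = CAT_MAGNIFICATION,
                                 seed: int = 0,
                                 return_pvalues: bool = False):
    """False-negative rate of the dipole-correlation test by simulation.

    The procedure builds an unmodulated PIPP null ensemble (*n_pipp*
    realizations at the reference densities scaled to *area_mm2*); each
    repeat resamples 100 of its correlation functions, forms the T
    distribution from *n_draws* averages of *n_mosaics* resampled
    functions, computes S from *n_mosaics* fresh mPIPP realizations at
    *beta* (each with an independent OPM region), and records the rank
    p-value over the requested *band* ('local': positive correlation in
    the first bins, upper tail; 'anticorrelation': 200–400 µm, lower
    tail).  The false-negative rate is the fraction of repeats with
    p > *alpha*.
    """
    if n_mosaics < 1:
        raise ValueError("n_mosaics must be >= 1")
    if opm_source is None:
        opm_source = synthetic_opm_sampler()
    side = 1000.0 * np.sqrt(area_mm2)
    window = (0.0, side, 0.0, side)
    n_on = round(density_on * area_mm2)
    n_off = round(density_off * area_mm2)
    diagonal = side * np.sqrt(2.0)
    edges = np.linspace(0.0, diagonal, n_bins + 1)
    mask = _band_mask(edges, band)
    alternative = "upper" if band == "local" else "lower"

    root = np.random.SeedSequence(seed)
    null_seq, mod_seq, draw_seq = root.spawn(3)
    null_corrs = _simulate_corr_ensemble(n_pipp, window, n_on, n_off, params,
                                         0.0, d, magnification, None, n_sweeps,
                                         edges, null_seq)
    ok = ~np.isnan(null_corrs[:, mask]).any(axis=1)
    if ok.sum() < 0.9 * n_pipp:
        raise ValueError("too many null realizations with undefined bins in the band")
    null_corrs = null_corrs[ok]

    draw_rng = np.random.default_rng(draw_seq)
    mod_seeds = mod_seq.spawn(n_repeats)
    pvals = np.empty(n_repeats)
    for r in range(n_repeats):
        pool = null_corrs[draw_rng.integers(0, null_corrs.shape[0], size=100)]
        picks = draw_rng.integers(0, 100, size=(n_draws, n_mosaics))
        averaged = pool[picks].mean(axis=1)  # (n_draws, n_bins)
        cbar = averaged.mean(axis=0)
        t_vals = (averaged[:, mask] - cbar[mask]).sum(axis=1)
        mod_corrs = _simulate_corr_ensemble(n_mosaics, window, n_on, n_off, params,
                                            float(beta), d, magnification,
                                            opm_source, n_sweeps, edges,
                                            mod_seeds[r])
        with warnings.catch_warnings():
            # far bins can be all-NaN across the N draws; only band bins matter
            warnings.simplefilter("ignore", RuntimeWarning)
            s_curve = np.nanmean(mod_corrs, axis=0)
        if np.isnan(s_curve[mask]).any():
            raise ValueError("modulated realizations produced undefined band bins")
        s_val = float((s_curve[mask] - cbar[mask]).sum())
        pvals[r] = monte_carlo_pvalue(t_vals, s_val, alternative=alternative)
    fnr = float(np.mean(pvals > alpha))
    if return_pvalues:
        return fnr, pvals
    return fnr


def power_grid(beta_values: Sequence[float], n_values: Sequence[int],
               area_values: Sequence[float], band: str,
               params: InteractionParams = CAT_BETA_INTERACTIONS,
               opm_source: Optional[Callable] = None, seed: int = 0,
               **kwargs) -> PowerGrid:
    """False-negative-rate surface over (β, N, area) grids.

    Keyword arguments are forwarded to
    :func:`estimate_false_negative_rate` (repeat counts, densities, d, ...).
    """
    beta_values = np.asarray(beta_values, dtype=float)
    n_values = np.asarray(n_values, dtype=int)
    area_values = np.asarray(area_values, dtype=float)
    fnr = np.empty((beta_values.size, n_values.size, area_values.size))
    for a, beta in enumerate(beta_values):
        for b, n in enumerate(n_values):
            for c, area in enumerate(area_values):
                cell_seed = np.random.SeedSequence(entropy=seed, spawn_key=(a, b, c))
                fnr[a, b, c] = estimate_false_negative_rate(
                    float(beta), int(n), float(area), band, params=params,
                    opm_source=opm_source,
                    seed=int(cell_seed.generate_state(1)[0] % (2**31)), **kwargs)
    return PowerGrid(beta_values, n_values, area_values, fnr, band)
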