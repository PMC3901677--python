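"""Monte-Carlo tests, calibration and statistical power."""
import numpy as np
import pytest

from rgcdipoles import (
    BinnedCorrelation,
    PointMosaic,
    beta_magnification_scan,
    dipole_correlation,
    distance_band,
    estimate_false_negative_rate,
    extract_dipoles,
    local_stats_pvalue,
    monte_carlo_pvalue,
    positive_correlation_band,
    s_statistic,
    simulate_mpipp,
    synthetic_opm_sampler,
    t_statistic,
)
from rgcdipoles.presets import (
    CAT_BETA_INTERACTIONS,
    CAT_MAGNIFICATION,
    DIPOLE_DISTANCE,
    M623_WINDOW,
    default_config,
    mosaic_counts,
)


def _corr(values, edges=None, counts=None):
    values = np.asarray(values, dtype=float)
    if edges is None:
        edges = np.arange(values.size + 1) * 50.0
    if counts is None:
        counts = np.where(np.isnan(values), 0, 10).astype(int)
    return BinnedCorrelation(edges, values, counts)


class TestBandMasks:
    def test_distance_band_selects_centers(self):
        edges = np.arange(6) * 100.0
        np.testing.assert_array_equal(distance_band(edges, 200, 400),
                                      [False, False, True, True, False])

    def test_positive_band_thresholds_ensemble_mean(self):
        mask = positive_correlation_band(_corr([0.5, 0.05, 0.3]), threshold=0.1)
        np.testing.assert_array_equal(mask, [True, False, True])


class TestTandS:
    def test_zero_deviation_gives_zero(self):
        c = _corr([0.4, 0.2, 0.1])
        assert t_statistic(c, c, [True, True, True]) == 0.0

    def test_single_bin_deviation(self):
        assert t_statistic(_corr([0.5]), _corr([0.3]), [True]) == pytest.approx(0.2)

    def test_exchangeable_ensemble_centred_at_zero(self):
        rng = np.random.default_rng(0)
        ens = rng.normal(0.2, 0.05, size=(500, 6))
        cbar = ens.mean(axis=0)
        band = np.ones(6, bool)
        t_vals = [t_statistic(row, cbar, band) for row in ens]
        assert abs(np.mean(t_vals)) < 3 * np.std(t_vals) / np.sqrt(len(t_vals))

    def test_undefined_bins_in_band_rejected(self):
        with pytest.raises(ValueError, match="NaN"):
            t_statistic(_corr([0.5, np.nan]), _corr([0.3, 0.3]), [True, True])

    def test_empty_band_rejected(self):
        with pytest.raises(ValueError, match="no bins"):
            s_statistic(_corr([0.5]), _corr([0.3]), [False])

    def test_uncorrelated_data_against_correlated_ensemble_is_negative(self):
        s = s_statistic(_corr([0.0, 0.0]), _corr([0.6, 0.5]), [True, True])
        assert s < -1.0


class TestMonteCarloPvalue:
    def test_floor_is_exactly_one_percent(self):
        t = np.linspace(0.0, 1.0, 99)
        assert monte_carlo_pvalue(t, -5.0, "lower") == 0.01

    def test_median_observation_two_sided(self):
        t = np.linspace(-1, 1, 99)
        assert monte_carlo_pvalue(t, 0.0, "two-sided") > 0.95

    def test_null_calibration_uniform(self):
        """p-values of null draws are uniform on their support lattice."""
        rng = np.random.default_rng(1)
        pvals = []
        for _ in range(1000):
            t = rng.standard_normal(99)
            s = rng.standard_normal()
            pvals.append(monte_carlo_pvalue(t, s, "lower"))
        pvals = np.asarray(pvals)
        support = np.arange(1, 101) / 100.0
        assert set(np.round(pvals, 9)) <= set(np.round(support, 9))
        grid = np.linspace(0.05, 0.95, 19)
        ecdf = np.array([(pvals <= q).mean() for q in grid])
        assert np.max(np.abs(ecdf - grid)) < 0.05

    def test_small_ensemble_rejected(self):
        with pytest.raises(ValueError, match="99"):
            monte_carlo_pvalue(np.zeros(50), 0.0)

    def test_calibrated_s_within_central_region(self):
        """S drawn from the ensemble's own distribution lands inside the
        central 95% of T in ≈ 95% of repeats."""
        rng = np.random.default_rng(2)
        hits = 0
        reps = 400
        for _ in range(reps):
            t = rng.standard_normal(99)
            s = rng.standard_normal()
            lo, hi = np.percentile(t, [2.5, 97.5])
            hits += lo <= s <= hi
        assert 0.90 <= hits / reps <= 0.99


class TestLocalStatsPvalue:
    def test_model_fits_itself(self, csr_mosaic):
        res = local_stats_pvalue(csr_mosaic(12345), csr_mosaic, "g", m=99, seed=1)
        assert res.p_value > 0.05

    def test_mu2_calibrated_under_the_model(self, csr_mosaic):
        res = local_stats_pvalue(csr_mosaic(777), csr_mosaic, "mu2", m=99, seed=2)
        assert res.p_value > 0.05

    def test_hexagonal_lattice_rejected_against_csr(self, csr_mosaic, hex_points):
        pts = hex_points((0, 1000, 0, 1000), 110.0)
        observed = PointMosaic(pts, csr_mosaic(7).off_points, (0, 1000, 0, 1000))
        with pytest.warns(UserWarning, match="density"):
            res = local_stats_pvalue(observed, csr_mosaic, "g", m=99,
                                     polarity="on", seed=1)
        assert res.p_value == 0.01  # forced extreme rank

    def test_small_m_rejected(self, csr_mosaic):
        with pytest.raises(ValueError, match="99"):
            local_stats_pvalue(csr_mosaic(0), csr_mosaic, "g", m=50)


def _observed_correlation(beta, seed, n_sweeps=20):
    sampler = synthetic_opm_sampler()
    opm = sampler(seed + 900, M623_WINDOW, CAT_MAGNIFICATION) if beta > 0 else None
    mosaic = simulate_mpipp(M623_WINDOW, *mosaic_counts(1.0), CAT_BETA_INTERACTIONS,
                            opm=opm,
                            cfg=default_config(beta=beta, seed=seed, n_sweeps=n_sweeps))
    dipoles = extract_dipoles(mosaic, DIPOLE_DISTANCE)
    return dipole_correlation(dipoles, 20, np.hypot(1000.0, 1000.0))


class TestBetaMagnificationScan:
    def test_consistent_and_inconsistent_observations(self):
        """A PIPP-generated correlation function is consistent with the
        β = 0 cell; a strongly modulated one reaches the p floor there."""
        sampler = synthetic_opm_sampler()
        kwargs = dict(n_real=100, d=DIPOLE_DISTANCE, params=CAT_BETA_INTERACTIONS,
                      window=M623_WINDOW, n_on=72, n_off=76, seed=3)
        p_null = beta_magnification_scan(_observed_correlation(0.0, 42), sampler,
                                         [0.0], [CAT_MAGNIFICATION], **kwargs)
        p_modulated = beta_magnification_scan(_observed_correlation(30.0, 43), sampler,
                                              [0.0], [CAT_MAGNIFICATION], **kwargs)
        assert p_null[0, 0] > 0.05
        assert p_modulated[0, 0] == pytest.approx(2 / 101)  # two-sided floor

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            beta_magnification_scan(_corr([0.1]), synthetic_opm_sampler(), [], [1.7],
                                    window=M623_WINDOW, n_on=72, n_off=76)


class TestFalseNegativeRate:
    def test_monotone_in_n_and_harder_anticorrelation_band(self):
        """More mosaics lower the miss rate; the anticorrelation band needs
        more data than the local band at matched settings."""
        kwargs = dict(params=CAT_BETA_INTERACTIONS, n_pipp=100, n_repeats=100,
                      seed=21)
        fnr_local_1 = estimate_false_negative_rate(1.0, 1, 0.64, "local", **kwargs)
        fnr_local_3 = estimate_false_negative_rate(1.0, 3, 0.64, "local", **kwargs)
        fnr_anti_1 = estimate_false_negative_rate(1.0, 1, 0.64, "anticorrelation",
                                                  **kwargs)
        assert fnr_local_3 <= fnr_local_1 + 0.05
        assert fnr_anti_1 >= fnr_local_1 - 0.05

    def test_band_undefined_for_tiny_grid(self):
        with pytest.raises(ValueError, match="band"):
            estimate_false_negative_rate(1.0, 1, 0.01, "anticorrelation",
                                         n_pipp=100, n_repeats=5, n_bins=2)

    def test_invalid_mosaic_count(self):
        with pytest.raises(ValueError, match="n_mosaics"):
            estimate_false_negative_rate(1.0, 0, 1.0, "local")
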