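"""Interaction functions and the Monte-Carlo mosaic simulator."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rgcdipoles import (
    InteractionParams,
    MPIPPConfig,
    OrientationField,
    PairRepulsion,
    PointMosaic,
    SimulationState,
    acceptance_probability,
    angular_modulation,
    extract_dipoles,
    generate_moire_hexagonal,
    inter_step,
    intra_interaction,
    modulated_inter_interaction,
    simulate_mpipp,
)
from rgcdipoles.dipoles import _extract_arrays, dipole_correlation
from rgcdipoles.inference import synthetic_opm_sampler
from rgcdipoles.presets import (
    CAT_BETA_INTERACTIONS,
    CAT_MAGNIFICATION,
    DIPOLE_DISTANCE,
    M623_WINDOW,
    default_config,
    mosaic_counts,
)

PAIR = PairRepulsion(delta=20.0, phi=40.0, alpha=2.0)


class TestInteractionFunctions:
    def test_intra_zero_inside_and_at_exclusion(self):
        assert intra_interaction(10.0, PAIR) == 0.0
        assert intra_interaction(20.0, PAIR) == 0.0

    def test_intra_saturates(self):
        assert intra_interaction(20.0 + 10 * 40.0, PAIR) == pytest.approx(1.0, abs=1e-9)

    @given(st.floats(0, 500), st.floats(0, 500))
    def test_intra_nondecreasing(self, a, b):
        lo, hi = sorted((a, b))
        assert intra_interaction(lo, PAIR) <= intra_interaction(hi, PAIR) + 1e-12

    def test_inter_step_boundary_inclusive(self):
        assert inter_step(0.0, 15.0) == 0.0
        assert inter_step(15.0, 15.0) == 1.0  # "not less than" the soma distance
        assert inter_step(30.0, 15.0) == 1.0

    def test_modulation_trivial_values(self):
        assert angular_modulation(0.0, 4.2) == pytest.approx(1.0)
        assert angular_modulation(1.234, 0.0) == pytest.approx(1.0)
        assert angular_modulation(np.pi / 2, 2.5) == pytest.approx(np.exp(-5.0))

    @given(st.floats(-10, 10), st.floats(0, 50))
    def test_modulation_pi_periodic_and_bounded(self, dtheta, beta):
        v = angular_modulation(dtheta, beta)
        assert 0.0 <= v <= 1.0
        assert v == pytest.approx(angular_modulation(dtheta + np.pi, beta), rel=1e-9)


CONST_OPM = OrientationField(np.zeros((100, 100)), 10.0, 500.0)


class TestModulatedInterInteraction:
    CFG = MPIPPConfig(beta=2.5, d_mod=80.0)

    def test_soma_core_forbidden(self):
        assert modulated_inter_interaction((0, 0), (5, 0), CONST_OPM, self.CFG, 15.0) == 0.0

    def test_no_modulation_beyond_d(self):
        assert modulated_inter_interaction((100, 100), (100, 190), CONST_OPM, self.CFG, 15.0) == 1.0

    def test_aligned_dipole_unpenalized(self):
        # vertical pair -> horizontal preferred orientation = the map's 0
        assert modulated_inter_interaction((100, 100), (100, 140), CONST_OPM,
                                           self.CFG, 15.0) == pytest.approx(1.0)

    def test_orthogonal_dipole_penalized(self):
        v = modulated_inter_interaction((100, 100), (140, 100), CONST_OPM, self.CFG, 15.0)
        assert v == pytest.approx(np.exp(-5.0))


class TestAcceptanceProbability:
    PARAMS = CAT_BETA_INTERACTIONS

    def _state(self, on, off):
        return SimulationState(PointMosaic(on, off, (0, 1000, 0, 1000)))

    def test_zero_inside_same_polarity_exclusion(self):
        state = self._state([(500, 500), (520, 500)], [])
        cfg = default_config()
        p = acceptance_probability((510, 500), 0, "on", state, None, self.PARAMS, cfg)
        assert p == 0.0

    def test_isolated_candidate_accepted(self):
        state = self._state([(500, 500), (10, 10)], [(990, 990)])
        cfg = default_config(beta=7.0)
        p = acceptance_probability((500, 500), 0, "on", state, CONST_OPM, self.PARAMS, cfg)
        assert p == pytest.approx(1.0, abs=1e-3)

    def test_single_orthogonal_neighbour_gives_modulation_factor(self):
        beta = 2.5
        state = self._state([(500, 500)], [(540, 500)])
        cfg = default_config(beta=beta)
        p = acceptance_probability((500, 500), 0, "on", state, CONST_OPM, self.PARAMS, cfg)
        assert p == pytest.approx(np.exp(-2 * beta))

    @given(st.integers(0, 10))
    def test_bounded_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        state = self._state(rng.random((20, 2)) * 1000, rng.random((20, 2)) * 1000)
        p = acceptance_probability(rng.random(2) * 1000, 3, "on", state,
                                   CONST_OPM, self.PARAMS, default_config(beta=1.0))
        assert 0.0 <= p <= 1.0


class TestSimulate:
    def test_bit_reproducible(self):
        a = simulate_mpipp(M623_WINDOW, 30, 30, CAT_BETA_INTERACTIONS,
                           cfg=default_config(seed=9))
        b = simulate_mpipp(M623_WINDOW, 30, 30, CAT_BETA_INTERACTIONS,
                           cfg=default_config(seed=9))
        np.testing.assert_array_equal(a.on_points, b.on_points)
        np.testing.assert_array_equal(a.off_points, b.off_points)

    def test_beta_zero_identical_with_and_without_opm(self):
        """At β = 0 the OPM is never consulted: the code path is the plain PIPP."""
        opm = synthetic_opm_sampler()(0, M623_WINDOW, CAT_MAGNIFICATION)
        a = simulate_mpipp(M623_WINDOW, 40, 40, CAT_BETA_INTERACTIONS,
                           opm=opm, cfg=default_config(seed=2))
        b = simulate_mpipp(M623_WINDOW, 40, 40, CAT_BETA_INTERACTIONS,
                           opm=None, cfg=default_config(seed=2))
        np.testing.assert_array_equal(a.on_points, b.on_points)
        np.testing.assert_array_equal(a.off_points, b.off_points)

    def test_infeasible_packing_rejected_before_simulation(self):
        dense = InteractionParams(PairRepulsion(200.0, 40.0, 2.0),
                                  PairRepulsion(200.0, 40.0, 2.0),
                                  PairRepulsion(15.0))
        with pytest.raises(ValueError, match="packing"):
            simulate_mpipp((0, 500, 0, 500), 50, 50, dense, cfg=default_config())

    def test_beta_without_opm_rejected(self):
        with pytest.raises(ValueError, match="OPM"):
            simulate_mpipp(M623_WINDOW, 20, 20, CAT_BETA_INTERACTIONS,
                           cfg=default_config(beta=1.0))

    def test_exclusion_zones_respected_after_sweeps(self):
        """Same-polarity pairs closer than δ are (almost) never left over."""
        violations = 0
        for seed in range(100):
            mosaic = simulate_mpipp(M623_WINDOW, *mosaic_counts(1.0),
                                    CAT_BETA_INTERACTIONS, cfg=default_config(seed=seed))
            for pts, delta in ((mosaic.on_points, 30.0), (mosaic.off_points, 30.0)):
                d = np.hypot(*(pts[:, None, :] - pts[None, :, :]).transpose(2, 0, 1))
                np.fill_diagonal(d, np.inf)
                if d.min() < delta:
                    violations += 1
                    break
        assert violations <= 1  # <= 1% of realizations

    def test_dipole_count_decreases_with_modulation(self):
        """Modulation thins dipoles: the β = 0 → 2.5 ordering of mean counts."""
        sampler = synthetic_opm_sampler()
        counts = {0.0: [], 2.5: []}
        for beta in counts:
            for seed in range(10):
                opm = sampler(seed, M623_WINDOW, CAT_MAGNIFICATION) if beta else None
                mosaic = simulate_mpipp(M623_WINDOW, *mosaic_counts(1.0),
                                        CAT_BETA_INTERACTIONS, opm=opm,
                                        cfg=default_config(beta=beta, seed=seed))
                counts[beta].append(len(extract_dipoles(mosaic, DIPOLE_DISTANCE)))
        assert np.mean(counts[2.5]) < np.mean(counts[0.0])


class TestMoireFixture:
    def test_aligned_lattices_give_identical_dipole_orientations(self):
        mosaic = generate_moire_hexagonal((0, 1000, 0, 1000), 100.0, 0.0, 0.0, seed=0)
        dipoles = extract_dipoles(mosaic, 60.0)
        thetas = {round(d.orientation, 9) for d in dipoles}
        assert len(dipoles) > 50 and len(thetas) == 1
        corr = dipole_correlation(dipoles, 10, 800.0)
        np.testing.assert_allclose(corr.values[corr.defined], 1.0)

    def test_moire_period_from_small_rotation(self):
        """The orientation pattern is periodic with period a / (2 sin(α/2))."""
        a, rot = 130.0, np.deg2rad(8.0)
        expected = a / (2 * np.sin(rot / 2))
        mosaic = generate_moire_hexagonal((0, 4000, 0, 4000), a, 0.0, rot, seed=0)
        _, _, mid, _, theta = _extract_arrays(mosaic.on_points, mosaic.off_points, 80.0)
        ng, px = 128, 4000.0 / 128
        grid = np.zeros((ng, ng), complex)
        cnt = np.zeros((ng, ng))
        ix = np.clip((mid[:, 0] / px).astype(int), 0, ng - 1)
        iy = np.clip((mid[:, 1] / px).astype(int), 0, ng - 1)
        np.add.at(grid, (iy, ix), np.exp(2j * theta))
        np.add.at(cnt, (iy, ix), 1)
        grid = np.where(cnt > 0, grid / np.maximum(cnt, 1), 0)
        spec = np.abs(np.fft.fft2(grid)) ** 2
        spec[0, 0] = 0.0
        kf = 2 * np.pi * np.fft.fftfreq(ng, px)
        k = np.hypot(kf[:, None], kf[None, :])
        low_k = (k > 0) & (k < 2 * np.pi / (1.5 * a))  # below the lattice scale
        k_peak = k[low_k][np.argmax(spec[low_k])]
        assert abs(2 * np.pi / k_peak - expected) / expected < 0.3

    def test_heavy_jitter_destroys_correlations(self):
        a = 130.0
        mosaic = generate_moire_hexagonal((0, 2000, 0, 2000), a, a / 2, np.deg2rad(8.0),
                                          seed=1)
        dipoles = extract_dipoles(mosaic, 80.0)
        corr = dipole_correlation(dipoles, 15, 1500.0)
        beyond_first = corr.values[1:][corr.defined[1:]]
        assert np.all(np.abs(beyond_first) < 0.1)
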