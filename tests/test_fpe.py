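"""Transition kernels, drift/diffusion estimation and fixed-point analysis."""

import numpy as np
import pytest
from scipy import stats

from locustswarm import (
    DriftDiffusionCurves,
    ParameterError,
    SimulationConfig,
    TransitionKernel,
    WorldConfig,
    alignment,
    empirical_km,
    estimate_transition_kernel,
    find_fixed_points,
    km_from_kernel,
    make_fixed_disposition,
    meanfield_drift_diffusion,
    run_simulation,
    sample_conditioned_swarm,
    z_grid,
)


@pytest.fixture(scope="module")
def kernel_d0_n10():
    rng = np.random.default_rng(101)
    return estimate_transition_kernel(
        WorldConfig(80, 5, 10), make_fixed_disposition(0.0), 4000, rng
    )


@pytest.fixture(scope="module")
def kernel_d5_n10():
    rng = np.random.default_rng(102)
    return estimate_transition_kernel(
        WorldConfig(80, 5, 10), make_fixed_disposition(5.0), 4000, rng
    )


class TestConditionedSampling:
    def test_extreme_alignment_sets_all_headings(self, rng):
        cfg = WorldConfig(80, 5, 7)
        swarm = sample_conditioned_swarm(1.0, cfg, make_fixed_disposition(1.0), rng)
        assert np.all(swarm.headings == 1)

    def test_balanced_alignment_splits_evenly(self, rng):
        cfg = WorldConfig(80, 5, 10)
        swarm = sample_conditioned_swarm(0.0, cfg, make_fixed_disposition(1.0), rng)
        assert (swarm.headings == 1).sum() == 5

    @pytest.mark.parametrize("z", [-1.0, -0.6, 0.2, 1.0])
    def test_alignment_matches_conditioning_value(self, z, rng):
        cfg = WorldConfig(80, 5, 10)
        swarm = sample_conditioned_swarm(z, cfg, make_fixed_disposition(1.0), rng)
        assert alignment(swarm) == pytest.approx(z)

    def test_off_grid_value_rejected(self, rng):
        with pytest.raises(ParameterError):
            sample_conditioned_swarm(0.05, WorldConfig(80, 5, 10),
                                     make_fixed_disposition(1.0), rng)


class TestKernel:
    def test_grid_and_row_stochasticity(self, kernel_d5_n10):
        assert np.allclose(np.diff(kernel_d5_n10.grid), 2 / 10)
        assert np.allclose(kernel_d5_n10.P.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(kernel_d5_n10.P >= 0)

    def test_mirror_symmetry(self, kernel_d5_n10):
        """P(z'|z) equals P(-z'|-z) within Monte-Carlo error."""
        P, n = kernel_d5_n10.P, kernel_d5_n10.counts[0]
        mirrored = P[::-1, ::-1]
        se = np.sqrt(np.maximum(P * (1 - P), 1e-12) / n)
        assert np.all(np.abs(P - mirrored) <= 4 * (se + se[::-1, ::-1]) + 1e-12)

    def test_zero_decisiveness_rows_are_binomial_and_z_independent(self, kernel_d0_n10):
        """With d = 0 every post-turn heading is uniform, so each row is the
        distribution of (2 Binomial(N, 1/2) - N)/N regardless of z."""
        N, n = 10, kernel_d0_n10.counts[0]
        expect = stats.binom.pmf(np.arange(N + 1), N, 0.5)
        se = np.sqrt(expect * (1 - expect) / n)
        for row in kernel_d0_n10.P:
            assert np.all(np.abs(row - expect) <= 4 * se + 1e-12)


class TestKramersMoyal:
    def test_deterministic_kernel_has_zero_drift_and_diffusion(self):
        grid = z_grid(4)
        kernel = TransitionKernel(grid, np.eye(5), np.full(5, 100))
        curves = km_from_kernel(kernel)
        assert np.allclose(curves.F, 0) and np.allclose(curves.D, 0)

    def test_zero_decisiveness_closed_forms_within_mc_error(self, kernel_d0_n10):
        curves = km_from_kernel(kernel_d0_n10)
        assert np.all(np.abs(curves.F + curves.z) <= 4 * curves.se_F)
        assert np.all(np.abs(curves.D - 1 / 20) <= 4 * curves.se_D + 1e-3)

    def test_drift_vanishes_at_zero_for_symmetric_policy(self, kernel_d5_n10):
        curves = km_from_kernel(kernel_d5_n10)
        i0 = np.argmin(np.abs(curves.z))
        assert abs(curves.F[i0]) <= 4 * curves.se_F[i0]


class TestMeanField:
    def test_zero_decisiveness_closed_forms_exact(self):
        for N in (10, 40):
            curves = meanfield_drift_diffusion(N, 8, make_fixed_disposition(0.0))
            assert np.allclose(curves.F, -curves.z, atol=1e-12)
            assert np.allclose(curves.D, 1 / (2 * N), atol=1e-15)

    def test_drift_odd_diffusion_even(self):
        curves = meanfield_drift_diffusion(40, 8, make_fixed_disposition(30.0))
        assert np.allclose(curves.F, -curves.F[::-1], atol=1e-12)
        assert np.allclose(curves.D, curves.D[::-1], atol=1e-12)

    def test_high_density_destabilises_disorder(self):
        curves = meanfield_drift_diffusion(70, 8, make_fixed_disposition(30.0))
        i0 = np.argmin(np.abs(curves.z))
        slope = (curves.F[i0 + 1] - curves.F[i0 - 1]) / (curves.z[i0 + 1] - curves.z[i0 - 1])
        assert slope > 0

    def test_agreement_with_kernel_at_moderate_decisiveness(self, kernel_d5_n10):
        """The mean field ignores within-sweep sequential feedback; observed
        systematic drift deviations stay below 0.1 for d in {1, 5}."""
        mf = meanfield_drift_diffusion(10, 8, make_fixed_disposition(5.0))
        ck = km_from_kernel(kernel_d5_n10)
        assert np.max(np.abs(mf.F - ck.F)) < 0.1

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ParameterError):
            meanfield_drift_diffusion(1, 8, make_fixed_disposition(1.0))
        with pytest.raises(ParameterError):
            meanfield_drift_diffusion(10, 0, make_fixed_disposition(1.0))


class TestEmpirical:
    def test_constant_trajectory_gives_zero_drift_and_diffusion(self):
        curves = empirical_km(np.ones(50), N=4)
        assert curves.z.tolist() == [1.0]
        assert curves.F[0] == 0.0 and curves.D[0] == 0.0

    def test_zero_decisiveness_long_run_matches_closed_form(self):
        rec = run_simulation(SimulationConfig(N=10, mode="fixed", d=0.0,
                                              steps=12000, seed=11))
        curves = empirical_km(rec, burn_in=100)
        well = curves.n >= 50
        assert np.all(np.abs(curves.F[well] + curves.z[well]) <= 4 * curves.se_F[well])
        assert np.allclose(curves.D[well], 1 / 20, atol=0.01)

    def test_agreement_with_kernel_on_well_sampled_bins(self):
        """Stationary position-heading correlations shift the empirical drift
        relative to the uniform-position kernel; at N = 40, d = 5 the
        deviation stays below 0.08 on well-sampled bins."""
        rec = run_simulation(SimulationConfig(N=40, mode="fixed", d=5.0,
                                              steps=15000, seed=12))
        emp = empirical_km(rec, burn_in=200)
        rng = np.random.default_rng(103)
        kernel = estimate_transition_kernel(
            WorldConfig(80, 5, 40), make_fixed_disposition(5.0), 3000, rng
        )
        ck = km_from_kernel(kernel)
        well = emp.n >= 200
        idx = np.searchsorted(np.round(ck.z, 9), np.round(emp.z[well], 9))
        assert np.max(np.abs(emp.F[well] - ck.F[idx])) < 0.08

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            empirical_km(np.array([0.0]), burn_in=0)


class TestFixedPoints:
    def test_linear_restoring_drift_has_single_stable_root(self):
        grid = z_grid(10)
        curves = DriftDiffusionCurves(grid, -grid, np.full(11, 0.05), "meanfield")
        points = find_fixed_points(curves)
        assert len(points) == 1
        assert points.points[0].z0 == pytest.approx(0.0)
        assert points.points[0].stability == "stable"
        assert points.points[0].slope == pytest.approx(-1.0)

    def test_cubic_drift_has_pitchfork_structure(self):
        z = np.linspace(-1, 1, 21)
        curves = DriftDiffusionCurves(z, z - z**3, np.full(21, 0.01), "meanfield")
        points = find_fixed_points(curves)
        assert [round(p.z0, 6) for p in points] == [-1.0, 0.0, 1.0]
        assert [p.stability for p in points] == ["stable", "unstable", "stable"]

    def test_identically_zero_drift_is_degenerate(self):
        grid = z_grid(6)
        curves = DriftDiffusionCurves(grid, np.zeros(7), np.zeros(7), "meanfield")
        points = find_fixed_points(curves)
        assert points.degenerate and len(points) == 0

    def test_low_density_meanfield_has_unique_stable_origin(self):
        curves = meanfield_drift_diffusion(10, 8, make_fixed_disposition(30.0))
        points = find_fixed_points(curves)
        assert len(points.stable()) == 1 and len(points.unstable()) == 0
        assert abs(points.stable()[0].z0) < 0.05
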