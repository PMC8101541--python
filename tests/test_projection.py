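import numpy as np
import pytest

from sharkcast.bandwidth import gaussian_kde_density, sheather_jones_bandwidth
from sharkcast.core_data import PopulationSeries, ScaledRateSeries
from sharkcast.errors import (
    AlignmentError,
    ConfigError,
    FitError,
    SamplerDegeneracyError,
)
from sharkcast.projection import (
    ProjectionEnsemble,
    back_transform_to_counts,
    build_residual_sampler,
    fit_sinusoid,
    project_ensemble,
    split_residuals,
)


class TestSinusoidFit:
    def test_noiseless_recovery_to_machine_precision(
            self, noiseless_sinusoid_series):
        fit = fit_sinusoid(noiseless_sinusoid_series)
        assert fit.alpha == pytest.approx(0.5, rel=1e-6)
        assert fit.beta == pytest.approx(0.3, rel=1e-6)
        assert fit.period == pytest.approx(100.0, rel=1e-6)
        assert fit.delta == pytest.approx(1.0, rel=1e-6)
        assert fit.sse < 1e-12

    @pytest.mark.parametrize("phase", [0.5, 2.0, 4.0, 5.5])
    def test_solution_normalized_to_positive_amplitude(self, phase):
        years = np.arange(1900, 2000)
        t = years - 1900.0
        y = 0.8 - 0.4 * np.cos(2 * np.pi / 60 * t + phase)  # negative amp
        fit = fit_sinusoid(ScaledRateSeries("NSW", years, y, 1.0))
        assert fit.beta >= 0.0
        assert 0.0 <= fit.delta < 2 * np.pi
        np.testing.assert_allclose(fit.predict(years), y, atol=1e-8)

    def test_five_point_fit_beats_dense_grid_oracle(self):
        years = np.arange(2000, 2005)
        y = np.array([1.2, 0.7, 0.4, 0.8, 1.3])
        fit = fit_sinusoid(ScaledRateSeries("NSW", years, y, 1.0),
                           min_obs=5)
        # brute-force oracle over a dense 4-D parameter grid
        x = years - years[0]
        alphas = np.linspace(0.0, 2.0, 21)
        betas = np.linspace(0.0, 1.5, 16)
        gammas = 2 * np.pi / np.linspace(2.5, 40.0, 60)
        deltas = np.linspace(0.0, 2 * np.pi, 25, endpoint=False)
        A, B, G, D = np.meshgrid(alphas, betas, gammas, deltas,
                                 indexing="ij")
        pred = A[..., None] + B[..., None] * np.cos(
            G[..., None] * x + D[..., None])
        grid_sse = ((pred - y) ** 2).sum(axis=-1).min()
        assert fit.sse <= grid_sse + 1e-8

    def test_constant_series_is_a_fit_error(self):
        s = ScaledRateSeries("NSW", np.arange(1900, 1950), np.full(50, 1.0),
                             1.0)
        with pytest.raises(FitError):
            fit_sinusoid(s)


class TestResidualPools:
    def fit_and_series(self):
        years = np.arange(1900, 2020)
        t = years - 1900.0
        rng = np.random.default_rng(0)
        y = 1.0 + 0.4 * np.cos(2 * np.pi / 90 * t) + \
            0.1 * rng.standard_normal(len(t))
        s = ScaledRateSeries("NSW", years, y, 1.0)
        return s, fit_sinusoid(s)

    def test_sign_partition_by_hand(self):
        s, fit = self.fit_and_series()
        resid = np.array([-1.0, 2.0, -3.0, 4.0])
        fake = ScaledRateSeries("NSW", fit.years[:4],
                                fit.fitted[:4] + resid, 1.0)
        from dataclasses import replace
        small_fit = replace(fit, years=fit.years[:4], fitted=fit.fitted[:4])
        pools = split_residuals(fake, small_fit)
        np.testing.assert_allclose(sorted(pools.positive), [2.0, 4.0])
        np.testing.assert_allclose(sorted(pools.negative), [-3.0, -1.0])

    def test_pools_partition_all_years(self):
        s, fit = self.fit_and_series()
        pools = split_residuals(s, fit)
        assert pools.n == len(s.scaled)

    def test_perfect_fit_is_degenerate(self, noiseless_sinusoid_series):
        fit = fit_sinusoid(noiseless_sinusoid_series)
        with pytest.raises(SamplerDegeneracyError):
            build_residual_sampler(
                split_residuals(noiseless_sinusoid_series, fit))


class TestSheatherJones:
    # Reference values computed once with R 4.3.3 stats::bw.SJ(x,
    # method="ste") on these exact samples.
    @pytest.mark.parametrize("sample,expected", [
        (lambda: np.random.RandomState(0).standard_normal(500), 0.30915314),
        (lambda: np.random.default_rng(1).standard_normal(200), 0.29785541),
        (lambda: np.random.default_rng(2).exponential(1.0, 300), 0.10453013),
        (lambda: np.random.default_rng(3).standard_normal(80), 0.42469532),
    ])
    def test_matches_independent_plugin_oracle(self, sample, expected):
        bw = sheather_jones_bandwidth(sample())
        assert bw == pytest.approx(expected, rel=0.05)

    def test_kde_integrates_to_one(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(100)
        bw = sheather_jones_bandwidth(x)
        grid = np.linspace(-8, 8, 4001)
        dens = gaussian_kde_density(grid, x, bw)
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-3)


class TestResidualSampler:
    def symmetric_pools(self):
        from sharkcast.projection import ResidualPools
        pos = np.array([0.5, 1.0, 1.5, 2.0])
        return ResidualPools(pos, np.full(4, 1.0), -pos, np.full(4, 1.0))

    def test_mirrored_pools_get_mirrored_weights(self):
        # negative pool is the exact reflection of the positive pool, so
        # the KDE density (hence weight) at -v equals the one at +v
        sampler = build_residual_sampler(self.symmetric_pools())
        np.testing.assert_allclose(sampler.positive.weights,
                                   sampler.negative.weights)
        assert sampler.positive.weights.sum() == pytest.approx(1.0)
        assert sampler.negative.weights.sum() == pytest.approx(1.0)

    def test_two_point_symmetric_pool_weights_equal(self):
        from sharkcast.projection import ResidualPools
        pools = ResidualPools(np.array([1.0, -1.0]) + 2.0, np.full(2, 1.0),
                              np.array([-1.0, -3.0]), np.full(2, 1.0))
        sampler = build_residual_sampler(pools)
        np.testing.assert_allclose(sampler.positive.weights, [0.5, 0.5])

    def test_identical_pool_values_are_degenerate(self):
        from sharkcast.projection import ResidualPools
        pools = ResidualPools(np.full(5, 0.3), np.full(5, 1.0),
                              -np.full(5, 0.3), np.full(5, 1.0))
        with pytest.raises(SamplerDegeneracyError):
            build_residual_sampler(pools)

    def test_magnitude_scale_respects_floor(self):
        from sharkcast.projection import ResidualPools
        fitted = np.linspace(0.2, 1.8, 10)
        values = 0.05 + 0.5 * fitted   # magnitude grows with level
        pools = ResidualPools(values, fitted, -values, fitted)
        sampler = build_residual_sampler(pools, scale_floor=0.1)
        scales = sampler.positive.scale_at(np.array([-100.0, 0.2, 1.8]), 0.1)
        assert scales[0] == 0.1
        assert scales[1] < 1.0 < scales[2]


class TestProjection:
    def make_sampler(self, eps=1e-9):
        from sharkcast.projection import ResidualPools
        pos = np.array([eps, 2 * eps])
        pools = ResidualPools(pos, np.full(2, 1.0), -pos, np.full(2, 1.0))
        return build_residual_sampler(pools)

    def make_fit(self):
        years = np.arange(1900, 2020)
        t = years - 1900.0
        y = 1.0 + 0.4 * np.cos(2 * np.pi / 90 * t)
        s = ScaledRateSeries("NSW", years, y, 1.0)
        return fit_sinusoid(s)

    def test_degenerate_residuals_reproduce_the_median(self):
        fit = self.make_fit()
        ens = project_ensemble(fit, self.make_sampler(),
                               np.arange(2020, 2067), n_iter=50, seed=1)
        expected = np.broadcast_to(fit.predict(ens.years), ens.matrix.shape)
        np.testing.assert_allclose(ens.matrix, expected, atol=1e-6)

    def test_sign_draws_are_a_fair_coin(self):
        fit = self.make_fit()
        from sharkcast.projection import ResidualPools
        pools = ResidualPools(np.array([1.0, 2.0]), np.full(2, 1.0),
                              np.array([-1.0, -2.0]), np.full(2, 1.0))
        sampler = build_residual_sampler(pools)
        years = np.arange(2020, 2030)
        ens = project_ensemble(fit, sampler, years, n_iter=10_000, seed=2)
        median = fit.predict(years)
        frac_pos = np.mean(ens.matrix - median[None, :] > 0)
        se = np.sqrt(0.25 / ens.matrix.size)
        assert abs(frac_pos - 0.5) < 3 * se

    def test_same_seed_gives_identical_bytes(self):
        fit = self.make_fit()
        sampler = self.make_sampler()
        a = project_ensemble(fit, sampler, np.arange(2020, 2067), 100, seed=9)
        b = project_ensemble(fit, sampler, np.arange(2020, 2067), 100, seed=9)
        assert a.matrix.tobytes() == b.matrix.tobytes()

    def test_unseeded_projection_rejected(self):
        with pytest.raises(ConfigError):
            project_ensemble(self.make_fit(), self.make_sampler(),
                             np.arange(2020, 2030), 10, seed=None)

    def test_projections_are_non_negative(self):
        years = np.arange(1900, 2020)
        t = years - 1900.0
        rng = np.random.default_rng(3)
        y = np.maximum(0.0, 0.3 + 0.25 * np.cos(2 * np.pi / 80 * t)
                       + 0.3 * rng.standard_normal(len(t)))
        s = ScaledRateSeries("NSW", years, y, 1.0)
        fit = fit_sinusoid(s)
        sampler = build_residual_sampler(split_residuals(s, fit))
        ens = project_ensemble(fit, sampler, np.arange(2020, 2067),
                               n_iter=2000, seed=4)
        assert np.all(ens.matrix >= 0.0)

    def test_ensemble_median_matches_mixture_oracle(self):
        """Per-year ensemble median converges to the median of the exact
        discrete sign-mixture distribution around the sinusoid."""
        years = np.arange(1900, 2020)
        t = years - 1900.0
        rng = np.random.default_rng(5)
        y = 1.0 + 0.4 * np.cos(2 * np.pi / 90 * t) \
            + 0.15 * rng.standard_normal(len(t))
        s = ScaledRateSeries("NSW", years, y, 1.0)
        fit = fit_sinusoid(s)
        sampler = build_residual_sampler(split_residuals(s, fit))
        proj_years = np.arange(2020, 2040)
        ens = project_ensemble(fit, sampler, proj_years, n_iter=50_000,
                               seed=6)
        med_fit = fit.predict(proj_years)

        # oracle: enumerate the discrete mixture support per year
        for j in [0, 7, 19]:
            support, probs = [], []
            for pool, sign_p in ((sampler.positive, 0.5),
                                 (sampler.negative, 0.5)):
                scale = pool.scale_at(np.array([med_fit[j]]),
                                      sampler.scale_floor)[0]
                support.extend(med_fit[j] + pool.values * scale)
                probs.extend(sign_p * pool.weights)
            support = np.maximum(0.0, np.asarray(support))
            order = np.argsort(support)
            cdf = np.cumsum(np.asarray(probs)[order])
            oracle_median = support[order][np.searchsorted(cdf, 0.5)]
            assert np.median(ens.matrix[:, j]) == pytest.approx(
                oracle_median, rel=0.02, abs=0.02)


class TestBackTransform:
    def make_ensemble(self):
        return ProjectionEnsemble("NSW", np.arange(2020, 2023),
                                  np.full((4, 3), 2e-6), units="scaled",
                                  seed=0)

    def test_counts_are_rate_times_population(self):
        pop = PopulationSeries("NSW", np.arange(2020, 2023),
                               np.full(3, 1_000_000))
        out = back_transform_to_counts(self.make_ensemble(), 1.0, pop)
        np.testing.assert_allclose(out.matrix, 2.0)
        assert out.units == "counts"

    def test_doubling_population_doubles_counts(self):
        years = np.arange(2020, 2023)
        pop1 = PopulationSeries("NSW", years, np.full(3, 1e6))
        pop2 = PopulationSeries("NSW", years, np.full(3, 2e6))
        a = back_transform_to_counts(self.make_ensemble(), 3.0, pop1)
        b = back_transform_to_counts(self.make_ensemble(), 3.0, pop2)
        np.testing.assert_allclose(b.matrix, 2 * a.matrix)

    def test_missing_projection_population_is_alignment_error(self):
        pop = PopulationSeries("NSW", np.arange(2020, 2022), [1e6, 1e6])
        with pytest.raises(AlignmentError):
            back_transform_to_counts(self.make_ensemble(), 1.0, pop)
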