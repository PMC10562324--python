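"""Synthetic landscape generation and uncertainty samplers."""

import numpy as np
import pytest
from scipy import stats

from borealprio.landscape import (DECIDUOUS, LandscapeConfig, ParameterPool,
                                  SiteTypeProbitModel, StructuralErrorModel,
                                  WeatherPool, default_parameter_pool,
                                  default_probit_model,
                                  default_structural_model,
                                  default_weather_pool, generate_landscape,
                                  quantile_match, sample_age,
                                  sample_parameters, sample_site_type,
                                  sample_structural_errors, sample_weather)


def _fields_equal(a, b):
    return all(np.array_equal(getattr(a, n), getattr(b, n))
               for n in ("height_m", "dbh_cm", "volume_m3ha",
                         "dec_volume_m3ha", "age_yr", "species",
                         "site_type", "segment_id", "land_mask"))


class TestGenerateLandscape:
    def test_deterministic_given_seed(self):
        cfg = LandscapeConfig(grid_rows=20, grid_cols=25, n_segments=40)
        assert _fields_equal(generate_landscape(cfg, 3),
                             generate_landscape(cfg, 3))

    def test_every_cell_its_own_segment_when_degenerate(self):
        cfg = LandscapeConfig(grid_rows=8, grid_cols=8, n_segments=64,
                              land_fraction=1.0)
        state = generate_landscape(cfg, 0)
        assert state.n_segments == 64
        assert len(np.unique(state.segment_id)) == 64

    def test_zero_deciduous_share_gives_zero_dec_volume(self):
        cfg = LandscapeConfig(grid_rows=12, grid_cols=12, n_segments=20,
                              dec_share_mean_conifer=0.0,
                              dec_share_mean_deciduous=0.0)
        state = generate_landscape(cfg, 1)
        assert np.all(state.dec_volume_m3ha == 0)

    def test_segments_contiguous_and_coherent(self):
        from scipy import ndimage
        cfg = LandscapeConfig(grid_rows=30, grid_cols=30, n_segments=50,
                              land_fraction=0.85)
        state = generate_landscape(cfg, 5)
        state.assert_segment_coherent()
        for sid in state.segment_ids:
            _, n_comp = ndimage.label(state.segment_id == sid)
            assert n_comp == 1

    def test_physical_bounds_and_dec_le_vol(self):
        state = generate_landscape(LandscapeConfig(grid_rows=25, grid_cols=25,
                                                   n_segments=80), 9)
        land = state.land_mask
        for name in ("height_m", "dbh_cm", "volume_m3ha",
                     "dec_volume_m3ha", "age_yr"):
            assert getattr(state, name)[land].min() >= 0
        assert np.all(state.dec_volume_m3ha <= state.volume_m3ha + 1e-9)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            LandscapeConfig(grid_rows=3, grid_cols=3, n_segments=10)
        with pytest.raises(ValueError):
            LandscapeConfig(cell_size=0.0)


class TestStructuralErrors:
    def test_zero_covariance_is_identity(self, small_bundle):
        model = StructuralErrorModel(
            cov=np.zeros((4, 4)),
            bounds=default_structural_model().bounds)
        out = sample_structural_errors(small_bundle.baseline, model, 7)
        assert _fields_equal(out, small_bundle.baseline)

    def test_non_psd_covariance_rejected(self):
        cov = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError):
            StructuralErrorModel(variables=("height_m", "dbh_cm"), cov=cov,
                                 bounds={"height_m": (0, 45),
                                         "dbh_cm": (0, 90)})

    def test_mean_recovery_within_monte_carlo_error(self, small_bundle):
        """Diagonal covariance: repeated draws recover baseline means (3 SE).

        Bounds are set far away so quantile matching reduces to the
        identity and the untruncated normal oracle applies.
        """
        model = StructuralErrorModel(
            variables=("height_m", "dbh_cm", "volume_m3ha"),
            cov=np.diag([1.5, 2.5, 25.0])**2,
            bounds={"height_m": (-1e6, 1e6), "dbh_cm": (-1e6, 1e6),
                    "volume_m3ha": (-1e6, 1e6)})
        state = small_bundle.baseline
        draws = {v: [] for v in model.variables}
        n = 2000
        for i in range(n):
            out = sample_structural_errors(state, model, seed=i)
            for v in model.variables:
                draws[v].append(out.segment_values(v)[0])
        for j, v in enumerate(model.variables):
            base = state.segment_values(v)[0]
            sd = np.sqrt(model.cov[j, j])
            se = sd / np.sqrt(n)
            assert abs(np.mean(draws[v]) - base) < 3 * se

    def test_error_correlation_survives_matching(self, small_bundle):
        sds = np.array([1.5, 2.5])
        corr = np.array([[1.0, 0.9], [0.9, 1.0]])
        model = StructuralErrorModel(
            variables=("height_m", "dbh_cm"),
            cov=corr * np.outer(sds, sds),
            bounds={"height_m": (0, 45.0), "dbh_cm": (0, 90.0)})
        state = small_bundle.baseline
        hs, ds = [], []
        for i in range(400):
            out = sample_structural_errors(state, model, seed=10_000 + i)
            hs.append(out.segment_values("height_m")
                      - state.segment_values("height_m"))
            ds.append(out.segment_values("dbh_cm")
                      - state.segment_values("dbh_cm"))
        rho = stats.spearmanr(np.concatenate(hs), np.concatenate(ds)).statistic
        assert rho >= 0.8

    def test_segment_coherence_after_sampling(self, small_bundle):
        out = sample_structural_errors(small_bundle.baseline,
                                       default_structural_model(), 3)
        out.assert_segment_coherent()
        assert np.all(out.dec_volume_m3ha <= out.volume_m3ha + 1e-9)


class TestQuantileMatch:
    def test_bound_enforcement(self):
        model = StructuralErrorModel(variables=("height_m",),
                                     cov=np.array([[4.0]]),
                                     bounds={"height_m": (0.0, 45.0)})
        out = quantile_match({"height_m": np.array([-3.2, 50.0, 10.0])},
                             {"height_m": np.array([5.0, 40.0, 10.0])}, model)
        assert np.all(out["height_m"] >= 0.0)
        assert np.all(out["height_m"] <= 45.0)

    def test_rank_preservation(self):
        model = StructuralErrorModel(variables=("height_m",),
                                     cov=np.array([[2.0]]),
                                     bounds={"height_m": (0.0, 45.0)})
        raw = np.array([12.0, 3.0, 7.0])  # ranks (3, 1, 2)
        out = quantile_match({"height_m": raw},
                             {"height_m": np.full(3, 8.0)}, model)["height_m"]
        assert list(np.argsort(np.argsort(out))) == [2, 0, 1]

    def test_empty_input_is_noop(self):
        model = default_structural_model()
        out = quantile_match({"height_m": np.array([])},
                             {"height_m": np.array([])}, model)
        assert out["height_m"].size == 0

    def test_in_bounds_values_barely_move(self):
        """Values at the target quantiles, far from bounds, stay put."""
        model = StructuralErrorModel(variables=("height_m",),
                                     cov=np.array([[1.0]]),
                                     bounds={"height_m": (-1e6, 1e6)})
        raw = np.array([19.0, 20.0, 21.5])
        out = quantile_match({"height_m": raw},
                             {"height_m": np.full(3, 20.0)}, model)["height_m"]
        np.testing.assert_allclose(out, raw, atol=1e-8)


class TestSiteType:
    def test_probabilities_sum_to_one(self, small_bundle):
        model = default_probit_model()
        state = small_bundle.baseline
        probs = model.class_probabilities({
            "volume_m3ha": state.segment_values("volume_m3ha"),
            "height_m": state.segment_values("height_m"),
            "dec_share": np.zeros(state.n_segments)})
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)

    def test_extreme_threshold_collapses_to_one_class(self, small_bundle):
        model = SiteTypeProbitModel(coef={}, standardize={},
                                    thresholds=np.array([-1e9]))
        out = sample_site_type(small_bundle.baseline, model, 4)
        assert np.all(out.site_type[out.land_mask] == 2)

    def test_fifty_fifty_frequencies(self):
        model = SiteTypeProbitModel(coef={}, standardize={},
                                    thresholds=np.array([0.0]))
        cfg = LandscapeConfig(grid_rows=100, grid_cols=100, n_segments=10_000,
                              land_fraction=1.0)
        state = generate_landscape(cfg, 2)
        out = sample_site_type(state, model, 8)
        freq = np.mean(out.segment_values("site_type") == 1)
        assert abs(freq - 0.5) < 0.02

    def test_unordered_thresholds_rejected(self):
        with pytest.raises(ValueError):
            SiteTypeProbitModel(coef={}, standardize={},
                                thresholds=np.array([1.0, 0.5]))


class TestAgeSampler:
    def test_zero_cv_is_identity(self, small_bundle):
        out = sample_age(small_bundle.baseline, cv=0.0, seed=1)
        np.testing.assert_array_equal(out.age_yr,
                                      small_bundle.baseline.age_yr)

    def test_sd_recovery(self):
        cfg = LandscapeConfig(grid_rows=100, grid_cols=100, n_segments=10_000,
                              land_fraction=1.0)
        state = generate_landscape(cfg, 3)
        state = state.replace_segments(age_yr=np.full(10_000, 100.0))
        out = sample_age(state, cv=0.10, seed=5)
        sd = out.segment_values("age_yr").std()
        assert abs(sd - 10.0) < 0.5

    def test_zero_age_stays_zero_and_nonnegative(self, small_bundle):
        state = small_bundle.baseline.replace_segments(
            age_yr=np.zeros(small_bundle.baseline.n_segments))
        out = sample_age(state, cv=0.5, seed=2)
        assert np.all(out.age_yr == 0.0)


class TestParameterPool:
    def test_single_vector_pool(self):
        pool = ParameterPool(names=("a", "b"), vectors=[[2.0, 3.0]],
                             crown_base_index=1, crown_base_sd=0.0)
        vec = sample_parameters(pool, 0)
        np.testing.assert_allclose(vec, [2.0, 3.0])

    def test_bootstrap_frequencies_uniform(self):
        pool = ParameterPool(names=("a",),
                             vectors=[[1.0], [2.0], [3.0], [4.0]],
                             crown_base_index=0, crown_base_sd=0.0)
        draws = np.array([sample_parameters(pool, s)[0]
                          for s in range(10_000)])
        for v in (1.0, 2.0, 3.0, 4.0):
            assert abs(np.mean(draws == v) - 0.25) < 0.015

    def test_whole_vector_sampling_preserves_membership(self):
        pool = default_parameter_pool(size=20)
        for s in range(50):
            vec = sample_parameters(pool, s)
            # all non-crown-base entries must match one pool member exactly
            other = [i for i in range(len(pool.names))
                     if i != pool.crown_base_index]
            match = (pool.vectors[:, other] == vec[other]).all(axis=1)
            assert match.sum() >= 1

    def test_crown_base_multiplier_applied(self):
        pool = ParameterPool(names=("a", "cb"), vectors=[[1.0, 2.0]],
                             crown_base_index=1, crown_base_sd=0.1)
        draws = np.array([sample_parameters(pool, s)[1] for s in range(4000)])
        assert abs(draws.mean() - 2.0) < 3 * 0.2 / np.sqrt(4000)
        assert abs(draws.std() - 0.2) < 0.02

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            ParameterPool(names=("a",), vectors=np.empty((0, 1)))


class TestWeather:
    def test_constant_pool_gives_constant_series(self):
        series = sample_weather(WeatherPool([1.0]), 30, 5)
        assert np.all(series == 1.0)

    def test_mean_recovery(self):
        pool = default_weather_pool()
        series = sample_weather(pool, 10_000, 3)
        se = pool.modifiers.std() / np.sqrt(10_000)
        assert abs(series.mean() - pool.modifiers.mean()) < 3 * se

    def test_deterministic_given_seed(self):
        pool = default_weather_pool()
        np.testing.assert_array_equal(sample_weather(pool, 35, 9),
                                      sample_weather(pool, 35, 9))

    def test_default_pool_has_46_years(self):
        assert default_weather_pool().size == 46
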