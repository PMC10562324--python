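"""Growth engine: height curve, carbon mass balance, periods, sink rule."""

import numpy as np
import pytest

from borealprio.growth import (CarbonState, GrowthParams, PeriodSpec,
                               carbon_step, chapman_richards, default_periods,
                               grow, init_carbon, init_soil_steady,
                               period_average, run_simulation, simulate_carbon,
                               sink_layer, tree_carbon)
from borealprio.landscape import ForestState, LandscapeConfig, generate_landscape


def _single_cell_state(height=10.0, volume=100.0, dec=10.0, age=40.0,
                       species=0, site=3):
    one = np.ones((1, 1))
    return ForestState(
        height_m=one * height, dbh_cm=one * 15.0, volume_m3ha=one * volume,
        dec_volume_m3ha=one * dec, age_yr=one * age,
        species=np.full((1, 1), species, dtype=np.int8),
        site_type=np.full((1, 1), site, dtype=np.int8),
        segment_id=np.zeros((1, 1), dtype=np.int32),
        land_mask=np.ones((1, 1), dtype=bool))


class TestGrow:
    def test_zero_years_returns_initial_state(self):
        state = _single_cell_state()
        traj = grow(state, GrowthParams(), [], 0)
        assert len(traj) == 1
        np.testing.assert_array_equal(traj[0].height_m, state.height_m)

    def test_matches_closed_form_chapman_richards(self):
        """Unit weather: engine height equals the closed-form curve."""
        params = GrowthParams()
        sp, st, age0 = 1, 3, 20.0
        hmax = params.hmax(np.array([sp]), np.array([st]))[0]
        k = params.k_by_species[sp]
        h0 = chapman_richards(age0, hmax, k, params.shape_m)
        state = _single_cell_state(height=h0, species=sp, site=st, age=age0)
        traj = grow(state, params, np.ones(60), 60)
        for t in (1, 10, 30, 60):
            expected = chapman_richards(age0 + t, hmax, k, params.shape_m)
            assert abs(traj[t].height_m[0, 0] - expected) < 1e-6

    def test_long_run_approaches_asymptote(self):
        params = GrowthParams()
        state = _single_cell_state(height=2.0, species=0, site=3, age=5.0)
        hmax = params.hmax(np.array([0]), np.array([3]))[0]
        traj = grow(state, params, np.ones(500), 500)
        assert traj[-1].height_m[0, 0] > 0.99 * hmax

    def test_monotone_nondecreasing_under_weather(self):
        cfg = LandscapeConfig(grid_rows=15, grid_cols=15, n_segments=30)
        state = generate_landscape(cfg, 4)
        rng = np.random.default_rng(0)
        weather = rng.uniform(0.5, 1.5, 35)
        traj = grow(state, GrowthParams(), weather, 35)
        for a, b in zip(traj[:-1], traj[1:]):
            for name in ("height_m", "dbh_cm", "volume_m3ha", "age_yr"):
                assert np.all(getattr(b, name) >= getattr(a, name) - 1e-9)

    def test_mismatched_weather_length_rejected(self):
        with pytest.raises(ValueError):
            grow(_single_cell_state(), GrowthParams(), np.ones(3), 5)

    def test_initial_offsets_persist(self):
        """A perturbed initial volume stays perturbed along the trajectory."""
        params = GrowthParams()
        a = _single_cell_state(volume=100.0)
        b = _single_cell_state(volume=120.0)
        ta = grow(a, params, np.ones(10), 10)
        tb = grow(b, params, np.ones(10), 10)
        ratio = tb[10].volume_m3ha[0, 0] / ta[10].volume_m3ha[0, 0]
        assert ratio == pytest.approx(1.2, rel=1e-9)


class TestCarbon:
    def test_zero_volume_zero_tree_carbon(self):
        state = _single_cell_state(height=0.0, volume=0.0, dec=0.0, age=0.0)
        assert tree_carbon(state, GrowthParams())[0, 0] == 0.0

    def test_nep_is_exact_mass_balance(self):
        cfg = LandscapeConfig(grid_rows=10, grid_cols=10, n_segments=25)
        state = generate_landscape(cfg, 7)
        params = GrowthParams()
        traj = grow(state, params, np.ones(20), 20)
        carbons = simulate_carbon(traj, params)
        for t in range(1, 21):
            delta = carbons[t].total() - carbons[t - 1].total()
            np.testing.assert_allclose(carbons[t].nep, delta * 0.1,
                                       rtol=1e-9, atol=1e-9)

    def test_soil_converges_to_litter_over_decay(self):
        """Constant tree carbon: soil tends to litter_coef*treeC/decay."""
        params = GrowthParams()
        state = _single_cell_state()
        carbon = CarbonState(tree_c=tree_carbon(state, params),
                             soil_c=np.zeros((1, 1)), gv_c=np.zeros((1, 1)),
                             nep=np.zeros((1, 1)))
        for _ in range(800):
            carbon = carbon_step(state, state, carbon, params)
        expected = (params.litter_coef * carbon.tree_c[0, 0]
                    / params.soil_decay)
        assert carbon.soil_c[0, 0] == pytest.approx(expected, rel=1e-6)

    def test_steady_state_init(self):
        params = GrowthParams()
        zero = _single_cell_state(height=0.0, volume=0.0, dec=0.0, age=0.0)
        assert init_soil_steady(zero, params)[0, 0] == 0.0
        state = _single_cell_state()
        carbon0 = init_carbon(state, params)
        # one growth-free step from equilibrium changes nothing
        carbon1 = carbon_step(state, state, carbon0, params)
        np.testing.assert_allclose(carbon1.soil_c, carbon0.soil_c, rtol=1e-9)
        np.testing.assert_allclose(carbon1.nep, 0.0, atol=1e-9)

    def test_soil_init_linear_in_litter_coefficient(self):
        state = _single_cell_state()
        p1 = GrowthParams()
        p2 = GrowthParams(litter_coef=2 * p1.litter_coef)
        np.testing.assert_allclose(init_soil_steady(state, p2),
                                   2 * init_soil_steady(state, p1))


class TestPeriods:
    def test_invalid_periods_rejected(self):
        with pytest.raises(ValueError):
            PeriodSpec(periods=(("T1", 2017, 2025), ("T2", 2027, 2033)))

    def test_one_year_period_returns_that_year(self):
        state = _single_cell_state()
        traj = grow(state, GrowthParams(), np.ones(5), 5)
        spec = PeriodSpec(periods=(("P", 2018, 2018),))
        out = period_average(traj, spec, start_year=2015)
        np.testing.assert_array_equal(out["P"][0].height_m,
                                      traj[3].height_m)

    def test_linear_ramp_averages_to_midpoint(self):
        state = _single_cell_state()
        traj = [state.replace_segments(height_m=np.array([float(v)]))
                for v in range(1, 12)]
        spec = PeriodSpec(periods=(("T1", 2017, 2025),))
        out = period_average(traj, spec, start_year=2015)
        # years 2017..2025 -> indices 2..10 -> heights 3..11, mean 7
        assert out["T1"][0].height_m[0, 0] == pytest.approx(7.0)

    def test_missing_years_rejected(self):
        state = _single_cell_state()
        traj = grow(state, GrowthParams(), np.ones(3), 3)
        with pytest.raises(ValueError):
            period_average(traj, default_periods(), start_year=2015)


class TestSinkRule:
    def test_sources_zeroed_ties_included(self):
        mean_nep = np.array([[-2.0, 0.0, 3.0]])
        period_nep = {"T1": np.array([[5.0, 5.0, 5.0]])}
        out = sink_layer(period_nep, mean_nep)
        np.testing.assert_array_equal(out["T1"], [[0.0, 0.0, 5.0]])

    def test_all_positive_nep_passes_through(self):
        nep = np.array([[1.0, 2.0], [3.0, 4.0]])
        out = sink_layer({"T1": nep}, np.full((2, 2), 1.0))
        np.testing.assert_array_equal(out["T1"], nep)

    def test_regional_flux_unaffected_by_zeroing(self):
        """The sink rule masks a copy; the NEP layer itself is untouched."""
        nep = np.array([[-1.0, 2.0]])
        out = sink_layer({"T1": nep}, nep)
        assert nep[0, 0] == -1.0
        np.testing.assert_array_equal(out["T1"], [[0.0, 2.0]])


def test_growth_evens_out_stand_differences(small_bundle):
    """Within (species, site type) groups, height variance shrinks T1->T3."""
    sim = run_simulation(small_bundle.baseline, small_bundle.growth_params,
                         np.ones(35), default_periods())
    t1, t3 = sim.period_states["T1"], sim.period_states["T3"]
    sp = t1.segment_values("species")
    st = t1.segment_values("site_type")
    shrunk, total = 0, 0
    for s in np.unique(sp):
        for c in np.unique(st):
            grp = (sp == s) & (st == c)
            if grp.sum() < 5:
                continue
            total += 1
            if (t3.segment_values("height_m")[grp].var()
                    < t1.segment_values("height_m")[grp].var()):
                shrunk += 1
    assert total > 0 and shrunk == total
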