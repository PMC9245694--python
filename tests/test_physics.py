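"""Two-box oxygen physics: geometry, mixing, conservation, saturation."""

import numpy as np
import pandas as pd
import pytest

from lakehybrid.errors import ForcingError
from lakehybrid.physics import (
    BoxState,
    ForcingSeries,
    Hypsometry,
    PhysicsParams,
    SurrogatePhysicsParams,
    box_volumes,
    do_saturation,
    make_box_state,
    read_forcing,
    repartition,
    surface_do_update,
    surrogate_physics,
    winter_mix_step,
    write_forcing,
)
from lakehybrid.synthetic import synthetic_hypsometry

NO_SOURCES = PhysicsParams(k_gas=0.0, river_underflow=False, deep_consumption=0.0)


def cylinder(z_max=100.0, area=1e6):
    return Hypsometry([0.0, z_max], [area, area])


def cone(z_max=100.0, area=1e6):
    # area tapering linearly to (almost) zero at the bottom
    return Hypsometry(np.linspace(0, z_max, 201),
                      np.maximum(area * (1 - np.linspace(0, 1, 201)), 1e-3))


class TestGeometry:
    def test_cylinder_split_at_half_depth(self):
        v_up, v_low = box_volumes(cylinder(), 50.0)
        assert v_up == pytest.approx(v_low)
        assert v_up + v_low == pytest.approx(1e6 * 100.0)

    def test_boundary_at_bottom_empties_lower_box(self):
        v_up, v_low = box_volumes(cylinder(), 100.0)
        assert v_low == pytest.approx(0.0, abs=1e-6)

    def test_cone_closed_form(self):
        """Linear-area basin: volume below half depth is 1/8 of a matching
        cone's total, i.e. V_low/V_total = 1/4 for the area-linear basin."""
        h = cone()
        v_up, v_low = box_volumes(h, 50.0)
        # area linear in z => V(z..zmax) = A0 (zmax - z)^2 / (2 zmax)
        expect_low = 1e6 * 50.0**2 / (2 * 100.0)
        assert v_low == pytest.approx(expect_low, rel=1e-4)
        assert v_up + v_low == pytest.approx(h.total_volume)

    def test_depth_outside_range_rejected(self):
        with pytest.raises(ForcingError):
            box_volumes(cylinder(), 0.0)
        with pytest.raises(ForcingError):
            box_volumes(cylinder(), 101.0)

    @pytest.mark.parametrize("depth", [1.0, 17.5, 150.0, 240.0, 310.0])
    def test_volumes_always_sum_to_total(self, depth):
        h = synthetic_hypsometry()
        v_up, v_low = box_volumes(h, depth)
        assert v_up + v_low == pytest.approx(h.total_volume, rel=1e-9)


class TestSaturation:
    def test_monotone_decreasing_in_temperature(self):
        t = np.linspace(0, 30, 61)
        sat = do_saturation(t)
        assert np.all(np.diff(sat) < 0)

    def test_reference_values(self):
        # standard freshwater values at 1 atm: ~14.6 at 0 C, ~9.1 at 20 C
        assert do_saturation(0.0) == pytest.approx(14.6, abs=0.2)
        assert do_saturation(20.0) == pytest.approx(9.1, abs=0.15)

    def test_pressure_scaling(self):
        assert do_saturation(10.0, 0.9) == pytest.approx(
            0.9 * do_saturation(10.0, 1.0)
        )


class TestMixing:
    def test_full_mixing_homogenizes_and_conserves(self):
        h = synthetic_hypsometry()
        state = make_box_state(h, 240.0, do_up=10.0, do_low=4.0)
        mass0 = state.total_mass
        out = winter_mix_step(state, h, h.z_max, t_surf=6.0, params=NO_SOURCES)
        assert out.do_up == pytest.approx(out.do_low, rel=1e-12)
        assert out.do_up == pytest.approx(state.volume_mean_do, rel=1e-12)
        assert out.total_mass == pytest.approx(mass0, rel=1e-9)

    def test_shallow_mixing_leaves_deep_box_untouched(self):
        h = synthetic_hypsometry()
        state = make_box_state(h, 240.0, do_up=10.0, do_low=4.0)
        out = winter_mix_step(state, h, 150.0, t_surf=6.0, params=NO_SOURCES)
        assert out.do_low == pytest.approx(4.0)

    def test_mass_conserved_over_many_steps(self):
        """Pure mixing (all sources/sinks off): drift < 1e-9 over 1e4 steps."""
        h = synthetic_hypsometry()
        state = make_box_state(h, 240.0, do_up=10.0, do_low=4.0)
        mass0 = state.total_mass
        rng = np.random.default_rng(0)
        depths = rng.uniform(20.0, 310.0, 10_000)
        for d in depths:
            state = winter_mix_step(state, h, d, t_surf=6.0, params=NO_SOURCES)
        assert abs(state.total_mass - mass0) / mass0 < 1e-9

    def test_repartition_conserves_mass(self):
        h = synthetic_hypsometry()
        state = make_box_state(h, 30.0, do_up=11.0, do_low=5.0)
        mass0 = state.total_mass
        for depth in (120.0, 17.5, 240.0, 60.0):
            state = repartition(state, h, depth)
            assert state.total_mass == pytest.approx(mass0, rel=1e-12)
            assert state.v_up + state.v_low == pytest.approx(
                h.total_volume, rel=1e-9
            )

    def test_gas_exchange_relaxes_to_saturation(self):
        """Undersaturated surface water rises monotonically and asymptotes."""
        h = cylinder()
        params = PhysicsParams(k_gas=1.0, river_underflow=False,
                               deep_consumption=0.0, pressure_atm=1.0)
        sat = float(do_saturation(6.0))
        state = make_box_state(h, 50.0, do_up=6.0, do_low=6.0)
        kappa = params.k_gas * h.surface_area / state.v_up
        vals = []
        for i in range(50):
            state = winter_mix_step(state, h, 10.0, t_surf=6.0, params=params)
            vals.append(state.do_up)
            # closed form: sat + (C0 - sat) exp(-kappa t)
            expect = sat + (6.0 - sat) * np.exp(-kappa * (i + 1))
            assert state.do_up == pytest.approx(expect, rel=1e-9)
        assert np.all(np.diff(vals) > -1e-12)
        assert vals[-1] < sat + 1e-6


class TestSurfaceUpdate:
    def test_saturation_with_zero_chl_is_fixed_point(self):
        h = cylinder()
        params = PhysicsParams(river_underflow=False, deep_consumption=0.0)
        sat = float(do_saturation(15.0, params.pressure_atm))
        state = make_box_state(h, 50.0, do_up=sat, do_low=5.0)
        out = surface_do_update(state, h, chl=0.0, t_surf=15.0, params=params)
        assert out.do_up == pytest.approx(sat, rel=1e-12)

    def test_production_linear_in_chl(self):
        h = cylinder()
        params = PhysicsParams(river_underflow=False, deep_consumption=0.0)
        sat = float(do_saturation(15.0, params.pressure_atm))
        state = make_box_state(h, 50.0, do_up=sat, do_low=5.0)
        d1 = surface_do_update(state, h, 5.0, 15.0, params=params).do_up - sat
        d2 = surface_do_update(state, h, 10.0, 15.0, params=params).do_up - sat
        assert d2 == pytest.approx(2 * d1, rel=1e-9)

    def test_matches_closed_form_over_180_days(self):
        """Default linear plug-in vs the analytic solution of
        dC/dt = kappa (Csat - C) + p chl, constant forcing."""
        h = cylinder()
        params = PhysicsParams(river_underflow=False, deep_consumption=0.0)
        state = make_box_state(h, 50.0, do_up=7.0, do_low=5.0)
        sat = float(do_saturation(18.0, params.pressure_atm))
        kappa = params.k_gas * h.surface_area / state.v_up
        prod = params.chl_production * 6.0
        c_eq = sat + prod / kappa
        c0 = 7.0
        for day in range(1, 181):
            state = surface_do_update(state, h, 6.0, 18.0, params=params)
            expect = c_eq + (c0 - c_eq) * np.exp(-kappa * day)
            assert state.do_up == pytest.approx(expect, abs=1e-6)

    def test_custom_production_plugin(self):
        h = cylinder()
        params = PhysicsParams(
            river_underflow=False, deep_consumption=0.0,
            surface_production_fn=lambda chl, t: 0.5,
        )
        state = make_box_state(h, 50.0, do_up=8.0, do_low=5.0)
        out = surface_do_update(state, h, chl=123.0, t_surf=15.0, params=params)
        assert out.do_up > 8.0


def daily_t_atm(years=5, start="2000-01-01"):
    idx = pd.date_range(start, periods=365 * years, freq="D")
    doy = idx.dayofyear.to_numpy()
    return pd.Series(11.0 + 9.0 * np.cos(2 * np.pi * (doy - 196) / 365.25), index=idx)


class TestSurrogatePhysics:
    def test_same_seed_identical(self):
        t = daily_t_atm()
        a = surrogate_physics(t, seed=5)
        b = surrogate_physics(t, seed=5)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_zero_amplitude_constant_thermocline(self):
        t = daily_t_atm()
        p = SurrogatePhysicsParams(seasonal_amplitude=0.0)
        f = surrogate_physics(t, p, seed=0)
        assert f.data["thermocline_depth_m"].std() == pytest.approx(0.0, abs=1e-9)

    def test_warming_reduces_deep_mixing_frequency(self):
        """Same seed stream, +3 degC offset: strictly fewer deep winters."""
        t = daily_t_atm(years=60)
        f0 = surrogate_physics(t, seed=3)
        f3 = surrogate_physics(t + 3.0, seed=3)
        deep0 = (f0.winter_max_mixing_depth() >= 250).sum()
        deep3 = (f3.winter_max_mixing_depth() >= 250).sum()
        assert deep3 < deep0

    def test_winter_max_equals_drawn_depth_regime(self):
        t = daily_t_atm(years=30)
        f = surrogate_physics(t, seed=1)
        wd = f.winter_max_mixing_depth()
        # every winter peaks either in the shallow or the deep regime
        full = wd[(wd.index > wd.index.min()) & (wd.index < wd.index.max())]
        assert ((full.between(55, 185)) | (full.between(245, 310))).all()


class TestForcingIO:
    def test_round_trip(self, tmp_path):
        f = surrogate_physics(daily_t_atm(2), seed=0)
        path = tmp_path / "forcing.csv"
        write_forcing(f, path)
        back = read_forcing(path)
        pd.testing.assert_frame_equal(
            back.data, f.data, check_freq=False, check_names=False, atol=1e-9
        )

    def test_gap_day_errors_or_fills(self, tmp_path):
        f = surrogate_physics(daily_t_atm(1), seed=0)
        df = f.data.drop(f.data.index[10])
        path = tmp_path / "gappy.csv"
        out = df.copy()
        out.index.name = "date"
        out.to_csv(path)
        with pytest.raises(ForcingError, match="missing calendar days"):
            read_forcing(path)
        filled = read_forcing(path, on_gap="ffill")
        assert len(filled.data) == len(f.data)

    def test_dialect_renames_columns(self, tmp_path):
        path = tmp_path / "ext.csv"
        path.write_text(
            "time,thermo,ts,mix,q,tr,ta\n"
            "2000-01-01,30,5,30,200,6,2\n"
            "2000-01-02,31,5,31,200,6,2\n"
            "2000-01-03,32,5,32,200,6,2\n"
        )
        dialect = {
            "time": "date", "thermo": "thermocline_depth_m", "ts": "T_surf_C",
            "mix": "mixing_depth_m", "q": "Q_m3s", "tr": "T_river_C",
            "ta": "T_atm_C",
        }
        f = read_forcing(path, dialect=dialect)
        assert list(f.data.columns) == list(dialect.values())[1:]
        assert f.data["thermocline_depth_m"].iloc[-1] == 32
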