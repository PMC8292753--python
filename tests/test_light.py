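"""Illuminance transform, windowed trapezoid AUC, and RSE."""
import numpy as np
import pytest

from circalux.errors import InsufficientDataError, UndefinedStatisticError
from circalux.light import (
    LOD_LUX, WINDOWS, WINDOWS_BY_NAME, ExposureWindow, auc_trapezoid,
    log_illuminance, relative_standard_error, window_exposures,
)
from circalux.solar import solar_times


def riemann_oracle(values, t_start, t_end, cadence=5.0, step_s=1.0):
    """Fine-grid Riemann sum of the linear interpolant on [t_start, t_end].

    Independent of the implementation under test: literal 1-second
    rectangles on the piecewise-linear curve through the slot values, with
    the closed-cycle 1440' point appended.
    """
    t = np.arange(len(values) + 1) * cadence
    v = np.append(values, values[0])
    grid = np.arange(t_start, t_end, step_s / 60.0)
    interp = np.interp(grid + step_s / 120.0, t, v)  # midpoint rule
    return float(interp.sum() * step_s / 60.0)


class TestLogIlluminance:
    def test_floor_and_log(self):
        assert log_illuminance(10.0) == 1.0
        assert log_illuminance(0.0) == 0.0
        assert log_illuminance(9.99) == 0.0
        assert log_illuminance(100000.0) == 5.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            log_illuminance(-1.0)

    def test_vectorized_with_nan_passthrough(self):
        out = log_illuminance(np.array([0.0, 10.0, np.nan, 1000.0]))
        assert out[0] == 0.0 and out[1] == 1.0 and out[3] == 3.0
        assert np.isnan(out[2])


class TestAucTrapezoid:
    def test_constant_rectangle(self, day_factory):
        day = day_factory(np.ones(288))
        w = ExposureWindow("w", 18.0, 19.0)  # 60 min at 1 log10lux
        assert auc_trapezoid(day, w) == pytest.approx(60.0)

    def test_linear_ramp_exact(self, day_factory):
        vals = np.zeros(288)
        vals[12:25] = np.linspace(0, 2, 13)  # 18:00-19:00 ramp 0 -> 2
        day = day_factory(vals)
        assert auc_trapezoid(day, ExposureWindow("w", 18.0, 19.0)) == pytest.approx(60.0)

    def test_full_day_constant_scale_check(self, day_factory):
        day = day_factory(np.ones(288))
        assert auc_trapezoid(day, WINDOWS_BY_NAME["total_day"]) == pytest.approx(1440.0)

    def test_matches_riemann_oracle_on_random_days(self, day_factory):
        rng = np.random.default_rng(42)
        for _ in range(100):
            vals = rng.uniform(0, 5, 288)
            day = day_factory(vals)
            for name, a, b in [
                ("total", 17.0, 17.0), ("night", 21.0, 2.0), ("am", 4.0, 12.0),
            ]:
                got = auc_trapezoid(day, ExposureWindow(name, a, b))
                t0 = ((a - 17) % 24) * 60
                t1 = ((b - 17) % 24) * 60
                if t1 <= t0:
                    want = riemann_oracle(vals, t0, 1440.0) + riemann_oracle(vals, 0.0, t1)
                else:
                    want = riemann_oracle(vals, t0, t1)
                assert got == pytest.approx(want, rel=1e-6)

    def test_additivity_on_complete_data(self, day_factory):
        rng = np.random.default_rng(3)
        day = day_factory(rng.uniform(0, 4, 288))
        ab = auc_trapezoid(day, ExposureWindow("ab", 18.0, 22.0))
        bc = auc_trapezoid(day, ExposureWindow("bc", 22.0, 3.0))
        ac = auc_trapezoid(day, ExposureWindow("ac", 18.0, 3.0))
        assert ab + bc == pytest.approx(ac, rel=1e-9)

    def test_monotone_in_slot_values(self, day_factory):
        rng = np.random.default_rng(4)
        vals = rng.uniform(0, 4, 288)
        day = day_factory(vals)
        w = ExposureWindow("w", 21.0, 2.0)
        base = auc_trapezoid(day, w)
        vals2 = vals.copy()
        vals2[60] += 1.0  # 22:00, inside the window
        assert auc_trapezoid(day_factory(vals2), w) > base

    def test_short_gap_bridged_long_gap_missing(self, day_factory):
        vals = np.ones(288)
        vals[50:56] = np.nan  # 30-min interior run: bridged
        w = ExposureWindow("w", 20.0, 23.0)
        assert auc_trapezoid(day_factory(vals), w) == pytest.approx(180.0)
        vals[50:58] = np.nan  # 40-min run: window missing
        assert np.isnan(auc_trapezoid(day_factory(vals), w))

    def test_fully_missing_window_is_missing_not_zero(self, day_factory):
        vals = np.ones(288)
        vals[48:109] = np.nan  # 21:00-02:00 entirely
        assert np.isnan(
            auc_trapezoid(day_factory(vals), WINDOWS_BY_NAME["std_night_2100_0200"])
        )


class TestWindowExposures:
    def test_below_lod_day_has_zero_everywhere(self, day_factory):
        day = day_factory(log_illuminance(np.full(288, 5.0)))
        sol = solar_times("2018-12-18", 40.85, -73.93, -5)
        for name, auc in window_exposures(day, sol).items():
            assert auc == pytest.approx(0.0), name

    def test_outdoor_style_day_dark_night(self, day_factory):
        sol = solar_times("2018-06-18", 40.85, -73.93, -4)
        vals = np.zeros(288)
        # light only between sunrise and sunset (all log10lux = 3)
        for i in range(288):
            clock = (17.0 + i * 5 / 60.0) % 24.0
            if sol.sunrise_hours < clock < sol.sunset_hours:
                vals[i] = 3.0
        day = day_factory(vals)
        out = window_exposures(day, sol)
        assert out["night_sunset_0400"] == pytest.approx(0.0, abs=20.0)
        assert out["total_day"] > 1000.0

    def test_hand_computed_toy_day(self, day_factory):
        # 1 log10lux 18:00-20:00, 3 log10lux 22:00-23:00, else 0
        vals = np.zeros(288)
        vals[12:37] = 1.0
        vals[60:73] = 3.0
        day = day_factory(vals)
        # evening window 17:00-23:00, worked by hand:
        # 17:55-18:00 ramp 0->1: 2.5;   18:00-20:00 at 1: 120
        # 20:00-20:05 ramp 1->0: 2.5;   21:55-22:00 ramp 0->3: 7.5
        # 22:00-23:00 at 3: 3*60 = 180 (window ends exactly at 23:00)
        want = 2.5 + 120.0 + 2.5 + 7.5 + 180.0
        got = auc_trapezoid(day, WINDOWS_BY_NAME["fixed_evening_1700_2300"])
        assert got == pytest.approx(want)

    def test_total_day_bounds_every_subwindow(self, day_factory):
        rng = np.random.default_rng(9)
        day = day_factory(rng.uniform(0, 5, 288))
        sol = solar_times("2018-09-19", 40.85, -73.93, -4)
        out = window_exposures(day, sol)
        for name, auc in out.items():
            assert auc <= out["total_day"] + 1e-9, name


class TestRelativeStandardError:
    def test_identical_values_zero(self):
        assert relative_standard_error([5, 5, 5, 5]) == 0.0

    def test_direct_arithmetic(self):
        # sd([1,2,3]) = 1, se = 1/sqrt(3), mean 2 -> 28.8675%
        assert relative_standard_error([1, 2, 3]) == pytest.approx(28.8675, abs=1e-4)

    def test_single_value_insufficient(self):
        with pytest.raises(InsufficientDataError):
            relative_standard_error([3.0])

    def test_zero_mean_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            relative_standard_error([-1.0, 1.0])
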