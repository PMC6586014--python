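"""Vapor pressure deficit, PET, daily aggregation, gaps, lapse rates."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from larix import microclimate as mc


class TestVpd:
    @pytest.mark.parametrize("t, rh, expected", [
        (20.0, 100.0, 0.0),              # saturation
        (20.0, 50.0, 1.16914),           # hand evaluation of the Magnus form
        (0.0, 0.0, 0.6108),              # e_s(0), exponent vanishes
    ])
    def test_known_values(self, t, rh, expected):
        assert mc.compute_vpd(t, rh) == pytest.approx(expected, abs=1e-4)

    def test_rh_domain_error(self):
        with pytest.raises(ValueError):
            mc.compute_vpd(10.0, 104.0)
        with pytest.raises(ValueError):
            mc.compute_vpd(10.0, -1.0)

    @given(t=st.floats(-30, 45), rh=st.floats(0, 100))
    @settings(max_examples=60, deadline=None)
    def test_zero_iff_saturated_and_nonnegative(self, t, rh):
        v = float(mc.compute_vpd(t, rh))
        assert v >= 0.0
        assert (v == 0.0) == (rh == 100.0)

    def test_strictly_increasing_in_temperature(self):
        t = np.linspace(-10, 35, 50)
        v = mc.compute_vpd(t, 60.0)
        assert np.all(np.diff(v) > 0)


class TestPetFao56:
    @staticmethod
    def _oracle(tmean, tmin, tmax, rh, rs, u2, lat, elev, doy):
        # independent re-coding of the daily reference-ET equation, written
        # from the published formulation rather than the module's code path
        from math import acos, cos, exp, pi, sin, sqrt, tan

        def es(t):
            return 0.6108 * exp(17.27 * t / (t + 237.3))

        e_s = (es(tmax) + es(tmin)) / 2
        e_a = e_s * rh / 100
        slope = 4098 * es(tmean) / (tmean + 237.3) ** 2
        press = 101.3 * ((293 - 0.0065 * elev) / 293) ** 5.26
        gamma = 0.000665 * press
        phi = lat * pi / 180
        dr = 1 + 0.033 * cos(2 * pi * doy / 365)
        dec = 0.409 * sin(2 * pi * doy / 365 - 1.39)
        ws = acos(max(-1, min(1, -tan(phi) * tan(dec))))
        ra = 24 * 60 / pi * 0.082 * dr * (
            ws * sin(phi) * sin(dec) + cos(phi) * cos(dec) * sin(ws))
        rso = (0.75 + 2e-5 * elev) * ra
        rns = 0.77 * rs
        rnl = 4.903e-9 * ((tmax + 273.16) ** 4 + (tmin + 273.16) ** 4) / 2 \
            * (0.34 - 0.14 * sqrt(e_a)) \
            * (1.35 * min(1.0, rs / rso) - 0.35)
        rn = rns - rnl
        num = 0.408 * slope * rn + gamma * 900 / (tmean + 273) * u2 * (e_s - e_a)
        return max(0.0, num / (slope + gamma * (1 + 0.34 * u2)))

    def test_matches_independent_recoding(self):
        rng = np.random.default_rng(4)
        dates = pd.date_range("2013-04-01", periods=40, freq="7D")
        tmin = rng.uniform(-5, 15, 40)
        tmax = tmin + rng.uniform(3, 15, 40)
        daily = pd.DataFrame({
            "t_mean": (tmin + tmax) / 2, "t_min": tmin, "t_max": tmax,
            "rh_mean": rng.uniform(30, 95, 40),
            "rs_sum": rng.uniform(2, 28, 40),
            "wind_mean": rng.uniform(0.3, 6, 40),
        }, index=dates)
        pet = mc.compute_pet_fao56(daily, 46.7, 1160.0)
        for i, (d, row) in enumerate(daily.iterrows()):
            want = self._oracle(row.t_mean, row.t_min, row.t_max, row.rh_mean,
                                row.rs_sum, row.wind_mean, 46.7, 1160.0,
                                d.dayofyear)
            assert pet.iloc[i] == pytest.approx(want, abs=0.01)

    def test_reference_day_magnitude(self):
        # mid-latitude summer day with measured radiation: the published
        # worked value for these conditions is about 3.9 mm
        daily = pd.DataFrame({
            "t_mean": [16.9], "t_min": [12.3], "t_max": [21.5],
            "rh_mean": [73.5], "rs_sum": [22.07], "wind_mean": [2.078],
        }, index=pd.DatetimeIndex(["2001-07-06"]))
        pet = mc.compute_pet_fao56(daily, 50.8, 100.0).iloc[0]
        assert pet == pytest.approx(3.9, abs=0.15)

    def test_zero_when_numerator_vanishes(self):
        # saturated winter air (e_s = e_a), no wind, and net radiation at or
        # below zero: the numerator is non-positive and PET clips to 0
        daily = pd.DataFrame({
            "t_mean": [15.0], "t_min": [15.0], "t_max": [15.0],
            "rh_mean": [100.0], "rs_sum": [6.0], "wind_mean": [0.0],
        }, index=pd.DatetimeIndex(["2013-01-15"]))
        assert mc.compute_pet_fao56(daily, 50.8, 100.0).iloc[0] == 0.0

    def test_wind_increases_pet_at_fixed_vpd(self):
        base = {"t_mean": 18.0, "t_min": 11.0, "t_max": 25.0,
                "rh_mean": 50.0, "rs_sum": 20.0}
        idx = pd.DatetimeIndex(["2013-07-01"])
        lo = mc.compute_pet_fao56(pd.DataFrame({**base, "wind_mean": 1.0}, index=idx),
                                  46.7, 1000.0).iloc[0]
        hi = mc.compute_pet_fao56(pd.DataFrame({**base, "wind_mean": 2.0}, index=idx),
                                  46.7, 1000.0).iloc[0]
        assert hi > lo

    def test_missing_covariate_gives_nan_not_zero(self):
        daily = pd.DataFrame({
            "t_mean": [np.nan], "t_min": [np.nan], "t_max": [np.nan],
            "rh_mean": [60.0], "rs_sum": [20.0], "wind_mean": [2.0],
        }, index=pd.DatetimeIndex(["2013-07-01"]))
        assert np.isnan(mc.compute_pet_fao56(daily, 46.7, 1000.0).iloc[0])


class TestThornthwaite:
    def test_cold_limit_all_zero(self):
        assert np.all(mc.compute_pet_thornthwaite([-5.0] * 12, 46.7) == 0.0)

    def test_uniform_ten_degrees_closed_form(self):
        # heat index I = 12*(2)^1.514 ~= 34.27, a ~= 1.043: 48.9 mm per
        # standardized 30-day month of 12-h days
        pet = mc.compute_pet_thornthwaite([10.0] * 12, 0.0)
        days = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
        L = mc.monthly_daylength(0.0)
        standardized = pet / (days / 30.0) / (L / 12.0)
        assert np.allclose(standardized, 48.9, atol=0.2)

    def test_daylength_factor_is_linear(self):
        # with only July above freezing, July PET scales exactly with the
        # mean July daylength across latitudes
        t = [-10.0] * 6 + [15.0] + [-10.0] * 5
        pet_eq = mc.compute_pet_thornthwaite(t, 0.0)[6]
        pet_north = mc.compute_pet_thornthwaite(t, 60.0)[6]
        ratio = mc.monthly_daylength(60.0)[6] / mc.monthly_daylength(0.0)[6]
        assert pet_north / pet_eq == pytest.approx(ratio, rel=1e-9)

    def test_annual_pet_nondecreasing_in_warming(self):
        t = np.array([-6, -4, 0, 4, 8, 13, 15, 14, 10, 5, -1, -5], float)
        base = mc.compute_pet_thornthwaite(t, 46.7).sum()
        warmer = mc.compute_pet_thornthwaite(t + 2.0, 46.7).sum()
        assert warmer >= base


class TestAggregateDaily:
    def test_means_and_sums(self):
        idx = pd.date_range("2013-06-01", periods=144, freq="10min")
        met = pd.DataFrame({
            "t_air": 5.0, "rh": 80.0, "rs": 0.1, "precip": 0.1,
            "wind": 2.0, "swc_5": 0.10, "swc_20": 0.20, "swc_50": 0.30,
        }, index=idx)
        d = mc.aggregate_daily(met)
        assert d["t_mean"].iloc[0] == pytest.approx(5.0)
        assert d["precip"].iloc[0] == pytest.approx(14.4)
        assert d["swc_mean"].iloc[0] == pytest.approx(0.20)

    def test_incomplete_day_flagged(self):
        idx = pd.date_range("2013-06-01", periods=48, freq="1h")
        met = pd.DataFrame({"t_air": 10.0, "rh": 50.0}, index=idx)
        met.loc[met.index[:20], "t_air"] = np.nan  # day 1 has 4/24 values
        d = mc.aggregate_daily(met)
        assert not d["complete"].iloc[0]
        assert np.isnan(d["t_mean"].iloc[0])
        assert d["complete"].iloc[1]

    def test_precipitation_mass_conserved(self, met_s1200):
        d = mc.aggregate_daily(met_s1200)
        assert d["precip"].sum() == pytest.approx(met_s1200["precip"].sum())


class TestFillGaps:
    def _series(self):
        idx = pd.date_range("2013-06-01", periods=24, freq="1h")
        return pd.DataFrame({"t_air": np.arange(24.0), "precip": 0.5}, index=idx)

    def test_midpoint_interpolation(self):
        met = self._series()
        met.iloc[5, 0] = np.nan
        filled, report = mc.fill_gaps(met, max_gap=6)
        assert filled["t_air"].iloc[5] == pytest.approx(5.0)
        assert len(report) == 1 and report["n_filled"].iloc[0] == 1

    def test_long_gap_left_missing(self):
        met = self._series()
        met.iloc[4:16, 0] = np.nan
        filled, report = mc.fill_gaps(met, max_gap=6)
        assert filled["t_air"].iloc[4:16].isna().all()
        assert len(report) == 0

    def test_precip_gap_zero_filled_and_reported(self):
        met = self._series()
        met.iloc[10:12, 1] = np.nan
        filled, report = mc.fill_gaps(met, max_gap=6)
        assert (filled["precip"].iloc[10:12] == 0.0).all()
        assert report["method"].iloc[0] == "zero"

    def test_filled_count_matches_report(self):
        met = self._series()
        met.iloc[3, 0] = np.nan
        met.iloc[8:10, 0] = np.nan
        filled, report = mc.fill_gaps(met, max_gap=6)
        assert report["n_filled"].sum() == 3
        assert not filled["t_air"].isna().any()


class TestLapse:
    def test_temperature_shift(self):
        idx = pd.date_range("2013-01-01", periods=365, freq="D")
        daily = pd.DataFrame({"t_mean": 10.0, "precip": 1.0}, index=idx)
        up = mc.lapse_extrapolate(daily, 1000.0, mc.LapseSpec(0.54, 12.0))
        assert up["t_mean"].iloc[0] == pytest.approx(4.6)

    def test_identity_at_zero_delta(self):
        idx = pd.date_range("2013-01-01", periods=10, freq="D")
        daily = pd.DataFrame({"t_mean": 3.0, "precip": 2.0}, index=idx)
        same = mc.lapse_extrapolate(daily, 0.0)
        pd.testing.assert_frame_equal(same, daily)

    def test_annual_precip_gain(self):
        idx = pd.date_range("2013-01-01", "2013-12-31", freq="D")
        rng = np.random.default_rng(0)
        daily = pd.DataFrame({"precip": rng.gamma(0.5, 3.0, len(idx))}, index=idx)
        up = mc.lapse_extrapolate(daily, 500.0, mc.LapseSpec(0.54, 12.0))
        assert up["precip"].sum() - daily["precip"].sum() == pytest.approx(60.0, abs=0.1)

    @given(delta=st.floats(-1500, 1500))
    @settings(max_examples=30, deadline=None)
    def test_invertible(self, delta):
        idx = pd.date_range("2013-01-01", periods=365, freq="D")
        rng = np.random.default_rng(1)
        daily = pd.DataFrame({"t_mean": rng.normal(8, 5, 365),
                              "precip": rng.gamma(0.5, 3.0, 365)}, index=idx)
        there = mc.lapse_extrapolate(daily, delta)
        back = mc.lapse_extrapolate(there, -delta)
        assert np.allclose(back["t_mean"], daily["t_mean"])
        assert np.allclose(back["precip"], daily["precip"], rtol=1e-9)
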