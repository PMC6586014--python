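"""Daily meteorological covariates from raw station series.

Derives vapor pressure deficit (VPD), potential evapotranspiration (PET,
daily FAO-56 Penman-Monteith and monthly Thornthwaite), daily aggregates of
sub-daily records, gap filling, and elevational lapse extrapolation for an
alpine forest transect.

Conventions
-----------
* Air temperature in deg C, relative humidity in % (0-100), global radiation
  in MJ m-2 per logging interval, precipitation in mm per interval, wind in
  m s-1 at 2 m, soil water content in m3 m-3.
* Sub-daily series are pandas objects indexed by a timezone-naive
  DatetimeIndex with strictly increasing timestamps.
* Daily tables use a DatetimeIndex of dates and the column names of
  :data:`DAILY_COLUMNS`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LapseSpec",
    "saturation_vapor_pressure",
    "compute_vpd",
    "compute_pet_fao56",
    "compute_pet_thornthwaite",
    "monthly_daylength",
    "daylength",
    "aggregate_daily",
    "fill_gaps",
    "lapse_extrapolate",
    "lapse_rate_per_100m",
]

#: Columns produced by :func:`aggregate_daily`.
DAILY_COLUMNS = [
    "t_mean", "t_min", "t_max", "rh_mean", "vpd_mean",
    "rs_sum", "precip", "wind_mean", "swc_mean", "complete",
]

# Days in each calendar month of a non-leap year; Thornthwaite's month-length
# correction uses these as the "days/30" factor.
_MONTH_DAYS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
# Mid-month day of year used for the mean monthly daylength.
_MONTH_MID_DOY = np.array([16, 45, 75, 105, 136, 166, 197, 228, 258, 289, 319, 350])


@dataclass(frozen=True)
class LapseSpec:
    """Elevational lapse rates along the transect.

    dt_per_100m
        Temperature decrease per 100 m of ascent (K, positive = cooling
        upward), e.g. 0.54 K / 100 m for the Matsch/Mazia valley.
    dp_per_100m
        Annual precipitation increase per 100 m of ascent (mm yr-1),
        e.g. 12 mm / 100 m.
    """

    dt_per_100m: float = 0.54
    dp_per_100m: float = 12.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.dt_per_100m) and np.isfinite(self.dp_per_100m)):
            raise ValueError("lapse rates must be finite")


def saturation_vapor_pressure(t_air):
    """Saturation vapor pressure e_s (kPa) by the FAO-56 Magnus form."""
    t = np.asarray(t_air, dtype=float)
    return 0.6108 * np.exp(17.27 * t / (t + 237.3))


def compute_vpd(t_air, rh):
    """Vapor pressure deficit (kPa) from air temperature (deg C) and RH (%).

    VPD = e_s(T) * (1 - RH/100) with the Magnus saturation curve. NaN inputs
    propagate; RH outside [0, 100] raises.
    """
    rh_arr = np.asarray(rh, dtype=float)
    finite = np.isfinite(rh_arr)
    if np.any((rh_arr[finite] < 0) | (rh_arr[finite] > 100)):
        raise ValueError("relative humidity must lie in [0, 100] %")
    vpd = saturation_vapor_pressure(t_air) * (1.0 - rh_arr / 100.0)
    if isinstance(t_air, pd.Series):
        return pd.Series(vpd, index=t_air.index, name="vpd")
    return vpd


def _extraterrestrial_radiation(latitude_deg: float, doy):
    """Daily extraterrestrial radiation Ra (MJ m-2 d-1)."""
    doy = np.asarray(doy, dtype=float)
    phi = np.deg2rad(latitude_deg)
    dr = 1.0 + 0.033 * np.cos(2.0 * np.pi * doy / 365.0)
    delta = 0.409 * np.sin(2.0 * np.pi * doy / 365.0 - 1.39)
    x = np.clip(-np.tan(phi) * np.tan(delta), -1.0, 1.0)
    ws = np.arccos(x)
    gsc = 0.0820  # MJ m-2 min-1
    return (24.0 * 60.0 / np.pi) * gsc * dr * (
        ws * np.sin(phi) * np.sin(delta) + np.cos(phi) * np.cos(delta) * np.sin(ws)
    )


def daylength(latitude_deg: float, doy):
    """Astronomical daylength N (hours) from latitude and day of year."""
    doy = np.asarray(doy, dtype=float)
    phi = np.deg2rad(latitude_deg)
    delta = 0.409 * np.sin(2.0 * np.pi * doy / 365.0 - 1.39)
    x = np.clip(-np.tan(phi) * np.tan(delta), -1.0, 1.0)
    return 24.0 / np.pi * np.arccos(x)


def monthly_daylength(latitude_deg: float) -> np.ndarray:
    """Mean daylength (h) for each calendar month at ``latitude_deg``."""
    return daylength(latitude_deg, _MONTH_MID_DOY)


def compute_pet_fao56(daily: pd.DataFrame, latitude_deg: float, elevation_m: float) -> pd.Series:
    """Daily FAO-56 Penman-Monteith reference evapotranspiration (mm d-1).

    Expects a daily table with columns ``t_mean``, ``t_min``, ``t_max``,
    ``rh_mean``, ``rs_sum`` (MJ m-2 d-1) and ``wind_mean`` (m s-1 at 2 m),
    indexed by date. Soil heat flux G = 0, albedo 0.23, standard clear-sky
    and net-longwave estimates. Days with any missing covariate yield NaN
    (never a silent zero); negative numerators are clipped to 0.
    """
    required = ["t_mean", "t_min", "t_max", "rh_mean", "rs_sum", "wind_mean"]
    missing = [c for c in required if c not in daily.columns]
    if missing:
        raise KeyError(f"compute_pet_fao56 needs daily columns {missing}")

    t = daily["t_mean"].to_numpy(float)
    tmin = daily["t_min"].to_numpy(float)
    tmax = daily["t_max"].to_numpy(float)
    rh = daily["rh_mean"].to_numpy(float)
    rs = daily["rs_sum"].to_numpy(float)
    u2 = daily["wind_mean"].to_numpy(float)
    doy = daily.index.dayofyear.to_numpy()

    es = (saturation_vapor_pressure(tmax) + saturation_vapor_pressure(tmin)) / 2.0
    ea = es * rh / 100.0
    delta = 4098.0 * saturation_vapor_pressure(t) / (t + 237.3) ** 2
    p_kpa = 101.3 * ((293.0 - 0.0065 * elevation_m) / 293.0) ** 5.26
    gamma = 0.000665 * p_kpa

    ra = _extraterrestrial_radiation(latitude_deg, doy)
    rso = (0.75 + 2e-5 * elevation_m) * ra
    rns = (1.0 - 0.23) * rs
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.clip(np.where(rso > 0, rs / rso, 0.0), 0.0, 1.0)
    sigma = 4.903e-9  # MJ K-4 m-2 d-1
    rnl = (
        sigma * ((tmax + 273.16) ** 4 + (tmin + 273.16) ** 4) / 2.0
        * (0.34 - 0.14 * np.sqrt(np.clip(ea, 0.0, None)))
        * (1.35 * rel - 0.35)
    )
    rn = rns - rnl

    num = 0.408 * delta * rn + gamma * 900.0 / (t + 273.0) * u2 * (es - ea)
    den = delta + gamma * (1.0 + 0.34 * u2)
    pet = np.clip(num / den, 0.0, None)
    return pd.Series(pet, index=daily.index, name="pet")


def compute_pet_thornthwaite(monthly_t, latitude_deg: float) -> np.ndarray:
    """Monthly Thornthwaite potential evapotranspiration (mm month-1).

    ``monthly_t`` is an array of 12 monthly mean temperatures (deg C); the
    last axis may be 12 for gridded input. Uses the annual heat index
    I = sum_(T>0) (T/5)^1.514, the cubic exponent a(I), and the daylength /
    month-length corrections; months with T <= 0 deg C evaporate nothing.
    """
    t = np.asarray(monthly_t, dtype=float)
    if t.shape[-1] != 12:
        raise ValueError("monthly_t must have 12 entries on the last axis")
    tpos = np.clip(t, 0.0, None)
    heat = np.sum((tpos / 5.0) ** 1.514, axis=-1)
    a = 6.75e-7 * heat**3 - 7.71e-5 * heat**2 + 1.792e-2 * heat + 0.49239
    ld = monthly_daylength(latitude_deg) / 12.0 * (_MONTH_DAYS / 30.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pet = 16.0 * (10.0 * tpos / heat[..., None]) ** a[..., None] * ld
    pet = np.where((tpos > 0) & (heat[..., None] > 0), pet, 0.0)
    return pet


def aggregate_daily(series: pd.DataFrame, min_completeness: float = 0.9) -> pd.DataFrame:
    """Aggregate a sub-daily met table to daily covariates.

    Means for temperature, RH, VPD (computed per interval), wind and SWC
    (SWC first averaged across ``swc_*`` depth columns, unweighted); sums for
    radiation and precipitation. Days with fewer valid temperature intervals
    than ``min_completeness`` of the modal daily count are flagged
    ``complete=False`` and their aggregates set to NaN, except precipitation
    which is always the sum of what was observed (mass conservation).
    """
    if not series.index.is_monotonic_increasing or series.index.has_duplicates:
        raise ValueError("timestamps must be strictly increasing")
    df = series.copy()
    swc_cols = [c for c in df.columns if c.startswith("swc")]
    if swc_cols:
        df["_swc"] = df[swc_cols].mean(axis=1)
    if "t_air" in df.columns and "rh" in df.columns:
        df["_vpd"] = compute_vpd(df["t_air"], df["rh"])

    grouper = df.groupby(df.index.normalize())
    out = pd.DataFrame(index=grouper.size().index)
    counts = grouper["t_air"].count() if "t_air" in df.columns else grouper.size()
    expected = counts.max()
    out["t_mean"] = grouper["t_air"].mean() if "t_air" in df.columns else np.nan
    out["t_min"] = grouper["t_air"].min() if "t_air" in df.columns else np.nan
    out["t_max"] = grouper["t_air"].max() if "t_air" in df.columns else np.nan
    out["rh_mean"] = grouper["rh"].mean() if "rh" in df.columns else np.nan
    out["vpd_mean"] = grouper["_vpd"].mean() if "_vpd" in df.columns else np.nan
    out["rs_sum"] = grouper["rs"].sum() if "rs" in df.columns else np.nan
    out["precip"] = grouper["precip"].sum() if "precip" in df.columns else np.nan
    out["wind_mean"] = grouper["wind"].mean() if "wind" in df.columns else np.nan
    out["swc_mean"] = grouper["_swc"].mean() if "_swc" in df.columns else np.nan
    out["complete"] = counts >= min_completeness * expected
    bad = ~out["complete"]
    mask_cols = ["t_mean", "t_min", "t_max", "rh_mean", "vpd_mean", "rs_sum",
                 "wind_mean", "swc_mean"]
    out.loc[bad, mask_cols] = np.nan
    out.index.name = "date"
    return out


def fill_gaps(series: pd.DataFrame, max_gap: int = 36):
    """Fill short gaps in a sub-daily met table.

    Gaps of at most ``max_gap`` consecutive missing intervals are linearly
    interpolated, except precipitation where missing intervals in a short gap
    are set to 0 (rain gauges report accumulations; interpolating would
    invent water). Longer gaps are left missing. Returns ``(filled, report)``
    where ``report`` lists one row per filled span (column, start, end, n).
    """
    filled = series.copy()
    rows = []
    for col in series.columns:
        vals = series[col]
        isna = vals.isna().to_numpy()
        if not isna.any():
            continue
        # identify runs of consecutive NaNs
        edges = np.flatnonzero(np.diff(np.concatenate(([0], isna.astype(int), [0]))))
        for start, stop in zip(edges[::2], edges[1::2]):
            n = stop - start
            if n > max_gap or start == 0 or stop == len(vals):
                continue  # unbounded or too long: leave missing
            if col == "precip":
                filled.iloc[start:stop, filled.columns.get_loc(col)] = 0.0
            else:
                lo, hi = vals.iloc[start - 1], vals.iloc[stop]
                frac = np.arange(1, n + 1) / (n + 1)
                filled.iloc[start:stop, filled.columns.get_loc(col)] = lo + frac * (hi - lo)
            rows.append({
                "column": col,
                "start": series.index[start],
                "end": series.index[stop - 1],
                "n_filled": n,
                "method": "zero" if col == "precip" else "linear",
            })
    report = pd.DataFrame(rows, columns=["column", "start", "end", "n_filled", "method"])
    return filled, report


def lapse_extrapolate(daily: pd.DataFrame, delta_elev_m: float,
                      lapse: LapseSpec = LapseSpec()) -> pd.DataFrame:
    """Shift a daily climate table along the elevation gradient.

    Temperatures drop by ``dt_per_100m`` per 100 m of ascent; the annual
    precipitation total gains ``dp_per_100m`` per 100 m, distributed
    proportionally over observed precipitation events so event structure is
    preserved. Exactly invertible (+de then -de restores the input).
    """
    out = daily.copy()
    dt = lapse.dt_per_100m * delta_elev_m / 100.0
    for col in ("t_mean", "t_min", "t_max"):
        if col in out.columns:
            out[col] = out[col] - dt
    if "precip" in out.columns:
        p_ann = out["precip"].sum(skipna=True)
        years = max(len(out) / 365.25, 1e-9)
        dp = lapse.dp_per_100m * delta_elev_m / 100.0 * years
        if p_ann > 0:
            out["precip"] = out["precip"] * (1.0 + dp / p_ann)
    return out


def lapse_rate_per_100m(total_difference: float, elev_lo_m: float, elev_hi_m: float) -> float:
    """Per-100-m gradient from a total difference between two elevations."""
    if elev_hi_m == elev_lo_m:
        raise ValueError("elevations must differ")
    return total_difference / abs(elev_hi_m - elev_lo_m) * 100.0
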