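"""Seeded generators for every pipeline input, with known ground truth.

The generators emulate the study conditions of a dry inner-alpine larch
transect: five sites between 1070 and 2250 m sharing valley-wide weather,
with temperature and precipitation shifted by the local lapse rates
(0.54 K and 12 mm yr-1 per 100 m); station normals 528 mm and 6.6 deg C at
the 1570-m reference elevation; scripted summer drought episodes at the
lower sites; Gompertz seasonal stem growth with vapor-pressure-driven
diurnal shrinkage; saturating sap-flow responses to evaporative demand and
soil water; and AR-structured ring-width ensembles carrying a monthly
climate signal with a tunable interseries correlation.

Every generator is a pure function of (spec, seed): the same seed yields
bit-identical output. Weather noise is drawn from the seed alone, so two
sites generated with the same seed share the same storms and warm spells
and differ only by the deterministic lapse structure (plus site-scripted
droughts), as on a real transect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .microclimate import LapseSpec, daylength, _extraterrestrial_radiation
from .phenology import gompertz_curve

__all__ = [
    "SiteSpec", "GenTruth", "default_transect",
    "gen_microclimate", "gen_dendrometer", "gen_sapflow",
    "gen_monthly_climate", "gen_ringwidths",
]

REF_ELEVATION_M = 1570.0
REF_T_ANN_C = 6.6
REF_P_ANN_MM = 528.0


@dataclass(frozen=True)
class SiteSpec:
    """One transect site: elevation plus scripted drought episodes.

    ``drought_episodes`` holds (start_doy, end_doy, swc_floor) triples; the
    soil dries toward the floor and precipitation is suppressed within the
    episode.
    """

    site_id: str
    elevation_m: float
    lapse: LapseSpec = LapseSpec()
    t_ann_ref: float = REF_T_ANN_C
    p_ann_ref: float = REF_P_ANN_MM
    ref_elevation_m: float = REF_ELEVATION_M
    latitude_deg: float = 46.7
    drought_episodes: tuple = ()

    @property
    def t_ann(self) -> float:
        de = self.elevation_m - self.ref_elevation_m
        return self.t_ann_ref - self.lapse.dt_per_100m * de / 100.0

    @property
    def p_ann(self) -> float:
        de = self.elevation_m - self.ref_elevation_m
        return max(self.p_ann_ref + self.lapse.dp_per_100m * de / 100.0, 1.0)


def default_transect() -> list[SiteSpec]:
    """The five-site ensemble (1070-2250 m); the two lower instrumented
    sites carry a scripted mid-July drought (soil floor reached around
    DOY 175-200), the subalpine sites none."""
    episodes = ((175, 200, 0.08),)
    return [
        SiteSpec("S1100", 1070, drought_episodes=episodes),
        SiteSpec("S1200", 1160, drought_episodes=episodes),
        SiteSpec("S1700", 1715, drought_episodes=((180, 200, 0.10),)),
        SiteSpec("S2000", 1990),
        SiteSpec("S2200", 2250),
    ]


@dataclass
class GenTruth:
    """Ground truth injected by the generators (for recovery tests)."""

    seed: int
    gompertz: dict = field(default_factory=dict)      # tree_id -> (A, mu, lam)
    drought_episodes: tuple = ()
    sapflow: dict = field(default_factory=dict)       # response parameters
    ring_signal: dict = field(default_factory=dict)   # beta, month, rbar target
    rbar_target: float | None = None


# ---------------------------------------------------------------------------
# Microclimate

def _daily_weather(spec: SiteSpec, year: int, rng: np.random.Generator):
    """Valley-wide daily weather skeleton, lapse-shifted to the site."""
    dates = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
    doy = dates.dayofyear.to_numpy(float)
    n = len(dates)

    # temperature: seasonal cycle + AR(1) synoptic noise
    t_season = spec.t_ann + 9.0 * np.cos(2.0 * np.pi * (doy - 196.0) / 365.0)
    eps = np.empty(n)
    eps[0] = rng.normal(0, 1.5)
    innov = rng.normal(0, 1.5 * np.sqrt(1 - 0.8**2), n)
    for i in range(1, n):
        eps[i] = 0.8 * eps[i - 1] + innov[i]
    t_day = t_season + eps

    # precipitation: two-state occurrence chain with gamma amounts
    wet = np.zeros(n, dtype=bool)
    u = rng.random(n)
    wet[0] = u[0] < 0.3
    for i in range(1, n):
        wet[i] = u[i] < (0.55 if wet[i - 1] else 0.25)
    wet_frac = 0.25 / (1 + 0.25 - 0.55)
    mean_amount = spec.p_ann / (wet_frac * n)
    amounts = rng.gamma(0.7, mean_amount / 0.7, n) * wet

    # scripted droughts suppress rain; each breaks with a convective pulse
    # on the two following days (droughts here end with rain, as the TWD
    # relaxation behaviour requires)
    in_episode = np.zeros(n, dtype=bool)
    for start, end, _floor in spec.drought_episodes:
        in_episode |= (doy >= start) & (doy <= end)
        for offset, pulse in ((1, 14.0), (2, 10.0)):
            after = np.flatnonzero(doy == end + offset)
            if len(after):
                amounts[after[0]] = max(amounts[after[0]], pulse)
                wet[after[0]] = True
    amounts[in_episode] = 0.0
    wet &= ~in_episode

    # radiation: clear-sky envelope times a cloud factor tied to rain
    ra = _extraterrestrial_radiation(spec.latitude_deg, doy)
    cloud = np.where(wet, rng.uniform(0.15, 0.4, n), rng.uniform(0.65, 0.95, n))
    rs_day = 0.75 * ra * cloud

    # humidity anticorrelated with temperature anomaly, higher on wet days
    rh_day = np.clip(62.0 - 2.5 * eps + 22.0 * wet + rng.normal(0, 5, n), 15.0, 98.0)

    wind_day = rng.lognormal(np.log(1.8), 0.4, n)

    # soil water: single bucket (m3 m-3), drained by a temperature-driven
    # demand proxy, refilled by rain, overridden by scripted floors
    swc = np.empty(n)
    swc[0] = 0.28
    fc, wilt, depth_mm = 0.32, 0.05, 300.0
    for i in range(1, n):
        et = 0.18 * max(t_day[i], 0.0) * (swc[i - 1] - wilt) / (fc - wilt)
        swc[i] = np.clip(swc[i - 1] + (amounts[i] - et) / depth_mm, wilt, fc)
    for start, end, floor in spec.drought_episodes:
        idx = (doy >= start) & (doy <= end)
        if idx.any():
            # shallow alpine soils deplete within days: reach the floor a
            # third of the way into the episode, then hold
            pos = np.linspace(0.0, 1.0, idx.sum())
            ramp = np.clip(1.0 - 3.0 * pos, 0.0, 1.0)
            start_val = swc[np.argmax(idx)]
            swc[idx] = np.minimum(swc[idx], floor + (start_val - floor) * ramp)

    return pd.DataFrame({
        "t_day": t_day, "precip_day": amounts, "rs_day": rs_day,
        "rh_day": rh_day, "wind_day": wind_day, "swc_day": swc,
        "wet": wet,
    }, index=dates)


def gen_microclimate(spec: SiteSpec, year: int, seed: int,
                     freq: str = "1h") -> pd.DataFrame:
    """Sub-daily met series for one site-year.

    Columns: ``t_air`` (deg C), ``rh`` (%), ``rs`` (MJ m-2 per interval),
    ``precip`` (mm per interval), ``wind`` (m s-1), ``swc_5``/``swc_20``/
    ``swc_50`` (m3 m-3 at three depths).
    """
    rng = np.random.default_rng(seed)
    day = _daily_weather(spec, year, rng)
    steps = pd.date_range(day.index[0], day.index[-1] + pd.Timedelta("1D"),
                          freq=freq, inclusive="left")
    per_day = int(round(pd.Timedelta("1D") / pd.Timedelta(freq)))
    hours = steps.hour.to_numpy() + steps.minute.to_numpy() / 60.0
    d = day.reindex(steps.normalize())

    diurnal = -np.cos(2.0 * np.pi * (hours - 2.0) / 24.0)  # peak ~14:00
    t_air = d["t_day"].to_numpy() + 4.5 * diurnal
    rh = np.clip(d["rh_day"].to_numpy() - 10.0 * diurnal, 5.0, 100.0)

    # daylight half-sine radiation share
    dl = daylength(spec.latitude_deg, steps.dayofyear.to_numpy(float))
    rise = 12.0 - dl / 2.0
    frac = np.where((hours >= rise) & (hours <= rise + dl),
                    np.sin(np.pi * (hours - rise) / np.where(dl > 0, dl, 1.0)),
                    0.0)
    day_sum = pd.Series(frac).groupby(steps.normalize()).transform("sum").to_numpy()
    rs = d["rs_day"].to_numpy() * np.where(day_sum > 0, frac / day_sum, 0.0)

    # daily rain spread over an afternoon convective window
    rain_win = (hours >= 13) & (hours < 19)
    win_len = rain_win.reshape(-1, per_day).sum(axis=1)[0] or 1
    precip = np.where(rain_win, d["precip_day"].to_numpy() / win_len, 0.0)

    out = pd.DataFrame({
        "t_air": t_air, "rh": rh, "rs": rs, "precip": precip,
        "wind": d["wind_day"].to_numpy(),
        "swc_5": np.clip(d["swc_day"].to_numpy() * 0.9, 0.03, None),
        "swc_20": d["swc_day"].to_numpy(),
        "swc_50": np.clip(d["swc_day"].to_numpy() * 1.1, None, 0.38),
    }, index=steps)
    out.index.name = "timestamp"
    return out


# ---------------------------------------------------------------------------
# Dendrometer

def gen_dendrometer(truth: tuple[float, float, float], daily: pd.DataFrame,
                    seed: int, freq: str = "1h", noise_sd: float = 0.0,
                    swc_threshold: float = 0.12, k_vpd: float = 25.0,
                    episode_rate: float = 8.0, relax_days: float = 1.5) -> pd.Series:
    """Stem-circumference trace (um) for one tree-season.

    ``truth`` = (A, mu, lam) of the underlying Gompertz growth line;
    ``daily`` must provide ``vpd_mean`` and ``swc_mean``. The radius is the
    Gompertz curve minus a shrinkage term: a diurnal component proportional
    to the day's VPD (zero at night, so the nightly maxima trace the growth
    line) plus a drought component that builds at ``episode_rate`` um d-1
    while soil water sits below ``swc_threshold`` and relaxes exponentially
    (time constant ``relax_days``) after rewetting. Growth is therefore
    expressed only at water saturation, exactly the zero-growth reading of
    the trace. Output is circumference = 2*pi*radius.
    """
    A, mu, lam = truth
    rng = np.random.default_rng(seed)
    steps = pd.date_range(daily.index[0], daily.index[-1] + pd.Timedelta("1D"),
                          freq=freq, inclusive="left")
    hours = steps.hour.to_numpy() + steps.minute.to_numpy() / 60.0
    doy_f = steps.dayofyear.to_numpy(float) + hours / 24.0
    d = daily.reindex(steps.normalize())

    bell = np.clip(np.sin(np.pi * (hours - 8.0) / 12.0), 0.0, None)
    bell[(hours < 8) | (hours > 20)] = 0.0
    vpd = np.nan_to_num(d["vpd_mean"].to_numpy(float))
    shrink_diurnal = k_vpd * vpd * bell

    swc = np.nan_to_num(d["swc_mean"].to_numpy(float), nan=0.3)
    per_day = int(round(pd.Timedelta("1D") / pd.Timedelta(freq)))
    dt_d = 1.0 / per_day

    # potential growth rate (midpoint rule for the cumulative sum)
    y_mid = gompertz_curve(doy_f + dt_d / 2.0, A, mu, lam)
    u = mu * np.e / A * (lam - (doy_f + dt_d / 2.0)) + 1.0
    rate = y_mid * np.exp(u) * mu * np.e / A

    # growth only while the stem is water-saturated: the drought shrink
    # gates the increments (growth lost in an episode is not caught up),
    # which is the zero-growth assumption realized by construction
    episode = np.empty(len(steps))
    growth = np.empty(len(steps))
    e = 0.0
    g = float(gompertz_curve(doy_f[0], A, mu, lam))
    decay = np.exp(-dt_d / relax_days)
    eps_saturated = 10.0  # um of residual drought shrink that still blocks growth
    for i in range(len(steps)):
        if swc[i] < swc_threshold:
            e += episode_rate * dt_d
        else:
            e *= decay
        if e <= eps_saturated:
            g += rate[i] * dt_d
        episode[i] = e
        growth[i] = g

    radius = growth - shrink_diurnal - episode
    if noise_sd > 0:
        radius = radius + rng.normal(0.0, noise_sd, len(steps))
    circ = pd.Series(2.0 * np.pi * radius, index=steps, name="circumference_um")
    circ.index.name = "timestamp"
    return circ


# ---------------------------------------------------------------------------
# Sap flow

def gen_sapflow(daily: pd.DataFrame, seed: int, freq: str = "1h",
                qmax: float = 0.06, k_pet: float = 1.5, k_swc: float = 0.08,
                swc_wilt: float = 0.05, soil_limited: bool = True,
                noise_sd: float = 0.12, two_sensors: bool = True) -> pd.DataFrame:
    """Per-circumference sap-flow trace(s) (kg h-1 cm-1) for one tree-season.

    The daily amplitude saturates in evaporative demand, qmax * PET/(PET+k),
    and -- unless ``soil_limited=False`` (a high-elevation tree with ample
    water) -- in soil moisture above wilting. Flow follows a daylight bell,
    with multiplicative lognormal day-to-day noise. ``daily`` must provide
    ``pet`` and ``swc_mean``. Two sensor columns (north/south, slightly
    offset) are returned unless ``two_sensors=False``.
    """
    rng = np.random.default_rng(seed)
    steps = pd.date_range(daily.index[0], daily.index[-1] + pd.Timedelta("1D"),
                          freq=freq, inclusive="left")
    hours = steps.hour.to_numpy() + steps.minute.to_numpy() / 60.0
    d = daily.reindex(steps.normalize())

    pet = np.clip(np.nan_to_num(d["pet"].to_numpy(float)), 0.0, None)
    sat_pet = pet / (pet + k_pet)
    if soil_limited:
        swc = np.clip(np.nan_to_num(d["swc_mean"].to_numpy(float), nan=0.3)
                      - swc_wilt, 0.0, None)
        sat_swc = swc / (swc + k_swc)
    else:
        sat_swc = np.ones(len(steps))

    bell = np.clip(np.sin(np.pi * (hours - 7.0) / 13.0), 0.0, None)
    bell[(hours < 7) | (hours > 20)] = 0.0

    n_days = len(daily)
    day_noise = np.repeat(
        rng.lognormal(-0.5 * noise_sd**2, noise_sd, n_days),
        int(round(pd.Timedelta("1D") / pd.Timedelta(freq))),
    )[: len(steps)]
    rate = qmax * sat_pet * sat_swc * bell * day_noise

    out = pd.DataFrame(index=steps)
    out.index.name = "timestamp"
    if two_sensors:
        asym = rng.uniform(0.85, 1.15)
        out["north"] = rate * asym
        out["south"] = rate * (2.0 - asym)
    else:
        out["north"] = rate
    return out


# ---------------------------------------------------------------------------
# Ring widths and long-term monthly climate

def gen_monthly_climate(spec: SiteSpec, start_year: int, n_years: int,
                        seed: int) -> pd.DataFrame:
    """Monthly station series (t deg C, p mm) over ``n_years`` years."""
    rng = np.random.default_rng(seed)
    idx = pd.MultiIndex.from_product(
        [range(start_year, start_year + n_years), range(1, 13)],
        names=["year", "month"])
    months = idx.get_level_values("month").to_numpy()
    cycle = spec.t_ann + 9.0 * np.cos(2.0 * np.pi * (months - 7) / 12.0)
    # temperature anomalies persist from month to month (the collinearity
    # among monthly predictors that motivates principal-components
    # regression downstream)
    n = len(idx)
    anom = np.empty(n)
    anom[0] = rng.normal(0.0, 1.2)
    innov = rng.normal(0.0, 1.2 * np.sqrt(1 - 0.5**2), n)
    for i in range(1, n):
        anom[i] = 0.5 * anom[i - 1] + innov[i]
    t = cycle + anom
    # summer-peaked monthly precipitation normals
    weights = 1.0 + 0.6 * np.cos(2.0 * np.pi * (months - 7) / 12.0)
    weights12 = 1.0 + 0.6 * np.cos(2.0 * np.pi * (np.arange(1, 13) - 7) / 12.0)
    normals = spec.p_ann * weights / weights12.sum()
    p = rng.gamma(4.0, normals / 4.0)
    return pd.DataFrame({"t": t, "p": p}, index=idx)


def gen_ringwidths(monthly: pd.DataFrame, n_trees: int, seed: int,
                   beta: float = 0.0, signal_var: str = "p",
                   signal_month: int = 6, signal_offset: int = 0,
                   rbar_target: float = 0.5, noise_sd: float = 0.8,
                   index_scale: float = 0.2, core_noise_sd: float = 0.1,
                   phi_common: float = 0.3):
    """Ring-width ensemble (two cores per tree) with known signal structure.

    Widths follow w_it = ageTrend_i(t) * exp(s * (common_t + eps_it)) where
    the common signal is beta * z(selected monthly climate) plus an AR(1)
    background whose variance is set so the expected interseries correlation
    matches ``rbar_target`` given the individual noise ``noise_sd``; ``s``
    (``index_scale``) sets the relative width variability. Each of the two
    cores per tree adds independent lognormal measurement noise. The first
    year is dropped (previous-year climate predictors must exist).

    Returns ``({core_id: Series um}, GenTruth)``.
    """
    rng = np.random.default_rng(seed)
    years = np.array(sorted({y for y, _ in monthly.index}))[1:]
    n = len(years)

    clim = np.array([monthly[signal_var].loc[(y + signal_offset, signal_month)]
                     for y in years])
    z = (clim - clim.mean()) / clim.std(ddof=1)

    var_common_needed = rbar_target / (1.0 - rbar_target) * noise_sd**2
    s_eta = np.sqrt(max(var_common_needed - beta**2, 1e-4))
    eta = np.empty(n)
    eta[0] = rng.normal(0, s_eta)
    innov = rng.normal(0, s_eta * np.sqrt(1 - phi_common**2), n)
    for i in range(1, n):
        eta[i] = phi_common * eta[i - 1] + innov[i]
    common = beta * z + eta

    series: dict[str, pd.Series] = {}
    truth_gomp = {}
    for i in range(n_trees):
        trng = np.random.default_rng(np.random.SeedSequence((seed, i)))
        a0 = trng.uniform(1500.0, 3500.0)
        b = trng.uniform(0.008, 0.03)
        k = trng.uniform(500.0, 1200.0)
        age = a0 * np.exp(-b * np.arange(n)) + k
        eps = trng.normal(0.0, noise_sd, n)
        tree_w = age * np.exp(index_scale * (common + eps))
        for core in ("a", "b"):
            cn = trng.lognormal(-0.5 * (index_scale * core_noise_sd)**2,
                                index_scale * core_noise_sd, n)
            w = np.round(np.clip(tree_w * cn, 1.0, None))
            sid = f"T{i + 1:02d}{core}"
            series[sid] = pd.Series(w, index=pd.Index(years, name="year"),
                                    name=sid)
        truth_gomp[f"T{i + 1:02d}"] = (a0, b, k)

    truth = GenTruth(
        seed=seed,
        ring_signal={"beta": beta, "var": signal_var, "month": signal_month,
                     "offset": signal_offset, "z": z, "common": common,
                     "age_params": truth_gomp},
        rbar_target=rbar_target,
    )
    return series, truth
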