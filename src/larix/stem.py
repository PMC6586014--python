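"""Zero-growth decomposition of dendrometer stem traces.

A band dendrometer logs stem circumference change (um). Under the
zero-growth assumption radial growth occurs only at stem water saturation,
so the running maximum of the radius trace is the irreversible growth line
(GRO) and the deviation below it is the reversible, drought-related tree
water deficit (TWD): radius = GRO - TWD at every timestamp.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GrowthPeriod",
    "circumference_to_radius",
    "partition_zero_growth",
    "daily_stem_stats",
    "detect_growth_period",
]


@dataclass(frozen=True)
class GrowthPeriod:
    """Main growth period of one tree-year: the longest run of days with a
    high GRO rate and near-zero daily minimum water deficit."""

    start_doy: int | None
    end_doy: int | None
    empty: bool = False

    def __post_init__(self) -> None:
        if not self.empty and (self.start_doy is None or self.end_doy is None
                               or self.start_doy >= self.end_doy):
            raise ValueError("non-empty period requires start_doy < end_doy")


def circumference_to_radius(circ: pd.Series, hourly: bool = True) -> pd.Series:
    """Convert a circumference-change trace (um) to stem radius (um).

    radius = circumference / (2*pi); with ``hourly=True`` the radius is then
    averaged to hourly means (the native 10-min signal is noisy and the
    partition is defined on the hourly trace).
    """
    if not circ.index.is_monotonic_increasing or circ.index.has_duplicates:
        raise ValueError("timestamps must be strictly increasing")
    radius = circ / (2.0 * np.pi)
    if hourly:
        radius = radius.resample("1h").mean().dropna()
    radius.name = "radius"
    return radius


def partition_zero_growth(radius: pd.Series) -> pd.DataFrame:
    """Partition a radius trace into growth line and tree water deficit.

    GRO(t) = max_{s<=t} radius(s) (moving maximum of current and previous
    readings); TWD(t) = GRO(t) - radius(t) >= 0. The identity
    radius = GRO - TWD holds exactly by construction.
    """
    if len(radius) == 0:
        raise ValueError("empty radius trace")
    r = radius.to_numpy(float)
    if np.isnan(r).any():
        raise ValueError("radius trace contains NaN; fill or drop gaps first")
    gro = np.maximum.accumulate(r)
    twd = gro - r
    return pd.DataFrame({"radius": r, "gro": gro, "twd": twd}, index=radius.index)


def daily_stem_stats(part: pd.DataFrame) -> pd.DataFrame:
    """Daily statistics of a partitioned trace.

    DRC (daily radius change) is the difference of consecutive daily mean
    radii (first day missing); TWD is summarized by its daily maximum (used
    in the daily climate models) and minimum (near 0 on days of active
    growth); GRO by its daily maximum.
    """
    g = part.groupby(part.index.normalize())
    out = pd.DataFrame({
        "radius_mean": g["radius"].mean(),
        "gro_max": g["gro"].max(),
        "twd_max": g["twd"].max(),
        "twd_min": g["twd"].min(),
    })
    out["drc"] = out["radius_mean"].diff()
    out.index.name = "date"
    return out


def detect_growth_period(stats: pd.DataFrame, window: int = 5,
                         rate_frac: float = 0.2,
                         twd_threshold: float = 30.0) -> GrowthPeriod:
    """Detect the main growth period of one season.

    A day qualifies when the GRO increase over the trailing ``window`` days
    (daily rate) reaches ``rate_frac`` of the season's maximum rate and the
    daily minimum TWD is at or below ``twd_threshold`` um (stem near water
    saturation). The longest contiguous run of qualifying days is returned;
    a flat trace (or a season with no qualifying day) yields an empty,
    flagged period. A mid-season drought that pushes TWD above the threshold
    splits the run and the longer fragment wins.
    """
    gro = stats["gro_max"].to_numpy(float)
    twd_min = stats["twd_min"].to_numpy(float)
    doy = stats.index.dayofyear.to_numpy()
    n = len(gro)
    if n <= window:
        return GrowthPeriod(None, None, empty=True)
    rate = np.full(n, np.nan)
    rate[window:] = (gro[window:] - gro[:-window]) / window
    max_rate = np.nanmax(rate)
    if not np.isfinite(max_rate) or max_rate <= 0:
        return GrowthPeriod(None, None, empty=True)
    ok = (rate >= rate_frac * max_rate) & (twd_min <= twd_threshold)
    ok &= np.isfinite(rate)
    if not ok.any():
        return GrowthPeriod(None, None, empty=True)
    # longest contiguous run of qualifying days
    best_len, best_start = 0, 0
    i = 0
    while i < n:
        if ok[i]:
            j = i
            while j < n and ok[j]:
                j += 1
            if j - i > best_len:
                best_len, best_start = j - i, i
            i = j
        else:
            i += 1
    start, end = best_start, best_start + best_len - 1
    if best_len < 2:
        return GrowthPeriod(None, None, empty=True)
    return GrowthPeriod(int(doy[start]), int(doy[end]))
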