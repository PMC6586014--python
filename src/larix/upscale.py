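"""Climatic-water-deficit classification of larch growth conditions.

Growth conditions over a grid (or the transect sites) are classified from
the annual climatic water deficit CWD = annual precipitation minus annual
Thornthwaite potential evapotranspiration, with a thermal floor: cells whose
mean annual temperature falls below -2.5 deg C lie beyond the cold limit of
European larch. Three CWD classes map to the transect: severely restricted
(the two low sites), drought restricted (mid elevation), favorable (the two
high sites). The two CWD cut points are calibration outputs, not constants:
:func:`calibrate_thresholds` anchors them to synthetic site climates built
from the valley's station normals (528 mm, 6.6 deg C at 1570 m) and the
local lapse rates. A warming scenario (uniform delta-T, fractional
precipitation change) can be applied before classification.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .microclimate import LapseSpec, compute_pet_thornthwaite

__all__ = [
    "ClimateCell", "ScenarioSpec", "GrowthClass",
    "annual_cwd", "apply_scenario", "classify_cell", "classify_grid",
    "transect_cells", "calibrate_thresholds",
    "FAVORABLE", "DROUGHT_RESTRICTED", "SEVERELY_RESTRICTED", "BELOW_THERMAL_LIMIT",
    "TRANSECT_ELEVATIONS",
]

FAVORABLE = "favorable"
DROUGHT_RESTRICTED = "drought-restricted"
SEVERELY_RESTRICTED = "severely-restricted"
BELOW_THERMAL_LIMIT = "below-thermal-limit"

#: Transect site elevations (m asl), low colline to high subalpine.
TRANSECT_ELEVATIONS = {"S1100": 1070, "S1200": 1160, "S1700": 1715,
                       "S2000": 1990, "S2200": 2250}

#: Station normals for the valley: annual precipitation (mm) and mean annual
#: temperature (deg C) at the reference elevation (m).
STATION_NORMALS = {"p_ann": 528.0, "t_ann": 6.6, "elevation": 1570.0}

#: Peak-to-mean amplitude (K) of the seasonal temperature cycle used when a
#: monthly cycle must be synthesized from an annual mean (continental alpine
#: valley; July warmest).
SEASONAL_AMPLITUDE_K = 9.0


@dataclass(frozen=True)
class ClimateCell:
    """One grid cell or site: elevation, monthly mean T, annual P."""

    cell_id: str
    elevation_m: float
    monthly_t: tuple
    annual_p: float
    latitude_deg: float = 46.7

    def __post_init__(self) -> None:
        if len(self.monthly_t) != 12:
            raise ValueError("monthly_t must hold 12 values")
        if not np.isfinite(self.annual_p) or self.annual_p < 0:
            raise ValueError("annual_p must be finite and >= 0")

    @property
    def t_ann(self) -> float:
        return float(np.mean(self.monthly_t))


@dataclass(frozen=True)
class ScenarioSpec:
    """Uniform warming scenario: delta_t (K) added to every month,
    annual precipitation scaled by (1 + delta_p_frac)."""

    delta_t: float = 3.2
    delta_p_frac: float = -0.145

    def __post_init__(self) -> None:
        if self.delta_p_frac <= -1:
            raise ValueError("delta_p_frac must exceed -1")


@dataclass(frozen=True)
class GrowthClass:
    label: str
    cwd: float
    t_ann: float


def seasonal_cycle(t_ann: float, amplitude: float = SEASONAL_AMPLITUDE_K) -> tuple:
    """Synthetic monthly temperature cycle around an annual mean (July peak)."""
    months = np.arange(12)
    return tuple(t_ann + amplitude * np.cos(2.0 * np.pi * (months - 6) / 12.0))


def annual_cwd(cell: ClimateCell) -> float:
    """Annual climatic water deficit: precipitation minus Thornthwaite PET (mm).

    Positive = water surplus, negative = deficit. Cells with every month at
    or below 0 deg C evaporate nothing, so CWD equals annual precipitation.
    """
    pet = compute_pet_thornthwaite(np.asarray(cell.monthly_t), cell.latitude_deg)
    return float(cell.annual_p - pet.sum())


def apply_scenario(cell: ClimateCell, scenario: ScenarioSpec) -> ClimateCell:
    """Apply a warming scenario to one cell."""
    return replace(
        cell,
        monthly_t=tuple(t + scenario.delta_t for t in cell.monthly_t),
        annual_p=cell.annual_p * (1.0 + scenario.delta_p_frac),
    )


def classify_cell(cell: ClimateCell, thresholds: tuple[float, float],
                  t_min_limit: float = -2.5) -> GrowthClass:
    """Classify one cell by its CWD and the larch thermal floor.

    ``thresholds`` = (severe/drought cut, drought/favorable cut) in mm of
    CWD, strictly increasing. Cells colder than ``t_min_limit`` on annual
    average are below the thermal limit regardless of CWD.
    """
    cut_lo, cut_hi = thresholds
    if not cut_lo < cut_hi:
        raise ValueError("thresholds must be strictly increasing")
    cwd = annual_cwd(cell)
    t_ann = cell.t_ann
    if t_ann < t_min_limit:
        label = BELOW_THERMAL_LIMIT
    elif cwd < cut_lo:
        label = SEVERELY_RESTRICTED
    elif cwd < cut_hi:
        label = DROUGHT_RESTRICTED
    else:
        label = FAVORABLE
    return GrowthClass(label=label, cwd=cwd, t_ann=t_ann)


def classify_grid(cells, thresholds: tuple[float, float],
                  scenario: ScenarioSpec | None = None,
                  t_min_limit: float = -2.5):
    """Classify a grid of cells; returns (per-cell table, per-class tally).

    When ``scenario`` is given it is applied to every cell first
    (classification commutes with pre-transforming the cells).
    """
    rows = []
    for cell in cells:
        c = apply_scenario(cell, scenario) if scenario is not None else cell
        gc = classify_cell(c, thresholds, t_min_limit=t_min_limit)
        rows.append({"cell_id": cell.cell_id, "elevation_m": cell.elevation_m,
                     "cwd": gc.cwd, "t_ann": gc.t_ann, "label": gc.label})
    table = pd.DataFrame(rows).set_index("cell_id")
    tally = table["label"].value_counts().reindex(
        [SEVERELY_RESTRICTED, DROUGHT_RESTRICTED, FAVORABLE, BELOW_THERMAL_LIMIT],
        fill_value=0)
    return table, tally


def transect_cells(lapse: LapseSpec = LapseSpec(),
                   amplitude: float = SEASONAL_AMPLITUDE_K,
                   latitude_deg: float = 46.7) -> list[ClimateCell]:
    """Synthetic site climates for the five transect elevations.

    Built from the station normals (528 mm, 6.6 deg C at 1570 m) with the
    local lapse rates and a synthesized seasonal temperature cycle.
    """
    cells = []
    for site, elev in TRANSECT_ELEVATIONS.items():
        de = elev - STATION_NORMALS["elevation"]
        t_ann = STATION_NORMALS["t_ann"] - lapse.dt_per_100m * de / 100.0
        p_ann = STATION_NORMALS["p_ann"] + lapse.dp_per_100m * de / 100.0
        cells.append(ClimateCell(
            cell_id=site, elevation_m=elev,
            monthly_t=seasonal_cycle(t_ann, amplitude),
            annual_p=p_ann, latitude_deg=latitude_deg,
        ))
    return cells


def calibrate_thresholds(cells: list[ClimateCell] | None = None) -> tuple[float, float]:
    """CWD cut points anchored to the transect site-to-class assignment.

    The two lowest sites must classify severely restricted, the middle site
    drought restricted, and the two highest favorable; with CWD monotone in
    elevation the midpoints between the bracketing site CWDs achieve this:
    cut_lo between S1200 and S1700, cut_hi between S1700 and S2000.
    """
    if cells is None:
        cells = transect_cells()
    bysite = {c.cell_id: annual_cwd(c) for c in cells}
    for lo, hi in [("S1200", "S1700"), ("S1700", "S2000")]:
        if bysite[lo] >= bysite[hi]:
            raise ValueError("site CWDs are not monotone in elevation; "
                             "cannot place cut points")
    cut_lo = 0.5 * (bysite["S1200"] + bysite["S1700"])
    cut_hi = 0.5 * (bysite["S1700"] + bysite["S2000"])
    return cut_lo, cut_hi
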