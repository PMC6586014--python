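"""Scaling of tissue-heat-balance sap-flow records to tree and site level.

THB sensors integrate over the whole sapwood depth and report flow per unit
trunk circumference (kg h-1 cm-1). Tree-level flow is that rate times the
effective circumference (stem circumference minus the bark + phloem annulus),
integrated to daily sums per tree (1 kg of sap = 1 litre), then averaged
(+/- SE) over the trees of a site.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["TreeGeometry", "clip_negative_rates", "scale_to_tree",
           "daily_sap_flow", "site_aggregate"]


@dataclass(frozen=True)
class TreeGeometry:
    """Stem geometry at sensor height (cm)."""

    circumference_cm: float
    bark_phloem_cm: float

    def __post_init__(self) -> None:
        if self.bark_phloem_cm < 0:
            raise ValueError("bark + phloem thickness must be >= 0")
        if self.effective_circumference_cm <= 0:
            raise ValueError("circumference must exceed 2*pi*bark thickness")

    @property
    def effective_circumference_cm(self) -> float:
        """C_eff = C - 2*pi*t_bark: circumference of the conducting xylem."""
        return self.circumference_cm - 2.0 * np.pi * self.bark_phloem_cm


def clip_negative_rates(trace: pd.DataFrame | pd.Series):
    """Clip negative raw rates (night-time sensor noise) to 0.

    Returns ``(clipped, n_clipped)``.
    """
    n = int((trace < 0).sum().sum() if isinstance(trace, pd.DataFrame)
            else (trace < 0).sum())
    return trace.clip(lower=0.0), n


def scale_to_tree(trace: pd.DataFrame | pd.Series, geom: TreeGeometry) -> pd.Series:
    """Tree-level sap flow (kg h-1) from per-circumference sensor rates.

    ``trace`` holds one column per sensor (e.g. north/south); sensors are
    averaged per timestamp before multiplying by the effective circumference.
    Trees with a single sensor are used as-is.
    """
    if isinstance(trace, pd.Series):
        mean_rate = trace
    else:
        if trace.shape[1] == 0:
            raise ValueError("need at least one sensor column")
        mean_rate = trace.mean(axis=1)
    out = mean_rate * geom.effective_circumference_cm
    out.name = "sap_kg_h"
    return out


def daily_sap_flow(tree_rate: pd.Series, min_completeness: float = 0.9) -> pd.DataFrame:
    """Integrate a tree-level rate series (kg h-1) to daily sums (l d-1).

    Step integration: each reading is held for its logging interval. Days
    with fewer valid readings than ``min_completeness`` of the modal count
    are flagged incomplete and set to NaN so they drop out of site means.
    """
    if len(tree_rate) < 2:
        raise ValueError("need at least two readings to infer the interval")
    dt_h = (tree_rate.index[1] - tree_rate.index[0]).total_seconds() / 3600.0
    g = tree_rate.groupby(tree_rate.index.normalize())
    total = g.sum() * dt_h
    counts = g.count()
    expected = counts.max()
    complete = counts >= min_completeness * expected
    out = pd.DataFrame({"sap_l": total.where(complete), "complete": complete})
    out.index.name = "date"
    return out


def site_aggregate(daily_per_tree: pd.DataFrame) -> pd.DataFrame:
    """Site mean +/- standard error of daily sums over trees.

    ``daily_per_tree``: one column per tree, indexed by date. SE = sd/sqrt(n)
    over the trees present that day; missing where n < 2.
    """
    n = daily_per_tree.count(axis=1)
    mean = daily_per_tree.mean(axis=1)
    se = daily_per_tree.std(axis=1, ddof=1) / np.sqrt(n)
    se[n < 2] = np.nan
    return pd.DataFrame({"mean": mean, "se": se, "n": n})
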