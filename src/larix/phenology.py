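"""Gompertz growth phenology of seasonal stem-increment curves.

The seasonal growth line of a tree is summarized by the growth-parameter
Gompertz form

    y(t) = A * exp(-exp( (mu*e/A) * (lam - t) + 1 ))

whose parameters are directly interpretable: A is the upper asymptote
(total yearly growth, um), mu the maximum growth rate (um d-1), lam the lag
phase / start of growth (day of year). The inflection point -- the date of
maximum growth rate -- is analytic in this form:

    I_p = lam + A / (e * mu),   y(I_p) = A / e.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import e as _E

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = ["GompertzFit", "gompertz_curve", "fit_gompertz", "fit_gompertz_table"]


@dataclass(frozen=True)
class GompertzFit:
    """Fitted phenology parameters with diagnostics."""

    A: float
    mu: float
    lam: float
    rss: float
    converged: bool

    @property
    def ip(self) -> float:
        """Inflection point I_p = lam + A/(e*mu) (day of year)."""
        return self.lam + self.A / (_E * self.mu)


def gompertz_curve(t, A: float, mu: float, lam: float):
    """Evaluate the growth-parameter Gompertz curve at times ``t`` (DOY)."""
    if not (A > 0 and mu > 0):
        raise ValueError("Gompertz requires A > 0 and mu > 0")
    t = np.asarray(t, dtype=float)
    return A * np.exp(-np.exp(mu * _E / A * (lam - t) + 1.0))


def _gomp(t, A, mu, lam):
    return A * np.exp(-np.exp(mu * _E / A * (lam - t) + 1.0))


def fit_gompertz(doy, gro, n_starts: int = 8, seed: int | None = 0) -> GompertzFit:
    """Fit the Gompertz curve to a seasonal growth-line series.

    ``gro`` is shifted to start at zero increment before fitting. Initial
    values are data-driven (A = max increment, mu = max daily difference,
    lam = first day exceeding 5% of max) and perturbed for a small
    multistart; the best nonlinear-least-squares solution wins. Degenerate
    seasons (flat series, fewer than 10 days, or no converged start) return
    ``converged=False`` with NaN parameters.
    """
    doy = np.asarray(doy, dtype=float)
    y = np.asarray(gro, dtype=float)
    keep = np.isfinite(doy) & np.isfinite(y)
    doy, y = doy[keep], y[keep]
    order = np.argsort(doy)
    doy, y = doy[order], y[order]
    if len(y) < 10:
        return GompertzFit(np.nan, np.nan, np.nan, np.nan, False)
    # shift to zero increment at the season start; a short baseline mean is
    # used so a single noisy first reading does not bias the asymptote
    y = y - y[: min(5, len(y) // 3)].mean()
    a0 = float(np.max(y))
    if a0 <= 0:
        return GompertzFit(np.nan, np.nan, np.nan, np.nan, False)
    dy = np.diff(y) / np.diff(doy)
    mu0 = float(np.max(dy)) if np.max(dy) > 0 else a0 / (doy[-1] - doy[0])
    above = doy[y > 0.05 * a0]
    lam0 = float(above[0]) if len(above) else float(doy[0])

    rng = np.random.default_rng(seed)
    starts = [(a0, mu0, lam0)]
    for _ in range(n_starts - 1):
        starts.append((
            a0 * rng.uniform(0.7, 1.3),
            mu0 * rng.uniform(0.5, 2.0),
            lam0 + rng.uniform(-15.0, 15.0),
        ))
    span = doy[-1] - doy[0]
    bounds = ([1e-9, 1e-9, doy[0] - span], [10 * a0 + 1, 100 * mu0 + 1, doy[-1]])
    best: tuple[float, np.ndarray] | None = None
    for p0 in starts:
        p0 = (min(max(p0[0], bounds[0][0]), bounds[1][0]),
              min(max(p0[1], bounds[0][1]), bounds[1][1]),
              min(max(p0[2], bounds[0][2]), bounds[1][2]))
        try:
            popt, _ = curve_fit(_gomp, doy, y, p0=p0, bounds=bounds, maxfev=5000)
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((y - _gomp(doy, *popt)) ** 2))
        if best is None or rss < best[0]:
            best = (rss, popt)
    if best is None:
        return GompertzFit(np.nan, np.nan, np.nan, np.nan, False)
    rss, (A, mu, lam) = best
    return GompertzFit(float(A), float(mu), float(lam), rss, True)


def fit_gompertz_table(gro_daily: pd.DataFrame, seed: int | None = 0) -> pd.DataFrame:
    """Fit every (tree_id, year) group of a tidy daily GRO table.

    Expects columns ``tree_id``, ``doy``, ``gro`` and optionally ``year``;
    returns one tidy row per group with A, mu, lam, ip, rss, converged.
    """
    keys = [k for k in ("tree_id", "year") if k in gro_daily.columns]
    rows = []
    for key, grp in gro_daily.groupby(keys) if keys else [((), gro_daily)]:
        fit = fit_gompertz(grp["doy"], grp["gro"], seed=seed)
        rec = dict(zip(keys, key if isinstance(key, tuple) else (key,)))
        rec.update(A=fit.A, mu=fit.mu, lam=fit.lam,
                   ip=fit.ip if fit.converged else np.nan,
                   rss=fit.rss, converged=fit.converged)
        rows.append(rec)
    return pd.DataFrame(rows)
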