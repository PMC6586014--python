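"""Bootstrap principal-components response functions.

Relates a residual site chronology to monthly temperature and precipitation
(previous-year June through current September by default). Monthly climate
predictors are collinear, so coefficients are estimated by principal
components regression: predictors are standardized, PCA is applied, the
chronology is regressed on the retained component scores (Kaiser rule,
eigenvalue > 1, by default), and the coefficients are rotated back to the
monthly predictors. Significance comes from a seeded bootstrap over years
(percentile confidence intervals; a predictor is significant when its CI
excludes zero). When every component is retained the back-rotated solution
equals ordinary least squares on the standardized predictors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ResponseResult", "monthly_climate_matrix", "static_response",
           "moving_response", "DEFAULT_WINDOW"]

_MONTH_ABBR = ["jan", "feb", "mar", "apr", "may", "jun",
               "jul", "aug", "sep", "oct", "nov", "dec"]

#: Default month window: previous-year June ... current September.
#: Entries are (year_offset, month); offset -1 = previous year.
DEFAULT_WINDOW = [(-1, m) for m in range(6, 13)] + [(0, m) for m in range(1, 10)]


@dataclass
class ResponseResult:
    """Per-predictor coefficients with bootstrap confidence intervals.

    ``table`` has one row per climate column: ``coef`` (standardized),
    ``ci_lo``, ``ci_hi``, ``significant`` (CI excludes 0 at ``alpha``).
    """

    table: pd.DataFrame
    n_boot: int
    alpha: float
    n_components: int
    n_years: int
    window: tuple | None = None
    meta: dict = field(default_factory=dict)


def _column_label(var: str, offset: int, month: int) -> str:
    abbr = _MONTH_ABBR[month - 1]
    # capital letters = current year, lower case = previous year
    return f"{var}.{abbr.upper() if offset == 0 else abbr}"


def monthly_climate_matrix(monthly: pd.DataFrame,
                           window=None) -> pd.DataFrame:
    """Lagged monthly climate predictor matrix, one row per chronology year.

    ``monthly``: DataFrame with columns ``t`` (monthly mean temperature) and
    ``p`` (monthly precipitation total), indexed by a MultiIndex
    (year, month) -- or columns ``year``/``month``/``t``/``p``. ``window``
    lists (year_offset, month) pairs; default previous-June .. current-
    September (16 months x 2 variables = 32 columns). Rows with any missing
    cell are dropped.
    """
    if window is None:
        window = DEFAULT_WINDOW
    df = monthly.copy()
    if not isinstance(df.index, pd.MultiIndex):
        df = df.set_index(["year", "month"])
    years = sorted({y for y, _ in df.index})
    cols = {}
    for var in ("t", "p"):
        for offset, month in window:
            label = _column_label(var.upper() if var == "t" else "P", offset, month)
            vals = []
            for y in years:
                key = (y + offset, month)
                vals.append(df[var].get(key, np.nan))
            cols[label] = vals
    X = pd.DataFrame(cols, index=pd.Index(years, name="year"))
    return X.dropna()


def _zscore(a: np.ndarray) -> np.ndarray:
    sd = a.std(axis=0, ddof=1)
    sd = np.where(sd == 0, 1.0, sd)
    return (a - a.mean(axis=0)) / sd


def _pc_rotation(X: np.ndarray, pc_rule: str, cum_var: float):
    """PCA of the standardized predictor matrix, computed once.

    Returns (scores, loadings V_k, k). The rotation is a property of the
    climate matrix alone; the bootstrap re-estimates only the regression on
    these fixed component scores, as in the classical response-function
    algorithm.
    """
    n = X.shape[0]
    Z = _zscore(X)
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    eig = s**2 / (n - 1)  # eigenvalues of the correlation matrix
    if pc_rule == "kaiser":
        k = int(np.sum(eig > 1.0))
    elif pc_rule == "cumvar":
        k = int(np.searchsorted(np.cumsum(eig) / eig.sum(), cum_var) + 1)
    elif pc_rule == "all":
        k = int(np.sum(s > s[0] * 1e-10))
    else:
        raise ValueError(f"unknown pc_rule {pc_rule!r}")
    if k == 0:
        raise ValueError("no principal components retained (all eigenvalues <= 1); "
                         "check predictor matrix scaling")
    scores = U[:, :k] * s[:k]
    return scores, Vt[:k].T, k


def _regress_rotate(scores: np.ndarray, V: np.ndarray, yz: np.ndarray) -> np.ndarray:
    gamma, *_ = np.linalg.lstsq(scores, yz, rcond=None)
    return V @ gamma


def static_response(chronology: pd.Series, X: pd.DataFrame,
                    n_boot: int = 1000, alpha: float = 0.05,
                    seed: int | None = None, pc_rule: str = "kaiser",
                    cum_var: float = 0.9, min_years: int = 30) -> ResponseResult:
    """Static bootstrap response function of a chronology on monthly climate.

    The full-sample point estimate uses all common years; the bootstrap
    resamples years with replacement ``n_boot`` times (default 1000),
    re-running the whole PCR each time, and forms percentile CIs at
    ``alpha``. Deterministic for a fixed ``seed``.
    """
    common = chronology.dropna().index.intersection(X.dropna().index)
    if len(common) < min_years:
        raise ValueError(f"only {len(common)} common years (< {min_years})")
    y = chronology.loc[common].to_numpy(float)
    Xm = X.loc[common].to_numpy(float)
    n = len(common)

    yz = (y - y.mean()) / (y.std(ddof=1) if y.std(ddof=1) > 0 else 1.0)
    scores, V, k = _pc_rotation(Xm, pc_rule, cum_var)
    beta = _regress_rotate(scores, V, yz)

    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, Xm.shape[1]))
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boots[b] = _regress_rotate(scores[idx], V, yz[idx])
    lo = np.nanpercentile(boots, 100 * alpha / 2, axis=0)
    hi = np.nanpercentile(boots, 100 * (1 - alpha / 2), axis=0)
    table = pd.DataFrame({
        "coef": beta, "ci_lo": lo, "ci_hi": hi,
        "significant": (lo > 0) | (hi < 0),
    }, index=X.columns)
    return ResponseResult(table=table, n_boot=n_boot, alpha=alpha,
                          n_components=k, n_years=n)


def moving_response(chronology: pd.Series, X: pd.DataFrame,
                    window: int = 25, step: int = 1, alpha: float = 0.1,
                    n_boot: int = 1000, seed: int | None = None,
                    pc_rule: str = "kaiser", depth: pd.Series | None = None,
                    min_depth: int = 5) -> dict[int, ResponseResult]:
    """Moving-window response functions (default 25-yr window, step 1).

    Returns {window start year: ResponseResult}. Windows whose mean sample
    depth falls below ``min_depth`` trees are excluded when ``depth`` is
    given. Each window draws its bootstrap from an independent substream of
    ``seed``, so results do not depend on which windows are evaluated.
    """
    common = chronology.dropna().index.intersection(X.dropna().index)
    years = np.sort(common.to_numpy())
    if len(years) < window:
        raise ValueError(f"overlap ({len(years)}) shorter than window ({window})")
    results: dict[int, ResponseResult] = {}
    ss = np.random.SeedSequence(seed)
    n_windows = (len(years) - window) // step + 1
    substreams = ss.spawn(n_windows)
    for w, i in enumerate(range(0, len(years) - window + 1, step)):
        yrs = years[i:i + window]
        if depth is not None and depth.reindex(yrs).mean() < min_depth:
            continue
        res = static_response(
            chronology.loc[yrs], X.loc[yrs], n_boot=n_boot, alpha=alpha,
            seed=substreams[w], pc_rule=pc_rule, min_years=window,
        )
        res.window = (int(yrs[0]), int(yrs[-1]))
        results[int(yrs[0])] = res
    return results
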