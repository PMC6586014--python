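"""Tree-ring series processing and chronology construction.

Implements the standard dendrochronological chain: Tucson (RWL) I/O, core
averaging, basal area increment, two-stage ratio detrending (modified
negative exponential, then a Cook-Peters smoothing spline with a 50%
frequency-response cutoff at two-thirds of the series length), AR
prewhitening, Tukey-biweight robust-mean site chronologies, chronology
statistics (mean sensitivity, first-order autocorrelation, rbar, SNR, EPS),
and segment-correlation crossdating quality control.

Ring widths are handled in micrometres throughout; years are integer
calendar years (pandas index). An ensemble of series is a DataFrame with
one column per core/tree and the union of years as index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.interpolate import make_smoothing_spline
from scipy.optimize import curve_fit
from statsmodels.tsa.ar_model import AutoReg

__all__ = [
    "read_rwl", "write_rwl",
    "average_cores_to_tree", "compute_bai",
    "detrend_series", "prewhiten",
    "tukey_biweight_mean", "build_chronology",
    "mean_sensitivity", "ChronStats", "chronology_stats",
    "crossdate_qc",
]


# ---------------------------------------------------------------------------
# Tucson RWL input/output

def read_rwl(path) -> dict[str, pd.Series]:
    """Read a Tucson-format ring-width file into {series_id: Series of um}.

    Handles both common dialects: 0.01 mm units terminated by 999 and
    0.001 mm units terminated by -9999 (auto-detected per series from the
    terminator). Decadal rows: series id, decade start year, up to ten
    values.
    """
    chunks: dict[str, list[tuple[int, int]]] = {}
    terminators: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            sid = line[:8].strip()
            rest = line[8:].split()
            if len(rest) < 2:
                continue
            try:
                year = int(rest[0])
            except ValueError:
                continue  # header line
            vals = []
            for tok in rest[1:]:
                v = int(tok)
                if v in (999, -9999):
                    terminators[sid] = v
                    break
                vals.append(v)
            lst = chunks.setdefault(sid, [])
            for i, v in enumerate(vals):
                lst.append((year + i, v))
    out: dict[str, pd.Series] = {}
    for sid, pairs in chunks.items():
        years = [y for y, _ in pairs]
        vals = np.array([v for _, v in pairs], dtype=float)
        scale = 1.0 if terminators.get(sid) == -9999 else 10.0  # -> um
        out[sid] = pd.Series(vals * scale, index=pd.Index(years, name="year"),
                             name=sid)
    return out


def write_rwl(path, series: dict[str, pd.Series], precision: str = "0.001") -> None:
    """Write ring-width series (um) to a Tucson file.

    ``precision`` "0.001" writes 0.001-mm integers with a -9999 terminator,
    "0.01" writes 0.01-mm integers with a 999 terminator.
    """
    if precision == "0.001":
        scale, term = 1.0, -9999
    elif precision == "0.01":
        scale, term = 10.0, 999
    else:
        raise ValueError("precision must be '0.001' or '0.01'")
    with open(path, "w") as fh:
        for sid, s in series.items():
            s = s.dropna().sort_index()
            years = s.index.to_numpy(int)
            vals = np.round(s.to_numpy(float) / scale).astype(int)
            i = 0
            while i < len(years):
                y = years[i]
                decade_end = (y // 10) * 10 + 10
                row_vals = []
                while i < len(years) and years[i] < decade_end:
                    row_vals.append(vals[i])
                    i += 1
                line = f"{sid:<8s}{y:>4d}" + "".join(f"{v:>6d}" for v in row_vals)
                if i == len(years):
                    line += f"{term:>6d}"
                fh.write(line + "\n")


# ---------------------------------------------------------------------------
# Basic series operations

def average_cores_to_tree(cores: list[pd.Series], name: str | None = None) -> pd.Series:
    """Per-year arithmetic mean of the cores of one tree.

    Years present in only one core use that core's value; zero overlapping
    years between any pair is an error (the cores cannot be crossdated to
    one tree).
    """
    if len(cores) < 1:
        raise ValueError("need at least one core")
    if len(cores) > 1:
        common = cores[0].dropna().index
        for c in cores[1:]:
            common = common.intersection(c.dropna().index)
        if len(common) == 0:
            raise ValueError("cores share no overlapping years")
    df = pd.concat(cores, axis=1)
    out = df.mean(axis=1)
    out.name = name or getattr(cores[0], "name", None)
    return out


def compute_bai(widths_um: pd.Series) -> pd.Series:
    """Basal area increment (mm2 yr-1) from annual ring widths (um).

    BAI_t = pi * (R_t^2 - R_{t-1}^2) with R_t the cumulative radius (mm) at
    the end of year t, assuming the first ring starts at the pith (R_0 = 0).
    The series telescopes: sum(BAI) = pi * R_n^2.
    """
    w_mm = widths_um.astype(float) / 1000.0
    r = w_mm.cumsum()
    r_prev = r.shift(1).fillna(0.0)
    bai = np.pi * (r**2 - r_prev**2)
    bai.name = "bai_mm2"
    return bai


# ---------------------------------------------------------------------------
# Detrending

def _spline_lambda(wavelength: float) -> float:
    # Cubic smoothing-spline penalty whose frequency response is 50% at the
    # given wavelength (years), with unit sample spacing.
    return (wavelength / (2.0 * np.pi)) ** 4


def detrend_series(widths: pd.Series, spline_frac: float = 2.0 / 3.0,
                   min_length: int = 20):
    """Two-stage ratio detrending of one ring-width series.

    Stage 1 removes the biological age trend: a modified negative
    exponential w = a*exp(-b*t) + k (a > 0, b >= 0, k >= 0), falling back to
    a linear regression with non-positive slope, and finally to the
    horizontal mean. Stage 2 removes stand-dynamics variance: a Cook-Peters
    cubic smoothing spline with 50% frequency response at a wavelength of
    ``spline_frac`` times the series length, fitted to the stage-1 ratios.
    Indices are ratios (observed / predicted) at each stage, so the final
    ring-width index is the product of the two ratio stages and has mean
    close to 1.

    Returns ``(rwi, info)`` with ``info`` recording the stage-1 method and
    the spline cutoff wavelength.
    """
    w = widths.dropna().astype(float)
    n = len(w)
    if n < min_length:
        raise ValueError(f"series too short to detrend ({n} < {min_length})")
    t = np.arange(n, dtype=float)
    y = w.to_numpy()

    method = "negexp"
    pred1 = None
    try:
        ymax = max(y.max(), 1e-9)
        p0 = (max(y[0] - y[-1], 0.1 * ymax), 1.0 / n, max(y[-1], 1e-3))
        popt, _ = curve_fit(
            lambda tt, a, b, k: a * np.exp(-b * tt) + k, t, y, p0=p0,
            bounds=([1e-12, 0.0, 0.0], [10 * ymax, 10.0, 10 * ymax]),
            maxfev=5000,
        )
        cand = popt[0] * np.exp(-popt[1] * t) + popt[2]
        if np.all(cand > 0):
            pred1 = cand
    except (RuntimeError, ValueError):
        pass
    if pred1 is None:
        slope, intercept = np.polyfit(t, y, 1)
        cand = slope * t + intercept
        if slope <= 0 and np.all(cand > 0):
            method, pred1 = "linear", cand
        else:
            method, pred1 = "mean", np.full(n, y.mean())

    ratio1 = y / pred1

    wavelength = spline_frac * n
    spl = make_smoothing_spline(t, ratio1, lam=_spline_lambda(wavelength))
    pred2 = spl(t)
    if np.any(pred2 <= 0):
        pred2 = np.full(n, ratio1.mean())
        spline_used = False
    else:
        spline_used = True
    rwi = pd.Series(ratio1 / pred2, index=w.index, name=widths.name)
    info = {"stage1": method, "spline_wavelength_yr": wavelength,
            "spline_used": spline_used}
    return rwi, info


# ---------------------------------------------------------------------------
# Prewhitening

def prewhiten(rwi: pd.Series, max_p: int = 3):
    """Remove serial autocorrelation from a detrended index series.

    Fits AR(p) models for p = 0..``max_p`` (constant included, conditioning
    all fits on the same ``max_p`` initial observations so AIC values are
    comparable) and keeps the AIC-best order. Output is the residuals plus
    the series mean, so the level of the index is preserved; the first
    ``max_p`` years are dropped. Returns ``(residual_series, p)``.

    A constant (zero-variance) series is returned unchanged with a warning.
    """
    x = rwi.dropna().astype(float)
    if x.std(ddof=0) == 0 or len(x) < max_p + 10:
        if x.std(ddof=0) == 0:
            warnings.warn("zero-variance series: prewhitening skipped")
            return rwi.copy(), 0
        raise ValueError("series too short to prewhiten")
    vals = x.to_numpy()
    best_p, best_aic, best_resid = 0, np.inf, None
    for p in range(max_p + 1):
        res = AutoReg(vals, lags=p, trend="c", hold_back=max_p).fit()
        if res.aic < best_aic:
            best_p, best_aic, best_resid = p, res.aic, res.resid
    out = pd.Series(best_resid + vals.mean(), index=x.index[max_p:],
                    name=rwi.name)
    return out, best_p


# ---------------------------------------------------------------------------
# Chronology

def tukey_biweight_mean(values, c: float = 9.0, max_iter: int = 10,
                        tol: float = 1e-8) -> float:
    """Tukey biweight robust mean (c = 9, median start, <= 10 iterations)."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) == 0:
        return np.nan
    m = float(np.median(x))
    for _ in range(max_iter):
        s = float(np.median(np.abs(x - m)))
        if s == 0:
            return m
        u = (x - m) / (c * s)
        w = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
        if w.sum() == 0:
            return m
        m_new = float(np.sum(w * x) / np.sum(w))
        if abs(m_new - m) < tol:
            return m_new
        m = m_new
    return m


def build_chronology(ensemble: pd.DataFrame, robust: bool = True) -> pd.DataFrame:
    """Site chronology: per-year (biweight) mean index with sample depth.

    ``ensemble``: DataFrame of detrended/prewhitened indices, one column per
    series. Returns columns ``index`` and ``depth``.
    """
    agg = (ensemble.apply(lambda row: tukey_biweight_mean(row.to_numpy()), axis=1)
           if robust else ensemble.mean(axis=1))
    depth = ensemble.count(axis=1)
    out = pd.DataFrame({"index": agg, "depth": depth})
    out = out[out["depth"] >= 1]
    return out


# ---------------------------------------------------------------------------
# Chronology statistics

def mean_sensitivity(widths) -> float:
    """Mean sensitivity: mean |2*(w_{t+1} - w_t) / (w_{t+1} + w_t)|."""
    w = np.asarray(pd.Series(widths).dropna(), dtype=float)
    if len(w) < 2:
        return np.nan
    num = 2.0 * np.abs(np.diff(w))
    den = w[1:] + w[:-1]
    return float(np.mean(num / den))


@dataclass(frozen=True)
class ChronStats:
    """Site chronology statistics.

    ms and ac1 are computed on raw widths (before prewhitening); rbar, and
    the derived SNR and EPS, on prewhitened indices over pairwise common
    years.
    """

    ms: float
    ac1: float
    rbar: float
    n_series: int

    @property
    def snr(self) -> float:
        """Signal-to-noise ratio N*rbar / (1 - rbar)."""
        return self.n_series * self.rbar / (1.0 - self.rbar)

    @property
    def eps(self) -> float:
        """Expressed population signal N*rbar / (N*rbar + 1 - rbar)."""
        nr = self.n_series * self.rbar
        return nr / (nr + 1.0 - self.rbar)


def _lag1_autocorr(x: np.ndarray) -> float:
    x = x[np.isfinite(x)]
    if len(x) < 3 or np.std(x) == 0:
        return np.nan
    return float(np.corrcoef(x[:-1], x[1:])[0, 1])


def interseries_rbar(ensemble: pd.DataFrame, min_overlap: int = 30) -> float:
    """Mean pairwise Pearson correlation over common years (>= min_overlap)."""
    cols = ensemble.columns
    rs = []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            pair = ensemble[[cols[i], cols[j]]].dropna()
            if len(pair) < min_overlap:
                continue
            a, b = pair.iloc[:, 0], pair.iloc[:, 1]
            if a.std() == 0 or b.std() == 0:
                continue
            rs.append(float(np.corrcoef(a, b)[0, 1]))
    return float(np.mean(rs)) if rs else np.nan


def chronology_stats(raw: pd.DataFrame, prewhitened: pd.DataFrame,
                     min_overlap: int = 30) -> ChronStats:
    """Chronology statistics for a site ensemble.

    ``raw``: width series (um, columns = trees) for MS and first-order
    autocorrelation (averaged over series); ``prewhitened``: residual index
    series for rbar / SNR / EPS with N = number of series.
    """
    if prewhitened.shape[1] < 2:
        raise ValueError("need >= 2 series for rbar")
    ms = float(np.nanmean([mean_sensitivity(raw[c]) for c in raw.columns]))
    ac1 = float(np.nanmean([_lag1_autocorr(raw[c].to_numpy(float))
                            for c in raw.columns]))
    rbar = interseries_rbar(prewhitened, min_overlap=min_overlap)
    return ChronStats(ms=ms, ac1=ac1, rbar=rbar,
                      n_series=prewhitened.shape[1])


# ---------------------------------------------------------------------------
# Crossdating quality control

def _critical_r(n: int, alpha: float) -> float:
    if n < 3:
        return 1.0
    t = sps.t.ppf(1.0 - alpha, n - 2)
    return float(t / np.sqrt(n - 2 + t**2))


def _shifted_corr(series: pd.Series, master: pd.Series, shift: int) -> tuple[float, int]:
    s = series.copy()
    s.index = s.index + shift
    pair = pd.concat([s, master], axis=1).dropna()
    if len(pair) < 10 or pair.iloc[:, 0].std() == 0 or pair.iloc[:, 1].std() == 0:
        return np.nan, len(pair)
    return float(np.corrcoef(pair.iloc[:, 0], pair.iloc[:, 1])[0, 1]), len(pair)


def crossdate_qc(ensemble: pd.DataFrame, seg_len: int = 50, lag: int = 25,
                 alpha: float = 0.01, max_shift: int = 10,
                 r_min: float | None = None) -> pd.DataFrame:
    """Segment-correlation crossdating check (Cofecha-style).

    Each series is split into segments of ``seg_len`` years overlapping by
    ``seg_len - lag``; each prewhitened segment is correlated against the
    biweight master built from all other series. Segments whose correlation
    falls below ``r_min`` (default: one-tailed critical r at ``alpha``) are
    flagged, with the best lag over +/- ``max_shift`` years suggested. A
    shorter trailing segment is tested as-is and noted.
    """
    report = []
    for col in ensemble.columns:
        others = ensemble.drop(columns=[col])
        if others.shape[1] == 0:
            raise ValueError("crossdating needs >= 2 series")
        master = build_chronology(others)["index"]
        series = ensemble[col].dropna()
        years = series.index.to_numpy()
        if len(years) == 0:
            continue
        starts = list(range(int(years[0]), int(years[-1]) - lag + 2, lag))
        for s0 in starts:
            s1 = min(s0 + seg_len - 1, int(years[-1]))
            seg = series.loc[s0:s1]
            if len(seg) < max(10, seg_len // 3):
                continue
            r, n = _shifted_corr(seg, master, 0)
            crit = r_min if r_min is not None else _critical_r(n, alpha)
            best_lag, best_r = 0, r
            for k in range(-max_shift, max_shift + 1):
                if k == 0:
                    continue
                rk, _ = _shifted_corr(seg, master, k)
                if np.isfinite(rk) and (not np.isfinite(best_r) or rk > best_r):
                    best_lag, best_r = k, rk
            # a segment fails QC if it does not correlate with the master at
            # dating position, or correlates clearly better at another lag
            # (likely missing/double ring)
            flagged = bool(np.isnan(r) or r < crit
                           or (best_lag != 0 and best_r > (r if np.isfinite(r) else -1) + 0.05))
            report.append({
                "series": col, "seg_start": s0, "seg_end": s1, "n": n,
                "r": r, "r_crit": crit, "flagged": flagged,
                "best_lag": best_lag, "best_r": best_r,
                "short_segment": (s1 - s0 + 1) < seg_len,
            })
    return pd.DataFrame(report)
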