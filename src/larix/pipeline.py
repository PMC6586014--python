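"""End-to-end pipeline orchestration from a single config.

Runs the stages synth -> climate -> stem -> sapflow -> phenology -> rings ->
response -> upscale on synthetic inputs (or a subset via ``stages``), writes
tidy CSV outputs per stage plus a JSON manifest recording every parameter
(defaults included) and the SHA-256 hash of each output file. Re-running
with the same config and seed is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from . import microclimate as mc
from . import phenology, response, rings, sapflow, stem, synth, upscale

__all__ = ["DEFAULT_CONFIG", "load_config", "run_pipeline"]

DEFAULT_CONFIG: dict = {
    "seed": 42,
    "year": 2013,
    "output_dir": "pipeline_out",
    "stages": ["synth", "climate", "stem", "sapflow", "phenology",
               "rings", "response", "upscale"],
    "sites": ["S1200", "S1700", "S2000"],
    "trees_per_site": 2,
    "freq": "1h",
    "dendro_noise_sd": 1.0,
    "sapflow": {"circumference_cm": 110.0, "bark_phloem_cm": 1.0},
    "growth_period": {"window": 5, "rate_frac": 0.2, "twd_threshold": 30.0},
    "rings": {"n_trees": 8, "n_years": 90, "start_year": 1925,
              "beta": 0.5, "signal_var": "p", "signal_month": 6,
              "rbar_target": 0.5},
    "response": {"n_boot": 200, "alpha": 0.05},
    "upscale": {"scenario": {"delta_t": 3.2, "delta_p_frac": -0.145}},
}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def load_config(path) -> dict:
    """Load a YAML run config, filling unset keys from DEFAULT_CONFIG."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = _merge(DEFAULT_CONFIG, user)
    return cfg


def _merge(base: dict, over: dict) -> dict:
    out = dict(base)
    for k, v in over.items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path, outputs: dict) -> None:
    df.to_csv(path)
    outputs[path.name] = _sha256(path)


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None) -> dict:
    """Execute the configured stages; returns the run manifest.

    ``config`` may be a dict or a YAML path. Missing input (an unknown stage,
    an unreadable config) raises :class:`PipelineError` naming the stage;
    outputs of completed stages are retained on failure.
    """
    cfg = load_config(config) if not isinstance(config, dict) else _merge(DEFAULT_CONFIG, config)
    out = Path(out_dir or cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    known = DEFAULT_CONFIG["stages"]
    unknown = [s for s in cfg["stages"] if s not in known]
    if unknown:
        raise PipelineError(f"config: unknown stages {unknown}")

    seed = int(cfg["seed"])
    outputs: dict[str, str] = {}
    state: dict = {}
    for stage in known:  # canonical order regardless of config order
        if stage not in cfg["stages"]:
            continue
        try:
            _STAGES[stage](cfg, seed, out, outputs, state)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - re-raise with stage name
            raise PipelineError(f"stage '{stage}' failed: {exc}") from exc

    manifest = {
        "config": cfg,
        "seed": seed,
        "outputs": outputs,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True,
                                                  default=str))
    return manifest


# ---------------------------------------------------------------------------
# stages

def _stage_synth(cfg, seed, out, outputs, state):
    specs = {s.site_id: s for s in synth.default_transect()}
    year = int(cfg["year"])
    met = {}
    for s, site in enumerate(cfg["sites"]):
        spec = specs[site]
        met[site] = synth.gen_microclimate(spec, year, seed, freq=cfg["freq"])
        _write(met[site], out / f"met_{site}.csv", outputs)
    state.update(met=met, specs=specs, year=year)
    # monthly climate + ring widths at the reference site (valley station)
    rcfg = cfg["rings"]
    station = synth.SiteSpec("station", 1310.0)
    monthly = synth.gen_monthly_climate(station, int(rcfg["start_year"]),
                                        int(rcfg["n_years"]),
                                        seed=seed + 1000)
    series, truth = synth.gen_ringwidths(
        monthly, n_trees=int(rcfg["n_trees"]), seed=seed + 2000,
        beta=float(rcfg["beta"]), signal_var=rcfg["signal_var"],
        signal_month=int(rcfg["signal_month"]),
        rbar_target=float(rcfg["rbar_target"]))
    rings.write_rwl(out / "rings.rwl", series)
    outputs["rings.rwl"] = _sha256(out / "rings.rwl")
    _write(monthly, out / "monthly_climate.csv", outputs)
    state.update(monthly=monthly, ring_series=series, ring_truth=truth)


def _stage_climate(cfg, seed, out, outputs, state):
    daily = {}
    for site, met in state["met"].items():
        spec = state["specs"][site]
        filled, report = mc.fill_gaps(met)
        d = mc.aggregate_daily(filled)
        d["pet"] = mc.compute_pet_fao56(d, spec.latitude_deg, spec.elevation_m)
        daily[site] = d
        _write(d, out / f"daily_{site}.csv", outputs)
        if len(report):
            _write(report, out / f"gapfill_{site}.csv", outputs)
    state["daily"] = daily


def _stage_stem(cfg, seed, out, outputs, state):
    gp = cfg["growth_period"]
    rows, daily_stats = [], {}
    season = slice(f"{state['year']}-04-01", f"{state['year']}-10-31")
    for s, site in enumerate(cfg["sites"]):
        d = state["daily"][site].loc[season]
        for t in range(int(cfg["trees_per_site"])):
            A = 900.0 + 300.0 * (s % 3) + 60.0 * t
            truth = (A, 18.0 + 3.0 * s, 135.0 + 4.0 * s)
            circ = synth.gen_dendrometer(truth, d, seed=seed + 10 * s + t,
                                         freq=cfg["freq"],
                                         noise_sd=float(cfg["dendro_noise_sd"]))
            radius = stem.circumference_to_radius(circ)
            part = stem.partition_zero_growth(radius)
            stats = stem.daily_stem_stats(part)
            period = stem.detect_growth_period(
                stats, window=int(gp["window"]), rate_frac=float(gp["rate_frac"]),
                twd_threshold=float(gp["twd_threshold"]))
            tree_id = f"{site}_t{t + 1}"
            daily_stats[tree_id] = stats
            rows.append({"tree_id": tree_id, "site": site, "A_true": A,
                         "mu_true": truth[1], "lam_true": truth[2],
                         "start_doy": period.start_doy, "end_doy": period.end_doy,
                         "empty": period.empty})
            _write(stats, out / f"stem_daily_{tree_id}.csv", outputs)
    _write(pd.DataFrame(rows).set_index("tree_id"),
           out / "growth_periods.csv", outputs)
    state["stem_daily"] = daily_stats
    state["stem_truth"] = {r["tree_id"]: (r["A_true"], r["mu_true"], r["lam_true"])
                           for r in rows}


def _stage_sapflow(cfg, seed, out, outputs, state):
    geom = sapflow.TreeGeometry(float(cfg["sapflow"]["circumference_cm"]),
                                float(cfg["sapflow"]["bark_phloem_cm"]))
    season = slice(f"{state['year']}-05-01", f"{state['year']}-09-30")
    for s, site in enumerate(cfg["sites"]):
        d = state["daily"][site].loc[season]
        per_tree = {}
        for t in range(int(cfg["trees_per_site"])):
            trace = synth.gen_sapflow(d, seed=seed + 100 * s + t, freq=cfg["freq"],
                                      soil_limited=site != "S2000")
            trace, _n_clip = sapflow.clip_negative_rates(trace)
            rate = sapflow.scale_to_tree(trace, geom)
            per_tree[f"t{t + 1}"] = sapflow.daily_sap_flow(rate)["sap_l"]
        daily_df = pd.DataFrame(per_tree)
        agg = sapflow.site_aggregate(daily_df)
        _write(daily_df, out / f"sap_daily_{site}.csv", outputs)
        _write(agg, out / f"sap_site_{site}.csv", outputs)


def _stage_phenology(cfg, seed, out, outputs, state):
    frames = []
    for tree_id, stats in state["stem_daily"].items():
        g = stats["gro_max"].dropna()
        frames.append(pd.DataFrame({
            "tree_id": tree_id, "year": state["year"],
            "doy": g.index.dayofyear, "gro": g.to_numpy(),
        }))
    fits = phenology.fit_gompertz_table(pd.concat(frames), seed=seed)
    _write(fits.set_index("tree_id"), out / "gompertz_fits.csv", outputs)
    state["gompertz_fits"] = fits


def _stage_rings(cfg, seed, out, outputs, state):
    series = state["ring_series"]
    trees: dict[str, pd.Series] = {}
    for tid in sorted({sid[:-1] for sid in series}):
        cores = [series[sid] for sid in series if sid.startswith(tid)]
        trees[tid] = rings.average_cores_to_tree(cores, name=tid)
    raw = pd.DataFrame(trees)
    rwi, pw = {}, {}
    for tid, w in trees.items():
        idx, _info = rings.detrend_series(w)
        rwi[tid] = idx
        pw[tid], _p = rings.prewhiten(idx)
    pw_df = pd.DataFrame(pw)
    chron = rings.build_chronology(pw_df)
    cstats = rings.chronology_stats(raw, pw_df)
    bai = pd.DataFrame({tid: rings.compute_bai(w) for tid, w in trees.items()})
    qc = rings.crossdate_qc(pw_df)
    _write(chron, out / "chronology.csv", outputs)
    _write(bai, out / "bai.csv", outputs)
    if len(qc):
        _write(qc.set_index("series"), out / "crossdate_qc.csv", outputs)
    stats_df = pd.DataFrame([{"ms": cstats.ms, "ac1": cstats.ac1,
                              "rbar": cstats.rbar, "snr": cstats.snr,
                              "eps": cstats.eps, "n_series": cstats.n_series}])
    _write(stats_df, out / "chronology_stats.csv", outputs)
    state.update(chronology=chron, prewhitened=pw_df)


def _stage_response(cfg, seed, out, outputs, state):
    X = response.monthly_climate_matrix(state["monthly"])
    chron = state["chronology"]["index"]
    res = response.static_response(
        chron, X, n_boot=int(cfg["response"]["n_boot"]),
        alpha=float(cfg["response"]["alpha"]), seed=seed + 3000)
    _write(res.table, out / "response_static.csv", outputs)
    state["response"] = res


def _stage_upscale(cfg, seed, out, outputs, state):
    cells = upscale.transect_cells()
    cuts = upscale.calibrate_thresholds(cells)
    scen_cfg = cfg["upscale"]["scenario"]
    scenario = upscale.ScenarioSpec(float(scen_cfg["delta_t"]),
                                    float(scen_cfg["delta_p_frac"]))
    current, tally_now = upscale.classify_grid(cells, cuts)
    future, tally_fut = upscale.classify_grid(cells, cuts, scenario=scenario)
    table = current.join(future[["cwd", "t_ann", "label"]],
                         rsuffix="_scenario")
    _write(table, out / "upscale_transect.csv", outputs)
    tallies = pd.DataFrame({"current": tally_now, "scenario": tally_fut})
    _write(tallies, out / "upscale_tally.csv", outputs)
    state["thresholds"] = cuts


_STAGES = {
    "synth": _stage_synth,
    "climate": _stage_climate,
    "stem": _stage_stem,
    "sapflow": _stage_sapflow,
    "phenology": _stage_phenology,
    "rings": _stage_rings,
    "response": _stage_response,
    "upscale": _stage_upscale,
}
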