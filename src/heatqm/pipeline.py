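"""Composable pipeline stages: simulate -> bias-correct -> evaluate ->
fit-health -> project -> ensemble, driven by one YAML config.

Each stage reads its inputs from and writes its outputs under
``config["outdir"]``, records a provenance line (stage, config hash, seeds,
output checksums, timestamp) in ``manifest.jsonl``, and is deterministic
given the global seed: per-stage and per-model sub-seeds are derived from it
with ``synthdata.derive_seed``, so adding a model never perturbs another
model's stream.
"""

from __future__ import annotations

import hashlib
import json
import logging

from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluate, health, projection, qmap, series, synthdata
from .synthdata import derive_seed

logger = logging.getLogger(__name__)

STAGES = ("simulate", "biascorrect", "evaluate", "fit-health", "project",
          "compare-methods")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "outdir": "results/run",
    "periods": {
        "historical": ["1993-01-01", "2004-12-31"],
        "projection": ["2050-01-01", "2099-12-31"],
        "decades": {"2050s": ["2050-01-01", "2059-12-31"],
                    "2090s": ["2090-01-01", "2099-12-31"]},
    },
    "obs": {},          # overrides for ObsTempConfig fields
    "models": [         # one entry per ensemble member; bias fields as in ModelBiasConfig
        {"name": "M1", "additive_bias": -0.55, "scale_bias": 1.06},
        {"name": "M2", "additive_bias": 0.88, "scale_bias": 1.03},
        {"name": "M3", "additive_bias": -2.25, "scale_bias": 1.05},
    ],
    "warming_trend": 0.5,   # deg C per decade, shared across members
    "biascorrect": {"method": "qdm", "seasonal": True, "grid_step": 0.01,
                    "k_nearest": 10, "n_boot": 10},
    "health": {"exposure_df": 3, "time_knot_spacing": "monthly",
               "lag_window": 3, "erf_slope": 0.01, "dispersion": 1.3,
               "mean_daily_count": 2286.0},
    "projection": {"n_draws": 1000, "day_pairing": "calendar"},
}


def load_config(path=None) -> dict:
    """Merge a YAML config file over the defaults (shallow per section)."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for key, value in user.items():
            if isinstance(value, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(value)
            else:
                cfg[key] = value
    return cfg


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str)
                          .encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _record(outdir: Path, stage: str, config: dict, seeds: dict,
            outputs: list[Path]) -> dict:
    rec = {
        "stage": stage,
        "config_hash": _config_hash(config),
        "seeds": seeds,
        "outputs": {str(p.relative_to(outdir)): _sha256(p) for p in outputs},
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    with open(outdir / "manifest.jsonl", "a") as fh:
        fh.write(json.dumps(rec) + "\n")
    return rec


def _obs_config(config: dict) -> synthdata.ObsTempConfig:
    hist = config["periods"]["historical"]
    fields = {"start_date": hist[0], "end_date": hist[1],
              "seed": derive_seed(config["seed"], "obs")}
    fields.update(config.get("obs", {}))
    return synthdata.ObsTempConfig(**fields)


def _bias_configs(config: dict) -> dict[str, synthdata.ModelBiasConfig]:
    out = {}
    for spec in config["models"]:
        spec = dict(spec)
        name = spec.pop("name")
        spec.setdefault("warming_trend", config.get("warming_trend", 0.0))
        spec["seed"] = derive_seed(config["seed"], "model", name)
        out[name] = synthdata.ModelBiasConfig(**spec)
    return out


def _require(paths: list[Path], stage: str) -> None:
    missing = [str(p) for p in paths if not p.exists()]
    if missing:
        raise FileNotFoundError(f"stage {stage!r} is missing inputs: {missing}")


def stage_simulate(config: dict) -> dict:
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    obs_cfg = _obs_config(config)
    obs = synthdata.gen_observed_temperature(obs_cfg)
    series.write_csv(obs, outdir / "obs_temperature.csv")

    hist = tuple(config["periods"]["historical"])
    proj = tuple(config["periods"]["projection"])
    biases = _bias_configs(config)
    outputs = [outdir / "obs_temperature.csv"]
    for name, bias in biases.items():
        hind, future = synthdata.gen_model_series(obs_cfg, bias, hist, proj)
        series.write_csv(hind, outdir / f"model_{name}_hist.csv")
        series.write_csv(future, outdir / f"model_{name}_proj.csv")
        outputs += [outdir / f"model_{name}_hist.csv", outdir / f"model_{name}_proj.csv"]

    h = config["health"]
    slope = h["erf_slope"]
    gen_cfg = synthdata.HealthGenConfig(
        true_erf=lambda x, s=slope: s * (x - 7.0),
        dispersion=h["dispersion"],
        lag_window=h["lag_window"],
        seed=derive_seed(config["seed"], "health"),
    )
    gen_cfg = synthdata.calibrate_baseline(obs, gen_cfg, h["mean_daily_count"])
    counts = series.warm_season(synthdata.gen_ed_counts(obs, gen_cfg))
    series.write_csv(counts, outdir / "ed_counts.csv")
    outputs.append(outdir / "ed_counts.csv")

    seeds = {"obs": obs_cfg.seed, "health": gen_cfg.seed,
             **{f"model_{n}": b.seed for n, b in biases.items()}}
    synthdata.write_provenance(outdir / "simulate_provenance.json",
                               stage="simulate", seeds=seeds,
                               config={"erf_slope": slope,
                                       "baseline_log_rate": gen_cfg.baseline_log_rate})
    return _record(outdir, "simulate", config, seeds, outputs)


def _correct_model(config: dict, obs: pd.Series, hind: pd.Series,
                   future: pd.Series, method: str, seed: int
                   ) -> tuple[pd.Series, pd.Series]:
    bc = config["biascorrect"]
    # table-based methods use the configured grid; QDM defaults to its
    # full-resolution per-order-statistic grid
    grid = None if method == "qdm" else qmap.quantile_grid(bc["grid_step"])
    kwargs = dict(grid=grid, seasonal=bc["seasonal"], k_nearest=bc["k_nearest"],
                  n_boot=bc["n_boot"], seed=seed)
    corr_hist = qmap.seasonal_fit_apply(method, obs, hind, hind, **kwargs)
    corr_proj = qmap.seasonal_fit_apply(method, obs, hind, future, **kwargs)
    return corr_hist, corr_proj


def stage_biascorrect(config: dict, method: str | None = None) -> dict:
    outdir = Path(config["outdir"])
    method = method or config["biascorrect"]["method"]
    names = [m["name"] for m in config["models"]]
    inputs = [outdir / "obs_temperature.csv"]
    inputs += [outdir / f"model_{n}_{p}.csv" for n in names for p in ("hist", "proj")]
    _require(inputs, "biascorrect")

    obs = series.read_csv(outdir / "obs_temperature.csv")
    outputs = []
    seeds = {}
    for name in names:
        hind = series.read_csv(outdir / f"model_{name}_hist.csv")
        future = series.read_csv(outdir / f"model_{name}_proj.csv")
        seed = derive_seed(config["seed"], "biascorrect", method, name)
        seeds[name] = seed
        corr_hist, corr_proj = _correct_model(config, obs, hind, future, method, seed)
        for tag, s in (("hist", corr_hist), ("proj", corr_proj)):
            path = outdir / f"corrected_{method}_{name}_{tag}.csv"
            series.write_csv(s, path)
            outputs.append(path)
    return _record(outdir, f"biascorrect[{method}]", config, seeds, outputs)


def stage_evaluate(config: dict, method: str | None = None) -> dict:
    outdir = Path(config["outdir"])
    method = method or config["biascorrect"]["method"]
    names = [m["name"] for m in config["models"]]
    inputs = [outdir / "obs_temperature.csv"]
    inputs += [outdir / f"corrected_{method}_{n}_hist.csv" for n in names]
    _require(inputs, "evaluate")
    obs = series.read_csv(outdir / "obs_temperature.csv")
    corrected = {n: series.read_csv(outdir / f"corrected_{method}_{n}_hist.csv")
                 for n in names}
    table = evaluate.metrics_table(obs, corrected)
    path = outdir / f"metrics_{method}.csv"
    table.to_csv(path, index_label="model")
    return _record(outdir, f"evaluate[{method}]", config, {}, [path])


def fit_health_from_files(config: dict) -> tuple[health.HealthModelFit,
                                                 health.ExposureResponse,
                                                 pd.Series, pd.Series]:
    outdir = Path(config["outdir"])
    _require([outdir / "obs_temperature.csv", outdir / "ed_counts.csv"], "fit-health")
    obs = series.read_csv(outdir / "obs_temperature.csv")
    counts = series.read_csv(outdir / "ed_counts.csv")
    h = config["health"]
    spec = health.HealthModelSpec(exposure_df=h["exposure_df"],
                                  time_knot_spacing=h["time_knot_spacing"],
                                  lag_window=h["lag_window"],
                                  use_holidays=False)
    exposure = health.moving_average(obs, spec.lag_window)
    design = health.build_design(exposure, counts.index, spec)
    fit = health.fit_quasipoisson(counts, design)
    erf = health.extract_erf(fit)
    return fit, erf, counts, design.exposure


def stage_fit_health(config: dict) -> dict:
    outdir = Path(config["outdir"])
    fit, erf, _, exposure = fit_health_from_files(config)
    coef_path = outdir / "health_coefficients.csv"
    fit.coefficients.rename("estimate").to_csv(coef_path, index_label="term")
    cov_path = outdir / "health_covariance.csv"
    fit.covariance.to_csv(cov_path, index_label="term")
    lo, hi = erf.observed_range
    curve = erf.curve(np.linspace(lo, hi, 100))
    curve_path = outdir / "exposure_response.csv"
    curve.to_csv(curve_path, index=False)
    logger.info("quasi-Poisson dispersion %.3f; reference exposure %.2f degC",
                fit.dispersion, erf.reference)
    return _record(outdir, "fit-health", config, {},
                   [coef_path, cov_path, curve_path])


def stage_project(config: dict, method: str | None = None,
                  decade: str | None = None) -> dict:
    outdir = Path(config["outdir"])
    method = method or config["biascorrect"]["method"]
    names = [m["name"] for m in config["models"]]
    _require([outdir / f"corrected_{method}_{n}_proj.csv" for n in names], "project")

    fit, erf, counts, exposure = fit_health_from_files(config)
    decades = config["periods"]["decades"]
    targets = {decade: decades[decade]} if decade else decades
    p = config["projection"]
    outputs = []
    for label, (d0, d1) in targets.items():
        future = {}
        for name in names:
            s = series.read_csv(outdir / f"corrected_{method}_{name}_proj.csv")
            s = health.moving_average(s, config["health"]["lag_window"])
            future[name] = s[(s.index >= pd.Timestamp(d0)) & (s.index <= pd.Timestamp(d1))]
        seed = derive_seed(config["seed"], "project", method, label)
        mc = projection.monte_carlo(erf, counts, exposure, future,
                                    n_draws=p["n_draws"], seed=seed,
                                    day_pairing=p["day_pairing"])
        table = projection.summary_table(mc)
        path = outdir / f"projection_{method}_{label}.csv"
        table.to_csv(path, index=False)
        outputs.append(path)
        draws_path = outdir / f"projection_draws_{method}_{label}.csv"
        pd.DataFrame(mc.annual_excess).to_csv(draws_path, index=False)
        outputs.append(draws_path)
    return _record(outdir, f"project[{method}]", config, {"mc": p["n_draws"]}, outputs)


def stage_compare_methods(config: dict) -> dict:
    """Fit-statistic table per method plus between-model SD tables for raw
    and all five methods over the configured decades."""
    outdir = Path(config["outdir"])
    names = [m["name"] for m in config["models"]]
    obs = series.read_csv(outdir / "obs_temperature.csv")

    metric_rows = {}
    raw = {n: series.read_csv(outdir / f"model_{n}_hist.csv") for n in names}
    m = evaluate.metrics_across_models(obs, list(raw.values()))
    metric_rows["raw"] = [m.mbe * 10, m.mae, m.rmse, m.nsd]

    sd_rows = {}
    decades = config["periods"]["decades"]
    raw_proj = {n: series.read_csv(outdir / f"model_{n}_proj.csv") for n in names}
    sd_rows["raw"] = [evaluate.between_model_sd(list(raw_proj.values()),
                                                tuple(pr)).sd_across_models
                      for pr in decades.values()]

    failures = {}
    for method in qmap.METHODS:
        try:
            stage_biascorrect(config, method)
            corr_h = {n: series.read_csv(outdir / f"corrected_{method}_{n}_hist.csv")
                      for n in names}
            mm = evaluate.metrics_across_models(obs, list(corr_h.values()))
            metric_rows[method] = [mm.mbe * 10, mm.mae, mm.rmse, mm.nsd]
            corr_p = [series.read_csv(outdir / f"corrected_{method}_{n}_proj.csv")
                      for n in names]
            sd_rows[method] = [evaluate.between_model_sd(corr_p, tuple(pr)).sd_across_models
                               for pr in decades.values()]
        except Exception as exc:  # keep going; report per-method failures
            failures[method] = str(exc)
            logger.error("method %s failed: %s", method, exc)

    metrics = pd.DataFrame.from_dict(metric_rows, orient="index",
                                     columns=["mbe_x10", "mae", "rmse", "nsd"])
    metrics_path = outdir / "compare_methods_metrics.csv"
    metrics.to_csv(metrics_path, index_label="method")
    sds = pd.DataFrame.from_dict(sd_rows, orient="index",
                                 columns=[f"sd_temp_{d}" for d in decades])
    sd_path = outdir / "compare_methods_between_model_sd.csv"
    sds.to_csv(sd_path, index_label="method")
    rec = _record(outdir, "compare-methods", config, {}, [metrics_path, sd_path])
    if failures:
        rec["failures"] = failures
    return rec


def run_stage(stage_name: str, config: dict) -> dict:
    dispatch = {
        "simulate": stage_simulate,
        "biascorrect": stage_biascorrect,
        "evaluate": stage_evaluate,
        "fit-health": stage_fit_health,
        "project": stage_project,
        "compare-methods": stage_compare_methods,
    }
    if stage_name not in dispatch:
        raise ValueError(f"unknown stage {stage_name!r}; expected one of {STAGES}")
    return dispatch[stage_name](config)


def run_all(config: dict) -> list[dict]:
    records = [stage_simulate(config)]
    records.append(stage_biascorrect(config))
    records.append(stage_evaluate(config))
    records.append(stage_fit_health(config))
    records.append(stage_project(config))
    return records
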