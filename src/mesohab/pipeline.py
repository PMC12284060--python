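"""End-to-end pipeline: configuration, per-member metric derivation,
boundary extraction, series statistics, evaluation, and the run report.

The pipeline ties the modules together in the order a projection analysis
runs them: (optional) synthetic ensemble generation → derived fields →
habitat boundaries → annual series / trends / epoch tests / ensemble
summary → (optional) model-vs-observation evaluation.  Outputs are
NetCDF for gridded results and CSV for tabular ones; every output records
the package version and a hash of the configuration that produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from . import __version__
from .boundaries import HabitatThresholds, compute_boundaries, habitat_area_at_depth
from .evaluation import cosample, evaluate, read_observations
from .fields import (HydroParams, OpticsParams, attenuation_coefficient,
                     buoyancy_frequency_max, euphotic_depth, extract_at_depth,
                     integrate_upper, light_profile, linear_density, phyto_to_chl)
from .grid import DomainMaskParams, ModelGrid, build_domain_mask, domain_area
from .io import read_member, write_dataset, write_member
from .series import (AnnualSeries, annual_spatial_mean, ensemble_mean_spread,
                     epoch_means_ttest, linear_trend)
from .synthetic import (ScenarioParams, default_ensemble_params, generate_grid,
                        generate_member, generate_observations)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs, with defaults matching the
    standard habitat-analysis constants (400 m isobath, 200 km offshore,
    34.5-40 °N, 0.0217 W/m², 63 mmol/m³, 300 m / 150 m / 100 m reference
    depths, epoch windows 2000-2030 and 2070-2100)."""

    members: dict[str, str] | None = None   # member id -> NetCDF path; None => synthesize
    var_map: dict[str, str] = field(default_factory=dict)
    synth_grid: dict = field(default_factory=lambda: {
        "nx": 24, "ny": 36, "shelf_width_cells": 6, "max_depth_m": 3000.0,
        "lat_range": (34.0, 40.5), "lon_range": (-125.0, -121.5)})
    start_year: int = 2000
    end_year: int = 2100
    domain: DomainMaskParams = field(default_factory=DomainMaskParams)
    optics: OpticsParams = field(default_factory=OpticsParams)
    hydro: HydroParams = field(default_factory=HydroParams)
    thresholds: HabitatThresholds = field(default_factory=HabitatThresholds)
    window1: tuple[int, int] = (2000, 2030)
    window2: tuple[int, int] = (2070, 2100)
    weighting: str = "area"
    omit_fallback: bool = False
    temp_reference_depth: float = 150.0
    light_reference_depth: float = 150.0
    upper_integral_depth: float = 100.0
    obs_path: str | None = None
    n_obs_per_year: int = 0                 # >0: generate pseudo-observations
    obs_noise_sd: dict = field(default_factory=lambda: {"temperature": 0.3, "oxygen": 5.0})
    sub_period: tuple[int, int] = (2000, 2013)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        for key, klass in (("domain", DomainMaskParams), ("optics", OpticsParams),
                           ("hydro", HydroParams), ("thresholds", HabitatThresholds)):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = klass(**kwargs[key])
        for key in ("window1", "window2", "sub_period"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        if "synth_grid" in kwargs:
            sg = dict(cls().synth_grid)
            sg.update(kwargs["synth_grid"])
            for key in ("lat_range", "lon_range"):
                sg[key] = tuple(sg[key])
            kwargs["synth_grid"] = sg
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


METRIC_UNITS = {
    "upper_boundary": "m", "lower_boundary": "m", "extent": "m",
    "habitat_area": "km2", "temperature_150m": "degC", "oxygen_300m": "mmol m-3",
    "chl_integral_0_100m": "mg m-2", "light_150m": "W m-2",
    "euphotic_depth": "m", "n2_max": "s-2",
}


def derive_member_metrics(member: xr.Dataset, grid: ModelGrid, config: PipelineConfig
                          ) -> tuple[xr.Dataset, dict[str, xr.DataArray]]:
    """Boundary dataset and the 2-D+time metric fields for one member."""
    optics, thr = config.optics, config.thresholds
    chl = phyto_to_chl(member["phyto"], optics)
    chl_avg = integrate_upper(chl, config.upper_integral_depth, "average")
    chl_int = integrate_upper(chl, config.upper_integral_depth, "integral")
    k = attenuation_coefficient(chl_avg, optics)
    depth_levels = member["depth"].values
    light = light_profile(member["swrad"].astype("float32"), k.astype("float32"),
                          depth_levels, optics)
    # flag light below the sea floor as missing, like every other field
    bottom = xr.DataArray(grid.bottom_depth, dims=("y", "x"))
    light = light.where(light["depth"] <= bottom)

    bnd = compute_boundaries(light, member["oxygen"], grid, thr,
                             omit_fallback=config.omit_fallback)

    density = linear_density(member["temperature"], params=config.hydro)
    n2_max, _ = buoyancy_frequency_max(density, params=config.hydro)

    metrics = {
        "upper_boundary": bnd["upper_depth"],
        "lower_boundary": bnd["lower_depth"],
        "extent": bnd["extent"],
        "temperature_150m": extract_at_depth(member["temperature"], config.temp_reference_depth),
        "oxygen_300m": extract_at_depth(member["oxygen"], thr.reference_depth_for_area),
        "chl_integral_0_100m": chl_int,
        "light_150m": extract_at_depth(light, config.light_reference_depth),
        "euphotic_depth": euphotic_depth(k),
        "n2_max": n2_max,
    }
    return bnd, metrics


def _annualize_scalar(series_1d: xr.DataArray, metric: str, member: str) -> AnnualSeries:
    t = pd.DatetimeIndex(series_1d["time"].values)
    df = pd.DataFrame({"year": t.year, "value": series_1d.values}).groupby("year")["value"]
    return AnnualSeries(df.mean().index.to_numpy(), df.mean().to_numpy(),
                        metric=metric, member=member, area_weighted=False)


def run_pipeline(config: PipelineConfig, output_dir) -> dict:
    """Execute the full analysis and write the report bundle.

    Writes per-member boundary NetCDFs, tidy CSVs (annual series, trends,
    epoch comparisons, ensemble summary), an optional evaluation CSV, a
    provenance YAML, and a text report of the headline habitat metrics.
    Returns the in-memory bundle as a dict.
    """
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    logger.info("pipeline run: config hash %s, seed %d", chash, config.seed)

    # --- inputs ---------------------------------------------------------
    if config.members:
        grids_members = {m: read_member(p, config.var_map) for m, p in config.members.items()}
        grid = next(iter(grids_members.values()))[0]
        members = {m: ds for m, (g, ds) in grids_members.items()}
    else:
        grid = generate_grid(**config.synth_grid)
        members = {}
        for p in default_ensemble_params(config.seed):
            members[p.member] = generate_member(grid, p, optics=config.optics,
                                                start_year=config.start_year,
                                                end_year=config.end_year)
    if len(members) < 2:
        logger.warning("fewer than 2 members: ensemble statistics will be skipped")

    mask = build_domain_mask(grid, config.domain)
    total_area = domain_area(grid, mask)

    # --- per-member metrics ----------------------------------------------
    annual: list[AnnualSeries] = []
    trend_rows, epoch_rows = [], []
    per_metric: dict[str, dict[str, AnnualSeries]] = {}
    for mname, mds in members.items():
        bnd, metrics = derive_member_metrics(mds, grid, config)
        write_dataset(bnd, output_dir / f"boundaries_{mname}.nc", chash)
        area_series = habitat_area_at_depth(mds["oxygen"], grid, mask, config.thresholds)
        series_for_member = {
            name: annual_spatial_mean(da, grid, mask, weighting=config.weighting,
                                      metric=name, member=mname)
            for name, da in metrics.items()
        }
        series_for_member["habitat_area"] = _annualize_scalar(area_series, "habitat_area", mname)
        for name, s in series_for_member.items():
            annual.append(s)
            per_metric.setdefault(name, {})[mname] = s
            tr = linear_trend(s)
            trend_rows.append({"member": mname, "metric": name, **tr.__dict__})
            ep = epoch_means_ttest(s, config.window1, config.window2)
            epoch_rows.append({"member": mname, "metric": name,
                               "mean1": ep.mean1, "mean2": ep.mean2,
                               "difference": ep.difference,
                               "t_statistic": ep.t_statistic, "p_value": ep.p_value})

    # --- ensemble statistics ---------------------------------------------
    ensemble_rows = []
    headline: dict[str, dict] = {}
    if len(members) >= 2:
        for name, by_member in per_metric.items():
            summ = ensemble_mean_spread(list(by_member.values()))
            ensemble_rows.append(summ.to_frame())
            ens_series = AnnualSeries(summ.years, summ.ensemble_mean, metric=name,
                                      member="ensemble-mean", area_weighted=False)
            tr = linear_trend(ens_series)
            trend_rows.append({"member": "ensemble-mean", "metric": name, **tr.__dict__})
            ep = epoch_means_ttest(ens_series, config.window1, config.window2)
            epoch_rows.append({"member": "ensemble-mean", "metric": name,
                               "mean1": ep.mean1, "mean2": ep.mean2,
                               "difference": ep.difference,
                               "t_statistic": ep.t_statistic, "p_value": ep.p_value})
            headline[name] = {"mean1": ep.mean1, "mean2": ep.mean2,
                              "difference": ep.difference, "trend": tr.slope,
                              "r_squared": tr.r_squared, "p_value": ep.p_value}

        # horizontal habitat area evaluated on the ensemble-mean oxygen
        # field (per-member areas are kept above; the headline loss
        # signature lives in the ensemble mean)
        ens_oxygen = sum(ds["oxygen"] for ds in members.values()) / len(members)
        ens_area = habitat_area_at_depth(ens_oxygen, grid, mask, config.thresholds)
        ens_series = _annualize_scalar(ens_area, "habitat_area", "ensemble-field")
        annual.append(ens_series)
        tr = linear_trend(ens_series)
        trend_rows.append({"member": "ensemble-field", "metric": "habitat_area", **tr.__dict__})
        ep = epoch_means_ttest(ens_series, config.window1, config.window2)
        epoch_rows.append({"member": "ensemble-field", "metric": "habitat_area",
                           "mean1": ep.mean1, "mean2": ep.mean2, "difference": ep.difference,
                           "t_statistic": ep.t_statistic, "p_value": ep.p_value})
        headline["habitat_area"] = {"mean1": ep.mean1, "mean2": ep.mean2,
                                    "difference": ep.difference, "trend": tr.slope,
                                    "r_squared": tr.r_squared, "p_value": ep.p_value}

    # --- evaluation (optional) -------------------------------------------
    eval_df = None
    if config.obs_path or config.n_obs_per_year > 0:
        if config.obs_path:
            obs = read_observations(config.obs_path)
        else:
            first = next(iter(members.values()))
            obs = generate_observations(first, grid, config.n_obs_per_year,
                                        noise_sd=config.obs_noise_sd,
                                        seed=config.seed + 1000)
        cos = {m: cosample(ds, grid, obs) for m, ds in members.items()}
        eval_df = evaluate(cos, sub_period=config.sub_period)
        _write_csv(eval_df, output_dir / "evaluation.csv", chash)

    # --- tabular outputs --------------------------------------------------
    annual_df = pd.concat([s.to_frame() for s in annual], ignore_index=True)
    trends_df = pd.DataFrame(trend_rows)
    epochs_df = pd.DataFrame(epoch_rows)
    _write_csv(annual_df, output_dir / "annual_series.csv", chash)
    _write_csv(trends_df, output_dir / "trends.csv", chash)
    _write_csv(epochs_df, output_dir / "epochs.csv", chash)
    ensemble_df = None
    if ensemble_rows:
        ensemble_df = pd.concat(ensemble_rows, ignore_index=True)
        _write_csv(ensemble_df, output_dir / "ensemble_summary.csv", chash)

    with open(output_dir / "provenance.yaml", "w") as fh:
        yaml.safe_dump({"package_version": __version__, "config_hash": chash,
                        "seed": config.seed, "config": config.to_dict()},
                       fh, default_flow_style=False)

    report = _format_report(headline, total_area, config, chash)
    (output_dir / "report.txt").write_text(report)

    return {"grid": grid, "mask": mask, "domain_area_km2": total_area,
            "annual": annual_df, "trends": trends_df, "epochs": epochs_df,
            "ensemble": ensemble_df, "evaluation": eval_df,
            "headline": headline, "report": report, "config_hash": chash}


def _write_csv(df: pd.DataFrame, path: Path, chash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# mesohab {__version__} config={chash}\n")
        df.to_csv(fh, index=False, float_format="%.10g")


def _format_report(headline: dict, total_area: float, config: PipelineConfig,
                   chash: str) -> str:
    w1, w2 = config.window1, config.window2
    lines = [
        f"mesohab {__version__} habitat report (config {chash}, seed {config.seed})",
        f"analysis domain area: {total_area:.0f} km2",
        f"epoch windows: {w1[0]}-{w1[1]} vs {w2[0]}-{w2[1]}",
        "",
    ]
    if not headline:
        lines.append("single-member run: no ensemble statistics")
        return "\n".join(lines) + "\n"
    for name in ("upper_boundary", "lower_boundary", "extent"):
        if name in headline:
            h = headline[name]
            lines.append(
                f"{name:>16s}: {h['mean1']:8.1f} -> {h['mean2']:8.1f} m "
                f"(diff {h['difference']:+7.1f} m, trend {h['trend']:+.3f} m/yr, "
                f"R2 {h['r_squared']:.2f}, p {h['p_value']:.3g})")
    if "extent" in headline and headline["extent"]["mean1"] != 0:
        pct = 100.0 * headline["extent"]["difference"] / headline["extent"]["mean1"]
        lines.append(f"{'extent change':>16s}: {pct:+.1f}% of the early-century mean")
    if "habitat_area" in headline:
        h = headline["habitat_area"]
        pct = 100.0 * h["difference"] / h["mean1"] if h["mean1"] else float("nan")
        lines.append(
            f"{'habitat_area':>16s}: {h['mean1']:.0f} -> {h['mean2']:.0f} km2 "
            f"({pct:+.1f}% at {config.thresholds.reference_depth_for_area:.0f} m)")
    return "\n".join(lines) + "\n"


def synthesize_to_files(config: PipelineConfig, output_dir) -> list[Path]:
    """Generate the synthetic ensemble and write one NetCDF per member
    plus a provenance sidecar; returns the written paths."""
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    grid = generate_grid(**config.synth_grid)
    paths = []
    prov = {"package_version": __version__, "config_hash": chash,
            "seed": config.seed, "members": {}}
    for p in default_ensemble_params(config.seed):
        ds = generate_member(grid, p, optics=config.optics,
                             start_year=config.start_year, end_year=config.end_year)
        path = output_dir / f"member_{p.member}.nc"
        write_member(ds, grid, path, chash)
        prov["members"][p.member] = asdict(p)
        paths.append(path)
    with open(output_dir / "synth_provenance.yaml", "w") as fh:
        yaml.safe_dump(prov, fh, default_flow_style=False)
    return paths
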