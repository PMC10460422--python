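"""End-to-end orchestration: generate -> expose -> forecast -> burden -> decompose.

The pipeline runs the full synthetic study: it generates every input with
seeded generators, composes and calibrates PM2.5 fields, aggregates them to
region-level population-weighted concentrations with multi-model intervals,
forecasts cause-specific mortality through the hinged-SDI model with
envelope constraining, computes attributable deaths with propagated bounds,
and decomposes the change over the projection horizon into its four
drivers.  Every stage writes tidy outputs plus a manifest recording the
configuration hash and per-stage seeds; rerunning an identical
configuration reproduces outputs bit-identically.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from . import burden as burden_mod
from . import decomposition as decomp_mod
from . import exposure, io, mortality, risk, synthetic
from .schema import AGE_BANDS, ALL_CAUSE, CAUSE_LEVEL, LEVEL2_CAUSES, \
    PM25_CAUSES, GroundTruth, ScenarioSpec

logger = logging.getLogger(__name__)

STAGES = ("generate", "expose", "forecast", "burden", "decompose")


@dataclass
class RunConfig:
    """Everything a reproducible run needs, serialisable to YAML."""

    seed: int = 0
    regions: list[str] = field(default_factory=lambda: ["R1", "R2", "R3", "R4"])
    grid_shape: tuple[int, int] = (12, 12)
    scenario_names: list[str] = field(
        default_factory=lambda: ["SSP1-2.6", "SSP2-4.5", "SSP3-7.0", "SSP5-8.5"])
    #: per-scenario multiplicative concentration drift per year
    concentration_trends: dict[str, float] = field(default_factory=lambda: {
        "SSP1-2.6": -0.03, "SSP2-4.5": -0.015, "SSP3-7.0": 0.005,
        "SSP5-8.5": -0.02})
    #: per-scenario aging drift of the age-proportion vector
    aging_drifts: dict[str, float] = field(default_factory=lambda: {
        "SSP1-2.6": 0.012, "SSP2-4.5": 0.012, "SSP3-7.0": 0.008,
        "SSP5-8.5": 0.012})
    n_models: int = 3
    #: interannual (non-trend) variability of the aerosol fields
    interannual_sd: float = 0.05
    #: scale on the per-age mortality time trends (0 freezes them)
    theta_scale: float = 1.0
    #: annual gain of the sociodemographic index (0 freezes development)
    sdi_annual_gain: float = 0.008
    #: innovation scale of the generative mortality residual process
    mortality_noise_sd: float = 0.04
    history_years: list[int] = field(
        default_factory=lambda: list(range(2000, 2020)))
    forecast_years: list[int] = field(
        default_factory=lambda: list(range(2020, 2036)))
    baseline_window: tuple[int, int] = (2015, 2019)
    base_population: int = 5_000_000
    arima_order: tuple[int, int, int] = (1, 0, 0)
    residual_model: str = "arima"  # or "white_noise"
    constrain_orientation: str = "constrain"  # or "as_printed"
    ci_mode: str = "prediction"  # or "as_printed"
    interval_mode: str = "as_printed"  # ensemble interval mode
    smoothing_window: int = 5
    n_rr_draws: int = 100
    decomposition_periods: list[tuple[int, int]] | None = None
    #: decompose between smoothed (reporting-layer) or raw annual endpoints
    decompose_smoothed: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        d["baseline_window"] = list(self.baseline_window)
        d["arima_order"] = list(self.arima_order)
        if self.decomposition_periods is not None:
            d["decomposition_periods"] = [list(p) for p in
                                          self.decomposition_periods]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key in ("grid_shape", "baseline_window", "arima_order"):
            if key in d:
                d[key] = tuple(d[key])
        if d.get("decomposition_periods"):
            d["decomposition_periods"] = [tuple(p) for p in
                                          d["decomposition_periods"]]
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def scenario_specs(self) -> list[ScenarioSpec]:
        years = tuple(self.history_years + self.forecast_years)
        return [
            ScenarioSpec(
                name=name, years=years,
                concentration_trend=self.concentration_trends.get(name, 0.0),
                aging_drift=self.aging_drifts.get(name, 0.0),
                n_models=self.n_models,
            )
            for name in self.scenario_names
        ]


def stage_seeds(master_seed: int) -> dict[str, int]:
    """Deterministic per-stage seeds below 2**31 derived from one master."""
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(len(STAGES) + 3)
    names = list(STAGES) + ["sdi", "demography", "observations"]
    return {name: int(child.generate_state(1)[0] % (2**31))
            for name, child in zip(names, children)}


def _region_raster(grid_shape, n_regions: int) -> np.ndarray:
    rows, cols = grid_shape
    flat = np.arange(rows * cols) * n_regions // (rows * cols)
    return flat.reshape(rows, cols)


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run all five stages; returns the manifest dictionary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    manifest: dict = {
        "config_hash": io.config_hash(config.to_dict()),
        "seed": config.seed,
        "stage_seeds": seeds,
        "stages": [],
        "outputs": {},
    }
    config.to_yaml(outdir / "config.yaml")

    state: dict = {}
    for stage in STAGES:
        t0 = time.perf_counter()
        logger.info("stage %s: start", stage)
        _STAGE_FUNCS[stage](config, seeds, state, outdir, manifest)
        dt = time.perf_counter() - t0
        manifest["stages"].append({"name": stage, "seconds": round(dt, 3)})
        logger.info("stage %s: done in %.2fs", stage, dt)

    io.write_manifest(manifest, outdir / "manifest.yaml")
    return manifest


def _stage_generate(config, seeds, state, outdir, manifest):
    inputs = outdir / "inputs"
    inputs.mkdir(exist_ok=True)
    specs = config.scenario_specs()
    regions = config.regions
    raster = _region_raster(config.grid_shape, len(regions))
    labels = dict(enumerate(regions))
    all_years = config.history_years + config.forecast_years

    truth = GroundTruth(
        beta1=-2.0, beta2=-0.8,
        theta_a={a: config.theta_scale * (-0.012 + 0.0012 * i)
                 for i, a in enumerate(AGE_BANDS)},
        phi=0.4, sigma=config.mortality_noise_sd,
    )
    sdi = synthetic.generate_sdi(regions, all_years, seed=seeds["sdi"],
                                 annual_gain=config.sdi_annual_gain)
    history = synthetic.generate_mortality_history(
        truth, regions, config.history_years,
        sdi[sdi["year"].isin(config.history_years)], seed=seeds["generate"])
    curves = synthetic.generate_rr_curves(
        PM25_CAUSES, n_draws=config.n_rr_draws, seed=seeds["generate"])

    fields = {}
    demog = {}
    for spec in specs:
        fields[spec.name] = synthetic.generate_aerosol_fields(
            spec, config.grid_shape, seed=seeds["generate"],
            interannual_sd=config.interannual_sd)
        demog[spec.name] = synthetic.generate_demography(
            regions, spec, {r: config.base_population for r in regions},
            seed=seeds["demography"])
    pop_grid = synthetic.generate_population(
        config.grid_shape, raster,
        {i: config.base_population for i in labels}, seed=seeds["generate"])

    # synthetic "observed" baseline: the composed field times a smooth
    # multiplicative bias, emulating model underestimation of observations
    rng = np.random.default_rng(seeds["observations"])
    bias = xr.DataArray(
        1.2 + 0.2 * rng.random(config.grid_shape), dims=("lat", "lon"))
    obs = {}
    lo, hi = config.baseline_window
    for spec in specs:
        est = exposure.compose_pm25(fields[spec.name])
        baseline = est.sel(year=slice(lo, hi)).mean("member")
        obs[spec.name] = (baseline * bias).assign_coords(
            lat=est["lat"], lon=est["lon"])
    state.update(sdi=sdi, history=history, curves=curves, fields=fields,
                 demog=demog, pop_grid=pop_grid, raster=raster,
                 labels=labels, obs=obs, truth=truth)

    io.write_netcdf(pop_grid, inputs / "population.nc")
    sdi.to_csv(inputs / "sdi.csv", index=False)
    history.to_csv(inputs / "mortality_history.csv", index=False)
    risk.write_rr_curves(curves, inputs / "rr_curves.csv")
    pd.concat(demog.values()).to_csv(inputs / "demography.csv", index=False)
    for name, ds in fields.items():
        io.write_netcdf(ds, inputs / f"aerosol_{name}.nc")
    io.write_region_mask(
        state_mask(raster, pop_grid), labels,
        inputs / "region_mask.nc", inputs / "region_labels.csv")
    io.write_manifest(
        {"seed": config.seed, "stage_seeds": seeds,
         "config_hash": manifest["config_hash"]},
        inputs / "inputs_manifest.yaml")
    manifest["outputs"]["inputs"] = sorted(
        p.name for p in inputs.iterdir())


def state_mask(raster, pop_grid):
    return xr.DataArray(raster, dims=("lat", "lon"),
                        coords={"lat": pop_grid["lat"], "lon": pop_grid["lon"]})


def _stage_expose(config, seeds, state, outdir, manifest):
    out = outdir / "exposure"
    out.mkdir(exist_ok=True)
    mask = state_mask(state["raster"], state["pop_grid"])
    rows = []
    for name, ds in state["fields"].items():
        est = exposure.compose_pm25(ds)
        lo, hi = config.baseline_window
        calibrated = exposure.calibrate(
            est, est, state["obs"][name], baseline_window=(lo, hi))
        weighted = exposure.population_weighted_concentration(
            calibrated, state["pop_grid"], mask, state["labels"])
        for region in weighted["region"].values:
            for year in weighted["year"].values:
                members = weighted.sel(region=region, year=year).values
                ival = exposure.ensemble_interval(
                    members, mode=config.interval_mode)
                rows.append({
                    "region": str(region), "year": int(year),
                    "scenario": name, "mean": ival.mean,
                    "lower": max(ival.lower, 0.0), "upper": ival.upper,
                })
    conc = pd.DataFrame(rows)
    conc.to_csv(out / "population_weighted_pm25.csv", index=False)
    state["conc"] = conc
    manifest["outputs"]["exposure"] = ["population_weighted_pm25.csv"]


def _stage_forecast(config, seeds, state, outdir, manifest):
    out = outdir / "forecast"
    out.mkdir(exist_ok=True)
    history, sdi = state["history"], state["sdi"]
    future_sdi = sdi[sdi["year"].isin(config.forecast_years)]
    causes = sorted(set(history["cause"]), key=lambda c: (CAUSE_LEVEL[c], c))
    forecasts = {}
    for cause in causes:
        fit = mortality.fit_trend(history, sdi, cause)
        residual_models = mortality.fit_stratum_residuals(
            fit, order=config.arima_order, model=config.residual_model)
        forecasts[cause] = mortality.forecast_rates(
            fit, residual_models, future_sdi, config.forecast_years,
            ci_mode=config.ci_mode)

    level2 = pd.concat([forecasts[c] for c in LEVEL2_CAUSES], ignore_index=True)
    envelope = forecasts[ALL_CAUSE]
    level2_con = mortality.constrain_level2(
        level2, envelope, extra_cols=("lower", "upper"),
        orientation=config.constrain_orientation)
    level3 = pd.concat(
        [forecasts[c] for c in causes if CAUSE_LEVEL[c] == 3],
        ignore_index=True)
    level3_con = mortality.constrain_level3(
        level3, level2_con, extra_cols=("lower", "upper"),
        orientation=config.constrain_orientation)

    constrained = pd.concat([envelope, level2_con, level3_con],
                            ignore_index=True)
    constrained["cause_level"] = constrained["cause"].map(CAUSE_LEVEL)
    constrained.to_csv(out / "constrained_rates.csv", index=False)
    state["rates"] = level3_con[level3_con["cause"].isin(PM25_CAUSES)]
    manifest["outputs"]["forecast"] = ["constrained_rates.csv"]


def _stage_burden(config, seeds, state, outdir, manifest):
    out = outdir / "burden"
    out.mkdir(exist_ok=True)
    paf = risk.paf_table(state["curves"], state["conc"], ages=AGE_BANDS)
    # attributable deaths are computed for the projection years, where
    # constrained forecast rates exist
    future = paf["year"].isin(config.forecast_years)
    pieces = []
    for name, demog in state["demog"].items():
        rates = state["rates"].copy()
        rates["scenario"] = name
        piece = burden_mod.compute_dapp(
            paf[(paf["scenario"] == name) & future], demog, rates)
        pieces.append(piece)
    result = pd.concat(pieces, ignore_index=True)
    result.to_csv(out / "dapp_strata.csv", index=False)

    national = burden_mod.aggregate(result, ["scenario", "year"])
    national = burden_mod.smooth_reporting(
        national, ("deaths_mean", "deaths_lower", "deaths_upper"),
        window=config.smoothing_window, by=["scenario"])
    national.to_csv(out / "dapp_national.csv", index=False)
    demog_all = pd.concat(state["demog"].values(), ignore_index=True)
    burden_mod.per_capita(result, demog_all).to_csv(
        out / "dapp_per_capita.csv", index=False)
    burden_mod.older_share_by_disease(result).to_csv(
        out / "older_share.csv", index=False)
    state["burden"] = result
    state["paf"] = paf
    manifest["outputs"]["burden"] = [
        "dapp_strata.csv", "dapp_national.csv", "dapp_per_capita.csv",
        "older_share.csv"]


def _factor_state(state, config, scenario: str, year: int
                  ) -> decomp_mod.FactorState:
    demog = state["demog"][scenario]
    d = demog[demog["year"] == year]
    agep = d.set_index(["region", "age"])["agep"]
    pop = d.drop_duplicates("region").set_index("region")["pop"].astype(float)
    paf = state["paf"]
    p = paf[paf["scenario"] == scenario]
    rates = state["rates"].rename(columns={"cause": "disease"})
    if config.decompose_smoothed:
        # endpoints taken from the reporting-layer smoothed series
        p = burden_mod.smooth_reporting(
            p, ("paf_mean",), window=config.smoothing_window,
            by=["region", "disease", "age"])
        rates = burden_mod.smooth_reporting(
            rates, ("rate",), window=config.smoothing_window,
            by=["region", "disease", "age"])
    paf_s = (p[p["year"] == year]
             .set_index(["region", "disease", "age"])["paf_mean"])
    rate_s = (rates[rates["year"] == year]
              .set_index(["region", "disease", "age"])["rate"])
    return decomp_mod.FactorState(agep=agep, pop=pop, paf=paf_s, rate=rate_s)


def _stage_decompose(config, seeds, state, outdir, manifest):
    out = outdir / "decomposition"
    out.mkdir(exist_ok=True)
    years = config.forecast_years
    periods = config.decomposition_periods
    if periods is None:
        mid = years[len(years) // 2]
        periods = [(years[0], mid), (mid, years[-1])]
    frames = []
    for scenario in config.scenario_names:
        states = {y: _factor_state(state, config, scenario, y)
                  for y in sorted({y for p in periods for y in p})}
        results = decomp_mod.period_decomposition(states, periods)
        for res in results:
            frame = res.to_frame()
            frame.insert(0, "scenario", scenario)
            frame["net_change"] = res.net_change
            frames.append(frame)
    table = pd.concat(frames, ignore_index=True)
    table.to_csv(out / "driver_contributions.csv", index=False)
    state["decomposition"] = table
    manifest["outputs"]["decomposition"] = ["driver_contributions.csv"]


_STAGE_FUNCS = {
    "generate": _stage_generate,
    "expose": _stage_expose,
    "forecast": _stage_forecast,
    "burden": _stage_burden,
    "decompose": _stage_decompose,
}


def validate_inputs(input_dir) -> dict:
    """Schema and invariant checks over a generated input bundle.

    Returns ``{"n_issues": int, "issues": [str, ...]}``; zero issues means
    every table and field passed.
    """
    input_dir = Path(input_dir)
    issues: list[str] = []

    demog_path = input_dir / "demography.csv"
    if demog_path.exists():
        demog = pd.read_csv(demog_path)
        sums = demog.groupby(["region", "year", "scenario"])["agep"].sum()
        bad = sums[(sums - 1.0).abs() > 1e-9]
        for key, val in bad.items():
            issues.append(f"demography: age proportions sum to {val:.6f} at {key}")
        if (demog["pop"] < 0).any():
            issues.append("demography: negative population")
    else:
        issues.append("demography.csv missing")

    hist_path = input_dir / "mortality_history.csv"
    if hist_path.exists():
        hist = pd.read_csv(hist_path)
        if (hist["rate"] <= 0).any():
            issues.append("mortality history: non-positive rates")
    else:
        issues.append("mortality_history.csv missing")

    sdi_path = input_dir / "sdi.csv"
    if sdi_path.exists():
        sdi = pd.read_csv(sdi_path)
        if ((sdi["sdi"] < 0) | (sdi["sdi"] > 1)).any():
            issues.append("sdi: values outside [0, 1]")

    curves_path = input_dir / "rr_curves.csv"
    if curves_path.exists():
        try:
            risk.read_rr_curves(curves_path)
        except ValueError as exc:
            issues.append(f"rr curves: {exc}")

    for nc in sorted(input_dir.glob("aerosol_*.nc")):
        ds = io.read_netcdf(nc)
        for name in ds.data_vars:
            arr = ds[name].values
            if (arr < 0).any():
                cells = np.argwhere(arr < 0)[:5]
                issues.append(
                    f"{nc.name}: negative {name} at indices {cells.tolist()}")
    return {"n_issues": len(issues), "issues": issues}
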