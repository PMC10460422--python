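"""Generators for every pipeline input, with known ground truth.

Real inputs to this kind of burden analysis are climate-model aerosol
fields, gridded census populations, registry mortality series and
meta-regression risk curves.  The generators here emulate their statistical
structure — smooth non-negative concentration fields, log-normal-ish
population surfaces, a three-level cause hierarchy, monotone concave risk
curves, and mortality following a hinged development-index regression with
per-age trends and AR residuals — so that every downstream stage can be
exercised end-to-end and parameters can be recovered against known truth.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import xarray as xr
from scipy import ndimage

from .risk import RRCurve
from .schema import (
    AGE_BANDS,
    ALL_CAUSE,
    CAUSE_LEVEL,
    HIERARCHY,
    LEVEL2_CAUSES,
    PARENT,
    PM25_CAUSES,
    GroundTruth,
    ScenarioSpec,
)

#: Typical component magnitudes (µg/m³) for a polluted continental region.
COMPONENT_LEVELS = {"BC": 2.0, "OA": 8.0, "SO4": 6.0, "SS": 3.0, "dust": 5.0}

#: Spatial smoothness (grid cells) of generated fields; the true spatial
#: covariance of climate-model output is not targeted, only plausibility.
SMOOTHNESS_CELLS = 2.0


def _smooth_noise(rng: np.random.Generator, shape, scale=SMOOTHNESS_CELLS):
    """Low-pass-filtered standard normal field (Gaussian blur of white noise)."""
    white = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(white, sigma=scale, mode="wrap")
    # restore unit variance lost to smoothing
    sd = smooth.std()
    return smooth / sd if sd > 0 else smooth


def generate_aerosol_fields(
    spec: ScenarioSpec,
    grid_shape: tuple[int, int],
    seed: int,
    member_spread: float = 0.15,
    interannual_sd: float = 0.05,
) -> xr.Dataset:
    """Gridded BC/OA/SO4/SS/dust concentrations per member and year.

    Each component is a shared smooth log-normal base pattern, perturbed
    per ensemble member (multiplicative spread ``member_spread``) and per
    year (``interannual_sd``), with the scenario's multiplicative
    concentration drift compounded across years.  All values are
    non-negative by construction.
    """
    rows, cols = grid_shape
    if rows <= 0 or cols <= 0:
        raise ValueError(f"grid_shape must be positive, got {grid_shape}")
    rng = np.random.default_rng(seed)
    lats = np.linspace(20.0, 50.0, rows)
    lons = np.linspace(80.0, 120.0, cols)
    years = np.array(spec.years)
    trend = np.power(1.0 + spec.concentration_trend, np.arange(len(years)))

    data_vars = {}
    for name, level in COMPONENT_LEVELS.items():
        base = level * np.exp(0.4 * _smooth_noise(rng, (rows, cols)))
        member_factor = np.exp(
            member_spread * _smooth_noise(rng, (spec.n_models, rows, cols))
        )
        year_factor = np.exp(
            interannual_sd * rng.standard_normal((spec.n_models, len(years), 1, 1))
        )
        values = (
            base[None, None, :, :]
            * member_factor[:, None, :, :]
            * year_factor
            * trend[None, :, None, None]
        )
        data_vars[name] = (("member", "year", "lat", "lon"), values,
                           {"units": "ug m-3"})
    return xr.Dataset(
        data_vars,
        coords={
            "member": np.arange(spec.n_models),
            "year": years,
            "lat": lats,
            "lon": lons,
        },
        attrs={"scenario": spec.name},
    )


def largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``weights``.

    Floors the exact shares and hands the remaining units to the cells
    with the largest fractional parts (ties broken by cell order), so the
    allocation sums to ``total`` exactly.
    """
    weights = np.asarray(weights, dtype=float)
    if total < 0:
        raise ValueError("total must be non-negative")
    if weights.sum() <= 0:
        raise ValueError("weights must have a positive sum")
    shares = total * weights / weights.sum()
    alloc = np.floor(shares).astype(np.int64)
    short = int(total - alloc.sum())
    if short > 0:
        frac = shares - alloc
        order = np.lexsort((np.arange(frac.size), -frac))
        alloc[order[:short]] += 1
    return alloc


def generate_population(
    grid_shape: tuple[int, int],
    region_raster: np.ndarray,
    totals: dict[int, int],
    seed: int,
) -> xr.DataArray:
    """Gridded person counts matching per-region totals exactly.

    Cell weights are log-normal (heavy-tailed, like settlement patterns),
    lightly smoothed; counts are integers allocated by largest remainder
    within each region.  Cells with a negative region id are masked (zero).
    """
    rows, cols = grid_shape
    region_raster = np.asarray(region_raster)
    if region_raster.shape != (rows, cols):
        raise ValueError(
            f"region raster shape {region_raster.shape} != grid {grid_shape}")
    rng = np.random.default_rng(seed)
    weights = np.exp(1.0 * _smooth_noise(rng, (rows, cols), scale=1.0))
    counts = np.zeros((rows, cols), dtype=np.int64)
    for rid, total in totals.items():
        if total < 0:
            raise ValueError(f"negative total for region {rid}")
        mask = region_raster == rid
        if not mask.any():
            raise ValueError(f"region {rid} has no cells in the raster")
        counts[mask] = largest_remainder(weights[mask], int(total))
    lats = np.linspace(20.0, 50.0, rows)
    lons = np.linspace(80.0, 120.0, cols)
    return xr.DataArray(
        counts, dims=("lat", "lon"), coords={"lat": lats, "lon": lons},
        name="population", attrs={"units": "persons"},
    )


def generate_sdi(
    regions: list[str],
    years: list[int],
    seed: int,
    start_range: tuple[float, float] = (0.45, 0.75),
    annual_gain: float = 0.008,
) -> pd.DataFrame:
    """Smoothly rising sociodemographic-index series per region, in [0, 1].

    Regions start at staggered development levels and improve by roughly
    ``annual_gain`` per year, so a multi-decade panel straddles the 0.8
    hinge for some regions — exactly the situation the hinged regression
    is built for.
    """
    rng = np.random.default_rng(seed)
    rows = []
    lo, hi = start_range
    for region in regions:
        start = rng.uniform(lo, hi)
        gains = annual_gain * (1 + 0.3 * rng.standard_normal(len(years) - 1))
        path = np.concatenate([[start], start + np.cumsum(np.abs(gains))])
        path = np.clip(path, 0.0, 1.0)
        for year, sdi in zip(years, path):
            rows.append({"region": region, "year": int(year), "sdi": float(sdi)})
    return pd.DataFrame(rows)


# baseline adult age distribution: mass declining with age, thin oldest bands
_BASE_AGE_SHAPE = np.exp(-0.22 * np.arange(len(AGE_BANDS)))


def generate_demography(
    regions: list[str],
    spec: ScenarioSpec,
    base_pop: dict[str, int],
    seed: int,
    pop_growth: float = 0.003,
) -> pd.DataFrame:
    """Total population and 15-band age proportions per region/year.

    The scenario's ``aging_drift`` tilts the age distribution toward older
    bands multiplicatively each year (proportions renormalised to sum to
    1); totals grow geometrically at ``pop_growth`` per year with small
    seeded regional variation.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for region in regions:
        p0 = _BASE_AGE_SHAPE * np.exp(0.05 * rng.standard_normal(len(AGE_BANDS)))
        p0 = p0 / p0.sum()
        growth = pop_growth * (1 + 0.3 * rng.standard_normal())
        for k, year in enumerate(spec.years):
            tilt = np.exp(spec.aging_drift * k * np.arange(len(AGE_BANDS)))
            p = p0 * tilt
            p = p / p.sum()
            pop = int(round(base_pop[region] * (1 + growth) ** k))
            for age, prop in zip(AGE_BANDS, p):
                rows.append({
                    "region": region, "year": int(year), "scenario": spec.name,
                    "age": age, "agep": float(prop), "pop": pop,
                })
    return pd.DataFrame(rows)


def hinge_basis(sdi: np.ndarray, knot: float = 0.8) -> tuple[np.ndarray, np.ndarray]:
    """Continuous linear-spline basis in the development index.

    ``h1 = min(sdi, knot)`` carries the below-knot slope, ``h2 =
    max(sdi - knot, 0)`` the above-knot slope; the fitted mean is
    continuous at the knot.
    """
    sdi = np.asarray(sdi, dtype=float)
    return np.minimum(sdi, knot), np.maximum(sdi - knot, 0.0)


def simulate_lograte_panel(
    truth: GroundTruth,
    regions: list[str],
    ages: tuple[str, ...],
    years: list[int],
    sdi: pd.DataFrame,
    seed: int,
    knot: float = 0.8,
    cause_offset: float = 0.0,
) -> pd.DataFrame:
    """One cause's mortality panel from the hinged generative model.

    log-rate = beta1*h1(SDI) + beta2*h2(SDI) + theta_a * t + alpha_la
    + cause_offset + AR(1) residual (phi, sigma from ``truth``), with t the
    year index from the first year.  With sigma = 0 the log-rate equals the
    regression mean exactly.
    """
    sdi_check = sdi["sdi"].values
    if np.any((sdi_check < 0) | (sdi_check > 1)):
        raise ValueError("SDI values must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    years = [int(y) for y in years]
    y0 = years[0]
    sdi_map = sdi.set_index(["region", "year"])["sdi"]
    n_years = len(years)
    rows = []
    for region in regions:
        for age in ages:
            theta = truth.theta_a.get(age, 0.0)
            alpha = truth.alpha_la.get((region, age))
            if alpha is None:
                alpha = float(rng.normal(-6.0, 0.5))
            # stationary AR(1) residual path
            eps = np.zeros(n_years)
            if truth.sigma > 0:
                innov = rng.normal(0.0, truth.sigma, size=n_years)
                eps[0] = innov[0] / np.sqrt(1 - truth.phi**2) \
                    if abs(truth.phi) < 1 else innov[0]
                for t in range(1, n_years):
                    eps[t] = truth.phi * eps[t - 1] + innov[t]
            for t, year in enumerate(years):
                s = float(sdi_map.loc[(region, year)])
                h1, h2 = hinge_basis(s, knot)
                mean = (truth.beta1 * h1 + truth.beta2 * h2
                        + theta * t + alpha + cause_offset)
                rows.append({
                    "region": region, "year": year, "age": age,
                    "lograte": mean + eps[t],
                })
    return pd.DataFrame(rows)


def generate_mortality_history(
    truth: GroundTruth,
    regions: list[str],
    years: list[int],
    sdi: pd.DataFrame,
    seed: int,
    ages: tuple[str, ...] = AGE_BANDS,
) -> pd.DataFrame:
    """Cause-specific mortality history across the full cause hierarchy.

    Level-3 causes (the six pollution-related causes plus the residual
    causes) are simulated from the hinged model with per-cause level
    offsets; level-2 rates are the sums of their children and the level-1
    all-cause rate the sum of level-2 — so children are consistent with
    their parents by construction and every level-3 family leaves a
    positive remainder below its parent.

    Returns a tidy frame: region, year, cause, cause_level, parent, age, rate.
    """
    if len(years) < 10:
        raise ValueError("need >= 10 years of history")
    rng = np.random.default_rng(seed)
    # seeded offsets put the residual causes above the named ones, as in
    # real cause-of-death data where the six causes are a minority share
    level3 = [c for c, lvl in CAUSE_LEVEL.items() if lvl == 3]
    offsets = {c: (1.2 if c.startswith("rest") else 0.0)
               + 0.3 * rng.standard_normal() for c in level3}
    # injuries has no level-3 children; simulate it directly
    frames = []
    for cause in level3 + ["injuries"]:
        sub_seed = int(rng.integers(0, 2**31 - 1))
        panel = simulate_lograte_panel(
            truth, regions, ages, years, sdi, seed=sub_seed,
            cause_offset=offsets.get(cause, 0.5),
        )
        panel["cause"] = cause
        panel["rate"] = np.exp(panel.pop("lograte"))
        frames.append(panel)
    df = pd.concat(frames, ignore_index=True)

    idx = ["region", "year", "age"]
    pieces = [df]  # level-3 causes plus injuries
    # aggregate level-3 families to their level-2 parents
    for parent in ("ncd", "cmnnd"):
        children = [c for c in level3 if PARENT[c] == parent]
        agg = (df[df["cause"].isin(children)]
               .groupby(idx, as_index=False)["rate"].sum())
        agg["cause"] = parent
        pieces.append(agg)
    level2 = pd.concat(
        [p for p in pieces[1:]] + [df[df["cause"] == "injuries"]],
        ignore_index=True)
    all_cause = level2.groupby(idx, as_index=False)["rate"].sum()
    all_cause["cause"] = ALL_CAUSE
    pieces.append(all_cause)

    result = pd.concat(pieces, ignore_index=True)
    result["cause_level"] = result["cause"].map(CAUSE_LEVEL)
    result["parent"] = result["cause"].map(PARENT).fillna("")
    return result[["region", "year", "cause", "cause_level", "parent",
                   "age", "rate"]]


def generate_rr_curves(
    diseases: tuple[str, ...] = PM25_CAUSES,
    shape_params: dict[str, dict] | None = None,
    n_draws: int = 100,
    seed: int = 0,
    conc_grid: np.ndarray | None = None,
    draw_sd: float = 0.1,
) -> dict[tuple[str, str], RRCurve]:
    """Monotone concave relative-risk curves with a draw ensemble.

    Supported shapes per disease (``shape_params[disease]``):

    * ``{"shape": "flat"}`` — RR identically 1 (null curve);
    * ``{"shape": "loglinear", "slope": s}`` — RR(c) = exp(s * c);
    * ``{"shape": "concave", "rr_max": m, "halfpoint": h}`` — saturating
      curve RR(c) = 1 + (m - 1) * (1 - exp(-c / h)), the default, which
      mimics the flattening of epidemiological exposure-response curves at
      high concentrations.

    Draws perturb the curve's log-excess-risk multiplicatively (log-normal
    with sd ``draw_sd``), so each draw stays anchored at RR(0) = 1 and
    non-decreasing.  Curves are labelled age ``"all-age"``.
    """
    if n_draws < 2:
        raise ValueError("n_draws must be >= 2")
    rng = np.random.default_rng(seed)
    if conc_grid is None:
        conc_grid = np.concatenate([[0.0], np.geomspace(1.0, 300.0, 40)])
    conc_grid = np.asarray(conc_grid, dtype=float)
    shape_params = shape_params or {}
    curves: dict[tuple[str, str], RRCurve] = {}
    for disease in diseases:
        params = shape_params.get(
            disease, {"shape": "concave", "rr_max": 1.8, "halfpoint": 60.0})
        shape = params.get("shape", "concave")
        if shape == "flat":
            mean = np.ones_like(conc_grid)
        elif shape == "loglinear":
            mean = np.exp(params["slope"] * conc_grid)
        elif shape == "concave":
            mean = 1.0 + (params["rr_max"] - 1.0) * (
                1.0 - np.exp(-conc_grid / params["halfpoint"]))
        else:
            raise ValueError(f"unknown curve shape {shape!r}")
        excess = np.log(mean)  # zero at c=0, non-decreasing
        factors = np.exp(rng.normal(0.0, draw_sd, size=n_draws))
        draws = np.exp(factors[:, None] * excess[None, :])
        curves[(disease, "all-age")] = RRCurve(
            disease=disease, age="all-age", grid=conc_grid,
            mean_rr=mean, draws=draws,
        )
    return curves
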