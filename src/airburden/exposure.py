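"""PM2.5 exposure fields: composition, calibration, regridding, weighting.

Surface PM2.5 is assembled from speciated aerosol components via the
empirical reconstruction

    PM2.5 = BC + OA + SO4 + NH4 + 0.25 * SS + 0.1 * dust,
    NH4   = 36 * SO4 / 96,

where ammonium is imputed from sulfate under the assumption that it is
present only as ammonium sulfate (climate-model output does not report
surface NH4).  Modelled fields are then bias-calibrated against an observed
baseline by a per-cell ratio, aggregated to region level as
population-weighted means, and summarised across ensemble members with a
t-distribution interval.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats

#: Mass ratio of ammonium to sulfate in ammonium sulfate, 2*18/96.
NH4_PER_SO4 = 36.0 / 96.0
SS_COEF = 0.25
DUST_COEF = 0.1

COMPONENTS = ("BC", "OA", "SO4", "SS", "dust")


@dataclass(frozen=True)
class UncertaintyInterval:
    """A mean with 95% bounds derived from an ensemble or draw set."""

    mean: float
    lower: float
    upper: float
    n: int

    def __post_init__(self) -> None:
        if math.isfinite(self.lower) and math.isfinite(self.upper):
            if not (self.lower <= self.mean <= self.upper):
                raise ValueError(
                    f"interval bounds out of order: "
                    f"{self.lower} <= {self.mean} <= {self.upper} fails"
                )
            if self.n < 2:
                raise ValueError("finite bounds require n >= 2")

    @property
    def width(self) -> float:
        return self.upper - self.lower


def nh4_from_so4(so4):
    """Impute ammonium from sulfate: NH4 = 36 * SO4 / 96."""
    return NH4_PER_SO4 * so4


def compose_pm25(fields: xr.Dataset) -> xr.DataArray:
    """Sum speciated components into a surface PM2.5 field.

    Parameters
    ----------
    fields:
        Dataset with variables ``BC``, ``OA``, ``SO4``, ``SS`` (µg/m³) and
        optionally ``dust``; a missing dust variable is treated as zero
        with a warning.

    Returns
    -------
    xr.DataArray
        Uncalibrated PM2.5 in µg/m³ on the same grid.
    """
    missing = [c for c in ("BC", "OA", "SO4", "SS") if c not in fields]
    if missing:
        raise ValueError(f"missing aerosol components: {missing}")
    for name in COMPONENTS:
        if name in fields and bool((fields[name] < 0).any()):
            raise ValueError(f"negative concentrations in component {name!r}")
    if "dust" in fields:
        dust = fields["dust"]
    else:
        warnings.warn("no dust field supplied; assuming dust = 0", stacklevel=2)
        dust = xr.zeros_like(fields["SO4"])

    pm25 = (
        fields["BC"]
        + fields["OA"]
        + fields["SO4"]
        + nh4_from_so4(fields["SO4"])
        + SS_COEF * fields["SS"]
        + DUST_COEF * dust
    )
    pm25 = pm25.rename("pm25")
    pm25.attrs.update(units="ug m-3", calibrated=0)
    return pm25


def _baseline_mean(field: xr.DataArray) -> xr.DataArray:
    """Multi-year mean over the ``year`` dimension if present."""
    if "year" in field.dims:
        return field.mean("year")
    return field


def calibrate(
    future_est: xr.DataArray,
    baseline_est: xr.DataArray,
    baseline_obs: xr.DataArray,
    baseline_window: tuple[int, int] = (2015, 2019),
) -> xr.DataArray:
    """Ratio-calibrate a modelled PM2.5 field against baseline observations.

    Per cell, ``calibrated = obs_bl * future_est / est_bl`` where the two
    baseline quantities are multi-year means over ``baseline_window``.
    Cells where the baseline estimate is zero but the observation is
    positive cannot be calibrated; they are masked (NaN) and counted in the
    output's ``n_masked_cells`` attribute rather than raising, so that a
    handful of degenerate cells does not poison regional aggregates.

    The default window is 2015-2019; it is configurable because reasonable
    alternatives (e.g. 2012-2019) exist and the choice is a modelling
    decision, not a fixed constant.
    """
    if "year" in baseline_est.dims:
        lo, hi = baseline_window
        baseline_est = baseline_est.sel(year=slice(lo, hi))
        if baseline_est.sizes["year"] == 0:
            raise ValueError(f"baseline window {baseline_window} selects no years")
    if "year" in baseline_obs.dims:
        lo, hi = baseline_window
        sel = baseline_obs.sel(year=slice(lo, hi))
        baseline_obs = sel if sel.sizes.get("year", 0) > 0 else baseline_obs

    est_bl = _baseline_mean(baseline_est)
    obs_bl = _baseline_mean(baseline_obs)

    bad = (est_bl == 0) & (obs_bl > 0)
    n_masked = int(bad.sum())
    if n_masked:
        warnings.warn(
            f"{n_masked} cells have zero baseline estimate with positive "
            "observations; masked in the calibrated field",
            stacklevel=2,
        )
    ratio = future_est / est_bl
    calibrated = obs_bl * ratio
    calibrated = calibrated.where(~bad)
    calibrated = calibrated.rename("pm25")
    calibrated.attrs.update(
        units="ug m-3",
        calibrated=1,
        baseline_window=list(baseline_window),
        n_masked_cells=n_masked,
    )
    return calibrated


def _overlap_weights(src_edges: np.ndarray, tgt_edges: np.ndarray) -> np.ndarray:
    """W[i, j] = fraction of source interval j covered by target interval i."""
    src_lo, src_hi = src_edges[:-1], src_edges[1:]
    tgt_lo, tgt_hi = tgt_edges[:-1], tgt_edges[1:]
    lo = np.maximum(tgt_lo[:, None], src_lo[None, :])
    hi = np.minimum(tgt_hi[:, None], src_hi[None, :])
    overlap = np.clip(hi - lo, 0.0, None)
    return overlap / (src_hi - src_lo)[None, :]


def _edges(centers: np.ndarray, span: tuple[float, float] | None = None
           ) -> np.ndarray:
    centers = np.asarray(centers, dtype=float)
    if centers.size == 1:
        # a single-cell axis carries no spacing; treat it as covering the
        # other grid's full extent (the "collapse" case)
        if span is None:
            span = (centers[0] - 0.5, centers[0] + 0.5)
        return np.asarray(span, dtype=float)
    step = np.diff(centers).mean()
    return np.concatenate([[centers[0] - step / 2], centers + step / 2])


def regrid(
    field: xr.DataArray,
    target_lats: np.ndarray,
    target_lons: np.ndarray,
    kind: str = "intensive",
) -> xr.DataArray:
    """Regrid between regular lat/lon grids.

    Intensive fields (concentrations) use bilinear interpolation, which is
    exact for constants.  Extensive fields (population counts) use
    area-proportional reallocation built from 1-D interval-overlap weights,
    which conserves the global sum when the target grid covers the source
    domain.
    """
    target_lats = np.asarray(target_lats, dtype=float)
    target_lons = np.asarray(target_lons, dtype=float)
    src_lats = field["lat"].values
    src_lons = field["lon"].values

    src_lat_edges = _edges(src_lats)
    src_lon_edges = _edges(src_lons)
    tgt_lat_edges = _edges(target_lats,
                           span=(src_lat_edges[0], src_lat_edges[-1]))
    tgt_lon_edges = _edges(target_lons,
                           span=(src_lon_edges[0], src_lon_edges[-1]))
    if tgt_lat_edges[-1] < src_lat_edges[0] or tgt_lat_edges[0] > src_lat_edges[-1] \
            or tgt_lon_edges[-1] < src_lon_edges[0] or tgt_lon_edges[0] > src_lon_edges[-1]:
        raise ValueError("source and target grid domains do not overlap")

    if kind == "intensive":
        return field.interp(
            lat=target_lats, lon=target_lons, method="linear",
            kwargs={"fill_value": None},
        )
    if kind != "extensive":
        raise ValueError(f"unknown regrid kind {kind!r}")

    w_lat = _overlap_weights(src_lat_edges, tgt_lat_edges)
    w_lon = _overlap_weights(src_lon_edges, tgt_lon_edges)
    out = xr.apply_ufunc(
        lambda block: np.einsum("ij,...jk,lk->...il", w_lat, block, w_lon),
        field,
        input_core_dims=[["lat", "lon"]],
        output_core_dims=[["lat", "lon"]],
        exclude_dims={"lat", "lon"},
    )
    out = out.assign_coords(lat=target_lats, lon=target_lons)
    out.attrs.update(field.attrs)
    return out


def population_weighted_concentration(
    conc: xr.DataArray,
    pop: xr.DataArray,
    region_mask: xr.DataArray,
    region_labels: dict[int, str] | None = None,
) -> xr.DataArray:
    """Population-weighted mean concentration per region.

    ``sum(pop * conc) / sum(pop)`` over a region's cells.  Any non-spatial
    dimensions of ``conc`` (ensemble member, year) are carried through.
    Raises for regions with zero total population, for which the weighted
    mean is undefined.
    """
    region_ids = np.unique(region_mask.values)
    region_ids = region_ids[region_ids >= 0]
    out = []
    empty = []
    for rid in region_ids:
        inside = region_mask == rid
        wsum = pop.where(inside).sum(("lat", "lon"))
        if float(wsum) == 0.0:
            empty.append(int(rid))
            continue
        num = (conc * pop).where(inside).sum(("lat", "lon"))
        out.append(num / wsum)
    if empty:
        names = [region_labels.get(r, r) if region_labels else r for r in empty]
        raise ValueError(f"zero population in regions {names}; weighted mean undefined")
    labels = [
        region_labels.get(int(r), str(int(r))) if region_labels else int(r)
        for r in region_ids
    ]
    return xr.concat(out, dim=pd.Index(labels, name="region"))


def ensemble_interval(
    member_values, mode: str = "as_printed"
) -> UncertaintyInterval:
    """95% interval across ensemble members, t-distribution based.

    The default ``"as_printed"`` mode computes ``mean ± sd * t_{0.975}(n-1)``
    with the sample standard deviation un-scaled by 1/sqrt(n): the interval
    describes the spread of members, not the uncertainty of their mean.
    ``mode="standard_error"`` applies the 1/sqrt(n) factor of a textbook
    t-interval for the ensemble mean.
    """
    values = np.asarray(member_values, dtype=float)
    n = values.size
    mean = float(values.mean()) if n else math.nan
    if n < 2:
        warnings.warn("fewer than 2 ensemble members; interval is unbounded",
                      stacklevel=2)
        return UncertaintyInterval(mean=mean, lower=-math.inf, upper=math.inf, n=n)
    sd = float(values.std(ddof=1))
    if mode == "standard_error":
        sd = sd / math.sqrt(n)
    elif mode != "as_printed":
        raise ValueError(f"unknown interval mode {mode!r}")
    half = sd * float(stats.t.ppf(0.975, n - 1))
    return UncertaintyInterval(mean=mean, lower=mean - half, upper=mean + half, n=n)


def percent_change(start: float, end: float) -> float:
    """Relative change from ``start`` to ``end`` in percent."""
    if start == 0:
        raise ValueError("percent change undefined for a zero start value")
    return (end - start) / start * 100.0
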