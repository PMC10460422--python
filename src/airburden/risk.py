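"""Exposure-response evaluation: relative risk and attributable fractions.

Relative-risk curves arrive as tables (concentration grid, mean curve, and
an ensemble of draw-level curves emulating the 1000 fits of a meta-regression
such as MR-BRT); they are consumed, never fit here.  The population
attributable fraction follows PAF = (RR - 1) / RR, applied at the exposure
level directly — no theoretical-minimum-risk counterfactual is subtracted,
which differs from some comparative-risk-assessment practice and is
documented deliberately.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exposure import UncertaintyInterval

logger = logging.getLogger(__name__)


@dataclass
class RRCurve:
    """Tabulated concentration -> relative-risk map for one (disease, age).

    ``grid`` is strictly increasing and starts at 0 µg/m³, where RR is
    anchored at 1.  ``draws`` holds one curve per row on the same grid.
    Sub-unity values are floored at 1 on construction (a relative risk
    below 1 would turn the attributable fraction into a benefit, which the
    burden calculation does not model); the number of floored entries is
    kept on the instance and logged.
    """

    disease: str
    age: str
    grid: np.ndarray
    mean_rr: np.ndarray
    draws: np.ndarray
    n_floored: int = field(default=0, init=False)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.mean_rr = np.asarray(self.mean_rr, dtype=float)
        self.draws = np.atleast_2d(np.asarray(self.draws, dtype=float))
        if self.grid.ndim != 1 or self.grid.size < 2:
            raise ValueError("curve grid must be 1-D with at least 2 nodes")
        if self.grid[0] != 0:
            raise ValueError("curve grid must start at 0 ug/m3")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("curve grid must be strictly increasing")
        if self.mean_rr.shape != self.grid.shape:
            raise ValueError("mean_rr shape does not match grid")
        if self.draws.shape[1] != self.grid.size:
            raise ValueError("draws shape does not match grid")
        n_below = int((self.mean_rr < 1).sum() + (self.draws < 1).sum())
        if n_below:
            logger.warning(
                "curve (%s, %s): flooring %d sub-unity RR values at 1",
                self.disease, self.age, n_below,
            )
            self.mean_rr = np.maximum(self.mean_rr, 1.0)
            self.draws = np.maximum(self.draws, 1.0)
        self.n_floored = n_below
        if not np.all(self.mean_rr[0] == 1.0) or not np.all(self.draws[:, 0] == 1.0):
            raise ValueError("RR at zero concentration must equal 1")
        if np.any(np.diff(self.mean_rr) < 0) or np.any(np.diff(self.draws, axis=1) < 0):
            raise ValueError("RR curves must be non-decreasing in concentration")

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]


def relative_risk(curve: RRCurve, concentration, draws: bool = False) -> np.ndarray:
    """Interpolate relative risk at a concentration (µg/m³).

    Linear interpolation between grid nodes; flat extrapolation beyond the
    last node (the curve's evidence does not extend further).  With
    ``draws=True`` returns one RR per draw curve.
    """
    conc = np.asarray(concentration, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentration must be non-negative")
    if draws:
        return np.stack([np.interp(conc, curve.grid, d) for d in curve.draws])
    return np.interp(conc, curve.grid, curve.mean_rr)


def paf(rr) -> np.ndarray:
    """Population attributable fraction, (RR - 1) / RR."""
    rr = np.asarray(rr, dtype=float)
    if np.any(rr < 1):
        raise ValueError("relative risk must be >= 1 (floor sub-unity draws first)")
    return (rr - 1.0) / rr


def draw_quantile_interval(per_draw_values) -> UncertaintyInterval:
    """Empirical 95% interval (2.5th / 97.5th percentiles) across draws.

    Uses the linear-interpolation quantile estimator; the reported mean is
    the draw mean.
    """
    values = np.asarray(per_draw_values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 draws for a quantile interval")
    lower, upper = np.percentile(values, [2.5, 97.5], method="linear")
    return UncertaintyInterval(
        mean=float(values.mean()), lower=float(lower), upper=float(upper),
        n=values.size,
    )


def paf_table(
    curves: dict[tuple[str, str], RRCurve] | list[RRCurve],
    concentrations: pd.DataFrame,
    ages: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Evaluate PAFs at region-level concentrations, with draw bounds.

    Parameters
    ----------
    curves:
        RRCurve per (disease, age); a curve with age ``"all-age"`` applies
        to every age band of that disease.
    concentrations:
        Tidy frame with columns ``region, year, scenario, mean, lower,
        upper`` (µg/m³).  Bounds columns are optional; absent bounds
        collapse to the mean.

    Returns
    -------
    pd.DataFrame
        Columns ``region, year, scenario, disease, age, paf_mean,
        paf_lower, paf_upper``.  The bound columns combine the concentration
        bound with the matching draw quantile (comonotone bound
        arithmetic): the lower PAF is the 2.5th draw percentile at the
        lower concentration, the upper the 97.5th at the upper.
    """
    if isinstance(curves, dict):
        curve_list = list(curves.values())
    else:
        curve_list = list(curves)
    conc = concentrations.copy()
    for col in ("lower", "upper"):
        if col not in conc.columns:
            conc[col] = conc["mean"]
    if "scenario" not in conc.columns:
        conc["scenario"] = "default"

    rows = []
    for curve in curve_list:
        curve_ages = list(ages) if (curve.age == "all-age" and ages) else [curve.age]
        rr_mean = relative_risk(curve, conc["mean"].values)
        rr_draw_lo = relative_risk(curve, conc["lower"].values, draws=True)
        rr_draw_hi = relative_risk(curve, conc["upper"].values, draws=True)
        q_lo = np.percentile(rr_draw_lo, 2.5, axis=0, method="linear")
        q_hi = np.percentile(rr_draw_hi, 97.5, axis=0, method="linear")
        # draw quantiles can cross the mean-curve value; order the bounds
        paf_mean = paf(rr_mean)
        paf_lo = np.minimum(paf(np.maximum(q_lo, 1.0)), paf_mean)
        paf_hi = np.maximum(paf(np.maximum(q_hi, 1.0)), paf_mean)
        for age_band in curve_ages:
            block = conc[["region", "year", "scenario"]].copy()
            block["disease"] = curve.disease
            block["age"] = age_band
            block["paf_mean"] = paf_mean
            block["paf_lower"] = paf_lo
            block["paf_upper"] = paf_hi
            rows.append(block)
    return pd.concat(rows, ignore_index=True)


CURVE_COLUMNS = ("disease", "age", "concentration", "draw_id", "rr")


def write_rr_curves(curves, path) -> None:
    """Write curves to CSV (columns disease, age, concentration, draw_id, rr).

    ``draw_id`` 0 is the mean curve; draws are numbered from 1.
    """
    curve_list = list(curves.values()) if isinstance(curves, dict) else list(curves)
    frames = []
    for c in curve_list:
        base = pd.DataFrame({
            "disease": c.disease, "age": c.age,
            "concentration": c.grid, "draw_id": 0, "rr": c.mean_rr,
        })
        frames.append(base)
        for i, d in enumerate(c.draws, start=1):
            frames.append(pd.DataFrame({
                "disease": c.disease, "age": c.age,
                "concentration": c.grid, "draw_id": i, "rr": d,
            }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_rr_curves(path) -> dict[tuple[str, str], RRCurve]:
    """Read curves from the CSV schema written by :func:`write_rr_curves`."""
    df = pd.read_csv(path)
    missing = set(CURVE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"curve file missing columns: {sorted(missing)}")
    curves: dict[tuple[str, str], RRCurve] = {}
    for (disease, age), grp in df.groupby(["disease", "age"], sort=False):
        mean = grp[grp["draw_id"] == 0].sort_values("concentration")
        if mean.empty:
            raise ValueError(f"curve ({disease}, {age}) lacks a mean curve (draw_id 0)")
        grid = mean["concentration"].values
        draw_ids = sorted(set(grp["draw_id"]) - {0})
        draws = []
        for did in draw_ids:
            d = grp[grp["draw_id"] == did].sort_values("concentration")
            if not np.array_equal(d["concentration"].values, grid):
                raise ValueError(
                    f"curve ({disease}, {age}) draw {did} on a different grid")
            draws.append(d["rr"].values)
        curves[(disease, age)] = RRCurve(
            disease=disease, age=age, grid=grid,
            mean_rr=mean["rr"].values, draws=np.array(draws),
        )
    return curves
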