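"""Cause-specific mortality forecasting and hierarchy constraining.

Log mortality rates are modelled as

    ln(m) = beta1 * h1(SDI) + beta2 * h2(SDI) + theta_a * t + alpha_{la} + eps

where (h1, h2) is a continuous linear spline in the sociodemographic index
with a knot at 0.8 (two slopes, one below and one above the knot), theta_a
is a per-age-band linear time trend, alpha_{la} a per-(region, age)
intercept, and eps a residual modelled by a low-order ARIMA process.  The
slopes are fit pooled across regions per cause ("global" coefficients);
t is the year index from the first fitted year.

Forecasts are exp(mean + ARIMA residual forecast) with symmetric log-scale
prediction intervals.  Because only a handful of causes are forecast
directly, cause-specific forecasts are reconciled to an all-cause envelope
by two rounds of proportional rescaling: level-2 causes (NCD, CMNND,
injuries) to the all-cause rate, then level-3 causes (including an explicit
residual cause) to their constrained level-2 parent.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .schema import AGE_BANDS, LEVEL2_CAUSES, PARENT
from .synthetic import hinge_basis

logger = logging.getLogger(__name__)


@dataclass
class TrendFit:
    """Fitted hinged-SDI trend for one cause."""

    cause: str
    knot: float
    year0: int
    beta1: float
    beta2: float
    beta1_se: float
    beta2_se: float
    theta: dict[str, float]
    theta_se: dict[str, float]
    alpha: dict[tuple[str, str], float]
    residuals: pd.DataFrame
    sigma: float
    n_obs: int
    n_params: int
    columns: list[str] = field(repr=False)
    params: np.ndarray = field(repr=False)
    xtx_inv: np.ndarray = field(repr=False)
    sdi_mean: float = 0.0
    sdi_sxx: float = 1.0
    pinned: str | None = None

    @property
    def s2(self) -> float:
        return self.sigma**2


def _design_matrix(
    df: pd.DataFrame,
    knot: float,
    year0: int,
    ages: list[str],
    strata: list[tuple[str, str]],
    drop: set[str],
) -> tuple[np.ndarray, list[str]]:
    n = len(df)
    h1, h2 = hinge_basis(df["sdi"].values, knot)
    t = (df["year"].values - year0).astype(float)
    cols: list[tuple[str, np.ndarray]] = []
    if "h1" not in drop:
        cols.append(("h1", h1))
    if "h2" not in drop:
        cols.append(("h2", h2))
    age_vals = df["age"].values
    for age in ages:
        cols.append((f"theta:{age}", t * (age_vals == age)))
    region_vals = df["region"].values
    for region, age in strata:
        cols.append((f"alpha:{region}|{age}",
                     ((region_vals == region) & (age_vals == age)).astype(float)))
    names = [name for name, _ in cols]
    X = np.column_stack([v for _, v in cols]) if cols else np.empty((n, 0))
    return X, names


def fit_trend(
    history: pd.DataFrame,
    sdi: pd.DataFrame,
    cause: str,
    knot: float = 0.8,
) -> TrendFit:
    """Least-squares fit of the hinged log-rate model for one cause.

    ``history`` is a tidy mortality table (region, year, age, cause, rate);
    ``sdi`` carries (region, year, sdi).  Rates must be strictly positive
    (the model lives on the log scale) and each stratum needs at least 10
    years.  If all SDI values fall on one side of the knot, the slope on
    the empty side is unidentifiable and is pinned to the identifiable one
    with a warning.
    """
    df = history[history["cause"] == cause].copy()
    if df.empty:
        raise ValueError(f"no rows for cause {cause!r}")
    if (df["rate"] <= 0).any():
        raise ValueError("rates must be strictly positive (log scale)")
    counts = df.groupby(["region", "age"])["year"].nunique()
    if (counts < 10).any():
        raise ValueError("need >= 10 years of history per stratum")
    df = df.merge(sdi, on=["region", "year"], how="left", validate="m:1")
    if df["sdi"].isna().any():
        raise ValueError("SDI missing for some (region, year) pairs")

    year0 = int(df["year"].min())
    ages = [a for a in AGE_BANDS if a in set(df["age"])]
    if not ages:  # ages outside the standard bands: keep data order
        ages = sorted(set(df["age"]))
    strata = sorted(set(zip(df["region"], df["age"])))

    sdi_vals = df["sdi"].values
    drop: set[str] = set()
    pinned = None
    if np.all(sdi_vals >= knot):
        # h1 is the constant `knot`, collinear with the intercepts
        drop.add("h1")
        pinned = "beta1"
    elif np.all(sdi_vals < knot):
        drop.add("h2")
        pinned = "beta2"
    if pinned:
        warnings.warn(
            f"all SDI values on one side of knot {knot}; "
            f"{pinned} pinned to the identifiable slope", stacklevel=2)

    X, names = _design_matrix(df, knot, year0, ages, strata, drop)
    y = np.log(df["rate"].values)
    xtx = X.T @ X
    xtx_inv = np.linalg.pinv(xtx, hermitian=True)
    params = xtx_inv @ (X.T @ y)
    fitted = X @ params
    resid = y - fitted
    rank = np.linalg.matrix_rank(xtx, hermitian=True)
    dof = max(len(y) - rank, 1)
    s2 = float(resid @ resid) / dof
    se = np.sqrt(np.clip(np.diag(xtx_inv) * s2, 0.0, None))
    coef = dict(zip(names, params))
    err = dict(zip(names, se))

    beta1 = coef.get("h1", coef.get("h2", 0.0))
    beta2 = coef.get("h2", coef.get("h1", 0.0))
    theta = {a: coef[f"theta:{a}"] for a in ages}
    theta_se = {a: err[f"theta:{a}"] for a in ages}
    alpha = {(r, a): coef[f"alpha:{r}|{a}"] for r, a in strata}

    residuals = df[["region", "year", "age"]].copy()
    residuals["resid"] = resid

    return TrendFit(
        cause=cause, knot=knot, year0=year0,
        beta1=float(beta1), beta2=float(beta2),
        beta1_se=float(err.get("h1", err.get("h2", np.nan))),
        beta2_se=float(err.get("h2", err.get("h1", np.nan))),
        theta=theta, theta_se=theta_se, alpha=alpha,
        residuals=residuals, sigma=float(np.sqrt(s2)),
        n_obs=len(y), n_params=int(rank),
        columns=names, params=params, xtx_inv=xtx_inv,
        sdi_mean=float(sdi_vals.mean()),
        sdi_sxx=float(((sdi_vals - sdi_vals.mean())**2).sum()),
        pinned=pinned,
    )


def _x_future(fit: TrendFit, region: str, age: str, year: int,
              sdi_value: float) -> np.ndarray:
    h1, h2 = hinge_basis(np.array([sdi_value]), fit.knot)
    t = float(year - fit.year0)
    x = np.zeros(len(fit.columns))
    for j, name in enumerate(fit.columns):
        if name == "h1":
            x[j] = h1[0]
        elif name == "h2":
            x[j] = h2[0]
        elif name == f"theta:{age}":
            x[j] = t
        elif name == f"alpha:{region}|{age}":
            x[j] = 1.0
    return x


def predict_mean(fit: TrendFit, region: str, age: str, year: int,
                 sdi_value: float) -> float:
    """Regression mean of ln(rate) for a stratum-year."""
    return float(_x_future(fit, region, age, year, sdi_value) @ fit.params)


class ResidualModel:
    """Forecast interface for a fitted residual process."""

    phi: float = 0.0
    phi_se: float = float("nan")

    def forecast(self, horizon: int) -> tuple[np.ndarray, np.ndarray]:
        raise NotImplementedError


class WhiteNoiseResidual(ResidualModel):
    """Zero-mean residual forecast with constant variance."""

    def __init__(self, variance: float):
        self.variance = float(variance)

    def forecast(self, horizon: int) -> tuple[np.ndarray, np.ndarray]:
        return np.zeros(horizon), np.full(horizon, self.variance)


class ArimaResidual(ResidualModel):
    """statsmodels ARIMA wrapper exposing mean and variance paths."""

    def __init__(self, result, order):
        self._result = result
        self.order = order
        names = list(result.param_names)
        if "ar.L1" in names:
            i = names.index("ar.L1")
            self.phi = float(result.params[i])
            self.phi_se = float(result.bse[i])

    def forecast(self, horizon: int) -> tuple[np.ndarray, np.ndarray]:
        pred = self._result.get_forecast(horizon)
        return (np.asarray(pred.predicted_mean, dtype=float),
                np.asarray(pred.var_pred_mean, dtype=float))


def fit_residual(residual_series, order: tuple[int, int, int] = (1, 0, 0)
                 ) -> ResidualModel:
    """Fit an ARIMA model to an in-sample residual series.

    Defaults to AR(1) with no trend term (the regression intercepts leave
    residuals mean-zero by construction).  An all-zero series returns a
    degenerate zero forecast; a non-convergent fit falls back to a
    white-noise model with a logged warning.
    """
    resid = np.asarray(residual_series, dtype=float)
    if resid.size < 10:
        raise ValueError("need >= 10 residuals to fit the residual process")
    if np.allclose(resid, 0.0):
        return WhiteNoiseResidual(0.0)
    from statsmodels.tsa.arima.model import ARIMA

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = ARIMA(resid, order=order, trend="n").fit()
        if not np.all(np.isfinite(result.params)):
            raise ValueError("non-finite ARIMA parameters")
        return ArimaResidual(result, order)
    except Exception as exc:  # pragma: no cover - statsmodels edge cases
        logger.warning("ARIMA fit failed (%s); falling back to white noise", exc)
        return WhiteNoiseResidual(np.var(resid, ddof=1))


def forecast_rates(
    fit: TrendFit,
    residual_models: dict[tuple[str, str], ResidualModel],
    future_sdi: pd.DataFrame,
    years: list[int],
    ci_mode: str = "prediction",
) -> pd.DataFrame:
    """Forecast rates per stratum with symmetric log-scale 95% intervals.

    The point forecast is exp(regression mean + residual-process forecast).
    The interval is ``ln(m) ± t_{0.975}(n-2) * se`` exponentiated, where
    ``se`` depends on ``ci_mode``:

    * ``"prediction"`` (default): the regression prediction standard error
      ``sqrt(s2 * (1 + x_f' (X'X)^- x_f))`` — the textbook prediction
      variance, of which the familiar simple-regression form
      ``s2 * (1 + 1/n + (x_f - xbar)^2 / Sxx)`` is the one-covariate case.
    * ``"as_printed"``: the literal reduced form
      ``sqrt(s2 * (1/n) * (sdi_f - sdi_bar)^2 / Sxx)`` offered for
      comparison; it omits the leading 1 and is much narrower.
    """
    if ci_mode not in ("prediction", "as_printed"):
        raise ValueError(f"unknown ci_mode {ci_mode!r}")
    sdi_map = future_sdi.set_index(["region", "year"])["sdi"]
    tcrit = float(stats.t.ppf(0.975, max(fit.n_obs - 2, 1)))
    s2_printed = (fit.s2 * (fit.n_obs - fit.n_params)) / max(fit.n_obs - 2, 1)
    rows = []
    for (region, age), model in residual_models.items():
        eps_mean, _eps_var = model.forecast(len(years))
        for h, year in enumerate(years):
            key = (region, int(year))
            if key not in sdi_map.index:
                raise ValueError(f"missing future SDI for {key}")
            s = float(sdi_map.loc[key])
            x = _x_future(fit, region, age, int(year), s)
            log_point = float(x @ fit.params) + eps_mean[h]
            if ci_mode == "prediction":
                se = np.sqrt(fit.s2 * (1.0 + float(x @ fit.xtx_inv @ x)))
            else:
                se = np.sqrt(
                    s2_printed * (1.0 / fit.n_obs)
                    * (s - fit.sdi_mean) ** 2 / fit.sdi_sxx)
            rows.append({
                "region": region, "age": age, "year": int(year),
                "cause": fit.cause,
                "rate": float(np.exp(log_point)),
                "lower": float(np.exp(log_point - tcrit * se)),
                "upper": float(np.exp(log_point + tcrit * se)),
            })
    return pd.DataFrame(rows)


def fit_stratum_residuals(fit: TrendFit, order=(1, 0, 0),
                          model: str = "arima"
                          ) -> dict[tuple[str, str], ResidualModel]:
    """Fit the residual process per (region, age) stratum of a trend fit."""
    models: dict[tuple[str, str], ResidualModel] = {}
    for (region, age), grp in fit.residuals.groupby(["region", "age"]):
        series = grp.sort_values("year")["resid"].values
        if model == "white_noise":
            models[(region, age)] = WhiteNoiseResidual(np.var(series, ddof=1))
        else:
            models[(region, age)] = fit_residual(series, order=order)
    return models


def _group_keys(df: pd.DataFrame) -> list[str]:
    return [c for c in ("region", "scenario", "year", "age") if c in df.columns]


def _apply_envelope(
    children: pd.DataFrame,
    envelope: pd.DataFrame,
    value_col: str,
    extra_cols: tuple[str, ...],
    orientation: str,
) -> pd.DataFrame:
    if orientation not in ("constrain", "as_printed"):
        raise ValueError(f"unknown orientation {orientation!r}")
    keys = _group_keys(children)
    env = envelope[keys + [value_col]].rename(columns={value_col: "_env"})
    merged = children.merge(env, on=keys, how="left", validate="m:1")
    if merged["_env"].isna().any():
        raise ValueError("envelope missing for some strata")
    if (merged["_env"] <= 0).any():
        raise ValueError("envelope rates must be strictly positive")
    sums = merged.groupby(keys)[value_col].transform("sum")
    if (sums == 0).any():
        raise ValueError("child rates sum to zero in some strata")
    if orientation == "constrain":
        factor = merged["_env"] / sums
    else:  # the printed orientation multiplies by (sum children) / envelope
        factor = sums / merged["_env"]
    out = children.copy()
    for col in (value_col, *extra_cols):
        out[col] = children[col].values * factor.values
    return out


def constrain_level2(
    level2_rates: pd.DataFrame,
    all_cause_envelope: pd.DataFrame,
    value_col: str = "rate",
    extra_cols: tuple[str, ...] = (),
    orientation: str = "constrain",
) -> pd.DataFrame:
    """Rescale level-2 cause rates to the all-cause envelope.

    Within each (region, scenario, year, age) group present, every level-2
    rate is multiplied by the common factor envelope / sum(level-2), so the
    three constrained rates sum exactly to the all-cause rate.

    ``orientation="as_printed"`` instead multiplies by the reciprocal
    factor sum(level-2) / envelope.  That is the orientation some sources
    print, but it moves the total *away* from the envelope whenever the
    children overshoot it; the default implements the stated purpose of
    the constraint.  ``extra_cols`` (e.g. interval bounds) are scaled by
    the same factor.
    """
    bad = set(level2_rates["cause"]) - set(LEVEL2_CAUSES)
    if bad:
        raise ValueError(f"unexpected level-2 causes: {sorted(bad)}")
    return _apply_envelope(level2_rates, all_cause_envelope, value_col,
                           extra_cols, orientation)


def constrain_level3(
    level3_rates: pd.DataFrame,
    constrained_parents: pd.DataFrame,
    value_col: str = "rate",
    extra_cols: tuple[str, ...] = (),
    orientation: str = "constrain",
) -> pd.DataFrame:
    """Rescale level-3 causes (incl. rest-causes) to their constrained parent.

    Applied family by family: the NCD children (five named causes plus the
    residual NCD cause) to the constrained NCD rate, the CMNND children
    (LRI plus residual) to the constrained CMNND rate.
    """
    out = []
    parents = level3_rates["cause"].map(PARENT)
    if parents.isna().any():
        orphans = sorted(set(level3_rates.loc[parents.isna(), "cause"]))
        raise ValueError(f"causes without a parent: {orphans}")
    for parent, fam in level3_rates.groupby(parents):
        env = constrained_parents[constrained_parents["cause"] == parent]
        if env.empty:
            raise ValueError(f"no constrained parent rates for {parent!r}")
        out.append(_apply_envelope(fam, env, value_col, extra_cols,
                                   orientation))
    return pd.concat(out, ignore_index=True)


def age_standardized_rate(
    rates: pd.DataFrame,
    standard: dict[str, float] | None = None,
    value_col: str = "rate",
) -> pd.DataFrame:
    """Age-standardised rate per (region, scenario, year, cause).

    ``standard`` is a fixed age-proportion vector (defaults to a uniform
    standard over the bands present); the result is the standard-weighted
    mean of age-specific rates, comparable across populations with
    different age structures.
    """
    df = rates.copy()
    if standard is None:
        bands = sorted(set(df["age"]), key=list(AGE_BANDS).index)
        standard = {a: 1.0 / len(bands) for a in bands}
    total = sum(standard.values())
    df["_w"] = df["age"].map(standard)
    if df["_w"].isna().any():
        raise ValueError("standard age structure missing some bands")
    keys = [c for c in ("region", "scenario", "year", "cause") if c in df.columns]
    df["_wr"] = df["_w"] * df[value_col]
    out = df.groupby(keys, as_index=False)[["_wr"]].sum()
    out[value_col] = out.pop("_wr") / total
    return out
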