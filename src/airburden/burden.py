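"""Attributable-death accounting: PAF x POP x Rate x AgeP and summaries.

Attributable deaths for one stratum are

    deaths_{a,d} = PAF_{a,d} * POP * Rate_{a,d} * AgeP_a

summed over the 15 adult age bands a and the six pollution-related causes
d.  Uncertainty intervals follow comonotone bound arithmetic: the lower
bound evaluates the product with every input at its lower bound, and the
upper analogously (a Monte-Carlo propagation mode is provided to quantify
how conservative that is).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .schema import AGE_BANDS, OLDER_BANDS, PM25_CAUSES

STRATUM_KEYS = ["region", "year", "scenario", "disease", "age"]


def _require(df: pd.DataFrame, cols: list[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{name} missing columns {missing}")


def compute_dapp(
    paf: pd.DataFrame,
    demog: pd.DataFrame,
    rates: pd.DataFrame,
    mc_draws: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Stratum-level attributable deaths with propagated bounds.

    Parameters
    ----------
    paf:
        ``region, year, scenario, disease, age, paf_mean, paf_lower,
        paf_upper``.
    demog:
        ``region, year, scenario, age, pop, agep``.
    rates:
        ``region, year, scenario (optional), cause, age, rate, lower,
        upper`` — level-3 cause-specific death rates per person-year.
    mc_draws:
        If positive, adds ``deaths_mc_lower`` / ``deaths_mc_upper``
        columns from a Monte-Carlo propagation: each input is sampled
        independently from a normal matched to its bounds (bounds read as
        a 95% interval), clipped to be non-negative.  Off by default.

    Returns
    -------
    pd.DataFrame
        One row per stratum with ``deaths_mean``, ``deaths_lower``,
        ``deaths_upper``.
    """
    _require(paf, ["region", "year", "disease", "age", "paf_mean"], "paf")
    _require(demog, ["region", "year", "age", "pop", "agep"], "demog")
    _require(rates, ["region", "year", "cause", "age", "rate"], "rates")

    paf = paf.copy()
    rates = rates.rename(columns={"cause": "disease"}).copy()
    for frame in (paf, rates, demog):
        if "scenario" not in frame.columns:
            frame["scenario"] = "default"
    for col, src in (("paf_lower", "paf_mean"), ("paf_upper", "paf_mean")):
        if col not in paf.columns:
            paf[col] = paf[src]
    for col in ("lower", "upper"):
        if col not in rates.columns:
            rates[col] = rates["rate"]

    merged = paf.merge(
        rates[["region", "year", "scenario", "disease", "age",
               "rate", "lower", "upper"]],
        on=["region", "year", "scenario", "disease", "age"], how="left",
        validate="1:1",
    ).merge(
        demog[["region", "year", "scenario", "age", "pop", "agep"]],
        on=["region", "year", "scenario", "age"], how="left", validate="m:1",
    )
    missing = merged["rate"].isna() | merged["pop"].isna()
    if missing.any():
        strata = merged.loc[missing, STRATUM_KEYS].drop_duplicates()
        raise ValueError(
            f"misaligned inputs; missing rate or demography for strata:\n"
            f"{strata.head(20).to_string(index=False)}")

    base = merged["pop"] * merged["agep"]
    merged["deaths_mean"] = merged["paf_mean"] * base * merged["rate"]
    merged["deaths_lower"] = merged["paf_lower"] * base * merged["lower"]
    merged["deaths_upper"] = merged["paf_upper"] * base * merged["upper"]

    if mc_draws > 0:
        rng = np.random.default_rng(seed)
        lo, hi = _mc_bounds(merged, base.values, mc_draws, rng)
        merged["deaths_mc_lower"] = lo
        merged["deaths_mc_upper"] = hi

    keep = STRATUM_KEYS + ["deaths_mean", "deaths_lower", "deaths_upper"]
    if mc_draws > 0:
        keep += ["deaths_mc_lower", "deaths_mc_upper"]
    return merged[keep]


def _mc_bounds(merged: pd.DataFrame, base: np.ndarray, n: int,
               rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Independent-normal Monte-Carlo propagation of stratum bounds."""
    z95 = 2 * 1.959963984540054
    def sample(mean, lower, upper):
        sd = (upper - lower) / z95
        draws = rng.normal(mean[None, :], np.maximum(sd, 0.0)[None, :],
                           size=(n, mean.size))
        return np.clip(draws, 0.0, None)

    paf_d = sample(merged["paf_mean"].values, merged["paf_lower"].values,
                   merged["paf_upper"].values)
    rate_d = sample(merged["rate"].values, merged["lower"].values,
                    merged["upper"].values)
    deaths = paf_d * rate_d * base[None, :]
    return (np.percentile(deaths, 2.5, axis=0),
            np.percentile(deaths, 97.5, axis=0))


def aggregate(
    burden: pd.DataFrame,
    by: list[str],
    value_cols: tuple[str, ...] = ("deaths_mean", "deaths_lower", "deaths_upper"),
    how: str = "sum",
) -> pd.DataFrame:
    """Aggregate stratum deaths, by sum (totals) or mean (across regions).

    Regional summary tables in this kind of analysis sometimes average the
    member provinces rather than summing them; both are offered.
    """
    if how not in ("sum", "mean"):
        raise ValueError(f"unknown aggregation {how!r}")
    grouped = burden.groupby(by, as_index=False)[list(value_cols)]
    return grouped.sum() if how == "sum" else grouped.mean()


def per_capita(
    burden: pd.DataFrame,
    demog: pd.DataFrame,
    per: float = 100_000.0,
) -> pd.DataFrame:
    """Attributable deaths per 100,000 persons by (region, year, scenario)."""
    totals = aggregate(burden, ["region", "year", "scenario"])
    demog = demog.copy()
    if "scenario" not in demog.columns:
        demog["scenario"] = "default"
    pop = (demog[["region", "year", "scenario", "pop"]]
           .drop_duplicates(["region", "year", "scenario"]))
    out = totals.merge(pop, on=["region", "year", "scenario"], validate="1:1")
    if (out["pop"] <= 0).any():
        bad = out.loc[out["pop"] <= 0, ["region", "year"]].drop_duplicates()
        raise ValueError(f"zero population; per-capita undefined for:\n{bad}")
    for col in ("deaths_mean", "deaths_lower", "deaths_upper"):
        out[col.replace("deaths", "per_capita")] = out[col] / out["pop"] * per
    return out


def older_share_by_disease(
    burden: pd.DataFrame,
    older_bands: tuple[str, ...] = OLDER_BANDS,
) -> pd.DataFrame:
    """Fraction of attributable deaths in the older bands, per disease.

    Grouped by (year, scenario, disease) pooled over regions.  Raises if a
    group has zero total deaths (the share is undefined).
    """
    unknown = set(older_bands) - set(AGE_BANDS)
    if unknown:
        raise ValueError(f"unknown age bands: {sorted(unknown)}")
    df = burden.copy()
    df["_older"] = df["age"].isin(older_bands)
    keys = ["year", "scenario", "disease"]
    total = df.groupby(keys)["deaths_mean"].sum()
    older = df[df["_older"]].groupby(keys)["deaths_mean"].sum()
    older = older.reindex(total.index, fill_value=0.0)
    if (total == 0).any():
        raise ValueError("zero total deaths in some groups; share undefined")
    out = (older / total).rename("older_share").reset_index()
    return out


def smooth_reporting(
    series: pd.DataFrame,
    value_cols: tuple[str, ...],
    window: int = 5,
    by: list[str] | None = None,
) -> pd.DataFrame:
    """Centred moving mean over years, applied at the reporting layer only.

    Annual outputs are smoothed over ``window`` years (default 5) to damp
    single-year artifacts; endpoints use the available part of the window.
    """
    df = series.sort_values("year").copy()
    keys = by or [c for c in ("region", "scenario", "disease", "age")
                  if c in df.columns]
    def _roll(g):
        for col in value_cols:
            g[col] = g[col].rolling(window, center=True, min_periods=1).mean()
        return g
    if keys:
        return (df.groupby(keys, group_keys=False)[df.columns]
                .apply(_roll).reset_index(drop=True))
    return _roll(df)
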