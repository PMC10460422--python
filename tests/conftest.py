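import numpy as np
import pandas as pd
import pytest
import xarray as xr
from hypothesis import settings

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")

from airburden.schema import AGE_BANDS, PM25_CAUSES, GroundTruth, ScenarioSpec


def component_dataset(grid=(3, 3), **levels):
    """Uniform-component aerosol dataset; unspecified components are zero."""
    rows, cols = grid
    lats = np.linspace(20.0, 30.0, rows)
    lons = np.linspace(100.0, 110.0, cols)
    data = {}
    for name in ("BC", "OA", "SO4", "SS", "dust"):
        value = float(levels.get(name, 0.0))
        data[name] = (("lat", "lon"), np.full((rows, cols), value))
    return xr.Dataset(data, coords={"lat": lats, "lon": lons})


@pytest.fixture
def scenario():
    return ScenarioSpec(name="SSP2-4.5", years=tuple(range(2000, 2020)),
                        n_models=3)


@pytest.fixture
def truth():
    return GroundTruth(
        beta1=-2.0, beta2=-0.6,
        theta_a={a: -0.01 for a in AGE_BANDS},
        phi=0.0, sigma=0.05,
    )


def sdi_panel(regions, years, lo=0.5, hi=0.95):
    """Deterministic SDI ramps straddling the 0.8 hinge."""
    rows = []
    for i, region in enumerate(regions):
        offset = 0.02 * i
        path = np.linspace(lo + offset, hi - offset, len(years))
        for year, s in zip(years, path):
            rows.append({"region": region, "year": int(year),
                         "sdi": float(np.clip(s, 0, 1))})
    return pd.DataFrame(rows)


@pytest.fixture
def small_history(truth):
    """Noise-free single-cause history for exact-recovery tests."""
    from airburden.synthetic import simulate_lograte_panel

    regions = ["A", "B", "C"]
    years = list(range(2000, 2012))
    ages = AGE_BANDS[:4]
    truth0 = GroundTruth(
        beta1=truth.beta1, beta2=truth.beta2,
        theta_a={a: truth.theta_a[a] for a in ages},
        alpha_la={(r, a): -6.0 + 0.1 * i
                  for i, (r, a) in enumerate(
                      (r, a) for r in regions for a in ages)},
        phi=0.0, sigma=0.0,
    )
    sdi = sdi_panel(regions, years)
    panel = simulate_lograte_panel(truth0, regions, ages, years, sdi, seed=0)
    panel["cause"] = "copd"
    panel["rate"] = np.exp(panel.pop("lograte"))
    return truth0, panel, sdi
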