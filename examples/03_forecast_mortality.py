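"""Forecast cause-specific mortality and constrain it to the envelope.

Log death rates follow a hinged regression on the sociodemographic index
(slope change at SDI = 0.8) with per-age time trends; AR(1) residuals carry
recent deviations forward.  Forecasts for the six pollution-related causes
are then reconciled so that causes sum to their parents and parents to the
all-cause envelope.
"""

import numpy as np

from airburden.mortality import (constrain_level2, constrain_level3,
                                 fit_stratum_residuals, fit_trend,
                                 forecast_rates)
from airburden.schema import AGE_BANDS, GroundTruth, LEVEL2_CAUSES
from airburden.synthetic import generate_mortality_history, generate_sdi

regions = ["east", "west"]
history_years = list(range(2000, 2020))
future_years = [2025, 2030, 2035]
truth = GroundTruth(beta1=-2.0, beta2=-0.8,
                    theta_a={a: -0.01 for a in AGE_BANDS}, phi=0.3,
                    sigma=0.03)
sdi = generate_sdi(regions, history_years + future_years, seed=1)
history = generate_mortality_history(truth, regions, history_years,
                                     sdi[sdi.year.isin(history_years)],
                                     seed=2, ages=AGE_BANDS[:5])
future_sdi = sdi[sdi.year.isin(future_years)]

forecasts = {}
for cause in sorted(set(history["cause"])):
    fit = fit_trend(history, sdi, cause)
    models = fit_stratum_residuals(fit)
    forecasts[cause] = forecast_rates(fit, models, future_sdi, future_years)

import pandas as pd

level2 = pd.concat([forecasts[c] for c in LEVEL2_CAUSES])
level2c = constrain_level2(level2, forecasts["all"],
                           extra_cols=("lower", "upper"))
level3 = pd.concat([forecasts[c] for c in forecasts
                    if c not in (*LEVEL2_CAUSES, "all")])
level3c = constrain_level3(level3, level2c, extra_cols=("lower", "upper"))

copd = level3c.query("cause == 'copd' and region == 'east' and age == '25-30'")
print(copd[["year", "rate", "lower", "upper"]].to_string(index=False))
check = level2c.groupby(["region", "year", "age"])["rate"].sum()
env = forecasts["all"].set_index(["region", "year", "age"])["rate"]
print("max |level-2 sum - envelope| =",
      f"{np.abs(check - env.loc[check.index]).max():.2e}",
      "(constraining is exact)")
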