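import numpy as np
import pandas as pd
import pytest

from airburden.mortality import (
    ArimaResidual,
    WhiteNoiseResidual,
    constrain_level2,
    constrain_level3,
    fit_residual,
    fit_stratum_residuals,
    fit_trend,
    forecast_rates,
    age_standardized_rate,
)
from airburden.schema import AGE_BANDS, GroundTruth
from airburden.synthetic import simulate_lograte_panel

from conftest import sdi_panel


class TestFitTrend:
    def test_noise_free_exact_recovery(self, small_history):
        truth, panel, sdi = small_history
        fit = fit_trend(panel, sdi, "copd")
        assert fit.beta1 == pytest.approx(truth.beta1, abs=1e-8)
        assert fit.beta2 == pytest.approx(truth.beta2, abs=1e-8)
        for age, theta in truth.theta_a.items():
            assert fit.theta[age] == pytest.approx(theta, abs=1e-8)
        for key, alpha in truth.alpha_la.items():
            assert fit.alpha[key] == pytest.approx(alpha, abs=1e-8)
        assert fit.sigma == pytest.approx(0.0, abs=1e-7)

    def test_constant_shift_moves_only_intercepts(self, small_history):
        truth, panel, sdi = small_history
        fit0 = fit_trend(panel, sdi, "copd")
        shifted = panel.copy()
        shifted["rate"] = shifted["rate"] * np.exp(0.7)
        fit1 = fit_trend(shifted, sdi, "copd")
        assert fit1.beta1 == pytest.approx(fit0.beta1, abs=1e-8)
        assert fit1.beta2 == pytest.approx(fit0.beta2, abs=1e-8)
        for age in fit0.theta:
            assert fit1.theta[age] == pytest.approx(fit0.theta[age], abs=1e-8)
        for key in fit0.alpha:
            assert fit1.alpha[key] - fit0.alpha[key] \
                == pytest.approx(0.7, abs=1e-8)

    def test_residuals_mean_zero_per_stratum(self, small_history):
        truth, panel, sdi = small_history
        rng = np.random.default_rng(0)
        noisy = panel.copy()
        noisy["rate"] *= np.exp(rng.normal(0, 0.05, len(panel)))
        fit = fit_trend(noisy, sdi, "copd")
        means = fit.residuals.groupby(["region", "age"])["resid"].mean()
        assert np.allclose(means.values, 0.0, atol=1e-10)

    def test_one_sided_sdi_pins_slope_with_warning(self, small_history):
        truth, panel, sdi = small_history
        low_sdi = sdi.copy()
        low_sdi["sdi"] = low_sdi["sdi"].clip(upper=0.79)
        with pytest.warns(UserWarning, match="pinned"):
            fit = fit_trend(panel, low_sdi, "copd")
        assert fit.beta1 == fit.beta2

    def test_nonpositive_rates_rejected(self, small_history):
        truth, panel, sdi = small_history
        bad = panel.copy()
        bad.loc[bad.index[0], "rate"] = 0.0
        with pytest.raises(ValueError, match="positive"):
            fit_trend(bad, sdi, "copd")

    def test_short_history_rejected(self, small_history):
        truth, panel, sdi = small_history
        short = panel[panel["year"] < 2006]
        with pytest.raises(ValueError, match="10 years"):
            fit_trend(short, sdi, "copd")


class TestFitResidual:
    def test_zero_series_gives_zero_forecast(self):
        model = fit_residual(np.zeros(20))
        mean, var = model.forecast(5)
        assert (mean == 0).all() and (var == 0).all()

    def test_ar1_forecast_decays_geometrically(self):
        rng = np.random.default_rng(1)
        x = np.zeros(200)
        for t in range(1, 200):
            x[t] = 0.6 * x[t - 1] + rng.normal(0, 1)
        model = fit_residual(x)
        assert isinstance(model, ArimaResidual)
        mean, var = model.forecast(5)
        # AR(1) mean forecasts satisfy m_{h+1} = phi * m_h exactly
        np.testing.assert_allclose(mean[1:], model.phi * mean[:-1],
                                   rtol=1e-8)
        assert (np.diff(var) >= -1e-12).all()

    def test_white_noise_residuals_forecast_near_zero(self):
        rng = np.random.default_rng(2)
        model = fit_residual(rng.normal(0, 1, 300))
        mean, _ = model.forecast(5)
        # fitted phi ~ 0, so the mean path collapses toward 0 immediately
        assert abs(model.phi) < 0.2
        assert np.all(np.abs(mean[1:]) <= np.abs(mean[0]) + 1e-12)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="10"):
            fit_residual(np.ones(5))


class TestForecast:
    def _fit(self, theta=0.0, constant_sdi=True, sigma=0.0):
        regions, ages = ["A"], (AGE_BANDS[0],)
        years = list(range(2000, 2020))
        truth = GroundTruth(beta1=-1.0, beta2=-0.3,
                            theta_a={ages[0]: theta},
                            alpha_la={("A", ages[0]): -5.0},
                            phi=0.0, sigma=sigma)
        if constant_sdi:
            sdi = sdi_panel(regions, years + [2020, 2021, 2022],
                            lo=0.6, hi=0.6)
        else:
            sdi = sdi_panel(regions, years + [2020, 2021, 2022])
        panel = simulate_lograte_panel(truth, regions, ages, years,
                                       sdi, seed=3)
        panel["cause"] = "copd"
        panel["rate"] = np.exp(panel.pop("lograte"))
        return panel, sdi, years

    def test_flat_truth_forecasts_last_value(self):
        panel, sdi, years = self._fit()
        with pytest.warns(UserWarning, match="pinned"):
            fit = fit_trend(panel, sdi, "copd")
        models = {("A", AGE_BANDS[0]): WhiteNoiseResidual(0.0)}
        out = forecast_rates(fit, models, sdi, [2020, 2021, 2022])
        last = panel[panel["year"] == years[-1]]["rate"].iloc[0]
        np.testing.assert_allclose(out["rate"].values, last, rtol=1e-10)

    def test_interval_symmetric_on_log_scale(self):
        panel, sdi, _ = self._fit(theta=-0.01, constant_sdi=False,
                                  sigma=0.03)
        fit = fit_trend(panel, sdi, "copd")
        models = fit_stratum_residuals(fit, model="white_noise")
        out = forecast_rates(fit, models, sdi, [2020, 2021])
        np.testing.assert_allclose(out["upper"] / out["rate"],
                                   out["rate"] / out["lower"], rtol=1e-10)

    def test_negative_trend_gives_decreasing_forecasts(self):
        panel, sdi, _ = self._fit(theta=-0.02)
        with pytest.warns(UserWarning, match="pinned"):
            fit = fit_trend(panel, sdi, "copd")
        models = {("A", AGE_BANDS[0]): WhiteNoiseResidual(0.0)}
        out = forecast_rates(fit, models, sdi, [2020, 2021, 2022])
        rates = out.sort_values("year")["rate"].values
        assert (np.diff(rates) < 0).all()

    def test_missing_future_sdi_rejected(self):
        panel, sdi, _ = self._fit()
        with pytest.warns(UserWarning, match="pinned"):
            fit = fit_trend(panel, sdi, "copd")
        models = {("A", AGE_BANDS[0]): WhiteNoiseResidual(0.0)}
        with pytest.raises(ValueError, match="missing future SDI"):
            forecast_rates(fit, models, sdi, [2050])

    def test_as_printed_interval_much_narrower(self):
        panel, sdi, _ = self._fit(theta=-0.01, constant_sdi=False,
                                  sigma=0.03)
        fit = fit_trend(panel, sdi, "copd")
        models = fit_stratum_residuals(fit, model="white_noise")
        default = forecast_rates(fit, models, sdi, [2021])
        printed = forecast_rates(fit, models, sdi, [2021],
                                 ci_mode="as_printed")
        assert (printed["upper"] - printed["lower"]).iloc[0] \
            < (default["upper"] - default["lower"]).iloc[0]


def _rates_frame(causes_rates, year=2030, region="A", age="65-70"):
    return pd.DataFrame([
        {"region": region, "year": year, "age": age, "cause": c, "rate": r}
        for c, r in causes_rates.items()
    ])


class TestEnvelopeConstraining:
    def test_already_consistent_unchanged(self):
        l2 = _rates_frame({"ncd": 0.006, "cmnnd": 0.003, "injuries": 0.001})
        env = _rates_frame({"all": 0.010})
        out = constrain_level2(l2, env)
        np.testing.assert_allclose(out["rate"].values, l2["rate"].values,
                                   rtol=1e-12)

    def test_level2_worked_example(self):
        l2 = _rates_frame({"ncd": 0.006, "cmnnd": 0.003, "injuries": 0.001})
        env = _rates_frame({"all": 0.008})
        out = constrain_level2(l2, env).set_index("cause")["rate"]
        assert out["ncd"] == pytest.approx(0.0048)
        assert out["cmnnd"] == pytest.approx(0.0024)
        assert out["injuries"] == pytest.approx(0.0008)

    def test_as_printed_orientation_reciprocal(self):
        l2 = _rates_frame({"ncd": 0.006, "cmnnd": 0.003, "injuries": 0.001})
        env = _rates_frame({"all": 0.008})
        out = constrain_level2(l2, env, orientation="as_printed")
        # printed factor is (sum children)/envelope = 1.25
        np.testing.assert_allclose(out["rate"].values,
                                   l2["rate"].values * 1.25, rtol=1e-12)

    def test_level3_worked_example(self):
        l3 = _rates_frame({"copd": 2e-4, "lung_cancer": 2e-4,
                           "rest_ncd": 1e-4})
        parent = _rates_frame({"ncd": 4e-4})
        out = constrain_level3(l3, parent).set_index("cause")["rate"]
        assert out["copd"] == pytest.approx(1.6e-4)
        assert out["lung_cancer"] == pytest.approx(1.6e-4)
        assert out["rest_ncd"] == pytest.approx(0.8e-4)

    def test_two_round_nested_conservation(self):
        rng = np.random.default_rng(4)
        rows2, rows3, env_rows = [], [], []
        for region in ("A", "B"):
            for year in (2030, 2031):
                l2_vals = rng.uniform(0.001, 0.01, 3)
                env_rows.append({"region": region, "year": year,
                                 "cause": "all",
                                 "rate": rng.uniform(0.005, 0.02)})
                for c, v in zip(("ncd", "cmnnd", "injuries"), l2_vals):
                    rows2.append({"region": region, "year": year,
                                  "cause": c, "rate": v})
                for c in ("copd", "lung_cancer", "ihd", "stroke",
                          "diabetes_t2", "rest_ncd", "lri", "rest_cmnnd"):
                    rows3.append({"region": region, "year": year,
                                  "cause": c,
                                  "rate": rng.uniform(1e-5, 1e-3)})
        l2 = pd.DataFrame(rows2)
        l3 = pd.DataFrame(rows3)
        env = pd.DataFrame(env_rows)
        l2c = constrain_level2(l2, env)
        l3c = constrain_level3(l3, l2c)
        keys = ["region", "year"]
        l2_sum = l2c.groupby(keys)["rate"].sum()
        env_idx = env.set_index(keys)["rate"]
        np.testing.assert_allclose(l2_sum.values,
                                   env_idx.loc[l2_sum.index].values,
                                   rtol=1e-12)
        from airburden.schema import PARENT
        fam_sum = (l3c.assign(parent=l3c["cause"].map(PARENT))
                   .groupby(keys + ["parent"])["rate"].sum())
        l2_idx = l2c.set_index(keys + ["cause"])["rate"]
        for (region, year, parent), total in fam_sum.items():
            assert total == pytest.approx(
                l2_idx.loc[(region, year, parent)], rel=1e-12)

    def test_zero_child_sum_rejected(self):
        l2 = _rates_frame({"ncd": 0.0, "cmnnd": 0.0, "injuries": 0.0})
        env = _rates_frame({"all": 0.01})
        with pytest.raises(ValueError, match="zero"):
            constrain_level2(l2, env)

    def test_nonpositive_envelope_rejected(self):
        l2 = _rates_frame({"ncd": 0.006, "cmnnd": 0.003, "injuries": 0.001})
        env = _rates_frame({"all": 0.0})
        with pytest.raises(ValueError, match="positive"):
            constrain_level2(l2, env)


def test_age_standardized_rate_uses_fixed_weights():
    rates = pd.DataFrame({
        "region": "A", "year": 2030, "cause": "copd",
        "age": ["25-30", "65-70"], "rate": [0.001, 0.01],
    })
    out = age_standardized_rate(rates, standard={"25-30": 0.9, "65-70": 0.1})
    assert out["rate"].iloc[0] == pytest.approx(0.9 * 0.001 + 0.1 * 0.01)
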