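import numpy as np
import pandas as pd
import pytest

from airburden.schema import AGE_BANDS, CAUSE_LEVEL, HIERARCHY, PARENT, \
    GroundTruth, ScenarioSpec
from airburden.synthetic import (
    generate_aerosol_fields,
    generate_demography,
    generate_mortality_history,
    generate_population,
    generate_rr_curves,
    generate_sdi,
    hinge_basis,
    largest_remainder,
    simulate_lograte_panel,
)

from conftest import sdi_panel


class TestScenarioSpec:
    def test_years_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            ScenarioSpec(name="x", years=(2001, 2000))

    def test_needs_two_models(self):
        with pytest.raises(ValueError, match="n_models"):
            ScenarioSpec(name="x", years=(2000,), n_models=1)

    def test_ground_truth_requires_stationary_residual(self):
        with pytest.raises(ValueError, match="stationary"):
            GroundTruth(phi=1.0)


class TestAerosolFields:
    def test_non_negative_and_shape(self):
        spec = ScenarioSpec(name="x", years=(2000, 2001), n_models=3)
        ds = generate_aerosol_fields(spec, (10, 10), seed=7)
        assert ds["BC"].dims == ("member", "year", "lat", "lon")
        assert ds["BC"].shape == (3, 2, 10, 10)
        for name in ("BC", "OA", "SO4", "SS", "dust"):
            assert (ds[name].values >= 0).all()

    def test_seeded_determinism_bit_identical(self):
        spec = ScenarioSpec(name="x", years=(2000, 2001), n_models=3)
        a = generate_aerosol_fields(spec, (10, 10), seed=7)
        b = generate_aerosol_fields(spec, (10, 10), seed=7)
        for name in a.data_vars:
            assert (a[name].values == b[name].values).all()
        c = generate_aerosol_fields(spec, (10, 10), seed=8)
        assert not (a["BC"].values == c["BC"].values).all()

    def test_zero_drift_year_means_equal_in_expectation(self):
        """Monte-Carlo over 100 replicates: paired year-mean differences
        are centred on zero when the concentration trend is zero."""
        spec = ScenarioSpec(name="x", years=(2000, 2001), n_models=2,
                            concentration_trend=0.0)
        diffs = []
        for seed in range(100):
            ds = generate_aerosol_fields(spec, (6, 6), seed=seed)
            m = ds["SO4"].mean(("member", "lat", "lon")).values
            diffs.append(m[1] - m[0])
        diffs = np.array(diffs)
        se = diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert abs(diffs.mean()) < 3 * se + 1e-12

    def test_positive_drift_raises_later_years(self):
        spec = ScenarioSpec(name="x", years=tuple(range(2000, 2010)),
                            n_models=2, concentration_trend=0.05)
        ds = generate_aerosol_fields(spec, (6, 6), seed=3, interannual_sd=0.0)
        m = ds["BC"].mean(("member", "lat", "lon")).values
        assert m[-1] > m[0]

    def test_invalid_grid_rejected(self):
        spec = ScenarioSpec(name="x", years=(2000,), n_models=2)
        with pytest.raises(ValueError, match="positive"):
            generate_aerosol_fields(spec, (0, 5), seed=1)


class TestPopulation:
    def test_regional_totals_exactly_conserved(self):
        raster = np.array([[0, 0], [1, 1]])
        pop = generate_population((2, 2), raster, {0: 1000, 1: 2345}, seed=1)
        assert pop.values[raster == 0].sum() == 1000
        assert pop.values[raster == 1].sum() == 2345

    def test_zero_total_gives_zero_cells(self):
        raster = np.zeros((2, 2), dtype=int)
        pop = generate_population((2, 2), raster, {0: 0}, seed=1)
        assert (pop.values == 0).all()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="raster"):
            generate_population((3, 3), np.zeros((2, 2), dtype=int),
                                {0: 10}, seed=1)

    def test_largest_remainder_uniform_7_over_3(self):
        alloc = largest_remainder(np.ones(3), 7)
        assert alloc.sum() == 7
        assert alloc.max() - alloc.min() <= 1

    def test_largest_remainder_matches_enumeration(self):
        # brute-force check: the allocation minimises the max deviation
        # |alloc - share| among integer vectors summing to the total
        weights = np.array([0.2, 0.5, 0.3])
        total = 11
        shares = total * weights / weights.sum()
        best = None
        from itertools import product
        for cand in product(range(total + 1), repeat=3):
            if sum(cand) != total:
                continue
            dev = max(abs(c - s) for c, s in zip(cand, shares))
            if best is None or dev < best[0]:
                best = (dev, cand)
        alloc = largest_remainder(weights, total)
        assert max(abs(a - s) for a, s in zip(alloc, shares)) \
            == pytest.approx(best[0])


class TestDemography:
    def test_age_proportions_sum_to_one(self):
        spec = ScenarioSpec(name="s", years=tuple(range(2020, 2031)),
                            aging_drift=0.01, n_models=2)
        demog = generate_demography(["A", "B"], spec,
                                    {"A": 10_000, "B": 20_000}, seed=2)
        sums = demog.groupby(["region", "year"])["agep"].sum()
        assert np.allclose(sums.values, 1.0, atol=1e-12)
        assert set(demog["age"]) == set(AGE_BANDS)

    def test_aging_drift_moves_mass_to_older_bands(self):
        spec = ScenarioSpec(name="s", years=tuple(range(2020, 2036)),
                            aging_drift=0.02, n_models=2)
        demog = generate_demography(["A"], spec, {"A": 10_000}, seed=2)
        older = demog[demog["age"].isin(AGE_BANDS[8:])]
        share = older.groupby("year")["agep"].sum()
        assert share.iloc[-1] > share.iloc[0]


class TestMortalityHistory:
    def test_zero_noise_matches_hinge_mean_exactly(self):
        regions, years = ["A", "B"], list(range(2000, 2012))
        ages = AGE_BANDS[:2]
        truth = GroundTruth(beta1=-1.5, beta2=-0.4,
                            theta_a={ages[0]: 0.0, ages[1]: 0.01},
                            alpha_la={(r, a): -5.0 for r in regions
                                      for a in ages},
                            phi=0.0, sigma=0.0)
        sdi = sdi_panel(regions, years)
        panel = simulate_lograte_panel(truth, regions, ages, years, sdi,
                                       seed=0)
        # independent recomputation of the regression mean
        smap = sdi.set_index(["region", "year"])["sdi"]
        for _, row in panel.iterrows():
            s = smap.loc[(row["region"], row["year"])]
            expected = (truth.beta1 * min(s, 0.8)
                        + truth.beta2 * max(s - 0.8, 0.0)
                        + truth.theta_a[row["age"]] * (row["year"] - years[0])
                        - 5.0)
            assert row["lograte"] == pytest.approx(expected, abs=1e-12)

    def test_pure_age_trend_increments_lograte_linearly(self):
        regions, years = ["A"], list(range(2000, 2012))
        ages = (AGE_BANDS[0],)
        truth = GroundTruth(beta1=0.0, beta2=0.0,
                            theta_a={ages[0]: 0.01},
                            alpha_la={("A", ages[0]): -5.0},
                            phi=0.0, sigma=0.0)
        sdi = sdi_panel(regions, years, lo=0.6, hi=0.6)  # constant SDI
        panel = simulate_lograte_panel(truth, regions, ages, years, sdi,
                                       seed=0).sort_values("year")
        steps = np.diff(panel["lograte"].values)
        np.testing.assert_allclose(steps, 0.01, atol=1e-12)

    def test_hierarchy_consistency(self, truth):
        regions, years = ["A"], list(range(2000, 2012))
        sdi = sdi_panel(regions, years)
        hist = generate_mortality_history(truth, regions, years, sdi, seed=5,
                                          ages=AGE_BANDS[:3])
        assert (hist["rate"] > 0).all()
        piv = hist.pivot_table(index=["region", "year", "age"],
                               columns="cause", values="rate")
        # level-2 parents equal the sum of their children (incl. rest)
        for parent in ("ncd", "cmnnd"):
            kids = list(HIERARCHY[parent])
            np.testing.assert_allclose(piv[parent], piv[kids].sum(axis=1),
                                       rtol=1e-12)
            # named causes leave a positive remainder below the parent
            named = [k for k in kids if not k.startswith("rest")]
            assert (piv[named].sum(axis=1) < piv[parent]).all()
        np.testing.assert_allclose(
            piv["all"], piv[["ncd", "cmnnd", "injuries"]].sum(axis=1),
            rtol=1e-12)

    def test_invalid_sdi_rejected(self, truth):
        sdi = pd.DataFrame({"region": ["A"], "year": [2000], "sdi": [1.2]})
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            simulate_lograte_panel(truth, ["A"], (AGE_BANDS[0],), [2000],
                                   sdi, seed=0)

    def test_seeded_determinism(self, truth):
        regions, years = ["A"], list(range(2000, 2012))
        sdi = sdi_panel(regions, years)
        a = generate_mortality_history(truth, regions, years, sdi, seed=9,
                                       ages=AGE_BANDS[:2])
        b = generate_mortality_history(truth, regions, years, sdi, seed=9,
                                       ages=AGE_BANDS[:2])
        pd.testing.assert_frame_equal(a, b)


class TestRRCurveGeneration:
    def test_flat_shape_is_null_curve(self):
        curves = generate_rr_curves(("copd",),
                                    {"copd": {"shape": "flat"}},
                                    n_draws=5, seed=0)
        curve = curves[("copd", "all-age")]
        assert (curve.mean_rr == 1.0).all()

    def test_anchor_at_zero_for_all_curves(self):
        curves = generate_rr_curves(n_draws=10, seed=1)
        for curve in curves.values():
            assert curve.mean_rr[0] == 1.0
            assert (curve.draws[:, 0] == 1.0).all()
            assert (np.diff(curve.mean_rr) >= 0).all()
            assert (np.diff(curve.draws, axis=1) >= 0).all()

    def test_loglinear_closed_form_on_grid(self):
        grid = np.array([0.0, 5.0, 10.0, 50.0])
        curves = generate_rr_curves(
            ("lri",), {"lri": {"shape": "loglinear", "slope": 0.01}},
            n_draws=5, seed=2, conc_grid=grid)
        np.testing.assert_allclose(curves[("lri", "all-age")].mean_rr,
                                   np.exp(0.01 * grid), rtol=1e-12)

    def test_needs_two_draws(self):
        with pytest.raises(ValueError, match="n_draws"):
            generate_rr_curves(n_draws=1, seed=0)


def test_sdi_within_unit_interval_and_rising():
    sdi = generate_sdi(["A", "B"], list(range(2000, 2030)), seed=4)
    assert ((sdi["sdi"] >= 0) & (sdi["sdi"] <= 1)).all()
    for _, grp in sdi.groupby("region"):
        vals = grp.sort_values("year")["sdi"].values
        assert (np.diff(vals) >= 0).all()


def test_hinge_basis_continuous_at_knot():
    below, above = hinge_basis(np.array([0.8 - 1e-12, 0.8, 0.8 + 1e-12]))
    total = -2.0 * below - 0.5 * above
    assert abs(total[2] - total[0]) < 1e-10
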