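"""Cox partial-likelihood core and the seasonal mortality formulations."""

import math

import numpy as np
import pytest
from scipy import optimize

import hlseason as h
from hlseason import survival as sv
from hlseason.survival import (
    ConvergenceError,
    DegenerateDesignError,
    SurvivalDesign,
)


def _toy_design(n=8, seed=1, ties=False):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    t = rng.exponential(1 / (0.1 * np.exp(0.8 * x)))
    if ties:
        t = np.floor(t) + 1
    event = rng.random(n) < 0.8
    return SurvivalDesign(t, event.astype(int), x[:, None], ["x"])


def _enumerated_partial_loglik(beta, time, event, x):
    """Direct textbook enumeration (no ties): sum over events of
    x_i beta - log sum_{j in risk set} exp(x_j beta)."""
    ll = 0.0
    for i in np.nonzero(event)[0]:
        risk = time >= time[i]
        ll += x[i] * beta - np.log(np.sum(np.exp(x[risk] * beta)))
    return ll


class TestMakeSurvival:
    def _case(self, months, status):
        return h.CaseRecord(
            case_id="c", month_dx=1, year_dx=2000, age_years=30, sex="male",
            histology="NOS", stage="I", county_latitude=40.0,
            survival_months=months, event=status)

    @pytest.mark.parametrize(
        "months,status,expected_time,expected_event",
        [
            (40, "death", 36, 0),  # death after the horizon -> censored at it
            (12, "death", 12, 1),
            (20, "censored", 20, 0),
            (36, "death", 36, 1),  # death exactly at the horizon counts
        ],
    )
    def test_horizon_censoring(self, months, status, expected_time, expected_event):
        time, event = sv.make_survival([self._case(months, status)], 36)
        assert time[0] == expected_time and event[0] == expected_event

    def test_non_positive_horizon_rejected(self):
        with pytest.raises(ValueError):
            sv.make_survival([self._case(1, "death")], 0)


class TestEncodeCovariates:
    def test_four_level_stage_gives_three_dummies(self, clean_cohort):
        design = sv.encode_covariates(clean_cohort)
        stage_cols = [c for c in design.columns if c.startswith("stage[")]
        assert stage_cols == ["stage[II]", "stage[III]", "stage[IV]"]

    def test_unseen_level_raises_with_name(self, clean_cohort):
        with pytest.raises(ValueError, match="II"):
            sv.encode_covariates(
                clean_cohort,
                factors={"stage": ("I", ("I", "III", "IV"))},
                continuous=("age_years",),
            )

    def test_interaction_column_is_elementwise_product(self, clean_cohort):
        design = sv.encode_covariates(clean_cohort)
        winter = sv._winter_indicator(clean_cohort)
        lat10 = np.array([c.county_latitude for c in clean_cohort]) / 10
        out = (design.with_column("w", winter)
                     .with_column("lat10", lat10)
                     .with_column("w:lat10", winter * lat10))
        assert np.array_equal(
            out.column("w:lat10"), out.column("w") * out.column("lat10"))

    def test_decoding_recovers_original_labels(self, clean_cohort):
        design = sv.encode_covariates(clean_cohort)
        for factor in ("sex", "histology", "stage"):
            decoded = sv.decode_factor(design, factor)
            assert decoded == [getattr(c, factor) for c in clean_cohort]


class TestFitCox:
    def test_newton_matches_enumerated_likelihood_grid(self):
        design = _toy_design(n=8, seed=3)
        fit = sv.fit_cox(design)
        res = optimize.minimize_scalar(
            lambda b: -_enumerated_partial_loglik(
                b, design.time, design.event, design.X[:, 0]),
            bounds=(-5, 5), method="bounded",
            options={"xatol": 1e-10})
        assert fit.beta[0] == pytest.approx(res.x, abs=1e-4)

    def test_efron_equals_breslow_without_ties(self):
        design = _toy_design(n=60, seed=4)
        assert len(np.unique(design.time[design.event == 1])) == int(
            design.event.sum())
        fe = sv.fit_cox(design, "efron")
        fb = sv.fit_cox(design, "breslow")
        assert np.allclose(fe.beta, fb.beta, atol=1e-12)
        assert fe.loglik == pytest.approx(fb.loglik, abs=1e-9)

    def test_matches_lifelines_with_heavy_ties(self):
        import pandas as pd
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(8)
        n = 1500
        x = rng.binomial(1, 0.4, n).astype(float)
        z = rng.normal(size=n)
        t = np.floor(rng.exponential(1 / (0.08 * np.exp(0.5 * x - 0.3 * z))))
        t = np.minimum(t, 24)
        event = (rng.random(n) < 0.9) & (t < 24)
        design = SurvivalDesign(t, event.astype(int), np.column_stack([x, z]),
                                ["x", "z"])
        fit = sv.fit_cox(design)
        cph = CoxPHFitter()
        cph.fit(pd.DataFrame({"T": t, "E": event.astype(int), "x": x, "z": z}),
                "T", "E")
        assert np.allclose(fit.beta, cph.params_.values, atol=1e-6)
        assert np.allclose(fit.se, cph.standard_errors_.values, atol=1e-6)
        assert fit.loglik == pytest.approx(cph.log_likelihood_, abs=1e-6)

    def test_true_hazard_ratio_recovered_within_ci(self):
        rng = np.random.default_rng(10)
        n = 20000
        x = rng.binomial(1, 0.5, n).astype(float)
        t = rng.exponential(1 / (0.03 * np.exp(np.log(2.0) * x)))
        horizon = 60.0
        event = (t <= horizon).astype(int)
        design = SurvivalDesign(np.minimum(t, horizon), event, x[:, None], ["x"])
        fit = sv.fit_cox(design)
        term = fit.term("x")
        assert term["ci_lower"] <= 2.0 <= term["ci_upper"]
        assert term["hr"] == pytest.approx(2.0, rel=0.1)

    def test_independent_covariate_null_behaviour(self):
        rng = np.random.default_rng(12)
        p_values, hrs = [], []
        for _ in range(40):
            n = 400
            x = rng.normal(size=n)
            t = rng.exponential(10.0, n)
            event = np.ones(n, dtype=int)
            fit = sv.fit_cox(SurvivalDesign(t, event, x[:, None], ["x"]))
            p_values.append(fit.p_values[0])
            hrs.append(fit.hazard_ratio[0])
        assert np.mean(hrs) == pytest.approx(1.0, abs=0.05)
        assert 0.3 < np.mean(p_values) < 0.7  # roughly uniform under the null

    def test_no_events_degenerate(self):
        design = SurvivalDesign(np.arange(1.0, 6.0), np.zeros(5, dtype=int),
                                np.arange(5.0)[:, None], ["x"])
        with pytest.raises(DegenerateDesignError, match="no events"):
            sv.fit_cox(design)

    def test_constant_column_flagged_by_name(self):
        design = _toy_design(20, seed=5).with_column("const", np.ones(20))
        with pytest.raises(DegenerateDesignError, match="const"):
            sv.fit_cox(design)

    def test_loglik_at_solution_beats_null(self):
        for seed in (1, 2, 3):
            fit = sv.fit_cox(_toy_design(50, seed=seed, ties=True))
            assert fit.loglik >= fit.loglik_null - 1e-12

    def test_covariate_scaling_invariance(self):
        design = _toy_design(100, seed=6, ties=True)
        fit1 = sv.fit_cox(design)
        scaled = SurvivalDesign(design.time, design.event, design.X * 10,
                                design.columns)
        fit2 = sv.fit_cox(scaled)
        assert fit2.beta[0] == pytest.approx(fit1.beta[0] / 10, rel=1e-8)
        assert fit2.p_values[0] == pytest.approx(fit1.p_values[0], abs=1e-10)


class TestSeasonalRiskTerm:
    @pytest.mark.parametrize("m,m_max,expected", [
        (3, 3, 1.0),    # diagnosis in the peak-risk month
        (9, 3, -1.0),   # six months away
        (2, 11, 0.0),   # quarter period from a November peak
        (8, 11, 0.0),
    ])
    def test_reference_values(self, m, m_max, expected):
        assert sv.seasonal_risk_term(m, m_max) == pytest.approx(expected, abs=1e-12)

    def test_out_of_range_month_rejected(self):
        with pytest.raises(ValueError):
            sv.seasonal_risk_term(0, 3)
        with pytest.raises(ValueError):
            sv.seasonal_risk_term(3, 13)

    def test_bounded_by_unit_interval(self):
        months = np.arange(1, 13)
        for m_max in range(1, 13):
            values = sv.seasonal_risk_term(months, m_max)
            assert np.all(np.abs(values) <= 1.0)


@pytest.fixture(scope="module")
def mortality_cohort():
    """10k-case cohort with a November-peaked seasonal hazard and a
    positive latitude interaction (strong effects for sign checks)."""
    config = h.SimConfig(
        n_cases=10000, seed=33,
        seasonal_log_hr=math.log(1.3), mortality_peak_month=11,
        latitude_interaction_log_hr=math.log(1.25),
        amplitude_latitude_slope=0.0)
    return h.simulate_registry(config)


class TestSeasonScan:
    def test_scan_antisymmetry_and_paired_p(self, mortality_cohort):
        cohort = mortality_cohort[:4000]
        design = sv.encode_covariates(cohort, horizon_months=36)
        scan = sv.scan_peak_month(design, [c.month_dx for c in cohort])
        beta = scan.beta1
        assert np.max(np.abs(beta + np.roll(beta, -6))) < 1e-10
        p = np.array([f.term("seasonal_risk")["p"] for f in scan.fits])
        assert np.allclose(p, np.roll(p, -6), atol=1e-8)
        hr = np.array([f.term("seasonal_risk")["hr"] for f in scan.fits])
        assert np.allclose(hr * np.roll(hr, -6), 1.0, atol=1e-10)

    def test_recovers_injected_peak_month(self, mortality_cohort):
        design = sv.encode_covariates(mortality_cohort, horizon_months=36)
        scan = sv.scan_peak_month(design, [c.month_dx for c in mortality_cohort])
        assert scan.best_m_max == 11


class TestSeasonHr:
    def test_winter_complement_gives_reciprocal_hr(self, mortality_cohort):
        cohort = mortality_cohort[:4000]
        design = sv.encode_covariates(cohort, horizon_months=36)
        winter = sv._winter_indicator(cohort)
        fit_w = sv.fit_cox(design.with_column("winter", winter))
        fit_s = sv.fit_cox(design.with_column("summer", 1.0 - winter))
        hr_w = fit_w.term("winter")["hr"]
        hr_s = fit_s.term("summer")["hr"]
        assert hr_w * hr_s == pytest.approx(1.0, abs=1e-8)

    def test_all_summer_cases_degenerate(self, mortality_cohort):
        summer_only = [c for c in mortality_cohort if c.month_dx in (3, 4, 5, 6, 7, 8)]
        with pytest.raises(DegenerateDesignError):
            sv.season_hr(summer_only[:2000], horizon_months=36)

    def test_north_south_contrast_with_injected_northern_effect(self):
        # winter-dichotomous injection confined to the north via a strong
        # latitude interaction around the split latitude
        config = h.SimConfig(
            n_cases=40000, seed=44, seasonal_form="winter",
            seasonal_log_hr=math.log(1.02),
            latitude_interaction_log_hr=math.log(1.6),
            mortality_peak_month=11, amplitude_latitude_slope=0.0)
        cohort = h.simulate_registry(config)
        h.assign_strata(cohort, h.StratumScheme())
        north = sv.season_hr(cohort, stratum=lambda c: c.north_south == "north")
        south = sv.season_hr(cohort, stratum=lambda c: c.north_south == "south")
        n_term = north.term("winter")
        s_term = south.term("winter")
        assert n_term["hr"] > 1 and n_term["ci_lower"] > 1
        assert s_term["ci_lower"] <= 1 <= s_term["ci_upper"] or s_term["hr"] < 1


class TestLatitudeInteraction:
    def test_interaction_invariant_to_latitude_shift(self, mortality_cohort):
        cohort = mortality_cohort[:4000]
        design = sv.encode_covariates(cohort, horizon_months=36)
        winter = sv._winter_indicator(cohort)
        lats = np.array([c.county_latitude for c in cohort])
        fit1 = sv.latitude_interaction(design, winter, lats)
        fit2 = sv.latitude_interaction(design, winter, lats + 7.0)
        t1, t2 = fit1.term("season:lat10"), fit2.term("season:lat10")
        assert t1["beta"] == pytest.approx(t2["beta"], abs=1e-6)
        # season main effect absorbs the shift
        assert fit1.term("season")["beta"] != pytest.approx(
            fit2.term("season")["beta"], abs=1e-3)

    def test_constant_latitude_is_collinear(self, mortality_cohort):
        cohort = mortality_cohort[:1000]
        design = sv.encode_covariates(cohort, horizon_months=36)
        winter = sv._winter_indicator(cohort)
        with pytest.raises(DegenerateDesignError):
            sv.latitude_interaction(design, winter, np.full(len(cohort), 40.0))

    def test_three_vs_five_year_horizons_agree_in_direction(self, mortality_cohort):
        for horizon in (36, 60):
            fit = sv.season_hr(mortality_cohort, horizon_months=horizon,
                               stratum=lambda c: c.north_south is None or True)
            assert fit.term("winter")["beta"] > 0  # strong injected winter risk
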