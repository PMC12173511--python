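"""Left-truncated Cox fits, AICc comparison, PH diagnostics, contrasts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from papiokit import DatasetError, SimulationConfig, simulate_cohort_for_survival
from papiokit.survival import (TABLE2_MODELS, aicc, build_survival_records,
                               fit_cox, fit_sci_mediation_set, run_model_set,
                               survival_contrast)
from papiokit.survival import test_ph as ph_test


def _weibull_cohort(rng, n, beta_x, shape=2.5, scale=21.0, entry=4.0,
                    tv_after=None):
    """Conditional-Weibull cohort with a standard-normal covariate; with
    ``tv_after`` the covariate only acts beyond that age (PH violation)."""
    x = rng.normal(size=n)
    u = rng.exponential(1.0, n)
    if tv_after is None:
        t = scale * ((entry / scale) ** shape
                     + u * np.exp(-beta_x * x)) ** (1 / shape)
    else:
        # piecewise: no effect until tv_after, full effect afterwards
        h_break = (tv_after / scale) ** shape - (entry / scale) ** shape
        t = np.where(
            u <= h_break,
            scale * ((entry / scale) ** shape + u) ** (1 / shape),
            scale * ((tv_after / scale) ** shape
                     + (u - h_break) * np.exp(-beta_x * x)) ** (1 / shape))
    cen = rng.uniform(5.0, 28.0, n)
    return pd.DataFrame({"entry_age": entry, "exit_age": np.minimum(t, cen),
                         "event": t < cen, "x": x})


class TestAicc:
    def test_formula_arithmetic(self):
        assert aicc(-400.0, 3, 216) == pytest.approx(806 + 24 / 212)

    def test_zero_parameters(self):
        assert aicc(-400.0, 0, 100) == 800.0

    def test_large_n_limit_is_aic(self):
        assert aicc(-123.4, 4, 10 ** 9) == pytest.approx(2 * 123.4 + 8, abs=1e-6)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            aicc(-10.0, 5, 6)


class TestFitCox:
    def test_truncation_is_actually_applied(self, rng):
        """With staggered entry ages, ignoring left truncation distorts the
        risk sets, so the two fits must differ; entry_age is really used."""
        n, shape, scale, beta = 3000, 2.5, 21.0, -0.4
        x = rng.normal(size=n)
        entry = rng.uniform(4.0, 14.0, n)
        u = rng.exponential(1.0, n)
        t = scale * ((entry / scale) ** shape
                     + u * np.exp(-beta * x)) ** (1 / shape)
        cen = entry + rng.uniform(1.0, 20.0, n)
        df = pd.DataFrame({"entry_age": entry,
                           "exit_age": np.minimum(t, cen),
                           "event": t < cen, "x": x})
        with_entry = fit_cox(df, ["x"])
        no_entry = fit_cox(df.assign(entry_age=1e-6), ["x"])
        assert abs(with_entry.coef["x"] - no_entry.coef["x"]) > 1e-4
        # and only the truncation-respecting fit recovers the truth well
        assert with_entry.coef["x"] == pytest.approx(beta, abs=0.1)

    def test_entry_equal_exit_rejected(self, rng):
        df = _weibull_cohort(rng, 50, beta_x=0.0)
        df.loc[0, "exit_age"] = df.loc[0, "entry_age"]
        with pytest.raises(Exception):
            fit_cox(df, ["x"])

    def test_rank_deficient_design_rejected(self, rng):
        df = _weibull_cohort(rng, 100, beta_x=0.0)
        df["x2"] = 2.0 * df["x"]
        with pytest.raises(DatasetError, match="rank-deficient"):
            fit_cox(df, ["x", "x2"])

    def test_missing_covariate_column_rejected(self, rng):
        df = _weibull_cohort(rng, 50, beta_x=0.0)
        with pytest.raises(DatasetError, match="lack covariate"):
            fit_cox(df, ["nope"])

    def test_null_interaction_ci_covers_one(self, rng):
        covered = 0
        for _ in range(20):
            df = _weibull_cohort(rng, 800, beta_x=-0.3)
            df["z"] = rng.normal(size=len(df))
            fit = fit_cox(df, ["x", "z"], interactions=[("x", "z")])
            if fit.ci_lower["x:z"] <= 1.0 <= fit.ci_upper["x:z"]:
                covered += 1
        assert covered >= 16  # nominal 95%, small Monte-Carlo sample

    def test_hr_and_ci_transforms_consistent(self, rng):
        df = _weibull_cohort(rng, 500, beta_x=-0.4)
        fit = fit_cox(df, ["x"])
        assert fit.hazard_ratios["x"] == pytest.approx(np.exp(fit.coef["x"]))
        assert fit.ci_lower["x"] < fit.hazard_ratios["x"] < fit.ci_upper["x"]


class TestModelSet:
    def test_duplicate_specs_identical_aicc(self):
        rec, _ = simulate_cohort_for_survival(SimulationConfig(), 800, seed=2)
        comp = run_model_set(rec, {"one": ["ela"], "two": ["ela"]})
        assert comp.fit("one").aicc == comp.fit("two").aicc
        assert comp.delta_aicc("two") == 0.0

    def test_aicc_ordering_invariant_to_covariate_rescaling(self):
        rec, _ = simulate_cohort_for_survival(SimulationConfig(), 800, seed=3)
        comp_a = run_model_set(rec)
        rec2 = rec.copy()
        rec2["mean_dsi_paternal"] = 10.0 * rec2["mean_dsi_paternal"] + 3.0
        rec2["coresidency_years"] = 0.1 * rec2["coresidency_years"]
        comp_b = run_model_set(rec2)
        pd.testing.assert_frame_equal(comp_a.table(), comp_b.table())

    def test_failed_member_reported_not_fatal(self):
        rec, _ = simulate_cohort_for_survival(SimulationConfig(), 400, seed=4)
        comp = run_model_set(rec, {"ok": ["ela"], "bad": ["missing_term"]})
        assert "bad" in comp.errors
        assert [f.name for f in comp.fits] == ["ok"]

    def test_interaction_models_join_the_comparison(self):
        rec, _ = simulate_cohort_for_survival(SimulationConfig(), 800, seed=5)
        comp = run_model_set(
            rec, interactions={
                "AxDSI": (["ela", "mean_dsi_paternal", "coresidency_years"],
                          [("ela", "mean_dsi_paternal")])})
        assert "AxDSI" in [f.name for f in comp.fits]
        assert "ela:mean_dsi_paternal" in comp.fit("AxDSI").terms


class TestProportionalHazards:
    def test_null_p_values_roughly_uniform(self):
        cfg = SimulationConfig()
        ps = []
        for seed in range(1, 41):
            rec, _ = simulate_cohort_for_survival(cfg, 400, seed=seed)
            fit = fit_cox(rec, ["ela", "mean_dsi_paternal"])
            ps.append(ph_test(fit).loc["GLOBAL", "p"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_time_varying_effect_detected(self, rng):
        detected = 0
        for _ in range(10):
            df = _weibull_cohort(rng, 2000, beta_x=-1.2, tv_after=14.0)
            fit = fit_cox(df, ["x"])
            if ph_test(fit).loc["x", "p"] < 0.05:
                detected += 1
        assert detected >= 8

    def test_zero_covariate_model_rejected(self, rng):
        df = _weibull_cohort(rng, 200, beta_x=0.0)
        fit = fit_cox(df, ["x"])
        fit.terms = []
        with pytest.raises(DatasetError):
            ph_test(fit)


class TestSurvivalContrast:
    PROFILE = {"ela": 1.0, "mean_dsi_paternal": 0.0, "coresidency_years": 2.0}

    def _fit(self, seed=1, n=5000):
        rec, _ = simulate_cohort_for_survival(SimulationConfig(), n, seed=seed)
        return fit_cox(rec, ["ela", "mean_dsi_paternal", "coresidency_years"])

    def test_identical_profiles_zero(self):
        fit = self._fit()
        assert survival_contrast(fit, self.PROFILE, self.PROFILE) == 0.0

    def test_protective_covariate_gain_nonnegative(self):
        fit = self._fit()
        better = dict(self.PROFILE, mean_dsi_paternal=1.0)  # HR < 1 term
        assert survival_contrast(fit, self.PROFILE, better) >= 0.0

    def test_matches_closed_form_weibull_medians(self):
        """The Breslow-baseline contrast approximates the analytic
        difference of conditional-Weibull medians; a large cohort keeps the
        step-function medians of both profiles well resolved."""
        cfg = SimulationConfig()
        sur = cfg.survival
        lo = dict(self.PROFILE, mean_dsi_paternal=-2.0)
        hi = dict(self.PROFILE, mean_dsi_paternal=2.0)

        def analytic_median(profile):
            eta = (sur.log_hr_ela * (profile["ela"] - sur.ela_center)
                   + sur.log_hr_dsi_paternal * profile["mean_dsi_paternal"]
                   + sur.log_hr_coresidency * (profile["coresidency_years"]
                                               - sur.coresidency_center_years))
            k, lam = sur.weibull_shape, sur.weibull_scale
            return lam * ((4 / lam) ** k + np.log(2) * np.exp(-eta)) ** (1 / k)

        expected = analytic_median(hi) - analytic_median(lo)
        got = survival_contrast(self._fit(n=20000), lo, hi)
        assert got == pytest.approx(expected, rel=0.05)

    def test_unreached_median_reported_unbounded(self):
        cfg = SimulationConfig()
        cfg.survival.weibull_scale = 80.0   # almost nobody dies in frame
        rec, _ = simulate_cohort_for_survival(cfg, 2000, seed=6)
        fit = fit_cox(rec, ["ela"])
        assert survival_contrast(fit, {"ela": 1.0}, {"ela": 1.5}) is None


class TestSciMediation:
    def test_sci_only_generator_prefers_sci_models(self):
        cfg = SimulationConfig()
        cfg.survival.log_hr_dsi_paternal = 0.0
        cfg.survival.log_hr_coresidency = 0.0
        cfg.survival.log_hr_sci_f = np.log(0.7)
        wins = 0
        for seed in range(1, 6):
            rec, _ = simulate_cohort_for_survival(cfg, 3000, seed=seed)
            comp = fit_sci_mediation_set(rec)
            if "sci_f" in comp.best().terms:
                wins += 1
        assert wins >= 4

    def test_joint_effects_select_both_terms(self):
        cfg = SimulationConfig()
        cfg.survival.log_hr_sci_f = np.log(0.75)
        rec, _ = simulate_cohort_for_survival(cfg, 5000, seed=7)
        best = fit_sci_mediation_set(rec).best()
        assert "sci_f" in best.terms
        assert "mean_dsi_paternal" in best.terms or \
            "coresidency_years" in best.terms

    def test_missing_sci_columns_informative_error(self):
        rec, _ = simulate_cohort_for_survival(SimulationConfig(), 300, seed=8)
        with pytest.raises(DatasetError, match="connectedness"):
            fit_sci_mediation_set(rec.drop(columns=["sci_f", "sci_m"]))


class TestBuildRecords:
    def _inputs(self):
        summaries = pd.DataFrame({
            "female_id": ["F1", "F2"],
            "mean_dsi_paternal": [0.5, -0.5],
            "mean_dsi_nonpaternal": [0.0, 0.0],
            "mean_dsi_all": [0.1, -0.1],
        })
        ela = pd.DataFrame({"female_id": ["F1", "F2"], "cumulative": [1, 3]})
        cores = pd.Series({"F1": 730, "F2": 0})
        ind = pd.DataFrame({
            "id": ["F1", "F2"], "sex": ["F", "F"],
            "birth_date": pd.to_datetime(["2000-01-01", "2000-01-01"]),
            "death_date": pd.to_datetime(
                [pd.Timestamp("2000-01-01")
                 + pd.Timedelta(days=int(10.2 * 365.25)), pd.NaT]),
            "censor_date": pd.to_datetime(
                [pd.NaT, pd.Timestamp("2000-01-01")
                 + pd.Timedelta(days=int(7.0 * 365.25))]),
            "mother_id": [np.nan, np.nan], "father_id": [np.nan, np.nan],
        })
        return summaries, ela, cores, ind

    def test_death_and_censor_records(self):
        summaries, ela, cores, ind = self._inputs()
        rec = build_survival_records(summaries, ela, cores, ind)
        f1 = rec[rec["female_id"] == "F1"].iloc[0]
        assert (f1["entry_age"], f1["event"]) == (4.0, True)
        assert f1["exit_age"] == pytest.approx(10.2, abs=0.01)
        assert f1["coresidency_years"] == pytest.approx(2.0, abs=0.01)
        f2 = rec[rec["female_id"] == "F2"].iloc[0]
        assert not f2["event"]
        assert f2["exit_age"] == pytest.approx(7.0, abs=0.01)

    def test_exit_before_entry_rejected(self):
        summaries, ela, cores, ind = self._inputs()
        ind.loc[1, "censor_date"] = pd.Timestamp("2003-01-01")
        with pytest.raises(DatasetError, match="exit age"):
            build_survival_records(summaries, ela, cores, ind)

    def test_no_exit_date_rejected(self):
        summaries, ela, cores, ind = self._inputs()
        ind.loc[1, "censor_date"] = pd.NaT
        with pytest.raises(DatasetError, match="neither death nor censor"):
            build_survival_records(summaries, ela, cores, ind)
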