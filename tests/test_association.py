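"""Mixed-model analyses: candidate sets, averaging, VIF, descriptive fits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from papiokit import DatasetError, SimulationConfig, simulate_father_years
from papiokit.association import (AssocComparison, MixedFit, TABLE3_TERMS,
                                  candidate_subsets, compute_vif,
                                  fit_allmale_grooming_model,
                                  fit_coresidency_model,
                                  fit_dsiall_father_model,
                                  fit_grooming_occurrence_model,
                                  fit_initiation_model, fit_lmm, model_average)


def _fake_fit(name, terms, betas, ses, loglik, k=3, n=100):
    return MixedFit(name=name, terms=terms,
                    params=pd.Series(betas, index=terms),
                    se=pd.Series(ses, index=terms),
                    re_var=0.1, resid_var=1.0, loglik=loglik, k=k, n=n,
                    n_groups=10, converged=True)


class TestModelAveraging:
    def test_singleton_subset_is_identity(self):
        fit = _fake_fit("m", ["a", "b"], [1.5, -0.7], [0.2, 0.3], -50.0)
        avg = model_average(AssocComparison(fits=[fit]), n=1)
        row = avg.set_index("term")
        assert row.loc["a", "beta"] == pytest.approx(1.5)
        assert row.loc["a", "se"] == pytest.approx(0.2)
        assert row.loc["b", "beta"] == pytest.approx(-0.7)
        assert row.loc["b", "se"] == pytest.approx(0.3)

    def test_equal_models_get_half_weights(self):
        f1 = _fake_fit("m1", ["a"], [2.0], [0.5], -50.0)
        f2 = _fake_fit("m2", ["a"], [2.0], [0.5], -50.0)
        avg = model_average(AssocComparison(fits=[f1, f2]), n=2)
        row = avg.set_index("term").loc["a"]
        assert row["beta"] == pytest.approx(2.0)
        assert row["se"] == pytest.approx(0.5)
        assert row["weight"] == pytest.approx(1.0)  # both models contain 'a'

    def test_three_model_manual_oracle(self):
        """Weights and conditional averages recomputed from first principles
        (AICc -> Akaike weights -> weighted means and unconditional SE)."""
        from papiokit.survival import aicc
        f1 = _fake_fit("m1", ["a"], [1.0], [0.30], -50.0, k=2)
        f2 = _fake_fit("m2", ["a", "b"], [1.4, 0.5], [0.40, 0.2], -49.0, k=3)
        f3 = _fake_fit("m3", ["b"], [0.8], [0.25], -52.0, k=2)
        avg = model_average(AssocComparison(fits=[f1, f2, f3]), n=3)

        a_vals = np.array([aicc(-50, 2, 100), aicc(-49, 3, 100),
                           aicc(-52, 2, 100)])
        w = np.exp(-(a_vals - a_vals.min()) / 2)
        w /= w.sum()
        # term 'a' appears in models 1 and 2
        wa = w[[0, 1]] / w[[0, 1]].sum()
        beta_a = wa[0] * 1.0 + wa[1] * 1.4
        se_a = np.sqrt(wa[0] * (0.30 ** 2 + (1.0 - beta_a) ** 2)
                       + wa[1] * (0.40 ** 2 + (1.4 - beta_a) ** 2))
        row = avg.set_index("term").loc["a"]
        assert row["beta"] == pytest.approx(beta_a)
        assert row["se"] == pytest.approx(se_a)
        assert row["weight"] == pytest.approx(w[0] + w[1])

    @given(st.lists(st.tuples(st.floats(-60, -40), st.floats(-2, 2)),
                    min_size=1, max_size=8))
    @settings(max_examples=50, deadline=None)
    def test_weights_sum_to_one(self, specs):
        fits = [_fake_fit(f"m{i}", ["a"], [b], [0.5], ll)
                for i, (ll, b) in enumerate(specs)]
        avg = model_average(AssocComparison(fits=fits), n=len(fits))
        assert avg.set_index("term").loc["a", "weight"] == pytest.approx(1.0)

    def test_empty_set_rejected(self):
        with pytest.raises(DatasetError, match="empty"):
            model_average(AssocComparison(fits=[]))


class TestVif:
    def test_orthogonal_predictors_unity(self):
        x = pd.DataFrame({"a": [1, 1, -1, -1.0], "b": [1, -1, 1, -1.0]})
        assert np.allclose(compute_vif(x), 1.0)

    def test_known_correlation_closed_form(self, rng):
        """Sample correlation exactly 0.6 gives VIF = 1/(1-0.36) = 1.5625."""
        n = 50
        z1 = rng.normal(size=n)
        z2 = rng.normal(size=n)
        z1 = (z1 - z1.mean()) / z1.std()
        z2 = z2 - z2.mean()
        z2 -= z1 * (z1 @ z2) / (z1 @ z1)          # orthogonalize
        z2 /= z2.std()
        x = pd.DataFrame({"a": z1, "b": 0.6 * z1 + 0.8 * z2})
        assert compute_vif(x)["b"] == pytest.approx(1.5625)

    def test_duplicate_column_infinite(self, rng):
        v = rng.normal(size=30)
        x = pd.DataFrame({"a": v, "b": v})
        assert np.isinf(compute_vif(x)).all()

    def test_single_predictor_rejected(self):
        with pytest.raises(ValueError):
            compute_vif(pd.DataFrame({"a": [1.0, 2.0, 3.0]}))


class TestCandidateSubsets:
    def test_small_set_is_all_subsets(self):
        subs = candidate_subsets(["a", "b"], max_models=64)
        assert subs == [(), ("a",), ("b",), ("a", "b")]

    def test_cap_keeps_full_model(self):
        terms = [f"t{i}" for i in range(11)]
        subs = candidate_subsets(terms, max_models=64)
        assert len(subs) == 64
        assert tuple(terms) in subs
        assert subs[0] == ()

    def test_deterministic(self):
        terms = [f"t{i}" for i in range(9)]
        assert candidate_subsets(terms, 32) == candidate_subsets(terms, 32)


class TestInitiationModel:
    def test_rising_initiation_with_age_recovered(self, default_sim,
                                                  default_cohort):
        ds, _ = default_sim
        fit = fit_initiation_model(ds, default_cohort)
        slope = SimulationConfig().grooming.initiation_age_slope
        assert fit.params["age"] > 0
        assert abs(fit.params["age"] - slope) < 3 * fit.se["age"] + 0.15

    def test_age_independent_initiation_null(self):
        from papiokit.simulate import simulate_population
        from papiokit.dataset import analysis_cohort
        from conftest import small_config
        cfg = small_config(seed=21, n_females=60, n_groups=5)
        cfg.grooming.initiation_age_slope = 0.0
        ds, _ = simulate_population(cfg)
        fit = fit_initiation_model(ds, analysis_cohort(ds))
        assert abs(fit.params["age"]) < 3 * fit.se["age"]

    def test_no_events_raises(self):
        from papiokit.fixtures import make_fixture
        ds = make_fixture("two_dyad_dsi")
        empty = ds.grooming.iloc[0:0]
        ds2 = type(ds)(**{**ds.tables(), "grooming": empty})
        with pytest.raises(DatasetError, match="no juvenile"):
            fit_initiation_model(ds2, ["FA", "FB"])


class TestDsiAllFatherModel:
    def test_father_effect_positive_and_supported(self, default_dsi):
        fit_with, fit_without, delta = fit_dsiall_father_model(default_dsi)
        assert fit_with.params["is_father"] > 0.3
        assert delta > 10.0  # adding the father term earns decisive support

    def test_constant_father_flag_rejected(self, default_dsi):
        nof = default_dsi[~default_dsi["is_father"]]
        with pytest.raises(DatasetError, match="constant"):
            fit_dsiall_father_model(nof)


@pytest.fixture(scope="module")
def father_years():
    rows, truth = simulate_father_years(SimulationConfig(), 2500, seed=31)
    return rows, truth


class TestGroomingOccurrenceSet:
    def test_consort_effect_sign_recovered_in_best_model(self, father_years):
        rows, truth = father_years
        comp = fit_grooming_occurrence_model(rows, max_models=32,
                                             group_col="father_id")
        best = comp.best()
        # fit the full model to read the sign regardless of selection
        full = [f for f in comp.fits if len(f.terms) == len(TABLE3_TERMS) + 1]
        assert full, "full model missing from capped candidate set"
        assert full[0].params["consort_proportion"] > 0
        assert best.aicc <= comp.table()["aicc"].min() + 1e-9

    def test_null_effects_keep_intercept_model_close(self):
        rng = np.random.default_rng(5)
        n = 600
        rows = pd.DataFrame({
            "father_id": rng.integers(0, 60, n).astype(str),
            "a": rng.normal(size=n), "b": rng.normal(size=n),
            "groomed": rng.random(n) < 0.4,
        })
        comp = fit_grooming_occurrence_model(rows, terms=["a", "b"],
                                             group_col="father_id")
        tab = comp.table().set_index("model")
        assert tab.loc["(intercept)", "delta_aicc"] <= 4.0

    def test_constant_predictor_dropped_with_set_still_running(self,
                                                               father_years):
        rows, _ = father_years
        rows = rows.copy()
        rows["ela"] = 2.0
        comp = fit_grooming_occurrence_model(rows, max_models=16,
                                             group_col="father_id")
        assert all("ela" not in f.terms for f in comp.fits)


class TestCoresidencyModel:
    def _pair_rows(self, rng, n=200, beta_page=0.15):
        fathers = rng.integers(0, 60, n)
        u = rng.normal(0, 0.4, 60)
        page = rng.uniform(8, 20, n)
        rank = rng.integers(1, 13, n).astype(float)
        y = 1.0 + beta_page * page + 0.0 * rank + u[fathers] + rng.normal(0, 0.8, n)
        return pd.DataFrame({
            "father_id": [f"M{j}" for j in fathers],
            "paternal_age": page, "rank": rank,
            "fertile_rate": rng.beta(2, 8, n),
            "coresidency_years": y,
        })

    def test_paternal_age_effect_recovered(self, rng):
        rows = self._pair_rows(rng)
        comp = fit_coresidency_model(
            rows, terms=["paternal_age", "rank", "fertile_rate"])
        full = [f for f in comp.fits if len(f.terms) == 3][0]
        assert full.params["paternal_age"] == pytest.approx(
            0.15, abs=3 * full.se["paternal_age"])

    def test_sired_next_excluded_by_design(self, rng):
        rows = self._pair_rows(rng)
        rows["sired_next"] = 0.0
        with pytest.raises(DatasetError, match="sired_next"):
            fit_coresidency_model(rows, terms=["paternal_age", "sired_next"])

    def test_degenerate_grouping_falls_back_to_ols(self, rng):
        rows = self._pair_rows(rng, n=8)
        rows["father_id"] = [f"M{j}" for j in range(8)]  # one row per father
        comp = fit_coresidency_model(rows, terms=["paternal_age"],
                                     max_models=4)
        assert all(f.model_type == "ols_fallback" for f in comp.fits)


class TestAllMaleModel:
    def test_father_term_always_present(self, rng):
        n = 800
        father = rng.random(n) < 0.1
        consort = np.where(father, rng.beta(3, 2, n), 0.0)
        u = rng.normal(0, 0.4, 80)
        male = rng.integers(0, 80, n)
        eta = -1.5 + 1.2 * father + 1.0 * consort + u[male]
        rows = pd.DataFrame({
            "male_id": [f"M{j}" for j in male],
            "is_father": father,
            "consort_proportion": consort,
            "rank": rng.integers(1, 13, n).astype(float),
            "groomed": rng.random(n) < 1 / (1 + np.exp(-eta)),
        })
        comp = fit_allmale_grooming_model(rows, terms=["consort_proportion",
                                                       "rank"], max_models=8)
        assert all("is_father" in f.terms for f in comp.fits)
        full = max(comp.fits, key=lambda f: len(f.terms))
        assert full.params["is_father"] > 0

    def test_no_nonfather_rows_rejected(self, rng):
        rows = pd.DataFrame({
            "male_id": ["M1"] * 10, "is_father": [True] * 10,
            "rank": rng.normal(size=10), "groomed": [True] * 5 + [False] * 5,
        })
        with pytest.raises(DatasetError, match="non-father"):
            fit_allmale_grooming_model(rows, terms=["rank"])
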