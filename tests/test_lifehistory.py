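"""Co-residency, adversity profiles and conception-window covariates."""

import numpy as np
import pandas as pd
import pytest

from papiokit import DatasetError, PopulationDataset
from papiokit.dataset import add_years
from papiokit.fixtures import make_fixture
from papiokit.lifehistory import (
    compute_consort_proportion, compute_coresidency, compute_ela_profiles,
    compute_fertile_female_rate, compute_offspring_years,
    count_potential_fathers,
)

from oracle_utils import (brute_coresidency, brute_fertile_rate,
                          brute_offspring_years, brute_potential_fathers,
                          random_mini_dataset)


class TestCoresidency:
    def test_father_departs_at_500_days(self):
        ds = make_fixture("two_dyad_dsi")
        res = ds.residencies.copy()
        birth = pd.Timestamp("2001-01-01")
        res.loc[res["individual_id"] == "MA", "end_date"] = \
            birth + pd.Timedelta(days=499)  # inclusive end: days 0..499
        ds2 = type(ds)(**{**ds.tables(), "residencies": res})
        assert compute_coresidency(ds2, "FA") == 500

    def test_father_immigrates_for_100_days(self):
        ds = make_fixture("two_dyad_dsi")
        res = ds.residencies.copy()
        birth = pd.Timestamp("2001-01-01")
        m = res["individual_id"] == "MA"
        res.loc[m, "start_date"] = birth + pd.Timedelta(days=100)
        res.loc[m, "end_date"] = birth + pd.Timedelta(days=199)
        ds2 = type(ds)(**{**ds.tables(), "residencies": res})
        assert compute_coresidency(ds2, "FA") == 100

    def test_missing_father_raises(self):
        ds = make_fixture("two_dyad_dsi")
        ind = ds.individuals.copy()
        ind.loc[ind["id"] == "FA", "father_id"] = np.nan
        ds2 = type(ds)(**{**ds.tables(), "individuals": ind})
        with pytest.raises(DatasetError, match="no father assignment"):
            compute_coresidency(ds2, "FA")


class TestBruteForceOracles:
    """Interval arithmetic must agree with day-by-day scans on randomized
    residency/ovulation/rank fixtures."""

    def test_coresidency_matches_day_scan(self, rng):
        for _ in range(60):
            ds, fid, father = random_mini_dataset(rng)
            birth = ds.individual(fid)["birth_date"]
            expected = brute_coresidency(ds, fid, father, birth,
                                         add_years(birth, 4))
            assert compute_coresidency(ds, fid) == expected

    def test_fertile_rate_matches_day_scan(self, rng):
        checked = 0
        for _ in range(60):
            ds, fid, father = random_mini_dataset(rng)
            birth = ds.individual(fid)["birth_date"]
            w = (birth, add_years(birth, 1))
            expected = brute_fertile_rate(ds, father, *w)
            if expected is None:
                with pytest.raises(DatasetError, match="no resident days"):
                    compute_fertile_female_rate(ds, father, w)
            else:
                assert compute_fertile_female_rate(ds, father, w) == \
                    pytest.approx(expected)
                checked += 1
        assert checked >= 10

    def test_offspring_years_matches_day_scan(self, rng):
        for _ in range(60):
            ds, fid, father = random_mini_dataset(rng)
            birth = ds.individual(fid)["birth_date"]
            w = (birth, add_years(birth, 1))
            assert compute_offspring_years(ds, father, w, exclude=fid) == \
                pytest.approx(brute_offspring_years(ds, father, birth, w[1],
                                                    exclude=fid))

    def test_potential_fathers_matches_day_scan(self, rng):
        for _ in range(60):
            ds, fid, _ = random_mini_dataset(rng)
            assert count_potential_fathers(ds, fid) == \
                brute_potential_fathers(ds, fid)


class TestElaProfiles:
    EXPECTED = pd.DataFrame({
        "female_id": [f"F{i}" for i in range(1, 9)],
        "drought": [1, 0, 0, 1, 0, 0, 0, 0],
        "maternal_loss": [0, 0, 1, 0, 0, 0, 1, 0],
        "large_group": [0, 0, 0, 0, 0, 0, 1, 1],
        "close_sibling": [1, 1, 0, 0, 0, 0, 0, 0],
        "low_maternal_rank": [1, 0, 0, 0, 0, 0, 0, 1],
        "maternal_isolation": [1, 0, 0, 0, 0, 0, 0, 1],
        "cumulative": [4, 1, 1, 1, 0, 0, 2, 3],
    })

    def test_eight_female_fixture_exact_profiles(self):
        """Every component flag on the hand-designed fixture matches the
        values derived by hand from its rainfall, deaths, group sizes,
        interbirth intervals, ranks and maternal grooming."""
        ds = make_fixture("eight_female_ela")
        prof = compute_ela_profiles(ds, [f"F{i}" for i in range(1, 9)])
        got = prof.astype({c: int for c in prof.columns if c != "female_id"})
        pd.testing.assert_frame_equal(got.reset_index(drop=True), self.EXPECTED)

    def test_cumulative_is_flag_sum(self, default_sim, default_cohort):
        ds, _ = default_sim
        prof = compute_ela_profiles(ds, default_cohort)
        comps = ["drought", "maternal_loss", "large_group", "close_sibling",
                 "low_maternal_rank", "maternal_isolation"]
        assert (prof[comps].sum(axis=1) == prof["cumulative"]).all()
        assert prof["cumulative"].between(0, 6).all()

    def test_quartile_flags_near_quarter(self, default_sim, default_cohort):
        ds, _ = default_sim
        prof = compute_ela_profiles(ds, default_cohort)
        for comp in ("low_maternal_rank", "maternal_isolation",
                     "large_group", "close_sibling"):
            assert 0.12 <= prof[comp].mean() <= 0.38

    def test_unevaluable_component_raises_named(self):
        ds = make_fixture("eight_female_ela")
        rain = ds.rainfall[ds.rainfall["period_start"] != pd.Timestamp("2001-07-01")]
        ds2 = type(ds)(**{**ds.tables(), "rainfall": rain.reset_index(drop=True)})
        with pytest.raises(DatasetError, match="'drought' unevaluable"):
            compute_ela_profiles(ds2, [f"F{i}" for i in range(1, 9)])

    def test_maternal_loss_at_age_three_point_five(self):
        ds = make_fixture("eight_female_ela")
        ind = ds.individuals.copy()
        # F5's mother dies at daughter age 3.5 -> flag must raise
        death = pd.Timestamp("2005-07-01") + pd.Timedelta(days=int(3.5 * 365.25))
        m5 = ind["id"] == "M5"
        ind.loc[m5, "death_date"] = death
        ind.loc[m5, "censor_date"] = pd.NaT
        res = ds.residencies.copy()
        res.loc[res["individual_id"] == "M5", "end_date"] = death
        ds2 = type(ds)(**{**ds.tables(), "individuals": ind, "residencies": res})
        prof = compute_ela_profiles(ds2, [f"F{i}" for i in range(1, 9)])
        assert bool(prof.loc[prof["female_id"] == "F5", "maternal_loss"].iloc[0])


def _consort_fixture():
    """two_dyad fixture plus a mother, conception window and consorts."""
    ds = make_fixture("two_dyad_dsi")
    ind = ds.individuals.copy()
    censor = pd.Timestamp("2006-01-01")
    mom = pd.DataFrame([("MOMA", "F", pd.Timestamp("1992-01-01"), pd.NaT,
                         censor, np.nan, np.nan)], columns=ind.columns)
    ind = pd.concat([ind, mom], ignore_index=True)
    ind["mother_id"] = ind["mother_id"].astype(object)
    ind.loc[ind["id"] == "FA", "mother_id"] = "MOMA"
    res = pd.concat([ds.residencies, pd.DataFrame(
        [("MOMA", "G1", pd.Timestamp("1999-01-01"), censor)],
        columns=ds.residencies.columns)], ignore_index=True)
    conc = pd.Timestamp("2001-01-01") - pd.Timedelta(days=178)
    ov = pd.DataFrame([("MOMA", conc - pd.Timedelta(days=4), conc, True)],
                      columns=["female_id", "start_date", "end_date",
                               "conception_flag"])
    consorts = pd.DataFrame(
        [("MA", "MOMA", conc - pd.Timedelta(days=2), 60.0),
         ("MB", "MOMA", conc - pd.Timedelta(days=1), 40.0)],
        columns=["male_id", "female_id", "date", "observed_minutes"])
    return type(ds)(**{**ds.tables(), "individuals": ind, "residencies": res,
                       "ovulation": ov, "consorts": consorts}).validate()


class TestConsortProportion:
    def test_father_share(self):
        ds = _consort_fixture()
        assert compute_consort_proportion(ds, "FA") == pytest.approx(0.6)

    def test_no_observed_consorts_is_excluded_marker(self):
        ds = _consort_fixture()
        empty = ds.consorts.iloc[0:0]
        ds2 = type(ds)(**{**ds.tables(), "consorts": empty})
        assert compute_consort_proportion(ds2, "FA") is None

    def test_single_male_monopoly(self):
        ds = _consort_fixture()
        only = ds.consorts[ds.consorts["male_id"] == "MA"].reset_index(drop=True)
        ds2 = type(ds)(**{**ds.tables(), "consorts": only})
        assert compute_consort_proportion(ds2, "FA") == pytest.approx(1.0)


class TestFertileRateExamples:
    def test_no_overlapping_windows_gives_zero(self):
        ds = _consort_fixture()
        w = (pd.Timestamp("2002-01-01"), pd.Timestamp("2003-01-01"))
        assert compute_fertile_female_rate(ds, "MA", w) == 0.0

    def test_five_fertile_days_over_fifty(self):
        ds = _consort_fixture()
        ov = pd.concat([ds.ovulation, pd.DataFrame(
            [("MOMA", pd.Timestamp("2002-01-10"), pd.Timestamp("2002-01-14"),
              False)], columns=ds.ovulation.columns)], ignore_index=True)
        ds2 = type(ds)(**{**ds.tables(), "ovulation": ov})
        w = (pd.Timestamp("2002-01-01"), pd.Timestamp("2002-02-20"))
        assert compute_fertile_female_rate(ds2, "MA", w) == pytest.approx(5 / 50)


class TestOffspringYears:
    def test_no_other_offspring(self):
        ds = _consort_fixture()
        w = (pd.Timestamp("2001-01-01"), pd.Timestamp("2002-01-01"))
        assert compute_offspring_years(ds, "MA", w, exclude="FA") == 0.0

    def test_one_full_year_coresident_offspring(self):
        ds = _consort_fixture()
        w = (pd.Timestamp("2001-01-01"), pd.Timestamp("2002-01-01"))
        assert compute_offspring_years(ds, "MA", w) == \
            pytest.approx(365 / 365.25)
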