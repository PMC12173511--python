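"""Father-daughter co-residency, cumulative early-life adversity, and the
covariates used to model why fathers groom and co-reside with daughters.

The cumulative early-life adversity (ELA) index counts six binary conditions
experienced before age 4: first-year drought (<200 mm rainfall), maternal
death, birth into a large group, a close-in-age younger sibling, a
low-ranking mother, and a socially isolated mother. Quartile-based
components use thresholds computed once over the analysis population
(configurable literal overrides honour the conventional cutoffs of >=36
adults and <1.5-year interbirth intervals).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import (
    PopulationDataset, DatasetError, add_years,
    FEMALE_ADULT_AGE_YEARS, MALE_ADULT_AGE_YEARS, JUVENILE_YEARS, DAYS_PER_YEAR,
)
from .sociality import maternal_isolation_scores

__all__ = [
    "DatasetIndex", "ElaThresholds", "compute_coresidency", "population_quartiles",
    "compute_ela", "compute_ela_profiles", "compute_consort_proportion",
    "compute_fertile_female_rate", "compute_offspring_years",
    "count_potential_fathers", "build_paternal_covariates",
    "build_coresidency_covariates",
]

ELA_COMPONENTS = ["drought", "maternal_loss", "large_group", "close_sibling",
                  "low_maternal_rank", "maternal_isolation"]


def _overlap_days(a0, a1, b0, b1) -> int:
    """Days in the intersection of half-open day windows [a0,a1) and [b0,b1)."""
    lo, hi = max(a0, b0), min(a1, b1)
    return max(0, (hi - lo).days)


class DatasetIndex:
    """Pre-grouped lookups over a dataset, for repeated covariate queries."""

    def __init__(self, ds: PopulationDataset):
        self.ds = ds
        self.res_by_id = dict(tuple(ds.residencies.groupby("individual_id", sort=False)))
        self.res_by_group = dict(tuple(ds.residencies.groupby("group_id", sort=False)))
        self.ranks_by_id: dict[str, dict[str, int]] = {}
        for iid, mo, rk in zip(ds.ranks["individual_id"], ds.ranks["month"],
                               ds.ranks["ordinal_rank"]):
            self.ranks_by_id.setdefault(iid, {})[mo] = int(rk)
        ovr = _ovulation_residency(ds)
        self.ov_by_group = dict(tuple(ovr.groupby("group_id", sort=False)))
        kids = ds.individuals[ds.individuals["father_id"].notna()]
        self.kids_by_father = dict(tuple(kids.groupby("father_id", sort=False)))
        g = ds.grooming
        self.groom_dates: dict[tuple[str, str], np.ndarray] = {
            pair: np.sort(sub["date"].to_numpy())
            for pair, sub in g.groupby(["actor_id", "recipient_id"], sort=False)
        }

    def segments(self, individual_id: str) -> pd.DataFrame:
        seg = self.res_by_id.get(individual_id)
        if seg is None:
            return self.ds.residencies.iloc[0:0]
        return seg


def _segments(res_or_index, individual_id: str) -> pd.DataFrame:
    if isinstance(res_or_index, DatasetIndex):
        return res_or_index.segments(individual_id)
    return res_or_index[res_or_index["individual_id"] == individual_id]


def _shared_group_days(res, id_a: str, id_b: str,
                       w0: pd.Timestamp, w1: pd.Timestamp) -> int:
    """Days in [w0, w1) on which both individuals reside in the same group.

    ``res`` is the residency table or a :class:`DatasetIndex`."""
    one_day = pd.Timedelta(days=1)
    total = 0
    for sa in _segments(res, id_a).itertuples():
        for sb in _segments(res, id_b).itertuples():
            if sa.group_id != sb.group_id:
                continue
            lo = max(sa.start_date, sb.start_date, w0)
            hi = min(sa.end_date + one_day, sb.end_date + one_day, w1)
            total += max(0, (hi - lo).days)
    return total


def compute_coresidency(ds: PopulationDataset, female_id: str,
                        father_id: str | None = None) -> int:
    """Cumulative days the female and her father lived in the same group
    during her first four years of life."""
    row = ds.individual(female_id)
    if father_id is None:
        father_id = row["father_id"]
    if pd.isna(father_id):
        raise DatasetError(f"female {female_id!r} has no father assignment",
                           table="individuals")
    w0, w1 = row["birth_date"], add_years(row["birth_date"], JUVENILE_YEARS)
    return _shared_group_days(ds.residencies, female_id, father_id, w0, w1)


# --------------------------------------------------------------------------
# early-life adversity
# --------------------------------------------------------------------------

@dataclass
class ElaThresholds:
    """Population quartile thresholds plus the per-female raw traits."""

    group_size_threshold: float    # flag if group size at birth >= this
    ibi_threshold_years: float     # flag if next sibling born < this after focal
    maternal_rank_threshold: float # flag if mother's ordinal rank >= this
    isolation_threshold: float     # flag if maternal grooming index <= this
    raw: pd.DataFrame              # per-female raw trait values


def _group_size_at_birth(ds: PopulationDataset, female_id: str) -> int:
    """Adults (females >=4 y, males >=7 y) resident in the natal group on the
    female's birth date, the focal's mother included, the newborn excluded."""
    row = ds.individual(female_id)
    birth = row["birth_date"]
    res = ds.residencies
    natal = res[(res["individual_id"] == female_id) & (res["start_date"] <= birth)
                & (res["end_date"] >= birth)]
    if not len(natal):
        raise DatasetError(f"female {female_id!r} has no natal residency",
                           table="residencies")
    gid = natal["group_id"].iloc[0]
    present = res[(res["group_id"] == gid) & (res["start_date"] <= birth)
                  & (res["end_date"] >= birth)]
    ind = ds.individuals.set_index("id")
    ages = (birth - present["individual_id"].map(ind["birth_date"])).dt.days / DAYS_PER_YEAR
    sexes = present["individual_id"].map(ind["sex"])
    adult = np.where(sexes == "F", ages >= FEMALE_ADULT_AGE_YEARS,
                     ages >= MALE_ADULT_AGE_YEARS)
    return int(adult.sum())


def _next_sibling_ibi(ds: PopulationDataset, female_id: str) -> float:
    """Years to the next younger maternal sibling's birth; inf if none."""
    row = ds.individual(female_id)
    mom = row["mother_id"]
    if pd.isna(mom):
        raise DatasetError(f"female {female_id!r} has no known mother",
                           table="individuals")
    ind = ds.individuals
    sibs = ind[(ind["mother_id"] == mom) & (ind["birth_date"] > row["birth_date"])]
    if not len(sibs):
        return np.inf
    return (sibs["birth_date"].min() - row["birth_date"]).days / DAYS_PER_YEAR


def _maternal_rank_at_birth(ds: PopulationDataset, female_id: str) -> int:
    row = ds.individual(female_id)
    mom = row["mother_id"]
    month = row["birth_date"].strftime("%Y-%m")
    hit = ds.ranks[(ds.ranks["individual_id"] == mom) & (ds.ranks["month"] == month)]
    if not len(hit):
        raise DatasetError(
            f"ELA component 'low_maternal_rank' unevaluable for {female_id!r}: "
            f"no rank record for mother {mom} in {month}", table="ranks")
    return int(hit["ordinal_rank"].iloc[0])


def _first_year_rainfall(ds: PopulationDataset, female_id: str) -> float:
    birth = ds.individual(female_id)["birth_date"]
    hit = ds.rainfall[ds.rainfall["period_start"] == birth]
    if not len(hit):
        raise DatasetError(
            f"ELA component 'drought' unevaluable for {female_id!r}: no "
            f"rainfall record for the 12 months from {birth.date()}", table="rainfall")
    return float(hit["total_mm"].iloc[0])


def population_quartiles(ds: PopulationDataset, females: list[str],
                         group_size_override: float | None = None,
                         ibi_override_years: float | None = None) -> ElaThresholds:
    """Raw adversity traits for every female and the population thresholds.

    Each quartile threshold is the type-7 (linear interpolation) quantile of
    the raw trait over the analysis population; the group-size and
    interbirth-interval cutoffs may be overridden with fixed literals.
    """
    rows = []
    for fid in females:
        rows.append(dict(
            female_id=fid,
            rainfall_mm=_first_year_rainfall(ds, fid),
            group_size=_group_size_at_birth(ds, fid),
            ibi_years=_next_sibling_ibi(ds, fid),
            maternal_rank=_maternal_rank_at_birth(ds, fid),
        ))
    raw = pd.DataFrame(rows)
    iso = maternal_isolation_scores(ds, females)
    raw["isolation_score"] = raw["female_id"].map(iso)
    if raw["isolation_score"].isna().any():
        bad = raw.loc[raw["isolation_score"].isna(), "female_id"].iloc[0]
        raise DatasetError(
            f"ELA component 'maternal_isolation' unevaluable for {bad!r}")
    finite_ibi = raw.loc[np.isfinite(raw["ibi_years"]), "ibi_years"]
    return ElaThresholds(
        group_size_threshold=(group_size_override if group_size_override is not None
                              else float(np.quantile(raw["group_size"], 0.75,
                                                     method="linear"))),
        ibi_threshold_years=(ibi_override_years if ibi_override_years is not None
                             else float(np.quantile(finite_ibi, 0.25, method="linear"))
                             if len(finite_ibi) >= 4 else 1.5),
        maternal_rank_threshold=float(np.quantile(raw["maternal_rank"], 0.75,
                                                  method="linear")),
        isolation_threshold=float(np.quantile(raw["isolation_score"], 0.25,
                                              method="linear")),
        raw=raw.set_index("female_id"),
    )


def compute_ela(ds: PopulationDataset, female_id: str,
                thresholds: ElaThresholds,
                drought_threshold_mm: float = 200.0) -> pd.Series:
    """The six adversity flags and their cumulative sum for one female."""
    if female_id not in thresholds.raw.index:
        raise DatasetError(f"female {female_id!r} not in the threshold population")
    raw = thresholds.raw.loc[female_id]
    row = ds.individual(female_id)
    mom = row["mother_id"]
    mom_death = ds.individual(mom)["death_date"] if pd.notna(mom) else pd.NaT
    if pd.isna(mom):
        raise DatasetError(
            f"ELA component 'maternal_loss' unevaluable for {female_id!r}: "
            "no known mother", table="individuals")
    flags = pd.Series({
        "drought": raw["rainfall_mm"] < drought_threshold_mm,
        "maternal_loss": (pd.notna(mom_death)
                          and mom_death < add_years(row["birth_date"], JUVENILE_YEARS)),
        "large_group": raw["group_size"] >= thresholds.group_size_threshold,
        "close_sibling": (np.isfinite(raw["ibi_years"])
                          and raw["ibi_years"] < thresholds.ibi_threshold_years),
        "low_maternal_rank": raw["maternal_rank"] >= thresholds.maternal_rank_threshold,
        "maternal_isolation": raw["isolation_score"] <= thresholds.isolation_threshold,
    }).astype(bool)
    flags["cumulative"] = int(flags[ELA_COMPONENTS].sum())
    flags["female_id"] = female_id
    return flags


def compute_ela_profiles(ds: PopulationDataset, females: list[str],
                         thresholds: ElaThresholds | None = None,
                         drought_threshold_mm: float = 200.0,
                         group_size_override: float | None = None,
                         ibi_override_years: float | None = None) -> pd.DataFrame:
    """ELA profiles (six flags + cumulative 0-6 score) for a set of females."""
    if thresholds is None:
        thresholds = population_quartiles(ds, females, group_size_override,
                                          ibi_override_years)
    rows = [compute_ela(ds, fid, thresholds, drought_threshold_mm)
            for fid in females]
    out = pd.DataFrame(rows)
    return out[["female_id"] + ELA_COMPONENTS + ["cumulative"]].reset_index(drop=True)


# --------------------------------------------------------------------------
# conception-window covariates
# --------------------------------------------------------------------------

def conception_window(ds: PopulationDataset, female_id: str) -> tuple[pd.Timestamp, pd.Timestamp]:
    """The 5-day peri-ovulatory window at the female's conception: her
    mother's conception-flagged ovulation window immediately before birth."""
    row = ds.individual(female_id)
    mom = row["mother_id"]
    if pd.isna(mom):
        raise DatasetError(f"female {female_id!r} has no known mother")
    ov = ds.ovulation
    cand = ov[(ov["female_id"] == mom) & ov["conception_flag"]
              & (ov["end_date"] < row["birth_date"])]
    if not len(cand):
        raise DatasetError(f"no conception window recorded for mother {mom} "
                           f"of {female_id!r}", table="ovulation")
    best = cand.loc[(row["birth_date"] - cand["end_date"]).idxmin()]
    return best["start_date"], best["end_date"]


def compute_consort_proportion(ds: PopulationDataset, female_id: str,
                               male_id: str | None = None) -> float | None:
    """Share of the mother's observed conceptive consort time held by the
    male (her father by default). ``None`` marks the excluded case where no
    consorts were observed in the window (sparse sampling, not evidence of
    absence)."""
    row = ds.individual(female_id)
    target = row["father_id"] if male_id is None else male_id
    w0, w1 = conception_window(ds, female_id)
    mom = row["mother_id"]
    c = ds.consorts
    sub = c[(c["female_id"] == mom) & (c["date"] >= w0) & (c["date"] <= w1)]
    total = sub["observed_minutes"].sum()
    if total <= 0:
        return None
    own = sub.loc[sub["male_id"] == target, "observed_minutes"].sum()
    return float(own / total)


def _ovulation_residency(ds: PopulationDataset) -> pd.DataFrame:
    """Ovulation windows joined to the cycling female's residency intervals
    (suffix ``_x`` = ovulation window, ``_y`` = residency)."""
    return ds.ovulation.merge(ds.residencies, left_on="female_id",
                              right_on="individual_id")


def compute_fertile_female_rate(ds: PopulationDataset, male_id: str,
                                window: tuple[pd.Timestamp, pd.Timestamp],
                                index: DatasetIndex | None = None) -> float:
    """Mean daily count of peri-ovulatory females in the male's group over
    the days in [w0, w1) on which he was resident."""
    w0, w1 = window
    one_day = pd.Timedelta(days=1)
    male_segs = _segments(index if index is not None else ds.residencies, male_id)
    resident_days = 0
    fertile_days = 0.0
    ov_by_group = (index.ov_by_group if index is not None
                   else dict(tuple(_ovulation_residency(ds).groupby("group_id",
                                                                    sort=False))))
    for seg in male_segs.itertuples():
        s0, s1 = max(seg.start_date, w0), min(seg.end_date + one_day, w1)
        if s1 <= s0:
            continue
        resident_days += (s1 - s0).days
        pool = ov_by_group.get(seg.group_id)
        if pool is None:
            continue
        sub = pool[(pool["end_date_x"] >= s0) & (pool["start_date_x"] < s1)]
        for w in sub.itertuples():
            lo = max(w.start_date_x, w.start_date_y, s0)
            hi = min(w.end_date_x + one_day, w.end_date_y + one_day, s1)
            fertile_days += max(0, (hi - lo).days)
    if resident_days == 0:
        raise DatasetError(f"male {male_id!r} has no resident days in "
                           f"[{w0.date()}, {w1.date()})")
    return fertile_days / resident_days


def compute_offspring_years(ds: PopulationDataset, male_id: str,
                            window: tuple[pd.Timestamp, pd.Timestamp],
                            exclude: str | None = None,
                            index: DatasetIndex | None = None) -> float:
    """Juvenile (under-4) offspring of the male alive and co-resident with
    him inside the window, scaled by their days of co-residency (in years)."""
    w0, w1 = window
    if index is not None:
        kids = index.kids_by_father.get(male_id, ds.individuals.iloc[0:0])
    else:
        kids = ds.individuals[ds.individuals["father_id"] == male_id]
    res = index if index is not None else ds.residencies
    total_days = 0
    for kid in kids.itertuples():
        if kid.id == exclude:
            continue
        k0 = max(w0, kid.birth_date)
        k1 = min(w1, add_years(kid.birth_date, JUVENILE_YEARS))
        exit_date = kid.death_date if pd.notna(kid.death_date) else kid.censor_date
        if pd.notna(exit_date):
            k1 = min(k1, exit_date + pd.Timedelta(days=1))
        if k1 <= k0:
            continue
        total_days += _shared_group_days(res, kid.id, male_id, k0, k1)
    return total_days / DAYS_PER_YEAR


def count_potential_fathers(ds: PopulationDataset, female_id: str,
                            index: DatasetIndex | None = None) -> int:
    """Distinct adult ranked males resident in the mother's group during the
    5-day peri-ovulatory conception window."""
    w0, w1 = conception_window(ds, female_id)
    mom = ds.individual(female_id)["mother_id"]
    mom_segs = _segments(index if index is not None else ds.residencies, mom)
    mom_segs = mom_segs[(mom_segs["start_date"] <= w1) & (mom_segs["end_date"] >= w0)]
    if not len(mom_segs):
        raise DatasetError(f"mother {mom} has no residency over the conception "
                           f"window of {female_id!r}", table="residencies")
    months = set()
    d = w0.normalize()
    while d <= w1:
        months.add(d.strftime("%Y-%m"))
        d += pd.offsets.MonthBegin(1)
    months.add(w1.strftime("%Y-%m"))
    if index is not None:
        ranked = {iid for iid, by_month in index.ranks_by_id.items()
                  if months & by_month.keys()}
    else:
        ranked = set(ds.ranks.loc[ds.ranks["month"].isin(months), "individual_id"])
    ind = ds.individuals.set_index("id")
    males = set()
    for seg in mom_segs.itertuples():
        if index is not None:
            pool = index.res_by_group.get(seg.group_id, ds.residencies.iloc[0:0])
        else:
            pool = ds.residencies[ds.residencies["group_id"] == seg.group_id]
        cand = pool[(pool["start_date"] <= w1) & (pool["end_date"] >= w0)]
        for mid in cand["individual_id"]:
            if mid in males or mid not in ranked:
                continue
            if ind.at[mid, "sex"] == "M":
                males.add(mid)
    return len(males)


# --------------------------------------------------------------------------
# father-year and pair-level covariate tables
# --------------------------------------------------------------------------

def _mean_rank_over_window(ds: PopulationDataset, male_id: str,
                           w0: pd.Timestamp, w1: pd.Timestamp,
                           index: DatasetIndex | None = None) -> float:
    months = pd.date_range(w0.normalize().replace(day=1), w1, freq="MS").strftime("%Y-%m")
    if index is not None:
        by_month = index.ranks_by_id.get(male_id, {})
        vals = [by_month[m] for m in months if m in by_month]
        return float(np.mean(vals)) if vals else np.nan
    r = ds.ranks
    sub = r[(r["individual_id"] == male_id) & (r["month"].isin(set(months)))]
    return float(sub["ordinal_rank"].mean()) if len(sub) else np.nan


def _sired_flag(ds: PopulationDataset, female_id: str, which: str) -> float:
    """1/0 if the father did/did not sire the mother's previous or next
    offspring; NaN when that sibling's paternity (or the sibling) is unknown."""
    row = ds.individual(female_id)
    ind = ds.individuals
    sibs = ind[(ind["mother_id"] == row["mother_id"]) & (ind["id"] != female_id)]
    if which == "previous":
        sibs = sibs[sibs["birth_date"] < row["birth_date"]]
        if not len(sibs):
            return np.nan
        sib = sibs.loc[sibs["birth_date"].idxmax()]
    else:
        sibs = sibs[sibs["birth_date"] > row["birth_date"]]
        if not len(sibs):
            return np.nan
        sib = sibs.loc[sibs["birth_date"].idxmin()]
    if pd.isna(sib["father_id"]):
        return np.nan
    return float(sib["father_id"] == row["father_id"])


def build_paternal_covariates(ds: PopulationDataset, females: list[str],
                              dyad_years: pd.DataFrame,
                              all_males: bool = False,
                              min_coresidency_days: int = 30) -> pd.DataFrame:
    """Per male-year covariate rows for the grooming-occurrence models.

    One row per (juvenile female, male, year of life) with >=
    ``min_coresidency_days`` days of co-residency; restricted to fathers
    unless ``all_males``. ``groomed`` records whether the male was observed
    grooming the juvenile (male is the actor) inside the window. Missing
    consort proportions (no observed conceptive consorts) and unknown
    sibling paternities are NaN; dropping them is the caller's choice.
    """
    ind = ds.individuals.set_index("id")
    dy = dyad_years
    dy = dy[dy["female_id"].isin(set(females))
            & (dy["coresident_days"] >= min_coresidency_days)]
    if not all_males:
        dy = dy[dy["is_father"]]

    index = DatasetIndex(ds)
    cp_cache: dict[tuple[str, str], float | None] = {}
    sired_cache: dict[tuple[str, str], float] = {}
    pf_cache: dict[str, int] = {}
    rows = []
    for r in dy.itertuples():
        fid, mid = r.female_id, r.male_id
        w0, w1 = r.window_start, r.window_end
        key = (fid, mid)
        if key not in cp_cache:
            cp_cache[key] = compute_consort_proportion(ds, fid, mid)
        if fid not in pf_cache:
            pf_cache[fid] = count_potential_fathers(ds, fid, index)
        for which in ("previous", "next"):
            if (fid, which) not in sired_cache:
                sired_cache[(fid, which)] = _sired_flag(ds, fid, which)
        dates = index.groom_dates.get((mid, fid))
        groomed = bool(dates is not None
                       and np.searchsorted(dates, np.datetime64(w1))
                       > np.searchsorted(dates, np.datetime64(w0)))
        cp = cp_cache[key]
        rows.append(dict(
            female_id=fid, male_id=mid, year_of_life=r.year_of_life,
            is_father=bool(r.is_father),
            coresident_days=r.coresident_days,
            rank=_mean_rank_over_window(ds, mid, w0, w1, index),
            fertile_rate=compute_fertile_female_rate(ds, mid, (w0, w1), index),
            consort_proportion=np.nan if cp is None else cp,
            n_potential_fathers=pf_cache[fid],
            sired_previous=sired_cache[(fid, "previous")] if r.is_father else 0.0,
            sired_next=sired_cache[(fid, "next")] if r.is_father else 0.0,
            offspring_years=compute_offspring_years(ds, mid, (w0, w1),
                                                    exclude=fid, index=index),
            juvenile_age=r.year_of_life + 0.5,
            paternal_age=(w0 - ind.at[mid, "birth_date"]).days / DAYS_PER_YEAR,
            maternal_age=((w0 - ind.at[ind.at[fid, "mother_id"], "birth_date"]).days
                          / DAYS_PER_YEAR),
            observer_effort=r.effort,
            groomed=groomed,
        ))
    return pd.DataFrame(rows)


def build_coresidency_covariates(ds: PopulationDataset, females: list[str],
                                 require_coresidency: bool = True) -> pd.DataFrame:
    """One row per father-daughter pair for the co-residency-duration models.

    Predictors are taken at/around the month co-residency ended, following
    the design in which a male's circumstances at departure explain how long
    he stayed. Pairs that never co-resided are excluded by default.
    """
    ind = ds.individuals.set_index("id")
    one_day = pd.Timedelta(days=1)
    index = DatasetIndex(ds)
    rows = []
    for fid in females:
        father = ind.at[fid, "father_id"]
        if pd.isna(father):
            raise DatasetError(f"female {fid!r} has no father assignment")
        birth = ind.at[fid, "birth_date"]
        w0, w1 = birth, add_years(birth, JUVENILE_YEARS)
        days = _shared_group_days(index, fid, father, w0, w1)
        if days == 0 and require_coresidency:
            continue
        # last day of co-residency inside the juvenile window
        fa_segs = _segments(index, father)
        end_day = birth
        for seg in fa_segs.itertuples():
            hi = min(seg.end_date + one_day, w1) - one_day
            if hi >= seg.start_date:
                end_day = max(end_day, hi)
        month_start = end_day.normalize().replace(day=1)
        month_end = month_start + pd.offsets.MonthBegin(1)
        cp = compute_consort_proportion(ds, fid)
        try:
            fert = compute_fertile_female_rate(ds, father, (month_start, month_end),
                                               index)
        except DatasetError:
            fert = np.nan
        rows.append(dict(
            female_id=fid, father_id=father,
            coresidency_days=days,
            rank=_mean_rank_over_window(ds, father, month_start, month_start, index),
            fertile_rate=fert,
            consort_proportion=np.nan if cp is None else cp,
            n_potential_fathers=count_potential_fathers(ds, fid),
            sired_previous=_sired_flag(ds, fid, "previous"),
            offspring_years=compute_offspring_years(
                ds, father, (end_day - pd.Timedelta(days=182),
                             end_day + pd.Timedelta(days=183)),
                exclude=fid, index=index),
            ela=np.nan,  # filled by callers that have profiles
            paternal_age=(end_day - ind.at[father, "birth_date"]).days / DAYS_PER_YEAR,
            maternal_age=((end_day - ind.at[ind.at[fid, "mother_id"], "birth_date"]).days
                          / DAYS_PER_YEAR),
        ))
    return pd.DataFrame(rows)
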