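"""Dyadic sociality index (DSI) and adult social connectedness (SCI).

The DSI scores each juvenile-female x adult-male pair, per year of the
female's life (birthday to birthday): the pair's daily grooming rate is
log-transformed, regressed against observer effort, and the residual z-scored
within the year-of-life stratum so that every score is comparable to all
other juvenile female-male pairs at the same life stage. Negative scores are
dyads that groomed less than typical, positive scores more.

Three variants differ only in which males enter a female's summary:
``DSI_all`` uses every adult male co-resident >=30 days, ``DSI_paternal`` the
father only (including father-absent years, which receive the shared
zero-grooming floor value), ``DSI_non-paternal`` the co-resident non-fathers.

The SCI applies the same rate -> effort-residual -> z-score construction to
an adult female's total grooming given and received with adult females
(``SCI_F``) and adult males (``SCI_M``), one value per female-year, averaged
over her adult years.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .dataset import (
    PopulationDataset, DatasetError, add_years,
    FEMALE_ADULT_AGE_YEARS, MALE_ADULT_AGE_YEARS, JUVENILE_YEARS, DAYS_PER_YEAR,
)

__all__ = [
    "EPSILON", "MIN_CORESIDENCY_DAYS",
    "build_dyad_years", "adjust_for_effort", "zscore_within_stratum",
    "compute_dsi", "summarize_females", "summarize_female",
    "compute_sci", "maternal_isolation_scores",
]

logger = logging.getLogger(__name__)

#: additive floor for log daily rates: one event per ten observation-years.
#: Guarantees all zero-grooming dyads (co-resident or not) share one value.
EPSILON = 1.0 / 3650.0

#: minimum days of co-residency for a dyad-year to enter DSI_all/non-paternal.
MIN_CORESIDENCY_DAYS = 30


def _day_weighted_effort(effort: pd.DataFrame, group_id, w0, w1) -> np.ndarray:
    """Day-weighted mean of group-calendar-year effort over [w0, w1) windows."""
    eff = {(r.group_id, r.year): r.effort for r in effort.itertuples()}
    out = np.empty(len(group_id))
    for i, (g, a, b) in enumerate(zip(group_id, w0, w1)):
        total, acc = 0, 0.0
        for year in range(a.year, b.year + 1):
            y0 = max(a, pd.Timestamp(year=year, month=1, day=1))
            y1 = min(b, pd.Timestamp(year=year + 1, month=1, day=1))
            days = (y1 - y0).days
            if days <= 0:
                continue
            e = eff.get((g, year))
            if e is None:
                raise DatasetError(f"no effort record for group {g}, year {year}",
                                   table="effort")
            total += days
            acc += days * e
        out[i] = acc / total if total else np.nan
    return out


def _pair_counts(grooming: pd.DataFrame, focal_ids: set) -> pd.DataFrame:
    """Grooming events with one focal participant, keyed (focal, partner)."""
    g = grooming
    a_focal = g["actor_id"].isin(focal_ids)
    r_focal = g["recipient_id"].isin(focal_ids)
    sub = g[a_focal | r_focal].copy()
    af = sub["actor_id"].isin(focal_ids)
    sub["focal_id"] = np.where(af, sub["actor_id"], sub["recipient_id"])
    sub["partner_id"] = np.where(af, sub["recipient_id"], sub["actor_id"])
    return sub


def build_dyad_years(ds: PopulationDataset, females: list[str] | None = None,
                     min_coresidency_days: int = MIN_CORESIDENCY_DAYS,
                     epsilon: float = EPSILON) -> pd.DataFrame:
    """One record per (juvenile female, co-resident adult male, year of life).

    Co-resident days come from interval intersection of the pair's residency
    in the same group within the half-open birthday window. Father dyads are
    always emitted, even with zero co-residency (flagged ``noncoresident``,
    carrying the zero-grooming log rate). ``included`` marks dyads meeting
    the co-residency threshold, the only ones entering DSI_all.
    """
    ind = ds.individuals.set_index("id")
    if females is None:
        females = sorted(ind[(ind["sex"] == "F") & ind["father_id"].notna()].index)

    res = ds.residencies
    male_birth = ind.loc[ind["sex"] == "M", "birth_date"]
    male_res = res[res["individual_id"].isin(male_birth.index)].copy()
    male_res = male_res.merge(male_birth.rename("male_birth"),
                              left_on="individual_id", right_index=True)

    rows = []
    for fid in females:
        birth = ind.at[fid, "birth_date"]
        father = ind.at[fid, "father_id"]
        fres = res[res["individual_id"] == fid]
        try:
            fexit = ds.exit_date(fid)
        except DatasetError:
            fexit = None
        for k in range(JUVENILE_YEARS):
            w0, w1 = add_years(birth, k), add_years(birth, k + 1)
            alive_end = w1 if fexit is None else min(w1, fexit + pd.Timedelta(days=1))
            if alive_end <= w0:
                continue
            # female presence intervals inside the window
            fseg = fres[(fres["start_date"] < alive_end) & (fres["end_date"] >= w0)]
            covered = int((fseg["end_date"].clip(upper=alive_end - pd.Timedelta(days=1))
                           - fseg["start_date"].clip(lower=w0)).dt.days.sum()
                          + len(fseg))
            window_days = (alive_end - w0).days
            if covered < window_days:
                raise DatasetError(
                    f"female {fid} lacks residency coverage for year-of-life {k}",
                    table="residencies")
            mid = w0 + (alive_end - w0) / 2
            home_group = fseg["group_id"].iloc[0]
            seen: dict[str, int] = {}
            for seg in fseg.itertuples():
                s0 = max(seg.start_date, w0)
                s1 = min(seg.end_date + pd.Timedelta(days=1), alive_end)
                cand = male_res[male_res["group_id"] == seg.group_id]
                adult = ((mid - cand["male_birth"]).dt.days
                         >= MALE_ADULT_AGE_YEARS * DAYS_PER_YEAR)
                cand = cand[adult | (cand["individual_id"] == father)]
                lo = np.maximum(cand["start_date"].to_numpy(), np.datetime64(s0))
                hi = np.minimum(cand["end_date"].to_numpy() + np.timedelta64(1, "D"),
                                np.datetime64(s1))
                days = ((hi - lo) / np.timedelta64(1, "D")).astype(int).clip(min=0)
                for mid_id, d in zip(cand["individual_id"], days):
                    if d > 0:
                        seen[mid_id] = seen.get(mid_id, 0) + int(d)
            if pd.notna(father) and father not in seen:
                seen[father] = 0
            for mid_id, d in sorted(seen.items()):
                rows.append((fid, mid_id, k, w0, alive_end, d,
                             mid_id == father, home_group))
    out = pd.DataFrame(rows, columns=["female_id", "male_id", "year_of_life",
                                      "window_start", "window_end",
                                      "coresident_days", "is_father", "group_id"])

    # grooming counts in either direction inside the window
    pair = _pair_counts(ds.grooming, set(females))
    key = ["female_id", "male_id", "year_of_life"]
    if len(pair) and len(out):
        merged = pair.merge(out[key + ["window_start", "window_end"]],
                            left_on=["focal_id", "partner_id"],
                            right_on=["female_id", "male_id"])
        inside = ((merged["date"] >= merged["window_start"])
                  & (merged["date"] < merged["window_end"]))
        counts = merged[inside].groupby(key).size()
        out["groom_count"] = pd.MultiIndex.from_frame(out[key]).map(counts).fillna(0).astype(int)
    else:
        out["groom_count"] = 0

    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(out["coresident_days"] > 0,
                        out["groom_count"] / out["coresident_days"].replace(0, np.nan),
                        0.0)
    out["daily_rate"] = np.nan_to_num(rate)
    out["log_rate"] = np.log(out["daily_rate"] + epsilon)
    out["included"] = out["coresident_days"] >= min_coresidency_days
    out["noncoresident"] = out["coresident_days"] == 0

    # observer effort, day-weighted over the calendar years the window spans
    out["effort"] = _day_weighted_effort(ds.effort, out["group_id"],
                                         out["window_start"], out["window_end"])
    return out


def adjust_for_effort(records: pd.DataFrame,
                      stratum_col: str = "year_of_life") -> pd.DataFrame:
    """Residuals of log grooming rate on observer effort, per stratum.

    The OLS line is fitted over included dyads; its prediction is subtracted
    from every record in the stratum (so non-co-resident father-years are
    positioned relative to the same line).
    """
    out = records.copy()
    out["residual"] = np.nan
    for stratum, idx in out.groupby(stratum_col).groups.items():
        sub = out.loc[idx]
        fit = sub[sub["included"]]
        if len(fit) < 3:
            raise DatasetError(
                f"stratum {stratum!r} has {len(fit)} included dyads; "
                "need >= 3 for the effort regression")
        x = fit["effort"].to_numpy(float)
        y = fit["log_rate"].to_numpy(float)
        vx = x.var()
        if vx > 0:
            b = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        else:
            b = 0.0
        a = y.mean() - b * x.mean()
        out.loc[idx, "residual"] = out.loc[idx, "log_rate"] - (a + b * out.loc[idx, "effort"])
    return out


def zscore_within_stratum(records: pd.DataFrame,
                          stratum_col: str = "year_of_life",
                          value_col: str = "residual",
                          out_col: str = "dsi") -> pd.DataFrame:
    """z-score residuals within strata; moments come from included dyads."""
    out = records.copy()
    out[out_col] = np.nan
    for stratum, idx in out.groupby(stratum_col).groups.items():
        sub = out.loc[idx]
        base = sub[sub["included"]] if "included" in sub else sub
        if len(base) < 2:
            raise DatasetError(f"stratum {stratum!r} has fewer than 2 dyads; "
                               "z-score undefined")
        m = base[value_col].mean()
        s = base[value_col].std(ddof=1)
        if s == 0:
            raise DatasetError(f"stratum {stratum!r} has zero variance")
        out.loc[idx, out_col] = (out.loc[idx, value_col] - m) / s
    return out


def compute_dsi(ds: PopulationDataset, females: list[str] | None = None,
                min_coresidency_days: int = MIN_CORESIDENCY_DAYS,
                epsilon: float = EPSILON,
                stratum_col: str = "year_of_life") -> pd.DataFrame:
    """Full DSI pipeline: dyad years -> effort residuals -> z-scores."""
    records = build_dyad_years(ds, females, min_coresidency_days, epsilon)
    records = adjust_for_effort(records, stratum_col)
    return zscore_within_stratum(records, stratum_col)


def _restandardize(values: pd.DataFrame, col: str) -> pd.Series:
    """z-score ``col`` across females within each year-of-life; degenerate
    strata (n < 2 or zero variance) pass through unchanged with a warning."""
    out = pd.Series(np.nan, index=values.index)
    for k, idx in values.groupby("year_of_life").groups.items():
        v = values.loc[idx, col]
        s = v.std(ddof=1)
        if len(v) < 2 or not np.isfinite(s) or s == 0:
            logger.warning("degenerate re-standardization stratum year=%s (n=%d); "
                           "values passed through", k, len(v))
            out.loc[idx] = v
        else:
            out.loc[idx] = (v - v.mean()) / s
    return out


def summarize_females(dsi_records: pd.DataFrame) -> pd.DataFrame:
    """Per-female summaries: mean DSI_paternal / non-paternal / all.

    Annual values are re-standardized across females within each year of
    life, then averaged over the female's available juvenile years.
    """
    rec = dsi_records
    pat = rec[rec["is_father"]].set_index(["female_id", "year_of_life"])["dsi"]
    inc = rec[rec["included"]]
    allm = inc.groupby(["female_id", "year_of_life"])["dsi"].mean()
    nonp = (inc[~inc["is_father"]]
            .groupby(["female_id", "year_of_life"])["dsi"].mean())

    def _mean_restd(series: pd.Series, name: str) -> pd.Series:
        df = series.rename("value").reset_index()
        df["z"] = _restandardize(df, "value")
        return df.groupby("female_id")["z"].mean().rename(name)

    parts = [
        _mean_restd(pat, "mean_dsi_paternal"),
        _mean_restd(nonp, "mean_dsi_nonpaternal"),
        _mean_restd(allm, "mean_dsi_all"),
    ]
    out = pd.concat(parts, axis=1)
    if out.empty:
        raise DatasetError("no juvenile DSI records to summarize")
    out.index.name = "female_id"
    return out.reset_index()


def summarize_female(dsi_records: pd.DataFrame, female_id: str) -> pd.Series:
    """Summary row for one female (re-standardization uses all females)."""
    summaries = summarize_females(dsi_records)
    row = summaries[summaries["female_id"] == female_id]
    if not len(row):
        raise DatasetError(f"female {female_id!r} has no juvenile DSI records")
    return row.iloc[0]


# --------------------------------------------------------------------------
# adult social connectedness
# --------------------------------------------------------------------------

def _adult_partner_class(ind: pd.DataFrame, partner_ids: pd.Series,
                         dates: pd.Series) -> pd.Series:
    """'F'/'M' for adult partners at the event date, else NaN."""
    sex = partner_ids.map(ind["sex"])
    birth = pd.to_datetime(partner_ids.map(ind["birth_date"]))
    age = (pd.to_datetime(dates.to_numpy()) - birth).dt.days / DAYS_PER_YEAR
    thresh = np.where(sex == "F", FEMALE_ADULT_AGE_YEARS, MALE_ADULT_AGE_YEARS)
    return sex.where(age.to_numpy() >= thresh)


def compute_sci(ds: PopulationDataset, females: list[str] | None = None,
                min_days: int = MIN_CORESIDENCY_DAYS,
                epsilon: float = EPSILON) -> pd.DataFrame:
    """Adult social connectedness indices per female.

    For each adult year of life (age 4 onward, birthday to birthday, resident
    >= ``min_days``), the female's total grooming given+received with adult
    females and with adult males is converted to a daily rate, log-
    transformed, adjusted for observer effort and z-scored across all
    female-years; per-female means over adult years give SCI_F and SCI_M.
    """
    ind = ds.individuals.set_index("id")
    if females is None:
        females = sorted(ind[(ind["sex"] == "F") & ind["father_id"].notna()].index)
    res = ds.residencies

    pair = _pair_counts(ds.grooming, set(females))
    if len(pair):
        pair["partner_class"] = _adult_partner_class(ind, pair["partner_id"], pair["date"])

    rows = []
    for fid in females:
        birth = ind.at[fid, "birth_date"]
        try:
            fexit = ds.exit_date(fid)
        except DatasetError:
            fexit = None
        fres = res[res["individual_id"] == fid]
        ev = pair[pair["focal_id"] == fid] if len(pair) else pair
        year = int(FEMALE_ADULT_AGE_YEARS)
        while True:
            w0, w1 = add_years(birth, year), add_years(birth, year + 1)
            if fexit is not None and w0 > fexit:
                break
            alive_end = w1 if fexit is None else min(w1, fexit + pd.Timedelta(days=1))
            seg = fres[(fres["start_date"] < alive_end) & (fres["end_date"] >= w0)]
            if not len(seg):
                break
            days = int((seg["end_date"].clip(upper=alive_end - pd.Timedelta(days=1))
                        - seg["start_date"].clip(lower=w0)).dt.days.sum()
                       + len(seg))
            if days >= min_days:
                in_w = ev[(ev["date"] >= w0) & (ev["date"] < alive_end)] if len(ev) else ev
                n_f = int((in_w["partner_class"] == "F").sum()) if len(in_w) else 0
                n_m = int((in_w["partner_class"] == "M").sum()) if len(in_w) else 0
                rows.append((fid, year, seg["group_id"].iloc[0], w0, alive_end,
                             days, n_f, n_m))
            year += 1
            if year > 40:
                break
    per_year = pd.DataFrame(rows, columns=["female_id", "adult_year", "group_id",
                                           "window_start", "window_end",
                                           "resident_days", "count_f", "count_m"])
    if per_year.empty:
        raise DatasetError("no adult female-years with sufficient residency for SCI")
    per_year["effort"] = _day_weighted_effort(ds.effort, per_year["group_id"],
                                              per_year["window_start"],
                                              per_year["window_end"])
    for cls in ("f", "m"):
        per_year[f"log_rate_{cls}"] = np.log(
            per_year[f"count_{cls}"] / per_year["resident_days"] + epsilon)
        sub = per_year.rename(columns={f"log_rate_{cls}": "log_rate"})
        sub = sub.assign(included=True, stratum=0)
        sub = adjust_for_effort(sub, "stratum")
        sub = zscore_within_stratum(sub, "stratum")
        per_year[f"sci_{cls}"] = sub["dsi"]
    out = per_year.groupby("female_id")[["sci_f", "sci_m"]].mean().reset_index()
    return out


def maternal_isolation_scores(ds: PopulationDataset,
                              daughters: list[str],
                              years: int = 2,
                              epsilon: float = EPSILON) -> pd.Series:
    """Maternal grooming-involvement index over each daughter's first years.

    The mother's grooming given+received with adult females over the
    daughter's first ``years`` of life (truncated at the mother's death),
    as a daily rate, log-transformed, effort-adjusted and z-scored across
    mothers. Low values are socially isolated mothers. Indexed by daughter.
    """
    ind = ds.individuals.set_index("id")
    mothers = {fid: ind.at[fid, "mother_id"] for fid in daughters}
    if any(pd.isna(m) for m in mothers.values()):
        missing = [f for f, m in mothers.items() if pd.isna(m)]
        raise DatasetError(f"daughters without known mothers: {missing[:3]}")
    pair = _pair_counts(ds.grooming, set(mothers.values()))
    if len(pair):
        pair["partner_class"] = _adult_partner_class(ind, pair["partner_id"], pair["date"])
    res = ds.residencies
    rows = []
    for fid in daughters:
        mom = mothers[fid]
        birth = ind.at[fid, "birth_date"]
        w0, w1 = birth, add_years(birth, years)
        try:
            mexit = ds.exit_date(mom)
            w1 = min(w1, mexit + pd.Timedelta(days=1))
        except DatasetError:
            pass
        seg = res[(res["individual_id"] == mom) & (res["start_date"] < w1)
                  & (res["end_date"] >= w0)]
        days = int((seg["end_date"].clip(upper=w1 - pd.Timedelta(days=1))
                    - seg["start_date"].clip(lower=w0)).dt.days.sum()
                   + len(seg)) if len(seg) else 0
        if days <= 0:
            raise DatasetError(f"mother {mom} of {fid} has no residency in the "
                               f"daughter's first {years} years")
        ev = pair[(pair["focal_id"] == mom) & (pair["date"] >= w0)
                  & (pair["date"] < w1)] if len(pair) else pair
        count = int((ev["partner_class"] == "F").sum()) if len(ev) else 0
        rows.append((fid, seg["group_id"].iloc[0], w0, w1, days, count))
    df = pd.DataFrame(rows, columns=["female_id", "group_id", "window_start",
                                     "window_end", "days", "count"])
    df["effort"] = _day_weighted_effort(ds.effort, df["group_id"],
                                        df["window_start"], df["window_end"])
    df["log_rate"] = np.log(df["count"] / df["days"] + epsilon)
    df = df.assign(included=True, stratum=0)
    df = adjust_for_effort(df, "stratum")
    df = zscore_within_stratum(df, "stratum")
    return df.set_index("female_id")["dsi"].rename("maternal_grooming_index")
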