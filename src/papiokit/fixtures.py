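"""Deterministic hand-sized datasets used across the test suite.

``two_dyad_dsi``
    Two juvenile females, two adult males, one group, with grooming counts
    chosen for hand-checkable dyad-year rates (73 events over 365 days).

``eight_female_ela``
    Eight females in one group whose adversity inputs are laid out so every
    component flag can be derived by hand: rainfall 150/180 mm give the two
    droughts, two mothers die at daughter age 2.5, group size at birth grows
    from 12 to 18 adults, interbirth intervals span 1.0-2.4 years, maternal
    ranks and maternal grooming involvement each isolate two females.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dataset import PopulationDataset

__all__ = ["FIXTURES", "make_fixture"]

_T = pd.Timestamp


def _individuals(rows):
    return pd.DataFrame(rows, columns=["id", "sex", "birth_date", "death_date",
                                       "censor_date", "mother_id", "father_id"])


def _residencies(rows):
    return pd.DataFrame(rows, columns=["individual_id", "group_id",
                                       "start_date", "end_date"])


def _two_dyad_dsi() -> PopulationDataset:
    censor = _T("2006-01-01")
    ind = _individuals([
        ("FA", "F", _T("2001-01-01"), pd.NaT, censor, np.nan, "MA"),
        ("FB", "F", _T("2001-01-01"), pd.NaT, censor, np.nan, "MB"),
        ("MA", "M", _T("1990-01-01"), pd.NaT, censor, np.nan, np.nan),
        ("MB", "M", _T("1990-01-01"), pd.NaT, censor, np.nan, np.nan),
    ])
    res = _residencies([
        ("FA", "G1", _T("2001-01-01"), censor),
        ("FB", "G1", _T("2001-01-01"), censor),
        ("MA", "G1", _T("1995-01-01"), censor),
        ("MB", "G1", _T("1995-01-01"), censor),
    ])
    # 73 MA->FA events spread over year-of-life 0 (365 days -> rate 0.2)
    dates = pd.date_range("2001-01-03", periods=73, freq="5D")
    groom = pd.DataFrame({
        "date": dates, "group_id": "G1", "actor_id": "MA",
        "recipient_id": "FA", "initiator_id": "MA",
    })
    effort = pd.DataFrame([("G1", y, 1.0) for y in range(2001, 2007)],
                          columns=["group_id", "year", "effort"])
    return PopulationDataset(individuals=ind, residencies=res,
                             grooming=groom, effort=effort).validate()


def _eight_female_ela() -> PopulationDataset:
    censor = _T("2015-01-01")
    old = _T("1990-01-01")
    births = {f"F{i}": _T(f"{2000 + i}-07-01") for i in range(1, 9)}
    rainfall_mm = [150.0, 250.0, 300.0, 180.0, 400.0, 350.0, 500.0, 320.0]
    mother_death = {"M3": _T("2006-01-01"), "M7": _T("2010-01-01")}
    # next-sibling intervals in days (F7, F8 have no younger sibling)
    sibling_gap_days = {"F1": 365, "F2": 438, "F3": 584,
                        "F4": 657, "F5": 730, "F6": 876}
    maternal_rank = {"M1": 8, "M2": 1, "M3": 2, "M4": 3,
                     "M5": 4, "M6": 5, "M7": 6, "M8": 7}
    mother_groom_counts = {"M1": 0, "M2": 5, "M3": 10, "M4": 15,
                           "M5": 20, "M6": 25, "M7": 30, "M8": 2}

    rows, res = [], []
    for i in range(1, 9):
        fid, mid = f"F{i}", f"M{i}"
        father = "P1" if i <= 4 else "P2"
        rows.append((fid, "F", births[fid], pd.NaT, censor, mid, father))
        death = mother_death.get(mid, pd.NaT)
        rows.append((mid, "F", old, death, pd.NaT if pd.notna(death) else censor,
                     np.nan, np.nan))
        res.append((fid, "G1", births[fid], censor))
        res.append((mid, "G1", _T("2000-01-01"),
                    death if pd.notna(death) else censor))
        if fid in sibling_gap_days:
            sb = births[fid] + pd.Timedelta(days=sibling_gap_days[fid])
            rows.append((f"S{i}", "M", sb, pd.NaT, censor, mid, "P1"))
            res.append((f"S{i}", "G1", sb, censor))
    for pid in ("P1", "P2"):
        rows.append((pid, "M", _T("1988-01-01"), pd.NaT, censor, np.nan, np.nan))
        res.append((pid, "G1", _T("2000-01-01"), censor))
    # background adult females immigrate one per year from 2002
    for j in range(1, 13):
        aid = f"AD{j:02d}"
        start = _T("2000-01-01") if j <= 2 else _T(f"{2000 + j - 1}-01-01")
        rows.append((aid, "F", _T("1985-01-01"), pd.NaT, censor, np.nan, np.nan))
        res.append((aid, "G1", start, censor))

    groom_rows = []
    for i in range(1, 9):
        mid, fid = f"M{i}", f"F{i}"
        n = mother_groom_counts[mid]
        if n:
            dates = pd.date_range(births[fid] + pd.Timedelta(days=10),
                                  periods=n, freq="20D")
            for d in dates:
                groom_rows.append((d, "G1", mid, "AD01", mid))
    groom = pd.DataFrame(groom_rows, columns=["date", "group_id", "actor_id",
                                              "recipient_id", "initiator_id"])
    if not len(groom):
        groom = PopulationDataset().grooming

    effort = pd.DataFrame([("G1", y, 1.0) for y in range(2000, 2016)],
                          columns=["group_id", "year", "effort"])
    ranks = pd.DataFrame(
        [(mid, births[f"F{i}"].strftime("%Y-%m"), maternal_rank[mid])
         for i, mid in ((i, f"M{i}") for i in range(1, 9))],
        columns=["individual_id", "month", "ordinal_rank"])
    rain = pd.DataFrame({
        "period_start": [births[f"F{i}"] for i in range(1, 9)],
        "period_end": [births[f"F{i}"] + pd.DateOffset(years=1)
                       - pd.Timedelta(days=1) for i in range(1, 9)],
        "total_mm": rainfall_mm,
    })
    rain["period_end"] = pd.to_datetime(rain["period_end"])
    return PopulationDataset(
        individuals=_individuals(rows), residencies=_residencies(res),
        grooming=groom, effort=effort, ranks=ranks, rainfall=rain,
    ).validate()


FIXTURES = {
    "two_dyad_dsi": _two_dyad_dsi,
    "eight_female_ela": _eight_female_ela,
}


def make_fixture(name: str) -> PopulationDataset:
    """Build one of the documented deterministic fixtures by name."""
    try:
        builder = FIXTURES[name]
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; available: "
                       f"{sorted(FIXTURES)}") from None
    return builder()
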