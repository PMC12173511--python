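"""Tabular data model for longitudinal primate life-history datasets.

A :class:`PopulationDataset` bundles the eight tables every downstream stage
consumes: individual life histories, group-residency intervals, time-stamped
dyadic grooming events, monthly ordinal dominance ranks, per-group observer
effort, first-year rainfall, consortship records and peri-ovulatory windows.

Conventions fixed here, package-wide:

* dates are calendar dates at day resolution (stored as pandas Timestamps,
  serialized ISO ``YYYY-MM-DD``);
* residency intervals are inclusive on both ends;
* year-of-life windows are half-open ``[birthday + k years, birthday + (k+1)
  years)`` so the four juvenile windows tile ``[birth, birth + 4y)`` exactly;
* a birthday of 29 February maps to 1 March in non-leap years;
* ordinal dominance rank 1 is the highest-ranking animal.
"""

from __future__ import annotations

import datetime as _dt
import re
from dataclasses import dataclass, field, fields as _dc_fields
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "DatasetError",
    "PopulationDataset",
    "TABLE_SCHEMAS",
    "add_years",
    "read_dataset",
    "write_dataset",
    "year_of_life_window",
    "load_schema_config",
    "analysis_cohort",
    "FEMALE_ADULT_AGE_YEARS",
    "MALE_ADULT_AGE_YEARS",
    "JUVENILE_YEARS",
    "DAYS_PER_YEAR",
    "DAYS_PER_MONTH",
]

#: age (years) from which a female counts as adult (median menarche ~4.5 y;
#: the survival analyses condition on survival to the fourth birthday).
FEMALE_ADULT_AGE_YEARS = 4.0
#: age (years) from which a male counts as an adult grooming/rank partner.
MALE_ADULT_AGE_YEARS = 7.0
#: number of juvenile year-of-life windows (ages 0-3).
JUVENILE_YEARS = 4
#: mean calendar-year length in days, used for day->year conversions.
DAYS_PER_YEAR = 365.25
#: mean month length in days, used for day->month conversions.
DAYS_PER_MONTH = 30.44


class DatasetError(ValueError):
    """Raised when a table violates the data model.

    ``table`` and ``row`` identify the offending record where applicable.
    """

    def __init__(self, message: str, table: str | None = None, row=None):
        self.table = table
        self.row = row
        prefix = f"[{table}] " if table else ""
        suffix = f" (row: {row})" if row is not None else ""
        super().__init__(f"{prefix}{message}{suffix}")


# table name -> (column, kind) pairs; kind in {id, opt_id, date, opt_date,
# month, str, float, int, bool}
TABLE_SCHEMAS: dict[str, list[tuple[str, str]]] = {
    "individuals": [
        ("id", "id"),
        ("sex", "str"),
        ("birth_date", "date"),
        ("death_date", "opt_date"),
        ("censor_date", "opt_date"),
        ("mother_id", "opt_id"),
        ("father_id", "opt_id"),
    ],
    "residencies": [
        ("individual_id", "id"),
        ("group_id", "id"),
        ("start_date", "date"),
        ("end_date", "date"),
    ],
    "grooming": [
        ("date", "date"),
        ("group_id", "id"),
        ("actor_id", "id"),
        ("recipient_id", "id"),
        ("initiator_id", "id"),
    ],
    "effort": [
        ("group_id", "id"),
        ("year", "int"),
        ("effort", "float"),
    ],
    "ranks": [
        ("individual_id", "id"),
        ("month", "month"),
        ("ordinal_rank", "int"),
    ],
    "rainfall": [
        ("period_start", "date"),
        ("period_end", "date"),
        ("total_mm", "float"),
    ],
    "consorts": [
        ("male_id", "id"),
        ("female_id", "id"),
        ("date", "date"),
        ("observed_minutes", "float"),
    ],
    "ovulation": [
        ("female_id", "id"),
        ("start_date", "date"),
        ("end_date", "date"),
        ("conception_flag", "bool"),
    ],
}

_ID_RE = re.compile(r"^[A-Za-z0-9_.:-]+$")
_MONTH_RE = re.compile(r"^\d{4}-\d{2}$")


def load_schema_config(path: str | Path) -> dict:
    """Read a YAML schema config mapping table names to file names/columns.

    The config may override, per table, the file name (``file``) and the
    on-disk column names (``columns``, a mapping from canonical name to the
    name used in the file). Tables not mentioned use the defaults.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    unknown = set(cfg) - set(TABLE_SCHEMAS)
    if unknown:
        raise DatasetError(f"schema config names unknown tables: {sorted(unknown)}")
    return cfg


def add_years(date: pd.Timestamp, k: int) -> pd.Timestamp:
    """``date`` plus ``k`` calendar years; 29 Feb maps to 1 Mar off-leap."""
    date = pd.Timestamp(date)
    try:
        return pd.Timestamp(_dt.date(date.year + k, date.month, date.day))
    except ValueError:
        # only reachable for 29 Feb in a non-leap target year
        return pd.Timestamp(_dt.date(date.year + k, 3, 1))


def year_of_life_window(birth_date: pd.Timestamp, k: int) -> tuple[pd.Timestamp, pd.Timestamp]:
    """Half-open window for year-of-life ``k`` (0..3), birthday to birthday."""
    if not 0 <= k < JUVENILE_YEARS:
        raise ValueError(f"year of life k must be in 0..{JUVENILE_YEARS - 1}, got {k}")
    return add_years(birth_date, k), add_years(birth_date, k + 1)


def _empty_table(name: str) -> pd.DataFrame:
    cols = {}
    for col, kind in TABLE_SCHEMAS[name]:
        if kind in ("date", "opt_date"):
            cols[col] = pd.Series([], dtype="datetime64[ns]")
        elif kind == "float":
            cols[col] = pd.Series([], dtype=float)
        elif kind == "int":
            cols[col] = pd.Series([], dtype=int)
        elif kind == "bool":
            cols[col] = pd.Series([], dtype=bool)
        else:
            cols[col] = pd.Series([], dtype=object)
    return pd.DataFrame(cols)


@dataclass
class PopulationDataset:
    """The bundle of tables consumed by all analysis stages."""

    individuals: pd.DataFrame = field(default_factory=lambda: _empty_table("individuals"))
    residencies: pd.DataFrame = field(default_factory=lambda: _empty_table("residencies"))
    grooming: pd.DataFrame = field(default_factory=lambda: _empty_table("grooming"))
    effort: pd.DataFrame = field(default_factory=lambda: _empty_table("effort"))
    ranks: pd.DataFrame = field(default_factory=lambda: _empty_table("ranks"))
    rainfall: pd.DataFrame = field(default_factory=lambda: _empty_table("rainfall"))
    consorts: pd.DataFrame = field(default_factory=lambda: _empty_table("consorts"))
    ovulation: pd.DataFrame = field(default_factory=lambda: _empty_table("ovulation"))

    def tables(self) -> dict[str, pd.DataFrame]:
        return {f.name: getattr(self, f.name) for f in _dc_fields(self)}

    # -- validation ---------------------------------------------------------

    def validate(self) -> "PopulationDataset":
        """Check schema, id hygiene, invariants and referential integrity.

        Returns self so calls can be chained; raises :class:`DatasetError`
        naming the offending table/row on the first violation found.
        """
        for name, df in self.tables().items():
            expected = [c for c, _ in TABLE_SCHEMAS[name]]
            missing = set(expected) - set(df.columns)
            if missing:
                raise DatasetError(f"missing columns {sorted(missing)}", table=name)
            for col, kind in TABLE_SCHEMAS[name]:
                if kind in ("id", "opt_id"):
                    vals = df[col].dropna()
                    bad = vals[~vals.astype(str).str.match(_ID_RE)]
                    if len(bad):
                        raise DatasetError(
                            f"invalid id in column {col!r}: {bad.iloc[0]!r}",
                            table=name, row=bad.index[0])
                    if kind == "id" and df[col].isna().any():
                        raise DatasetError(f"null id in required column {col!r}", table=name)
                elif kind in ("date", "opt_date"):
                    if not np.issubdtype(df[col].dtype, np.datetime64):
                        raise DatasetError(f"column {col!r} is not a date column", table=name)
                    if kind == "date" and df[col].isna().any():
                        raise DatasetError(f"null date in required column {col!r}", table=name)

        ind = self.individuals
        if ind["id"].duplicated().any():
            dup = ind.loc[ind["id"].duplicated(), "id"].iloc[0]
            raise DatasetError(f"duplicate individual id {dup!r}", table="individuals")
        bad_sex = ind[~ind["sex"].isin(["F", "M"])]
        if len(bad_sex):
            raise DatasetError(
                f"sex must be F or M, got {bad_sex['sex'].iloc[0]!r}",
                table="individuals", row=bad_sex["id"].iloc[0])
        both = ind[ind["death_date"].notna() & ind["censor_date"].notna()]
        if len(both):
            raise DatasetError(
                "both death_date and censor_date present",
                table="individuals", row=both["id"].iloc[0])
        exit_date = ind["death_date"].fillna(ind["censor_date"])
        bad_exit = ind[exit_date.notna() & (exit_date < ind["birth_date"])]
        if len(bad_exit):
            raise DatasetError(
                "death/censor date precedes birth",
                table="individuals", row=bad_exit["id"].iloc[0])

        sex_of = dict(zip(ind["id"], ind["sex"]))
        for col, want in (("mother_id", "F"), ("father_id", "M")):
            refs = ind[ind[col].notna()]
            for rid, ref in zip(refs["id"], refs[col]):
                if ref not in sex_of:
                    raise DatasetError(f"{col} {ref!r} not in individuals",
                                       table="individuals", row=rid)
                if sex_of[ref] != want:
                    raise DatasetError(f"{col} {ref!r} has sex {sex_of[ref]}",
                                       table="individuals", row=rid)

        res = self.residencies
        bad = res[res["end_date"] < res["start_date"]]
        if len(bad):
            raise DatasetError("residency end before start", table="residencies",
                               row=bad.index[0])
        # non-overlap within individual (intervals inclusive on both ends)
        r = res.sort_values(["individual_id", "start_date"])
        same = r["individual_id"].eq(r["individual_id"].shift())
        overlap = same & (r["start_date"] <= r["end_date"].shift())
        if overlap.any():
            raise DatasetError("overlapping residency intervals",
                               table="residencies", row=r.index[overlap.argmax()])

        known = set(ind["id"])
        for name, cols in (
            ("residencies", ["individual_id"]),
            ("grooming", ["actor_id", "recipient_id", "initiator_id"]),
            ("ranks", ["individual_id"]),
            ("consorts", ["male_id", "female_id"]),
            ("ovulation", ["female_id"]),
        ):
            df = self.tables()[name]
            for col in cols:
                missing = df[~df[col].isin(known)]
                if len(missing):
                    raise DatasetError(
                        f"{col} {missing[col].iloc[0]!r} not in individuals",
                        table=name, row=missing.index[0])

        g = self.grooming
        if (g["actor_id"] == g["recipient_id"]).any():
            raise DatasetError("actor equals recipient", table="grooming",
                               row=g.index[(g["actor_id"] == g["recipient_id"]).argmax()])
        bad_init = g[(g["initiator_id"] != g["actor_id"])
                     & (g["initiator_id"] != g["recipient_id"])]
        if len(bad_init):
            raise DatasetError("initiator is neither actor nor recipient",
                               table="grooming", row=bad_init.index[0])

        if (self.effort["effort"] < 0).any():
            raise DatasetError("negative effort", table="effort")
        if (self.ranks["ordinal_rank"] < 1).any():
            raise DatasetError("ordinal rank must be >= 1", table="ranks")
        if (self.rainfall["total_mm"] < 0).any():
            raise DatasetError("negative rainfall", table="rainfall")
        if (self.consorts["observed_minutes"] < 0).any():
            raise DatasetError("negative consort minutes", table="consorts")
        ov = self.ovulation
        if (ov["end_date"] < ov["start_date"]).any():
            raise DatasetError("ovulation window end before start", table="ovulation")
        return self

    # -- convenience lookups ------------------------------------------------

    def individual(self, individual_id: str) -> pd.Series:
        rows = self.individuals[self.individuals["id"] == individual_id]
        if not len(rows):
            raise DatasetError(f"unknown individual {individual_id!r}", table="individuals")
        return rows.iloc[0]

    def exit_date(self, individual_id: str) -> pd.Timestamp:
        row = self.individual(individual_id)
        out = row["death_date"] if pd.notna(row["death_date"]) else row["censor_date"]
        if pd.isna(out):
            raise DatasetError(f"individual {individual_id!r} has neither death nor "
                               "censor date", table="individuals")
        return out

    def equals(self, other: "PopulationDataset") -> bool:
        """Field-for-field semantic equality (dtype representation of missing
        ids may differ between in-memory and round-tripped tables)."""
        for name, df in self.tables().items():
            a = df.reset_index(drop=True)
            b = other.tables()[name].reset_index(drop=True)
            if len(a) != len(b):
                return False
            for col, kind in TABLE_SCHEMAS[name]:
                if kind in ("id", "opt_id", "str", "month"):
                    sa = a[col].astype(object).where(a[col].notna(), None)
                    sb = b[col].astype(object).where(b[col].notna(), None)
                    if not sa.equals(sb):
                        return False
                elif kind == "float":
                    if not np.allclose(a[col].astype(float),
                                       b[col].astype(float), equal_nan=True):
                        return False
                elif not a[col].equals(b[col]):
                    return False
        return True


def _resolve(schema_config: Mapping | None, table: str) -> tuple[str, dict]:
    cfg = (schema_config or {}).get(table, {})
    fname = cfg.get("file", f"{table}.csv")
    colmap = cfg.get("columns", {})  # canonical -> on-disk
    return fname, colmap


def read_dataset(path: str | Path, schema_config: Mapping | None = None) -> PopulationDataset:
    """Read a directory of delimited tables into a validated dataset."""
    path = Path(path)
    out: dict[str, pd.DataFrame] = {}
    for table, schema in TABLE_SCHEMAS.items():
        fname, colmap = _resolve(schema_config, table)
        fpath = path / fname
        if not fpath.exists():
            raise DatasetError(f"missing table file {fname!r}", table=table)
        df = pd.read_csv(fpath, dtype=object, keep_default_na=True)
        rename = {v: k for k, v in colmap.items()}
        df = df.rename(columns=rename)
        expected = [c for c, _ in schema]
        unknown = set(df.columns) - set(expected)
        if unknown:
            raise DatasetError(f"unknown column(s) {sorted(unknown)}", table=table)
        missing = set(expected) - set(df.columns)
        if missing:
            raise DatasetError(f"missing column(s) {sorted(missing)}", table=table)
        for col, kind in schema:
            if kind in ("date", "opt_date"):
                df[col] = pd.to_datetime(df[col], format="%Y-%m-%d")
            elif kind == "float":
                df[col] = df[col].astype(float)
            elif kind == "int":
                df[col] = df[col].astype(int)
            elif kind == "bool":
                df[col] = df[col].map({"True": True, "False": False}).astype(bool)
            elif kind == "month":
                bad = df[col].dropna()[~df[col].dropna().astype(str).str.match(_MONTH_RE)]
                if len(bad):
                    raise DatasetError(f"bad month value {bad.iloc[0]!r}",
                                       table=table, row=bad.index[0])
        out[table] = df[expected]
    return PopulationDataset(
        individuals=out["individuals"], residencies=out["residencies"],
        grooming=out["grooming"], effort=out["effort"], ranks=out["ranks"],
        rainfall=out["rainfall"], consorts=out["consorts"], ovulation=out["ovulation"],
    ).validate()


def write_dataset(ds: PopulationDataset, path: str | Path,
                  schema_config: Mapping | None = None) -> list[Path]:
    """Write the dataset as one CSV per table; lossless under read_dataset."""
    ds.validate()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    written = []
    for table, df in ds.tables().items():
        fname, colmap = _resolve(schema_config, table)
        out = df.copy()
        for col, kind in TABLE_SCHEMAS[table]:
            if kind in ("date", "opt_date"):
                out[col] = out[col].dt.strftime("%Y-%m-%d")
        out = out.rename(columns=colmap)
        fpath = path / fname
        out.to_csv(fpath, index=False)
        written.append(fpath)
    return written


def analysis_cohort(ds: PopulationDataset) -> list[str]:
    """Females eligible for the survival analyses: known mother and father,
    survived to the fourth birthday, and with a first-year rainfall record
    (the marker of complete early-life adversity information)."""
    ind = ds.individuals
    fem = ind[(ind["sex"] == "F") & ind["mother_id"].notna() & ind["father_id"].notna()]
    starts = set(ds.rainfall["period_start"])
    rank_months = set(zip(ds.ranks["individual_id"], ds.ranks["month"]))
    out = []
    for row in fem.itertuples():
        if row.birth_date not in starts:
            continue
        if (row.mother_id, row.birth_date.strftime("%Y-%m")) not in rank_months:
            continue
        exit_date = row.death_date if pd.notna(row.death_date) else row.censor_date
        if pd.notna(exit_date) and exit_date < add_years(row.birth_date, 4):
            continue
        out.append(row.id)
    return sorted(out)


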