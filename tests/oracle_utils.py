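"""Brute-force day-scan oracles and random mini-dataset builders.

The oracles recompute each life-history metric by iterating over calendar
days, independently of the interval-arithmetic implementations they check.
"""

import numpy as np
import pandas as pd

from papiokit import PopulationDataset

EPOCH = pd.Timestamp("1970-01-01")


def day(ts) -> int:
    return (pd.Timestamp(ts) - EPOCH).days


def ts(d) -> pd.Timestamp:
    return EPOCH + pd.Timedelta(days=int(d))


def random_mini_dataset(rng: np.random.Generator):
    """A tiny random dataset around one focal female.

    Returns (dataset, focal_id, father_id). Residency intervals, sibling
    paternities, ovulation windows and monthly ranks are all randomized;
    the mother holds one interval covering the whole frame so day-scan and
    interval semantics coincide for the conception-window queries.
    """
    t0 = day("2000-01-01")
    frame_days = 6 * 365
    birth = t0 + int(rng.integers(400, 800))
    conc = birth - 178
    groups = ["G1", "G2"][: int(rng.integers(1, 3))]

    ind_rows, res_rows = [], []
    censor = ts(t0 + frame_days + 400)

    def add(iid, sex, b_day, mother=np.nan, father=np.nan, death=pd.NaT):
        ind_rows.append((iid, sex, ts(b_day), death,
                         censor if pd.isna(death) else pd.NaT, mother, father))

    def add_res(iid, n_min=1, n_max=3, force_cover=None):
        """Non-overlapping random residency intervals for one individual."""
        if force_cover is not None:
            res_rows.append((iid, str(rng.choice(groups)),
                             ts(force_cover[0]), ts(force_cover[1])))
            return
        cuts = np.sort(rng.integers(0, frame_days, 2 * int(rng.integers(n_min, n_max + 1))))
        for a, b in zip(cuts[::2], cuts[1::2]):
            if b > a:  # inclusive interval [a, b-1]; sorted cuts cannot overlap
                res_rows.append((iid, str(rng.choice(groups)),
                                 ts(t0 + a), ts(t0 + b - 1)))

    n_males = int(rng.integers(2, 5))
    males = [f"M{j}" for j in range(1, n_males + 1)]
    for m in males:
        add(m, "M", t0 - 3000)
        add_res(m)
    n_fem = int(rng.integers(1, 4))
    females = [f"AF{j}" for j in range(1, n_fem + 1)]
    for f in females:
        add(f, "F", t0 - 3000)
        add_res(f)

    father = str(rng.choice(males))
    add("MOM", "F", t0 - 4000)
    add_res("MOM", force_cover=(t0 - 100, t0 + frame_days + 300))
    add("FOC", "F", birth, mother="MOM", father=father)
    add_res("FOC", force_cover=(birth, t0 + frame_days + 300))
    # a couple of other offspring of random males (siblings / half-sibs)
    for j in range(int(rng.integers(0, 3))):
        kid = f"K{j}"
        kb = t0 + int(rng.integers(0, frame_days - 200))
        add(kid, "M", kb, mother=np.nan, father=str(rng.choice(males)))
        add_res(kid)

    # ovulation windows for adult females (and the conception window)
    ov_rows = []
    for f in females + ["MOM"]:
        for _ in range(int(rng.integers(0, 6))):
            s = t0 + int(rng.integers(0, frame_days - 5))
            ov_rows.append((f, ts(s), ts(s + 4), False))
    ov_rows.append(("MOM", ts(conc - 4), ts(conc), True))

    # monthly ranks for a random subset of males over random month ranges
    rank_rows = []
    months = pd.date_range(ts(t0 - 60), ts(t0 + frame_days + 60), freq="MS")
    for m in males:
        if rng.random() < 0.85:
            lo, hi = sorted(rng.integers(0, len(months), 2))
            for mo in months[lo:hi + 1]:
                rank_rows.append((m, mo.strftime("%Y-%m"),
                                  int(rng.integers(1, 9))))

    ds = PopulationDataset(
        individuals=pd.DataFrame(ind_rows, columns=[
            "id", "sex", "birth_date", "death_date", "censor_date",
            "mother_id", "father_id"]),
        residencies=pd.DataFrame(res_rows, columns=[
            "individual_id", "group_id", "start_date", "end_date"]),
        ranks=pd.DataFrame(rank_rows, columns=["individual_id", "month",
                                               "ordinal_rank"]),
        ovulation=pd.DataFrame(ov_rows, columns=["female_id", "start_date",
                                                 "end_date", "conception_flag"]),
    )
    ds.individuals["death_date"] = pd.to_datetime(ds.individuals["death_date"])
    ds.individuals["censor_date"] = pd.to_datetime(ds.individuals["censor_date"])
    return ds.validate(), "FOC", father


def _intervals(ds, iid):
    sub = ds.residencies[ds.residencies["individual_id"] == iid]
    return [(day(r.start_date), day(r.end_date), r.group_id)
            for r in sub.itertuples()]


def group_on(intervals, d):
    for a, b, g in intervals:
        if a <= d <= b:
            return g
    return None


def brute_coresidency(ds, fid, father, w0, w1) -> int:
    """Day-by-day scan of shared group membership over [w0, w1)."""
    fi = _intervals(ds, fid)
    pi = _intervals(ds, father)
    return sum(1 for d in range(day(w0), day(w1))
               if group_on(fi, d) is not None and group_on(fi, d) == group_on(pi, d))


def brute_fertile_rate(ds, male_id, w0, w1):
    """Day-by-day: mean count of peri-ovulatory co-grouped females over the
    male's resident days in [w0, w1); None if he has no resident day."""
    mi = _intervals(ds, male_id)
    ov = ds.ovulation
    fem_int = {f: _intervals(ds, f) for f in ov["female_id"].unique()}
    windows = [(r.female_id, day(r.start_date), day(r.end_date))
               for r in ov.itertuples()]
    resident, fertile = 0, 0
    for d in range(day(w0), day(w1)):
        g = group_on(mi, d)
        if g is None:
            continue
        resident += 1
        for f, a, b in windows:
            if a <= d <= b and group_on(fem_int[f], d) == g:
                fertile += 1
    return None if resident == 0 else fertile / resident


def brute_offspring_years(ds, male_id, w0, w1, exclude=None) -> float:
    """Day-by-day co-residency with each under-4, alive offspring."""
    from papiokit.dataset import add_years
    mi = _intervals(ds, male_id)
    ind = ds.individuals
    total = 0
    for kid in ind[ind["father_id"] == male_id].itertuples():
        if kid.id == exclude:
            continue
        ki = _intervals(ds, kid.id)
        exit_date = kid.death_date if pd.notna(kid.death_date) else kid.censor_date
        hi = min(day(w1), day(add_years(kid.birth_date, 4)),
                 day(exit_date) + 1 if pd.notna(exit_date) else day(w1))
        for d in range(max(day(w0), day(kid.birth_date)), hi):
            g = group_on(ki, d)
            if g is not None and g == group_on(mi, d):
                total += 1
    return total / 365.25


def brute_potential_fathers(ds, fid) -> int:
    """Day-by-day: distinct ranked males sharing the mother's group on some
    day of the inclusive 5-day conception window."""
    from papiokit.lifehistory import conception_window
    w0, w1 = conception_window(ds, fid)
    mom = ds.individual(fid)["mother_id"]
    momi = _intervals(ds, mom)
    ind = ds.individuals
    months = set()
    for d in range(day(w0), day(w1) + 1):
        months.add(ts(d).strftime("%Y-%m"))
    ranked = set(ds.ranks.loc[ds.ranks["month"].isin(months), "individual_id"])
    found = set()
    for m in ind.loc[ind["sex"] == "M", "id"]:
        if m not in ranked:
            continue
        mi = _intervals(ds, m)
        for d in range(day(w0), day(w1) + 1):
            g = group_on(momi, d)
            if g is not None and group_on(mi, d) == g:
                found.add(m)
                break
    return len(found)
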