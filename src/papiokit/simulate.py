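"""Synthetic baboon-style populations with known ground truth.

Two generators are provided.

``simulate_population`` is the full behavioural simulator: it builds 13 social
groups with turnover of adult males and females, assigns each focal juvenile
female a mother and a genetic father, lets fathers depart (disperse or die)
under a memoryless monthly hazard, generates dyadic grooming events from a
Poisson process whose log rate carries father, age, dyad-propensity and
mating-opportunity terms, thins events by an effort-dependent detection
probability, assigns the six early-life adversity components, and draws each
female's adult age at death from a Weibull proportional-hazards model on her
realized covariates with administrative censoring.

``simulate_cohort_for_survival`` is a direct covariate-level generator that
bypasses the behavioural layer: covariates are drawn from their configured
marginal distributions and event times from the configured hazard. It exists
so proportional-hazards recovery experiments do not pay the cost (or inherit
the confounding) of the full simulator. ``simulate_father_years`` plays the
same role for the logistic father-grooming models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .dataset import PopulationDataset, DAYS_PER_YEAR, DAYS_PER_MONTH

__all__ = [
    "GroundTruth",
    "simulate_population",
    "simulate_cohort_for_survival",
    "simulate_father_years",
]

_EPOCH = pd.Timestamp("1970-01-01")


def _day(ts) -> int:
    return (pd.Timestamp(ts) - _EPOCH).days


def _ts(day) -> pd.Timestamp:
    return _EPOCH + pd.Timedelta(days=int(day))


def _ts_array(days) -> pd.Series:
    return pd.Series(pd.to_datetime(np.asarray(days, dtype="int64"), unit="D"))


def _opt_ts_array(vals) -> pd.Series:
    """Day numbers with missing values -> datetime series with NaT."""
    s = pd.to_numeric(pd.Series(vals), errors="coerce")
    out = pd.Series(pd.NaT, index=s.index, dtype="datetime64[ns]")
    mask = s.notna()
    if mask.any():
        out[mask] = pd.to_datetime(s[mask].to_numpy(dtype="int64"), unit="D")
    return out


@dataclass
class GroundTruth:
    """Generator-side truth for parameter-recovery oracles."""

    config: SimulationConfig
    paternities: pd.DataFrame        # female_id, father_id
    dyad_propensities: pd.DataFrame  # female_id, male_id, is_father, log_propensity
    females: pd.DataFrame            # per-female flags, covariates, eta, death ages
    group_effort: pd.DataFrame       # group_id, year, effort, detection_p


# --------------------------------------------------------------------------
# helpers
# --------------------------------------------------------------------------

def _truncated_exp(rng, rate: float, upper: float, size: int) -> np.ndarray:
    """Exponential(rate) draws conditioned to lie in [0, upper]."""
    u = rng.random(size)
    cap = 1.0 - np.exp(-rate * upper)
    return -np.log1p(-u * cap) / rate


def _roster(rng, n_target: float, span_days: int, mean_res_days: float):
    """Entry/exit day offsets for a stationary immigration-emigration process.

    Members present at day 0 get residual durations by memorylessness; later
    arrivals form a Poisson process whose rate sustains ``n_target`` members.
    """
    n0 = rng.poisson(n_target)
    entries = [np.zeros(n0)]
    durations = [rng.exponential(mean_res_days, n0)]
    arrival_rate = n_target / mean_res_days
    n_new = rng.poisson(arrival_rate * span_days)
    new_entries = np.sort(rng.random(n_new)) * span_days
    entries.append(new_entries)
    durations.append(rng.exponential(mean_res_days, n_new))
    entry = np.concatenate(entries)
    exit_ = entry + np.concatenate(durations)
    return entry, np.minimum(exit_, span_days)


# --------------------------------------------------------------------------
# full behavioural simulator
# --------------------------------------------------------------------------

def simulate_population(config: SimulationConfig) -> tuple[PopulationDataset, GroundTruth]:
    """Generate a full synthetic population and its ground truth.

    Identical ``(config, seed)`` produce identical outputs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    dem, gro, eff, adv, sur, beh = (config.demography, config.grooming,
                                    config.effort, config.adversity,
                                    config.survival, config.behaviour)

    birth_lo, birth_hi = _day(dem.birth_start), _day(dem.birth_end)
    censor_day = _day(dem.censor_date)
    study_start = birth_lo - int(6 * DAYS_PER_YEAR)  # room for mothers/siblings
    span = censor_day - study_start
    if birth_hi <= birth_lo or censor_day <= birth_hi:
        raise ValueError("birth window must precede the administrative censor date")

    groups = [f"G{g + 1:02d}" for g in range(config.n_groups)]

    # ---- background adults per group -------------------------------------
    male_rows, female_rows = [], []   # per-individual dicts
    mean_res_days = dem.male_residence_mean_months * DAYS_PER_MONTH
    for g, gid in enumerate(groups):
        m_entry, m_exit = _roster(rng, dem.n_males_per_group, span, mean_res_days)
        quality = rng.normal(size=len(m_entry))
        age_at_entry = rng.uniform(7.0, 15.0, len(m_entry))
        dies = rng.random(len(m_entry)) < dem.male_death_fraction
        for j in range(len(m_entry)):
            male_rows.append(dict(
                id=f"{gid}-M{j + 1:03d}", group=gid,
                entry=study_start + int(m_entry[j]), exit=study_start + int(m_exit[j]),
                birth=study_start + int(m_entry[j] - age_at_entry[j] * DAYS_PER_YEAR),
                quality=quality[j],
                dies=bool(dies[j]) and m_exit[j] < span,
            ))
        f_entry, f_exit = _roster(rng, dem.n_females_per_group, span,
                                  dem.female_residence_mean_years * DAYS_PER_YEAR)
        f_age = rng.uniform(4.5, 12.0, len(f_entry))
        for j in range(len(f_entry)):
            female_rows.append(dict(
                id=f"{gid}-F{j + 1:03d}", group=gid,
                entry=study_start + int(f_entry[j]), exit=study_start + int(f_exit[j]),
                birth=study_start + int(f_entry[j] - f_age[j] * DAYS_PER_YEAR),
            ))
    males = pd.DataFrame(male_rows)
    bg_females = pd.DataFrame(female_rows)

    # ---- ovulatory cycling of background females -------------------------
    ov_rows = []
    gap = dem.cycle_gap_mean_days
    for row in bg_females.itertuples():
        t = row.entry + rng.exponential(gap)
        while t + dem.cycle_window_days < row.exit:
            ov_rows.append((row.id, row.group, int(t), int(t + dem.cycle_window_days - 1)))
            t += dem.cycle_window_days + rng.exponential(gap)
    ov_bg = pd.DataFrame(ov_rows, columns=["female_id", "group", "start", "end"])

    # daily count of peri-ovulatory females per group (for mating-opportunity
    # effects inside the generator)
    ov_count = {}
    for gid in groups:
        arr = np.zeros(span + 2)
        sub = ov_bg[ov_bg["group"] == gid]
        np.add.at(arr, np.clip(sub["start"].to_numpy() - study_start, 0, span), 1.0)
        np.add.at(arr, np.clip(sub["end"].to_numpy() - study_start + 1, 0, span + 1), -1.0)
        ov_count[gid] = np.cumsum(arr)[:span + 1]

    # ---- focal females, mothers, fathers ---------------------------------
    n = config.n_females
    f_group = rng.integers(0, config.n_groups, n)
    f_birth = rng.integers(birth_lo, birth_hi + 1, n)
    order = np.lexsort((f_birth, f_group))
    f_group, f_birth = f_group[order], f_birth[order]
    f_conc = f_birth - dem.gestation_days

    focal_ids = [f"F{i + 1:03d}" for i in range(n)]
    mother_ids = [f"MOM{i + 1:03d}" for i in range(n)]

    mother_age = rng.uniform(dem.mother_age_min, dem.mother_age_max, n)
    mother_birth = f_birth - (mother_age * DAYS_PER_YEAR).astype(int)
    # maternal death in the daughter's first four years, else much later
    m_dies4 = rng.random(n) < adv.maternal_death_p4
    lam4 = -np.log(max(1.0 - adv.maternal_death_p4, 1e-12)) / 4.0
    d4 = _truncated_exp(rng, max(lam4, 1e-9), 4.0, n)
    later = 4.0 + rng.exponential(8.0, n)
    mother_death_age_off = np.where(m_dies4, d4, later)  # years after focal birth
    mother_death_day = f_birth + (mother_death_age_off * DAYS_PER_YEAR).astype(int)

    ibi_prev = np.exp(rng.normal(adv.ibi_log_mean, adv.ibi_log_sd, n))
    ibi_next = np.exp(rng.normal(adv.ibi_log_mean, adv.ibi_log_sd, n))
    prev_birth = f_birth - (ibi_prev * DAYS_PER_YEAR).astype(int)
    next_due = f_birth + (ibi_next * DAYS_PER_YEAR).astype(int)
    next_born = (next_due < np.minimum(mother_death_day, censor_day))

    # fathers: sampled among the group's males resident at conception,
    # weighted by rank quality (memoryless residence => remaining tenure is
    # exponential with the configured departure hazard)
    father_of = np.empty(n, dtype=object)
    males_by_group = {gid: males[males["group"] == gid].reset_index(drop=True)
                      for gid in groups}
    for i in range(n):
        gm = males_by_group[groups[f_group[i]]]
        resident = gm[(gm["entry"] <= f_conc[i]) & (gm["exit"] >= f_conc[i])]
        if not len(resident):
            resident = gm  # degenerate tiny configs: fall back to any group male
        w = np.exp(0.5 * resident["quality"].to_numpy())
        father_of[i] = resident["id"].iloc[int(rng.choice(len(resident), p=w / w.sum()))]

    # sibling paternities
    sib_same = rng.random((n, 2)) < adv.sibling_same_father_p
    sib_missing = rng.random((n, 2)) < adv.sibling_paternity_missing_p
    sib_sex = rng.choice(["F", "M"], size=(n, 2))

    male_lookup = males.set_index("id")

    def _other_male(i: int, col: int) -> str | float:
        if sib_missing[i, col]:
            return np.nan
        if sib_same[i, col]:
            return father_of[i]
        gm = males_by_group[groups[f_group[i]]]
        j = int(rng.integers(0, len(gm)))
        return gm["id"].iloc[j]

    prev_father = [_other_male(i, 0) for i in range(n)]
    next_father = [_other_male(i, 1) for i in range(n)]

    # ---- effort per group-year -------------------------------------------
    years = range(_ts(study_start).year, _ts(censor_day).year + 1)
    eff_rows = []
    for gid in groups:
        gm = males_by_group[gid]
        gf = bg_females[bg_females["group"] == gid]
        for year in years:
            mid = _day(pd.Timestamp(year=year, month=7, day=1))
            n_ad = int(((gm["entry"] <= mid) & (gm["exit"] >= mid)).sum()
                       + ((gf["entry"] <= mid) & (gf["exit"] >= mid)).sum())
            value = (eff.base + eff.group_size_slope * np.log(max(n_ad, 2) / 30.0)
                     + rng.normal(0.0, eff.sd))
            value = max(eff.minimum, value)
            eff_rows.append((gid, year, value, min(1.0, eff.detection_scale * value)))
    effort_df = pd.DataFrame(eff_rows, columns=["group_id", "year", "effort", "detection_p"])
    detection = {(r.group_id, r.year): r.detection_p for r in effort_df.itertuples()}

    # ---- monthly male ranks ----------------------------------------------
    rank_rows = []
    month_starts = pd.date_range(_ts(study_start), _ts(censor_day), freq="MS")
    for gid in groups:
        gm = males_by_group[gid]
        entry = gm["entry"].to_numpy()
        exit_ = gm["exit"].to_numpy()
        quality = gm["quality"].to_numpy()
        ids = gm["id"].to_numpy()
        for ms in month_starts:
            d0 = _day(ms)
            res = np.flatnonzero((entry <= d0) & (exit_ >= d0))
            if not len(res):
                continue
            order_q = res[np.argsort(-quality[res], kind="stable")]
            for r, j in enumerate(order_q, start=1):
                rank_rows.append((ids[j], ms.strftime("%Y-%m"), r))
    ranks_df = pd.DataFrame(rank_rows, columns=["individual_id", "month", "ordinal_rank"])
    rank_map = {(r.individual_id, r.month): r.ordinal_rank for r in ranks_df.itertuples()}

    # mothers' ordinal ranks in the focal birth month (for the maternal-rank
    # adversity component): a latent quality percentile among group females
    mother_rank_pct = rng.random(n)
    mother_rank_rows = []
    for i in range(n):
        gid = groups[f_group[i]]
        gf = bg_females[bg_females["group"] == gid]
        n_res = int(((gf["entry"] <= f_birth[i]) & (gf["exit"] >= f_birth[i])).sum()) + 1
        rank = 1 + int(mother_rank_pct[i] * n_res)
        mother_rank_rows.append((mother_ids[i], _ts(f_birth[i]).strftime("%Y-%m"), rank))

    # ---- consortships at the focal conception ----------------------------
    consort_rows = []
    consort_share: dict[tuple[int, str], float] = {}
    observed = rng.random(n) < beh.consort_observed_p
    share = rng.beta(beh.father_share_alpha, beh.father_share_beta, n)
    minutes = rng.gamma(beh.consort_minutes_shape, beh.consort_minutes_scale, n)
    for i in range(n):
        if not observed[i]:
            continue
        gm = males_by_group[groups[f_group[i]]]
        resident = gm[(gm["entry"] <= f_conc[i]) & (gm["exit"] >= f_conc[i])]
        others = resident[resident["id"] != father_of[i]]
        date = f_conc[i] - 2
        consort_rows.append((father_of[i], mother_ids[i], date, minutes[i] * share[i]))
        consort_share[(i, father_of[i])] = share[i]
        if len(others):
            other = others["id"].iloc[int(rng.integers(0, len(others)))]
            consort_rows.append((other, mother_ids[i], date, minutes[i] * (1 - share[i])))
            consort_share[(i, other)] = 1 - share[i]

    # ---- early-life adversity components ---------------------------------
    z_drought = np.sqrt(2) * _erfinv(2 * adv.drought_p - 1)
    rain_mu = np.log(adv.drought_threshold_mm) - adv.rainfall_log_sd * z_drought
    rainfall = np.exp(rng.normal(rain_mu, adv.rainfall_log_sd, n))
    drought = rainfall < adv.drought_threshold_mm
    maternal_loss = m_dies4

    group_size_birth = np.zeros(n, dtype=int)
    for i in range(n):
        gid = groups[f_group[i]]
        gm = males_by_group[gid]
        gf = bg_females[bg_females["group"] == gid]
        d0 = f_birth[i]
        group_size_birth[i] = int(((gm["entry"] <= d0) & (gm["exit"] >= d0)).sum()
                                  + ((gf["entry"] <= d0) & (gf["exit"] >= d0)).sum()) + 1
    large_group = group_size_birth >= np.quantile(group_size_birth, 0.75, method="linear")
    obs_ibi = np.where(next_born, ibi_next, np.inf)
    with_sib = obs_ibi[np.isfinite(obs_ibi)]
    close_sib = next_born & (ibi_next < (np.quantile(with_sib, 0.25, method="linear")
                                         if len(with_sib) >= 4 else 1.5))
    mother_ranks_arr = np.array([r for (_, _, r) in mother_rank_rows], dtype=float)
    low_rank = mother_ranks_arr >= np.quantile(mother_ranks_arr, 0.75, method="linear")
    mother_greg = rng.normal(0.0, gro.mother_gregariousness_sd, n)
    isolated = mother_greg <= np.quantile(mother_greg, 0.25, method="linear")
    ela_true = (drought.astype(int) + maternal_loss.astype(int) + large_group.astype(int)
                + close_sib.astype(int) + low_rank.astype(int) + isolated.astype(int))

    # ---- paternal co-residency and survival ------------------------------
    father_exit = np.array([male_lookup.loc[father_of[i], "exit"] for i in range(n)])
    father_entry = np.array([male_lookup.loc[father_of[i], "entry"] for i in range(n)])
    win_end = np.array([_add_years_day(f_birth[i], 4) for i in range(n)])
    cores_days = np.maximum(
        0, np.minimum(father_exit + 1, np.minimum(win_end, censor_day)) -
        np.maximum(father_entry, f_birth))
    cores_years = cores_days / DAYS_PER_YEAR

    dyad_noise_father = rng.normal(0.0, gro.dyad_noise_sd, n)
    raw_pat = np.where(cores_days > 0, dyad_noise_father,
                       -3.0 * max(gro.dyad_noise_sd, 1e-9))
    z_pat = (raw_pat - raw_pat.mean()) / max(raw_pat.std(ddof=1), 1e-12)

    greg = rng.normal(0.0, gro.gregariousness_sd, n)
    z_greg = ((greg - greg.mean()) / max(greg.std(ddof=1), 1e-12)
              if n > 1 else np.zeros(n))

    eta = (sur.log_hr_ela * (ela_true - sur.ela_center)
           + sur.log_hr_dsi_paternal * z_pat
           + sur.log_hr_coresidency * (cores_years - sur.coresidency_center_years)
           + (sur.log_hr_sci_f + sur.log_hr_sci_m) * z_greg)
    k_w, lam_w = sur.weibull_shape, sur.weibull_scale
    e_draw = rng.exponential(1.0, n)
    death_age = lam_w * ((4.0 / lam_w) ** k_w + e_draw * np.exp(-eta)) ** (1.0 / k_w)
    censor_age = (censor_day - f_birth) / DAYS_PER_YEAR
    event = death_age < censor_age
    exit_day = np.where(event,
                        f_birth + (death_age * DAYS_PER_YEAR).astype(int),
                        censor_day)

    # ---- individuals table ------------------------------------------------
    ind_rows = []
    for row in males.itertuples():
        ind_rows.append(dict(id=row.id, sex="M", birth_date=row.birth,
                             death_date=row.exit if row.dies else np.nan,
                             censor_date=np.nan if row.dies else censor_day,
                             mother_id=np.nan, father_id=np.nan))
    for row in bg_females.itertuples():
        ind_rows.append(dict(id=row.id, sex="F", birth_date=row.birth,
                             death_date=np.nan, censor_date=censor_day,
                             mother_id=np.nan, father_id=np.nan))
    for i in range(n):
        dies = mother_death_day[i] <= censor_day
        ind_rows.append(dict(id=mother_ids[i], sex="F", birth_date=mother_birth[i],
                             death_date=mother_death_day[i] if dies else np.nan,
                             censor_date=np.nan if dies else censor_day,
                             mother_id=np.nan, father_id=np.nan))
    for i in range(n):
        ind_rows.append(dict(id=focal_ids[i], sex="F", birth_date=f_birth[i],
                             death_date=exit_day[i] if event[i] else np.nan,
                             censor_date=np.nan if event[i] else censor_day,
                             mother_id=mother_ids[i], father_id=father_of[i]))
    sib_rows = []
    for i in range(n):
        sib_rows.append(dict(id=f"SIBP{i + 1:03d}", sex=sib_sex[i, 0],
                             birth_date=prev_birth[i], father=prev_father[i],
                             mother=mother_ids[i], group=groups[f_group[i]]))
        if next_born[i]:
            sib_rows.append(dict(id=f"SIBN{i + 1:03d}", sex=sib_sex[i, 1],
                                 birth_date=next_due[i], father=next_father[i],
                                 mother=mother_ids[i], group=groups[f_group[i]]))
    for s in sib_rows:
        ind_rows.append(dict(id=s["id"], sex=s["sex"], birth_date=s["birth_date"],
                             death_date=np.nan, censor_date=censor_day,
                             mother_id=s["mother"], father_id=s["father"]))
    individuals = pd.DataFrame(ind_rows)

    # ---- residencies -------------------------------------------------------
    res_rows = []
    for row in males.itertuples():
        res_rows.append((row.id, row.group, row.entry, row.exit))
    for row in bg_females.itertuples():
        res_rows.append((row.id, row.group, row.entry, row.exit))
    for i in range(n):
        gid = groups[f_group[i]]
        m_start = max(study_start, min(prev_birth[i] - 30, f_conc[i] - 365))
        m_end = min(mother_death_day[i], censor_day)
        res_rows.append((mother_ids[i], gid, m_start, m_end))
        res_rows.append((focal_ids[i], gid, f_birth[i], exit_day[i]))
    for s in sib_rows:
        # natal males disperse around maturity; females are philopatric
        if s["sex"] == "M":
            depart = s["birth_date"] + int(rng.uniform(7.5, 9.5) * DAYS_PER_YEAR)
            end = min(censor_day, depart)
        else:
            end = censor_day
        res_rows.append((s["id"], s["group"], s["birth_date"], end))
    residencies = pd.DataFrame(res_rows,
                               columns=["individual_id", "group_id", "start", "end"])

    # ---- conception ovulation windows -------------------------------------
    ov_all = ov_bg[["female_id", "start", "end"]].copy()
    ov_all["conception_flag"] = False
    ov_conc = pd.DataFrame({
        "female_id": mother_ids,
        "start": f_conc - 4, "end": f_conc,
        "conception_flag": True,
    })
    ovulation = pd.concat([ov_all, ov_conc], ignore_index=True)

    # ---- juvenile dyadic grooming events ----------------------------------
    # offspring birth days per male (focals + siblings) for the generator-side
    # co-resident-offspring effect; queried by binary search
    offspring_births: dict[str, list[int]] = {}
    for i in range(n):
        offspring_births.setdefault(father_of[i], []).append(int(f_birth[i]))
        if isinstance(prev_father[i], str):
            offspring_births.setdefault(prev_father[i], []).append(int(prev_birth[i]))
        if next_born[i] and isinstance(next_father[i], str):
            offspring_births.setdefault(next_father[i], []).append(int(next_due[i]))
    offspring_births = {m: np.sort(np.array(b)) for m, b in offspring_births.items()}
    four_years = int(4 * DAYS_PER_YEAR)

    def _n_offspring(male_id: str, at_day: int) -> int:
        b = offspring_births.get(male_id)
        if b is None:
            return 0
        return int(np.searchsorted(b, at_day, "right")
                   - np.searchsorted(b, at_day - four_years, "right"))

    dyad_noise: dict[tuple[int, str], float] = {}
    groom_parts = []
    dyad_rows = []
    for i in range(n):
        gid = groups[f_group[i]]
        gm = males_by_group[gid]
        entry = gm["entry"].to_numpy()
        exit_ = gm["exit"].to_numpy()
        ids = gm["id"].to_numpy()
        f_exit_i = exit_day[i]
        for k in range(4):
            w0 = _add_years_day(f_birth[i], k)
            w1 = min(_add_years_day(f_birth[i], k + 1), censor_day + 1, f_exit_i + 1)
            if w1 <= w0:
                continue
            lo = np.maximum(entry, w0)
            hi = np.minimum(exit_ + 1, w1)
            days = np.maximum(0, hi - lo)
            present = np.flatnonzero(days > 0)
            if not len(present):
                continue
            year = _ts(w0).year
            det = detection.get((gid, year), 0.5)
            mid_month = _ts((w0 + w1) // 2).strftime("%Y-%m")
            fert = ov_count[gid][max(0, w0 - study_start):max(1, w1 - study_start)].mean()
            for j in present:
                mid = ids[j]
                is_father = mid == father_of[i]
                if is_father:
                    noise = dyad_noise_father[i]
                elif (i, mid) in dyad_noise:
                    noise = dyad_noise[(i, mid)]
                else:
                    noise = dyad_noise[(i, mid)] = rng.normal(0.0, gro.dyad_noise_sd)
                rank = rank_map.get((mid, mid_month), len(present))
                cshare = consort_share.get((i, mid), 0.0)
                n_off = _n_offspring(mid, (w0 + w1) // 2) - int(is_father)
                log_rate = (gro.baseline_log_rate
                            + gro.father_effect * is_father
                            + gro.age_effect * (k + 0.5)
                            + noise
                            + beh.rank_effect * (rank - 6.0)
                            + beh.fertile_effect * fert
                            + beh.consort_effect * cshare
                            + beh.offspring_years_effect * n_off)
                mu = np.exp(log_rate) * days[j] * det
                count = rng.poisson(mu)
                dyad_rows.append((focal_ids[i], mid, k, bool(is_father),
                                  float(noise), int(days[j]), int(count)))
                if count:
                    dates = rng.integers(lo[j], hi[j], count)
                    age_at = (dates - f_birth[i]) / DAYS_PER_YEAR
                    p_fem = _ilogit(gro.initiation_intercept
                                    + gro.initiation_age_slope * age_at)
                    fem_init = rng.random(count) < p_fem
                    actor = np.where(fem_init, focal_ids[i], mid)
                    recip = np.where(fem_init, mid, focal_ids[i])
                    groom_parts.append(pd.DataFrame(dict(
                        date=dates, group_id=gid, actor_id=actor,
                        recipient_id=recip, initiator_id=actor)))

    # ---- adult grooming of focal females (connectedness indices) ----------
    fem_by_group = {gid: bg_females[bg_females["group"] == gid]["id"].to_numpy()
                    for gid in groups}
    male_ids_by_group = {gid: males_by_group[gid]["id"].to_numpy() for gid in groups}
    for i in range(n):
        gid = groups[f_group[i]]
        a0 = _add_years_day(f_birth[i], 4)
        a1 = min(exit_day[i], censor_day)
        if a1 <= a0:
            continue
        for partner_pool, rate in ((fem_by_group[gid], gro.adult_female_rate),
                                   (male_ids_by_group[gid], gro.adult_male_rate)):
            if not len(partner_pool):
                continue
            yr = _ts((a0 + a1) // 2).year
            det = detection.get((gid, yr), 0.5)
            mu = rate * np.exp(greg[i]) * (a1 - a0) * det
            count = rng.poisson(mu)
            if not count:
                continue
            dates = rng.integers(a0, a1, count)
            partners = partner_pool[rng.integers(0, len(partner_pool), count)]
            gives = rng.random(count) < 0.5
            actor = np.where(gives, focal_ids[i], partners)
            recip = np.where(gives, partners, focal_ids[i])
            groom_parts.append(pd.DataFrame(dict(
                date=dates, group_id=gid, actor_id=actor,
                recipient_id=recip, initiator_id=actor)))

    # ---- maternal grooming (isolation component) ---------------------------
    for i in range(n):
        gid = groups[f_group[i]]
        pool = fem_by_group[gid]
        if not len(pool):
            continue
        w0 = f_birth[i]
        w1 = min(_add_years_day(f_birth[i], 2), mother_death_day[i], censor_day)
        if w1 <= w0:
            continue
        det = detection.get((gid, _ts((w0 + w1) // 2).year), 0.5)
        mu = gro.mother_rate * np.exp(mother_greg[i]) * (w1 - w0) * det
        count = rng.poisson(mu)
        if not count:
            continue
        dates = rng.integers(w0, w1, count)
        partners = pool[rng.integers(0, len(pool), count)]
        gives = rng.random(count) < 0.5
        actor = np.where(gives, mother_ids[i], partners)
        recip = np.where(gives, partners, mother_ids[i])
        groom_parts.append(pd.DataFrame(dict(
            date=dates, group_id=gid, actor_id=actor,
            recipient_id=recip, initiator_id=actor)))

    grooming = (pd.concat(groom_parts, ignore_index=True) if groom_parts
                else pd.DataFrame(columns=["date", "group_id", "actor_id",
                                           "recipient_id", "initiator_id"]))
    grooming = grooming.sort_values(["date", "actor_id", "recipient_id"],
                                    kind="stable").reset_index(drop=True)

    # ---- assemble the dataset ---------------------------------------------
    individuals["birth_date"] = _ts_array(individuals["birth_date"])
    individuals["death_date"] = _opt_ts_array(individuals["death_date"])
    individuals["censor_date"] = _opt_ts_array(individuals["censor_date"])
    residencies = pd.DataFrame({
        "individual_id": residencies["individual_id"],
        "group_id": residencies["group_id"],
        "start_date": _ts_array(residencies["start"]),
        "end_date": _ts_array(residencies["end"]),
    })
    grooming_out = pd.DataFrame({
        "date": _ts_array(grooming["date"]),
        "group_id": grooming["group_id"].astype(object),
        "actor_id": grooming["actor_id"].astype(object),
        "recipient_id": grooming["recipient_id"].astype(object),
        "initiator_id": grooming["initiator_id"].astype(object),
    })
    ranks_all = pd.concat([
        ranks_df,
        pd.DataFrame(mother_rank_rows, columns=["individual_id", "month", "ordinal_rank"]),
    ], ignore_index=True)
    rainfall_df = pd.DataFrame({
        "period_start": _ts_array(f_birth),
        "period_end": _ts_array([_add_years_day(b, 1) - 1 for b in f_birth]),
        "total_mm": rainfall,
    })
    consorts_df = pd.DataFrame(consort_rows,
                               columns=["male_id", "female_id", "date", "observed_minutes"])
    consorts_df["date"] = _ts_array(consorts_df["date"]) if len(consorts_df) else \
        pd.Series([], dtype="datetime64[ns]")
    ovulation_df = pd.DataFrame({
        "female_id": ovulation["female_id"].astype(object),
        "start_date": _ts_array(ovulation["start"]),
        "end_date": _ts_array(ovulation["end"]),
        "conception_flag": ovulation["conception_flag"].astype(bool),
    })

    ds = PopulationDataset(
        individuals=individuals,
        residencies=residencies,
        grooming=grooming_out,
        effort=effort_df[["group_id", "year", "effort"]].copy(),
        ranks=ranks_all,
        rainfall=rainfall_df,
        consorts=consorts_df,
        ovulation=ovulation_df,
    ).validate()

    truth_females = pd.DataFrame({
        "female_id": focal_ids,
        "group_id": [groups[g] for g in f_group],
        "birth_day": f_birth,
        "father_id": father_of,
        "drought": drought, "maternal_loss": maternal_loss,
        "large_group": large_group, "close_sibling": close_sib,
        "low_maternal_rank": low_rank, "maternal_isolation": isolated,
        "ela_true": ela_true,
        "coresidency_days_true": cores_days,
        "z_paternal_true": z_pat,
        "z_gregariousness_true": z_greg,
        "eta_true": eta,
        "death_age_uncensored": death_age,
        "censor_age": censor_age,
        "event": event,
    })
    dyads = pd.DataFrame(dyad_rows, columns=[
        "female_id", "male_id", "year_of_life", "is_father",
        "log_propensity", "coresident_days", "observed_count"])
    truth = GroundTruth(
        config=config,
        paternities=pd.DataFrame({"female_id": focal_ids, "father_id": father_of}),
        dyad_propensities=dyads,
        females=truth_females,
        group_effort=effort_df,
    )
    return ds, truth


def _add_years_day(day: int, k: int) -> int:
    """Day number of ``day + k`` calendar years (29 Feb -> 1 Mar off-leap)."""
    from .dataset import add_years
    return _day(add_years(_ts(day), k))


def _ilogit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def _erfinv(x):
    from scipy.special import erfinv
    return float(erfinv(x))


# --------------------------------------------------------------------------
# direct covariate-level generators
# --------------------------------------------------------------------------

def simulate_cohort_for_survival(config: SimulationConfig, n: int,
                                 seed: int | None = None) -> tuple[pd.DataFrame, dict]:
    """Draw survival records directly from the configured hazard.

    Covariates come from their configured marginal distributions (adversity
    score as the sum of six Bernoulli components, paternal DSI standard
    normal, co-residency from the memoryless departure process); event times
    from the Weibull proportional-hazards model with entry at age 4 and
    administrative censoring at an age drawn uniformly over the range implied
    by the birth window. Returns the records and the true coefficients.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    adv, sur, dem = config.adversity, config.survival, config.demography

    p_components = np.array([0.25, 0.25, 0.25, 0.25,
                             adv.drought_p, adv.maternal_death_p4])
    ela = (rng.random((n, 6)) < p_components).sum(axis=1)
    dsi = rng.normal(0.0, 1.0, n)
    tenure_m = rng.exponential(dem.male_residence_mean_months, n)
    cores_m = np.clip(tenure_m - dem.gestation_days / DAYS_PER_MONTH, 0.0, 48.0)
    cores_years = cores_m / 12.0
    sci_f = rng.normal(0.0, 1.0, n)
    sci_m = rng.normal(0.0, 1.0, n)

    eta = (sur.log_hr_ela * (ela - sur.ela_center)
           + sur.log_hr_dsi_paternal * dsi
           + sur.log_hr_coresidency * (cores_years - sur.coresidency_center_years)
           + sur.log_hr_sci_f * sci_f + sur.log_hr_sci_m * sci_m)
    k_w, lam_w = sur.weibull_shape, sur.weibull_scale
    death_age = lam_w * ((4.0 / lam_w) ** k_w
                         + rng.exponential(1.0, n) * np.exp(-eta)) ** (1.0 / k_w)
    cen_lo = (_day(dem.censor_date) - _day(dem.birth_end)) / DAYS_PER_YEAR
    cen_hi = (_day(dem.censor_date) - _day(dem.birth_start)) / DAYS_PER_YEAR
    censor_age = rng.uniform(max(cen_lo, 4.01), cen_hi, n)
    event = death_age < censor_age
    records = pd.DataFrame({
        "female_id": [f"S{i + 1:05d}" for i in range(n)],
        "entry_age": 4.0,
        "exit_age": np.where(event, death_age, censor_age),
        "event": event,
        "ela": ela.astype(float),
        "mean_dsi_paternal": dsi,
        "mean_dsi_nonpaternal": rng.normal(0.0, 1.0, n),
        "mean_dsi_all": rng.normal(0.0, 1.0, n),
        "coresidency_years": cores_years,
        "sci_f": sci_f,
        "sci_m": sci_m,
    })
    truth = {
        "log_hr": {"ela": sur.log_hr_ela,
                   "mean_dsi_paternal": sur.log_hr_dsi_paternal,
                   "coresidency_years": sur.log_hr_coresidency,
                   "sci_f": sur.log_hr_sci_f, "sci_m": sur.log_hr_sci_m},
        "death_age_uncensored": death_age,
        "eta": eta,
    }
    return records, truth


#: true coefficients of the direct father-grooming generator, raw scale
FATHER_YEAR_COEF = {
    "rank": 0.185,
    "fertile_rate": -8.290,
    "consort_proportion": 2.334,
    "sired_previous": -0.378,
    "sired_next": -0.949,
    "offspring_years": 0.235,
    "ela": -0.416,
    "juvenile_age": 0.778,
    "paternal_age": 0.241,
    "maternal_age": 0.035,
    "observer_effort": 1.462,
}


def simulate_father_years(config: SimulationConfig, n: int,
                          seed: int | None = None,
                          random_intercept_sd: float = 0.7,
                          fathers: int | None = None) -> tuple[pd.DataFrame, dict]:
    """Direct logistic generator for father-year grooming occurrence.

    Covariates are drawn from realistic marginal distributions, the grooming
    flag from a logistic model with the package's default coefficients plus a
    father-level random intercept. Returns the rows and the truth (raw-scale
    coefficients, the intercept after centering, and the random-effect SD).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_f = fathers or max(2, n // 6)
    father_id = rng.integers(0, n_f, n)
    u = rng.normal(0.0, random_intercept_sd, n_f)

    x = pd.DataFrame({
        "rank": rng.integers(1, 13, n).astype(float),
        "fertile_rate": rng.beta(2.0, 8.0, n) * 0.5,
        "consort_proportion": rng.beta(3.0, 2.0, n),
        "sired_previous": (rng.random(n) < 0.15).astype(float),
        "sired_next": (rng.random(n) < 0.15).astype(float),
        "offspring_years": rng.gamma(2.0, 1.0, n),
        "ela": rng.binomial(6, 0.23, n).astype(float),
        "juvenile_age": rng.integers(0, 4, n) + 0.5,
        "paternal_age": rng.uniform(8.0, 20.0, n),
        "maternal_age": rng.uniform(7.0, 20.0, n),
        "observer_effort": np.maximum(0.2, rng.normal(1.2, 0.25, n)),
    })
    beta = pd.Series(FATHER_YEAR_COEF)
    centered = x - x.mean()
    logit = centered.to_numpy() @ beta.loc[x.columns].to_numpy() + u[father_id]
    groomed = rng.random(n) < _ilogit(logit)
    rows = x.copy()
    rows.insert(0, "father_id", [f"M{j + 1:04d}" for j in father_id])
    rows["groomed"] = groomed
    truth = {
        "coef": dict(beta),
        "intercept_centered": 0.0,
        "random_intercept_sd": random_intercept_sd,
        "x_means": dict(x.mean()),
    }
    return rows, truth
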