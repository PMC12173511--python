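"""Mixed-model analyses of grooming behaviour and co-residency.

Covers the descriptive models (does grooming initiation shift to the
juvenile with age; are father dyads stronger in DSI_all), the father-year
binomial mixed models of whether a male groomed his daughter, the pair-level
linear mixed models of co-residency duration, AICc candidate sets with
Akaike-weight model averaging, and the variance-inflation-factor screen.

Binomial mixed models use the package's marginal-ML random-intercept fitter
(:mod:`papiokit.glmm`); linear mixed models use statsmodels ``MixedLM``.
AICc comparisons across fixed-effect structures are made on maximum
likelihood fits.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .dataset import PopulationDataset, DatasetError, DAYS_PER_YEAR, JUVENILE_YEARS
from .glmm import GlmmFit, fit_logistic_glmm
from .survival import aicc

__all__ = [
    "TABLE3_TERMS", "TABLE4_TERMS", "MixedFit", "AssocComparison",
    "candidate_subsets", "fit_lmm", "fit_initiation_model",
    "fit_dsiall_father_model", "fit_grooming_occurrence_model",
    "fit_coresidency_model", "fit_allmale_grooming_model",
    "model_average", "compute_vif",
]

logger = logging.getLogger(__name__)

#: predictors of whether a father groomed his daughter in a given year
TABLE3_TERMS = [
    "rank", "fertile_rate", "consort_proportion", "sired_previous",
    "sired_next", "offspring_years", "ela", "juvenile_age", "paternal_age",
    "maternal_age", "observer_effort",
]

#: predictors of father-daughter co-residency duration (one row per pair);
#: whether the father sired the *next* offspring is excluded by design (only
#: long co-residencies could produce future offspring)
TABLE4_TERMS = [
    "rank", "fertile_rate", "consort_proportion", "n_potential_fathers",
    "sired_previous", "offspring_years", "ela", "paternal_age", "maternal_age",
]


@dataclass
class MixedFit:
    """A linear mixed model fit (random intercept), or its OLS fallback."""

    name: str
    terms: list[str]
    params: pd.Series
    se: pd.Series
    re_var: float
    resid_var: float
    loglik: float
    k: int
    n: int
    n_groups: int
    converged: bool
    model_type: str = "lmm"

    @property
    def zvalues(self) -> pd.Series:
        return self.params / self.se

    @property
    def aicc(self) -> float:
        return aicc(self.loglik, self.k, self.n)


@dataclass
class AssocComparison:
    """AICc-ordered set of mixed-model fits with per-model errors."""

    fits: list = field(default_factory=list)
    errors: dict[str, str] = field(default_factory=dict)
    dropped_rows: int = 0

    def table(self) -> pd.DataFrame:
        rows = [dict(model=f.name, loglik=f.loglik, k=f.k, n=f.n, aicc=f.aicc)
                for f in self.fits]
        out = pd.DataFrame(rows).sort_values("aicc", kind="stable")
        out["delta_aicc"] = out["aicc"] - out["aicc"].min()
        return out.reset_index(drop=True)

    def best(self):
        return min(self.fits, key=lambda f: f.aicc)

    def ordered(self) -> list:
        return sorted(self.fits, key=lambda f: f.aicc)


def candidate_subsets(terms: list[str], max_models: int = 64) -> list[tuple[str, ...]]:
    """Deterministic all-subsets candidate list, capped.

    Subsets are enumerated by increasing size (then lexicographically by the
    order of ``terms``); when the cap bites, the full model is appended so
    the richest structure is always a candidate.
    """
    out: list[tuple[str, ...]] = []
    full = tuple(terms)
    for size in range(len(terms) + 1):
        for comb in combinations(terms, size):
            out.append(comb)
            if len(out) >= max_models:
                if full not in out:
                    out[-1] = full
                return out
    return out


def fit_lmm(df: pd.DataFrame, response: str, terms: list[str], group_col: str,
            reml: bool = False, name: str = "lmm") -> MixedFit:
    """Random-intercept linear mixed model via statsmodels ``MixedLM``.

    Falls back to OLS (with a logged warning) when the grouping structure is
    degenerate — fewer than two groups, or no group with replication —
    since the intercept variance is then unidentifiable.
    """
    endog = df[response].astype(float)
    exog = sm.add_constant(df[list(terms)].astype(float), has_constant="add")
    groups = df[group_col]
    sizes = groups.value_counts()
    degenerate = (len(sizes) < 2) or (sizes.max() < 2)
    if not degenerate:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                model = sm.MixedLM(endog, exog, groups=groups)
                res = model.fit(reml=reml, method=["lbfgs", "bfgs", "cg"])
                if not np.isfinite(res.llf):
                    # exact zero random-effect variance makes the profiled
                    # log-likelihood degenerate under gradient methods
                    res = model.fit(reml=reml, method="powell")
                if not np.isfinite(res.llf):
                    raise ValueError("non-finite mixed-model log-likelihood")
                params = res.fe_params
                se = res.bse_fe
                re_var = float(np.asarray(res.cov_re)[0, 0])
                k = len(params) + 2  # + random-intercept and residual variances
                return MixedFit(
                    name=name, terms=list(terms),
                    params=params.copy(), se=se.copy(),
                    re_var=re_var, resid_var=float(res.scale),
                    loglik=float(res.llf), k=k, n=len(endog),
                    n_groups=len(sizes), converged=bool(res.converged),
                )
            except (np.linalg.LinAlgError, ValueError) as exc:
                logger.warning("MixedLM failed (%s); falling back to OLS", exc)
    else:
        logger.warning("degenerate grouping for %s (groups=%d); falling back "
                       "to fixed-effects-only OLS", name, len(sizes))
    res = sm.OLS(endog, exog).fit()
    return MixedFit(
        name=name, terms=list(terms),
        params=res.params.copy(), se=res.bse.copy(),
        re_var=0.0, resid_var=float(res.scale),
        loglik=float(res.llf), k=len(res.params) + 1, n=len(endog),
        n_groups=int(len(sizes)), converged=True, model_type="ols_fallback",
    )


# --------------------------------------------------------------------------
# descriptive models
# --------------------------------------------------------------------------

def initiation_events(ds: PopulationDataset, females: list[str]) -> pd.DataFrame:
    """Juvenile-female x adult-male grooming events with an initiation flag."""
    ind = ds.individuals.set_index("id")
    fset = set(females)
    g = ds.grooming
    a_f = g["actor_id"].isin(fset)
    r_f = g["recipient_id"].isin(fset)
    sub = g[a_f | r_f].copy()
    af = sub["actor_id"].isin(fset)
    sub["female_id"] = np.where(af, sub["actor_id"], sub["recipient_id"])
    sub["partner_id"] = np.where(af, sub["recipient_id"], sub["actor_id"])
    sub = sub[sub["partner_id"].map(ind["sex"]) == "M"]
    birth = sub["female_id"].map(ind["birth_date"])
    sub["age"] = (sub["date"] - birth).dt.days / DAYS_PER_YEAR
    sub = sub[(sub["age"] >= 0) & (sub["age"] < JUVENILE_YEARS)]
    sub["female_initiated"] = (sub["initiator_id"] == sub["female_id"]).astype(float)
    return sub[["female_id", "partner_id", "date", "age", "female_initiated"]]


def fit_initiation_model(ds: PopulationDataset, females: list[str]) -> GlmmFit:
    """Binomial mixed model: P(juvenile initiated the grooming) ~ age,
    random intercept per female."""
    ev = initiation_events(ds, females)
    if not len(ev):
        raise DatasetError("no juvenile-female x adult-male grooming events")
    return fit_logistic_glmm(ev[["age"]], ev["female_initiated"],
                             ev["female_id"], name="initiation")


def fit_dsiall_father_model(dyad_records: pd.DataFrame
                            ) -> tuple[MixedFit, MixedFit, float]:
    """DSI_all ~ age (+ male-is-father), random intercept per female.

    Returns (fit with the father term, fit without, AICc difference in
    favour of the father model: AICc(without) - AICc(with))."""
    inc = dyad_records[dyad_records["included"]].copy()
    if not len(inc):
        raise DatasetError("no included dyad-years")
    if inc["is_father"].nunique() < 2:
        raise DatasetError("is_father is constant; father model unidentifiable")
    inc["age"] = inc["year_of_life"].astype(float) + 0.5
    inc["is_father"] = inc["is_father"].astype(float)
    fit_with = fit_lmm(inc.assign(dsi=inc["dsi"]), "dsi", ["age", "is_father"],
                       "female_id", name="age+father")
    fit_without = fit_lmm(inc, "dsi", ["age"], "female_id", name="age")
    return fit_with, fit_without, fit_without.aicc - fit_with.aicc


# --------------------------------------------------------------------------
# candidate-set models
# --------------------------------------------------------------------------

def _prepare_rows(rows: pd.DataFrame, terms: list[str], response: str
                  ) -> tuple[pd.DataFrame, int, list[str]]:
    """Drop rows with missing predictors and constant columns."""
    df = rows.copy()
    usable = []
    for t in terms:
        if t not in df.columns:
            raise DatasetError(f"covariate table lacks term {t!r}")
        if df[t].nunique(dropna=True) < 2:
            logger.warning("dropping constant predictor %r from the candidate set", t)
            continue
        usable.append(t)
    before = len(df)
    df = df.dropna(subset=usable + [response])
    dropped = before - len(df)
    if dropped:
        logger.info("dropped %d rows with missing values among %s",
                    dropped, usable)
    return df, dropped, usable


def fit_grooming_occurrence_model(rows: pd.DataFrame,
                                  terms: list[str] | None = None,
                                  max_models: int = 64,
                                  group_col: str = "male_id",
                                  compute_se_all: bool = True) -> AssocComparison:
    """Binomial mixed models of whether the male groomed the juvenile.

    ``rows`` is the father-year (or male-year) covariate table restricted to
    >=30 co-resident days; rows with missing consort proportions or sibling
    paternities are dropped (count recorded on the comparison).
    """
    terms = TABLE3_TERMS if terms is None else terms
    df, dropped, usable = _prepare_rows(rows, terms, "groomed")
    comp = AssocComparison(dropped_rows=dropped)
    for subset in candidate_subsets(usable, max_models):
        name = "+".join(subset) if subset else "(intercept)"
        k = len(subset) + 2  # intercept + random-intercept variance
        if len(df) <= k + 1:
            comp.errors[name] = f"AICc undefined at n={len(df)}, k={k}"
            continue
        try:
            comp.fits.append(fit_logistic_glmm(
                df[list(subset)], df["groomed"].astype(float), df[group_col],
                name=name, compute_se=compute_se_all))
        except (FloatingPointError, ValueError, np.linalg.LinAlgError) as exc:
            comp.errors[name] = str(exc)
    if not comp.fits:
        raise DatasetError(f"every candidate model failed: {comp.errors}")
    return comp


def fit_coresidency_model(rows: pd.DataFrame,
                          terms: list[str] | None = None,
                          max_models: int = 64,
                          group_col: str = "father_id") -> AssocComparison:
    """Linear mixed models of co-residency duration (years), one row per
    father-daughter pair, random intercept per father."""
    terms = TABLE4_TERMS if terms is None else terms
    if "sired_next" in terms:
        raise DatasetError("sired_next is excluded from co-residency models: "
                           "only long co-residencies can sire future offspring")
    df = rows.copy()
    if "coresidency_years" not in df.columns:
        df["coresidency_years"] = df["coresidency_days"] / DAYS_PER_YEAR
    df, dropped, usable = _prepare_rows(df, terms, "coresidency_years")
    comp = AssocComparison(dropped_rows=dropped)
    for subset in candidate_subsets(usable, max_models):
        name = "+".join(subset) if subset else "(intercept)"
        k = len(subset) + 3  # intercept + two variance components
        if len(df) <= k + 1:
            comp.errors[name] = f"AICc undefined at n={len(df)}, k={k}"
            continue
        try:
            comp.fits.append(fit_lmm(df, "coresidency_years", list(subset),
                                     group_col, name=name))
        except (ValueError, np.linalg.LinAlgError) as exc:
            comp.errors[name] = str(exc)
    if not comp.fits:
        raise DatasetError(f"every candidate model failed: {comp.errors}")
    return comp


def fit_allmale_grooming_model(rows: pd.DataFrame,
                               terms: list[str] | None = None,
                               max_models: int = 64) -> AssocComparison:
    """Grooming-occurrence models over all co-resident males, adding a
    binary is-father effect to every candidate."""
    if not (~rows["is_father"]).any():
        raise DatasetError("no non-father rows; use the father-year model")
    terms = TABLE3_TERMS if terms is None else terms
    rows = rows.copy()
    rows["is_father"] = rows["is_father"].astype(float)
    # every candidate subset is augmented with is_father
    df, dropped, usable = _prepare_rows(rows, terms + ["is_father"], "groomed")
    usable = [t for t in usable if t != "is_father"]
    comp = AssocComparison(dropped_rows=dropped)
    for subset in candidate_subsets(usable, max_models):
        cols = list(subset) + ["is_father"]
        name = "+".join(cols)
        k = len(cols) + 2
        if len(df) <= k + 1:
            comp.errors[name] = f"AICc undefined at n={len(df)}, k={k}"
            continue
        try:
            comp.fits.append(fit_logistic_glmm(
                df[cols], df["groomed"].astype(float), df["male_id"], name=name))
        except (FloatingPointError, ValueError, np.linalg.LinAlgError) as exc:
            comp.errors[name] = str(exc)
    if not comp.fits:
        raise DatasetError(f"every candidate model failed: {comp.errors}")
    return comp


# --------------------------------------------------------------------------
# model averaging and collinearity screen
# --------------------------------------------------------------------------

def model_average(comparison: AssocComparison, rule: str = "top_n",
                  n: int = 7, delta_cutoff: float = 2.0) -> pd.DataFrame:
    """Akaike-weight conditional model averaging over a best-supported subset.

    ``rule='top_n'`` keeps the n lowest-AICc models, ``rule='delta'`` those
    within ``delta_cutoff`` of the best. Weights w_i are proportional to
    exp(-delta_i / 2). Each term is averaged over the models that contain it
    (weights renormalized); the unconditional SE folds in between-model
    variance: sqrt(sum w_i (se_i^2 + (b_i - b_bar)^2)).
    """
    fits = comparison.ordered()
    if not fits:
        raise DatasetError("empty model set")
    if rule == "top_n":
        subset = fits[:n]
    elif rule == "delta":
        best = fits[0].aicc
        subset = [f for f in fits if f.aicc - best <= delta_cutoff]
    else:
        raise ValueError(f"unknown averaging rule {rule!r}")
    a = np.array([f.aicc for f in subset])
    w = np.exp(-(a - a.min()) / 2.0)
    w /= w.sum()
    terms: list[str] = []
    for f in subset:
        for t in f.terms:
            if t != "(Intercept)" and t != "const" and t not in terms:
                terms.append(t)
    rows = []
    for t in terms:
        bs, ses, ws = [], [], []
        for f, wi in zip(subset, w):
            if t in f.params.index:
                bs.append(f.params[t]); ses.append(f.se[t]); ws.append(wi)
        bs, ses, ws = np.array(bs), np.array(ses), np.array(ws)
        support = float(ws.sum())   # summed Akaike weight of models with the term
        ws = ws / support
        bbar = float((ws * bs).sum())
        se = float(np.sqrt((ws * (ses ** 2 + (bs - bbar) ** 2)).sum()))
        rows.append(dict(term=t, beta=bbar, se=se,
                         z=abs(bbar) / se if se > 0 else np.inf,
                         n_models=len(bs), weight=support))
    out = pd.DataFrame(rows)
    out["in_all_models"] = out["n_models"] == len(subset)
    return out


def compute_vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factors, VIF_j = 1 / (1 - R^2_j).

    Each predictor is regressed on the others (with an intercept); exact
    collinearity yields ``inf``. Requires at least two predictors and more
    rows than predictors.
    """
    cols = list(design.columns)
    if len(cols) < 2:
        raise ValueError("VIF needs at least two predictors")
    x = design.to_numpy(float)
    if len(x) <= len(cols):
        raise ValueError("VIF needs more rows than predictors")
    out = {}
    for j, cj in enumerate(cols):
        others = np.column_stack([np.ones(len(x)), np.delete(x, j, axis=1)])
        yj = x[:, j]
        beta, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ beta
        ss_res = float(resid @ resid)
        ss_tot = float(((yj - yj.mean()) ** 2).sum())
        if ss_tot == 0:
            raise ValueError(f"predictor {cj!r} is constant")
        r2 = 1.0 - ss_res / ss_tot
        out[cj] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")
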