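"""Left-truncated Cox proportional-hazards models of adult female survival.

Females enter the risk set at age 4 (survival to the fourth birthday is a
cohort criterion, so earlier mortality cannot bias the fits) and exit at
death or administrative censoring. Candidate models combine cumulative
early-life adversity with the paternal-relationship covariates; models are
compared by small-sample-corrected Akaike information criterion (AICc).
Ties are handled by the Efron method; confidence intervals are log-scale
Wald intervals, reported as hazard ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter

from .dataset import DatasetError, DAYS_PER_YEAR

__all__ = [
    "ModelFit", "ModelComparison", "TABLE2_MODELS",
    "build_survival_records", "fit_cox", "aicc", "run_model_set",
    "test_ph", "survival_contrast", "fit_sci_mediation_set",
]

#: the seven candidate survival models, by covariate set
TABLE2_MODELS: dict[str, list[str]] = {
    "A": ["ela", "mean_dsi_paternal", "coresidency_years"],
    "B": ["ela", "mean_dsi_paternal"],
    "C": ["ela", "coresidency_years"],
    "D": ["ela", "mean_dsi_paternal", "mean_dsi_nonpaternal"],
    "E": ["ela"],
    "F": ["ela", "mean_dsi_nonpaternal"],
    "G": ["ela", "mean_dsi_all"],
}


@dataclass
class ModelFit:
    """A fitted Cox model: coefficients, hazard ratios, Wald CIs, AICc."""

    name: str
    terms: list[str]
    coef: pd.Series
    se: pd.Series
    loglik: float
    k: int
    n_used: int
    n_events: int
    fitter: CoxPHFitter | None = None
    training_df: pd.DataFrame | None = None

    @property
    def hazard_ratios(self) -> pd.Series:
        return np.exp(self.coef)

    @property
    def ci_lower(self) -> pd.Series:
        return np.exp(self.coef - 1.959963984540054 * self.se)

    @property
    def ci_upper(self) -> pd.Series:
        return np.exp(self.coef + 1.959963984540054 * self.se)

    @property
    def aicc(self) -> float:
        return aicc(self.loglik, self.k, self.n_used)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "coef": self.coef, "se": self.se, "hr": self.hazard_ratios,
            "hr_lower": self.ci_lower, "hr_upper": self.ci_upper,
        })


@dataclass
class ModelComparison:
    """AICc-ordered model set with per-model errors, if any."""

    fits: list[ModelFit] = field(default_factory=list)
    errors: dict[str, str] = field(default_factory=dict)

    def table(self) -> pd.DataFrame:
        rows = []
        for f in self.fits:
            rows.append(dict(model=f.name, loglik=f.loglik, k=f.k,
                             n=f.n_used, aicc=f.aicc))
        out = pd.DataFrame(rows).sort_values("aicc", kind="stable")
        out["delta_aicc"] = out["aicc"] - out["aicc"].min()
        return out.reset_index(drop=True)

    def best(self) -> ModelFit:
        return min(self.fits, key=lambda f: f.aicc)

    def fit(self, name: str) -> ModelFit:
        for f in self.fits:
            if f.name == name:
                return f
        raise KeyError(name)

    def delta_aicc(self, name: str) -> float:
        return self.fit(name).aicc - self.best().aicc


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample-corrected AIC: -2*loglik + 2k + 2k(k+1)/(n-k-1)."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n > k+1)")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def build_survival_records(summaries: pd.DataFrame, ela_profiles: pd.DataFrame,
                           coresidency_days: pd.Series,
                           individuals: pd.DataFrame,
                           sci: pd.DataFrame | None = None) -> pd.DataFrame:
    """Assemble one survival record per female.

    ``summaries`` carries the mean DSI covariates, ``ela_profiles`` the
    cumulative adversity score, ``coresidency_days`` days with the father
    (indexed by female), ``individuals`` the life-history dates. Exit age is
    age at death (event) or at censoring (no event), in years.
    """
    ind = individuals.set_index("id")
    rows = []
    for fid in summaries["female_id"]:
        row = ind.loc[fid]
        if pd.notna(row["death_date"]):
            exit_date, event = row["death_date"], True
        elif pd.notna(row["censor_date"]):
            exit_date, event = row["censor_date"], False
        else:
            raise DatasetError(f"female {fid!r} has neither death nor censor date")
        exit_age = (exit_date - row["birth_date"]).days / DAYS_PER_YEAR
        rows.append(dict(female_id=fid, entry_age=4.0, exit_age=exit_age,
                         event=event))
    rec = pd.DataFrame(rows)
    rec = rec.merge(summaries, on="female_id")
    rec = rec.merge(ela_profiles[["female_id", "cumulative"]]
                    .rename(columns={"cumulative": "ela"}), on="female_id")
    rec["coresidency_years"] = rec["female_id"].map(coresidency_days) / DAYS_PER_YEAR
    if sci is not None:
        rec = rec.merge(sci, on="female_id", how="left")
    bad = rec[rec["exit_age"] <= rec["entry_age"]]
    if len(bad):
        raise DatasetError(f"exit age <= entry age for {bad['female_id'].iloc[0]!r}")
    rec["ela"] = rec["ela"].astype(float)
    return rec


def fit_cox(records: pd.DataFrame, terms: list[str],
            interactions: list[tuple[str, str]] | None = None,
            name: str = "cox", robust: bool = False) -> ModelFit:
    """Left-truncated Cox fit (entry at ``entry_age``, exit at ``exit_age``).

    ``interactions`` adds product terms. Raises on fewer than two events,
    rank-deficient designs, missing covariates or non-convergence.
    """
    cols = list(terms)
    df = records.copy()
    missing = [t for t in cols if t not in df.columns or df[t].isna().all()]
    if missing:
        raise DatasetError(f"records lack covariate(s) {missing}; "
                           "cannot fit the requested survival model")
    for a, b in interactions or []:
        col = f"{a}:{b}"
        df[col] = df[a] * df[b]
        cols.append(col)
    df = df.dropna(subset=cols)
    if int(df["event"].sum()) < 2:
        raise DatasetError("fewer than 2 death events; Cox fit not identifiable")
    x = df[cols].to_numpy(float)
    rank = np.linalg.matrix_rank(x - x.mean(axis=0))
    if rank < len(cols):
        raise DatasetError(f"design matrix rank-deficient ({rank} < {len(cols)})")
    sub = df[["entry_age", "exit_age", "event"] + cols]
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(sub, duration_col="exit_age", event_col="event",
                entry_col="entry_age", robust=robust)
    return ModelFit(
        name=name, terms=cols,
        coef=cph.params_.copy(), se=cph.standard_errors_.copy(),
        loglik=float(cph.log_likelihood_), k=len(cols),
        n_used=len(sub), n_events=int(sub["event"].sum()),
        fitter=cph, training_df=sub,
    )


def run_model_set(records: pd.DataFrame,
                  set_spec: dict[str, list[str]] | None = None,
                  interactions: dict[str, tuple[list[str], list[tuple[str, str]]]] | None = None,
                  ) -> ModelComparison:
    """Fit a named set of Cox specifications and order them by AICc.

    Defaults to the seven-candidate paternal-relationship set. Per-model
    failures are recorded in ``errors`` and do not abort the comparison.
    ``interactions`` maps extra model names to (terms, interaction pairs).
    """
    set_spec = TABLE2_MODELS if set_spec is None else set_spec
    comp = ModelComparison()
    for mname, terms in set_spec.items():
        try:
            comp.fits.append(fit_cox(records, terms, name=mname))
        except (DatasetError, Exception) as exc:  # lifelines raises many types
            comp.errors[mname] = str(exc)
    for mname, (terms, pairs) in (interactions or {}).items():
        try:
            comp.fits.append(fit_cox(records, terms, pairs, name=mname))
        except Exception as exc:
            comp.errors[mname] = str(exc)
    if not comp.fits:
        raise DatasetError(f"every model in the set failed: {comp.errors}")
    return comp


def _schoenfeld_residuals(df: pd.DataFrame, terms: list[str],
                          coef: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Schoenfeld residuals at event times for a left-truncated Cox model.

    The risk set at event time t is {entry < t <= exit}. Returns (event
    times sorted ascending, d x p residual matrix). Assumes continuous
    times (ties, if any, are broken by order)."""
    x = df[terms].to_numpy(float)
    entry = df["entry_age"].to_numpy(float)
    exit_ = df["exit_age"].to_numpy(float)
    event = df["event"].to_numpy(bool)
    risk_score = np.exp(x @ coef)
    times = np.sort(exit_[event])
    resid = np.empty((len(times), x.shape[1]))
    for i, t in enumerate(times):
        at_risk = (entry < t) & (exit_ >= t)
        w = risk_score[at_risk]
        xbar = (w[:, None] * x[at_risk]).sum(axis=0) / w.sum()
        # the subject who dies at t (first match; continuous times)
        j = np.flatnonzero(event & (exit_ == t))[0]
        resid[i] = x[j] - xbar
    return times, resid


def test_ph(fit: ModelFit, time_transform: str = "rank") -> pd.DataFrame:
    """Scaled-Schoenfeld proportional-hazards test, per term plus global.

    The per-term statistic follows the Grambsch-Therneau approximation
    (correlating scaled residuals with transformed event times); the global
    row is the corresponding multivariate quadratic form on p degrees of
    freedom. Left truncation is respected in the risk sets.
    """
    from scipy import stats

    if fit.fitter is None or fit.training_df is None or not fit.terms:
        raise DatasetError("proportional-hazards test needs a fitted model "
                           "with at least one covariate")
    df = fit.training_df
    coef = fit.coef.to_numpy(float)
    times, resid = _schoenfeld_residuals(df, fit.terms, coef)
    d = len(times)
    if d < 2:
        raise DatasetError("too few events for the proportional-hazards test")
    cov = fit.fitter.variance_matrix_.loc[fit.terms, fit.terms].to_numpy(float)
    scaled = d * (resid @ cov)
    if time_transform == "rank":
        g = np.arange(1, d + 1, dtype=float)
    elif time_transform == "identity":
        g = times
    elif time_transform == "log":
        g = np.log(times)
    else:
        raise ValueError(f"unknown time transform {time_transform!r}")
    gc = g - g.mean()
    num = (gc[:, None] * scaled).sum(axis=0)
    se2 = np.diag(cov)
    t_stat = num ** 2 / (d * (gc ** 2).sum() * se2)
    rows = {term: {"test_statistic": t, "p": float(stats.chi2.sf(t, 1)), "df": 1}
            for term, t in zip(fit.terms, t_stat)}
    # global test: quadratic form over all terms
    v = d * (gc ** 2).sum() * cov
    try:
        t_glob = float(num @ np.linalg.solve(v, num))
        rows["GLOBAL"] = {"test_statistic": t_glob,
                          "p": float(stats.chi2.sf(t_glob, len(fit.terms))),
                          "df": len(fit.terms)}
    except np.linalg.LinAlgError:
        pass
    return pd.DataFrame(rows).T


def survival_contrast(fit: ModelFit, profile_a: dict, profile_b: dict
                      ) -> float | None:
    """Difference in predicted median survival age (years), b minus a.

    Predictions use the Breslow-type baseline from the fitted model; if
    either profile's survival curve never crosses 0.5, the contrast is
    unbounded and ``None`` is returned.
    """
    if fit.fitter is None:
        raise DatasetError("survival_contrast requires the fitted model object")
    frames = [pd.DataFrame([profile_a]), pd.DataFrame([profile_b])]
    medians = []
    for fr in frames:
        surv = fit.fitter.predict_survival_function(fr[fit.terms])
        s = surv.iloc[:, 0]
        below = s[s <= 0.5]
        medians.append(float(below.index[0]) if len(below) else None)
    if medians[0] is None or medians[1] is None:
        return None
    return medians[1] - medians[0]


def fit_sci_mediation_set(records: pd.DataFrame) -> ModelComparison:
    """Candidate set crossing paternal terms with adult connectedness terms.

    Requires ``sci_f``/``sci_m`` columns (females missing them are dropped
    inside each fit); used to ask whether paternal effects are attenuated
    once adult social connectedness is controlled.
    """
    for col in ("sci_f", "sci_m"):
        if col not in records.columns or records[col].isna().all():
            raise DatasetError(
                f"records lack adult connectedness column {col!r}; compute "
                "SCI before fitting the mediation set")
    base = ["ela"]
    paternal = [[], ["mean_dsi_paternal"], ["coresidency_years"],
                ["mean_dsi_paternal", "coresidency_years"]]
    sci = [[], ["sci_f"], ["sci_m"], ["sci_f", "sci_m"]]
    spec = {}
    for i, p in enumerate(paternal):
        for j, s in enumerate(sci):
            spec[f"P{i}S{j}"] = base + p + s
    return run_model_set(records, spec)
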