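"""Configuration for the synthetic-population generator.

The defaults define the study conditions the package emulates: a cohort of
216 juvenile females born into 13 social groups, followed from birth through
adulthood under administrative censoring, with father co-residency governed
by a memoryless male-departure process (median ~33 months of the 48 possible),
an early-life adversity mix whose cumulative score is zero for ~20% of
females, and an adult mortality hazard whose log-linear coefficients are the
natural logs of the package's default hazard ratios (1.262 per adversity
source, 0.787 per SD of mean paternal bond strength, 0.885 per year of
paternal co-residency).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, is_dataclass
from pathlib import Path

import yaml

__all__ = [
    "DemographyModel", "GroomingModel", "EffortModel", "AdversityModel",
    "SurvivalModel", "BehaviourModel", "SimulationConfig",
    "load_config", "save_config",
]


@dataclass
class DemographyModel:
    """Group composition, births and the male-departure process."""

    birth_start: str = "1993-01-01"       # focal birth window
    birth_end: str = "2016-12-31"
    censor_date: str = "2021-06-30"       # administrative end of observation
    gestation_days: int = 178
    n_males_per_group: float = 11.0       # steady-state adult males
    n_females_per_group: float = 20.0     # steady-state adult females
    # mean male residence in months; departure is exponential, so the hazard
    # of leaving is 1/mean per month regardless of tenure
    male_residence_mean_months: float = 56.0
    male_death_fraction: float = 0.3      # departures that are deaths
    female_residence_mean_years: float = 15.0
    mother_age_min: float = 7.0           # mother age at focal birth (uniform)
    mother_age_max: float = 20.0
    # background-female ovulatory cycling: mean gap between 5-day windows
    cycle_gap_mean_days: float = 120.0
    cycle_window_days: int = 5


@dataclass
class GroomingModel:
    """Dyadic juvenile-female x adult-male grooming rates (per day, log scale)."""

    baseline_log_rate: float = math.log(4.0e-4)
    father_effect: float = 0.55           # additive log-rate increment, father dyads
    age_effect: float = 0.50              # per-year log-rate increment
    dyad_noise_sd: float = 0.80           # lognormal dyad propensity SD
    # grooming-initiation logit: p(female initiates) = ilogit(a + b*age)
    initiation_intercept: float = -2.0
    initiation_age_slope: float = 1.0
    # adult grooming of focal females (for the adult connectedness indices)
    adult_female_rate: float = 0.040      # events/day with adult females
    adult_male_rate: float = 0.015        # events/day with adult males
    gregariousness_sd: float = 0.50       # per-female lognormal multiplier SD
    # maternal grooming (for the maternal social-isolation component)
    mother_rate: float = 0.050
    mother_gregariousness_sd: float = 0.50


@dataclass
class EffortModel:
    """Observer effort (focal samples per adult female per observation day)."""

    base: float = 1.20
    group_size_slope: float = -0.30       # vs log(adults/30): big groups get less
    sd: float = 0.15                      # group-year noise
    minimum: float = 0.20
    detection_scale: float = 0.50         # P(record event) = min(1, scale*effort)


@dataclass
class AdversityModel:
    """Marginal structure of the six early-life adversity components.

    Four components (large group, close sibling, low maternal rank, maternal
    isolation) are quartile flags on continuous traits and hit ~25% of
    females by construction; drought and maternal loss have configurable
    marginal probabilities.
    """

    drought_p: float = 0.180              # P(first-year rainfall < 200 mm)
    rainfall_log_sd: float = 0.40
    drought_threshold_mm: float = 200.0
    maternal_death_p4: float = 0.180      # P(mother dies in daughter's first 4 y)
    # interbirth intervals (years), lognormal
    ibi_log_mean: float = math.log(1.75)
    ibi_log_sd: float = 0.25
    # sibling paternity: P(same father as focal) and P(paternity unknown)
    sibling_same_father_p: float = 0.15
    sibling_paternity_missing_p: float = 0.12


@dataclass
class SurvivalModel:
    """Adult mortality hazard: Weibull baseline x log-linear covariate terms."""

    weibull_shape: float = 2.5
    weibull_scale: float = 21.0           # years; median adult death ~18
    log_hr_ela: float = math.log(1.262)          # per adversity source
    log_hr_dsi_paternal: float = math.log(0.787) # per SD of mean paternal DSI
    log_hr_coresidency: float = math.log(0.885)  # per year of co-residency
    log_hr_sci_f: float = 0.0
    log_hr_sci_m: float = 0.0
    # covariates are centered at these reference values inside the hazard so
    # the Weibull scale keeps its interpretation at a typical female
    ela_center: float = 1.40
    coresidency_center_years: float = 2.40


@dataclass
class BehaviourModel:
    """Why-fathers-groom generator: effects on the dyadic log grooming rate."""

    rank_effect: float = 0.030            # per ordinal rank unit (low rank grooms more)
    fertile_effect: float = -0.40         # per peri-ovulatory female per day
    consort_effect: float = 1.20          # per unit consort-time proportion
    offspring_years_effect: float = 0.08  # per co-resident offspring year
    # consort observation process at the focal's conception
    consort_observed_p: float = 0.856     # 1 - 31/216: some mothers never seen consorting
    father_share_alpha: float = 3.0       # Beta(a,b) father share of consort time
    father_share_beta: float = 2.0
    consort_minutes_shape: float = 2.0    # Gamma total observed minutes
    consort_minutes_scale: float = 30.0


@dataclass
class SimulationConfig:
    seed: int = 0
    n_females: int = 216
    n_groups: int = 13
    demography: DemographyModel = field(default_factory=DemographyModel)
    grooming: GroomingModel = field(default_factory=GroomingModel)
    effort: EffortModel = field(default_factory=EffortModel)
    adversity: AdversityModel = field(default_factory=AdversityModel)
    survival: SurvivalModel = field(default_factory=SurvivalModel)
    behaviour: BehaviourModel = field(default_factory=BehaviourModel)

    def __post_init__(self):
        self.validate()

    def validate(self) -> "SimulationConfig":
        if self.n_females < 1 or self.n_groups < 1:
            raise ValueError("n_females and n_groups must be positive")
        for name in ("drought_p", "maternal_death_p4", "sibling_same_father_p",
                     "sibling_paternity_missing_p"):
            p = getattr(self.adversity, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"adversity.{name} must be in [0, 1], got {p}")
        if not 0.0 <= self.behaviour.consort_observed_p <= 1.0:
            raise ValueError("behaviour.consort_observed_p must be in [0, 1]")
        if self.survival.weibull_scale <= 0 or self.survival.weibull_shape <= 0:
            raise ValueError("Weibull scale and shape must be positive")
        if self.demography.male_residence_mean_months <= 0:
            raise ValueError("male_residence_mean_months must be positive")
        if self.effort.detection_scale < 0:
            raise ValueError("detection_scale must be non-negative")
        return self

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        kwargs = dict(d)
        for name, sub in (("demography", DemographyModel), ("grooming", GroomingModel),
                          ("effort", EffortModel), ("adversity", AdversityModel),
                          ("survival", SurvivalModel), ("behaviour", BehaviourModel)):
            if name in kwargs and not is_dataclass(kwargs[name]):
                kwargs[name] = sub(**kwargs[name])
        return cls(**kwargs)


def load_config(path: str | Path) -> SimulationConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    return SimulationConfig.from_dict(d)


def save_config(config: SimulationConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
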