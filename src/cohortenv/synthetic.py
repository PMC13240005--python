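"""Seeded synthetic data with the statistical structure the analysis assumes.

Four generators share one :class:`SimulationConfig`:

* :func:`simulate_environment` — monthly station series (air temperature,
  sea-surface temperature, wind speed, wave height) as seasonal climatology +
  linear warming trend + a shared interannual anomaly (coupling air and water
  temperature) + independent monthly noise.
* :func:`simulate_cohorts` — per-generation ground truth.  Recruitment
  ``log N0`` responds to spring water temperature and spring wind of the birth
  year; the survivorship slope ``z`` responds to summer water temperature over
  the lifespan and, negatively, to the cohort's own (centered) ``log N0`` —
  density-dependent mortality.  ``z`` is truncated at 0 from above.
* :func:`sample_ages` — age-read sample tables: Poisson counts around true
  density x sampled area, partial detection of age-1 individuals, occasional
  individuals older than the nominal maximum age.
* :func:`simulate_biomass_surveys` — long-term biomass survey records built on
  the Box-Cox scale from a survey-specific longitude slope, a period-specific
  temperature slope, site random intercepts and Gaussian noise.

All randomness flows from ``config.seed`` through fixed per-stage substreams,
so identical configs give byte-identical tables.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import inv_boxcox

from cohortenv.env_features import season_mean, _monthly_lookup

__all__ = [
    "SimulationConfig",
    "GenerationTruth",
    "DEFAULT_SAMPLE_YEARS",
    "DEFAULT_SURVEY_DESIGN",
    "simulate_environment",
    "simulate_cohorts",
    "sample_ages",
    "simulate_biomass_surveys",
    "simulate_annual_temperature",
]

# Sampling years of the monitored population: near-annual coverage 2001-2020
# with gaps in 2008, 2014-2015 and 2019.
DEFAULT_SAMPLE_YEARS: tuple[int, ...] = (
    *range(2001, 2008), *range(2009, 2014), *range(2016, 2019), 2020,
)

#: survey label -> (years available, number of records).  The per-survey record
#: counts reproduce the decadal structure of the compiled long-term biomass
#: archive: 19 + 8 + 54 + 27 + 10 + 37 + 18 = 173 records.
DEFAULT_SURVEY_DESIGN: tuple[tuple[str, tuple[int, ...], int], ...] = (
    ("1930s", tuple(range(1933, 1940)), 19),
    ("1950s", tuple(range(1955, 1960)), 8),
    ("1960-1961", (1960, 1961), 54),
    ("1971", (1971,), 27),
    ("1981", (1981,), 10),
    ("2002-2005", tuple(range(2002, 2006)), 37),
    ("2010-2020", tuple(range(2010, 2021)), 18),
)

# per-stage substream identifiers (second entry of the entropy tuple)
_STAGES = {"environment": 1, "cohorts": 2, "ages": 3, "biomass": 4, "annual_temp": 5}

# monthly climatology: variable -> (annual mean, half-amplitude, month of peak)
_DEFAULT_CLIMATOLOGY: dict[str, tuple[float, float, int]] = {
    "air_temp": (1.5, 9.0, 7),
    "water_temp": (4.0, 4.5, 8),
    "wind": (6.5, 1.5, 1),
    "wave": (1.2, 0.5, 1),
}

_DEFAULT_ENV_NOISE = {"air_temp": 1.0, "water_temp": 0.6, "wind": 0.8, "wave": 0.25}


@dataclass
class SimulationConfig:
    """Parameters of one synthetic study.

    The defaults emulate a two-decade monitoring design: a 1995-2025
    environmental window, near-annual sampling 2001-2020, ten-year maximum age,
    density-dependent mortality, and a compiled biomass archive of 173 records
    at 62 sites spanning nine decades.
    """

    year_start: int = 1995
    year_end: int = 2025
    seed: int = 0

    # environment
    climatology: dict = field(default_factory=lambda: dict(_DEFAULT_CLIMATOLOGY))
    env_trend: float = 0.03  #: degC per year added to air and water temperature
    env_noise_sd: dict = field(default_factory=lambda: dict(_DEFAULT_ENV_NOISE))
    env_shared_anomaly_sd: float = 0.8  #: common monthly anomaly on both temperatures
    env_year_sd: float = 0.6  #: stationary SD of the yearly AR(1) temperature anomaly
    env_year_ar: float = 0.6  #: AR(1) coefficient of the yearly anomaly

    # cohorts: (intercept, spring water-temperature slope, spring wind slope) on log N0
    recruitment_effects: tuple[float, float, float] = (6.0, 1.0, 0.6)
    #: (intercept, lifespan summer water-temperature slope, density-dependence
    #: slope on centered log N0) on z.  The density slope of -0.2 places the
    #: zero crossing of the N0-Na association at age 5, reproducing the
    #: observed positive coupling of N0 with the young age classes (N2-N4) and
    #: negative coupling with the old ones.
    mortality_effects: tuple[float, float, float] = (-0.55, 0.2, -0.2)
    noise_sd: dict = field(
        default_factory=lambda: {"recruitment": 0.2, "mortality": 0.035}
    )
    max_age: int = 10

    # observation
    sample_years: tuple[int, ...] = DEFAULT_SAMPLE_YEARS
    core_area: float = 0.1  #: m2 per core
    n_cores: int = 5  #: cores pooled per sampling occasion
    age1_detection: float = 0.5
    observation: str = "poisson"  #: "poisson" or "exact" (noise-free counts)

    # biomass archive
    survey_design: tuple = DEFAULT_SURVEY_DESIGN
    n_sites: int = 62
    longitude_range: tuple[float, float] = (31.1, 39.6)
    biomass_lambda: float = 0.22  #: Box-Cox exponent of the generating scale
    biomass_intercept: float = 1.3  #: Box-Cox-scale grand mean
    #: survey label -> slope of Box-Cox biomass on longitude (deg E, centered)
    longitude_slopes: dict = field(default_factory=lambda: {"1960-1961": -0.25})
    #: period -> slope on the 5-year-preceding mean temperature (centered);
    #: "early" = surveys before period_split, "late" = after
    temperature_slopes: dict = field(default_factory=lambda: {"early": 0.8, "late": 0.1})
    period_split: int = 1975
    site_sd: float = 0.3
    biomass_noise_sd: float = 0.5

    # annual temperature series (regional thermal index)
    annual_temp_mean: float = 4.15
    annual_temp_amplitude: float = 0.5  #: multidecadal half-amplitude, degC
    annual_temp_period: float = 75.0  #: years; peak placed at 1945
    annual_temp_noise_sd: float = 0.25

    def __post_init__(self) -> None:
        if self.year_end - self.year_start < self.max_age + 4:
            raise ValueError(
                f"year_range {self.year_start}-{self.year_end} must span at least "
                f"max_age + 4 = {self.max_age + 4} years"
            )
        if not 0.0 <= self.age1_detection <= 1.0:
            raise ValueError(f"age1_detection {self.age1_detection} outside [0, 1]")
        if not -1.0 < self.biomass_lambda < 2.0:
            raise ValueError(f"biomass_lambda {self.biomass_lambda} outside (-1, 2)")
        if self.observation not in ("poisson", "exact"):
            raise ValueError(f"observation must be 'poisson' or 'exact', got {self.observation!r}")

    def with_(self, **kwargs) -> "SimulationConfig":
        """A copy with the given fields replaced."""
        return replace(self, **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("recruitment_effects", "mortality_effects", "sample_years",
                    "longitude_range"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        if "survey_design" in d and isinstance(d["survey_design"], list):
            d["survey_design"] = tuple(
                (label, tuple(years), int(n)) for label, years, n in d["survey_design"]
            )
        return cls(**d)


def _rng(config: SimulationConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((config.seed, _STAGES[stage])))


def simulate_environment(config: SimulationConfig) -> pd.DataFrame:
    """Monthly environmental series over ``config.year_range``.

    Each variable follows a cosine seasonal cycle around its annual mean; air
    and water temperature additionally carry a linear trend of
    ``config.env_trend`` degC/yr (anchored at ``year_start``), a persistent
    yearly AR(1) anomaly (multiannual thermal regimes), and a shared monthly
    anomaly that makes the two temperature series correlated.
    """
    rng = _rng(config, "environment")
    years = np.arange(config.year_start, config.year_end + 1)
    # stationary AR(1) yearly anomaly on both temperatures
    phi, sd_y = config.env_year_ar, config.env_year_sd
    innov_sd = sd_y * math.sqrt(max(1.0 - phi**2, 0.0))
    year_anom = np.zeros(len(years))
    prev = rng.normal(0.0, sd_y)
    for i in range(len(years)):
        prev = phi * prev + rng.normal(0.0, innov_sd) if i else prev
        year_anom[i] = prev
    rows = []
    for i, year in enumerate(years):
        for month in range(1, 13):
            shared = rng.normal(0.0, config.env_shared_anomaly_sd)
            row = {"year": int(year), "month": month}
            for var, (mean, amp, peak) in config.climatology.items():
                value = mean + amp * math.cos(2 * math.pi * (month - peak) / 12.0)
                if var in ("air_temp", "water_temp"):
                    value += (
                        config.env_trend * (year - config.year_start)
                        + year_anom[i]
                        + shared
                    )
                value += rng.normal(0.0, config.env_noise_sd.get(var, 0.0))
                row[var] = value
            rows.append(row)
    return pd.DataFrame(rows, columns=["year", "month", "air_temp", "water_temp", "wind", "wave"])


@dataclass
class GenerationTruth:
    """Ground truth per birth-year generation.

    ``table`` is indexed by birth year with columns ``true_log_n0`` (natural log
    count per m2 at age 0) and ``true_z`` (per-year log-scale slope, <= 0).
    """

    table: pd.DataFrame
    max_age: int

    @property
    def birth_years(self) -> np.ndarray:
        return self.table.index.to_numpy()

    def abundance(self, birth_year: int, age: int) -> float:
        """True abundance per m2 at ``age``: exp(log N0 + z * age)."""
        row = self.table.loc[birth_year]
        return float(np.exp(row["true_log_n0"] + row["true_z"] * age))

    def abundance_table(self, ages: Sequence[int] | None = None) -> pd.DataFrame:
        ages = list(ages) if ages is not None else list(range(1, self.max_age + 1))
        data = {
            f"age_{a}": np.exp(self.table["true_log_n0"] + self.table["true_z"] * a)
            for a in ages
        }
        return pd.DataFrame(data, index=self.table.index)


def simulate_cohorts(env: pd.DataFrame, config: SimulationConfig) -> GenerationTruth:
    """Draw per-generation truths from the environmental series.

    ``log N0 = a0 + a1 * spring water temp + a2 * spring wind + eps`` (covariates
    centered across generations); ``z = m0 + m1 * lifespan summer water temp +
    m2 * centered log N0 + eta``, truncated at 0 from above.  The lifespan
    covariate uses a fixed horizon of ``max_age`` years from birth.
    """
    rng = _rng(config, "cohorts")
    first_birth = config.year_start + 1  # spring of birth year must be covered
    last_birth = config.year_end - config.max_age
    births = np.arange(first_birth, last_birth + 1)
    if len(births) < 2:
        raise ValueError("environmental window too short for at least two generations")

    env_years = set(env["year"].astype(int))
    needed = set(range(first_birth, config.year_end + 1))
    missing = sorted(needed - env_years)
    if missing:
        raise ValueError(f"environmental series missing years: {missing}")

    water = _monthly_lookup(env, "water_temp")
    wind = _monthly_lookup(env, "wind")
    spring_water = np.array(
        [season_mean(env, "water_temp", "spring", b, _lookup=water) for b in births]
    )
    spring_wind = np.array(
        [season_mean(env, "wind", "spring", b, _lookup=wind) for b in births]
    )
    summer_life = np.array(
        [
            np.mean(
                [
                    season_mean(env, "water_temp", "summer", y, _lookup=water)
                    for y in range(b, b + config.max_age + 1)
                ]
            )
            for b in births
        ]
    )

    a0, a1, a2 = config.recruitment_effects
    m0, m1, m2 = config.mortality_effects
    sw = spring_water - spring_water.mean()
    wd = spring_wind - spring_wind.mean()
    sl = summer_life - summer_life.mean()

    log_n0 = a0 + a1 * sw + a2 * wd + rng.normal(0.0, config.noise_sd["recruitment"], len(births))
    z_raw = (
        m0
        + m1 * sl
        + m2 * (log_n0 - log_n0.mean())
        + rng.normal(0.0, config.noise_sd["mortality"], len(births))
    )
    n_truncated = int(np.sum(z_raw > 0))
    if n_truncated:
        warnings.warn(
            f"{n_truncated} generation(s) had positive raw z; truncated to 0",
            stacklevel=2,
        )
    z = np.minimum(z_raw, 0.0)

    table = pd.DataFrame(
        {
            "true_log_n0": log_n0,
            "true_z": z,
            "spring_water_temp": spring_water,
            "spring_wind": spring_wind,
            "lifespan_summer_water_temp": summer_life,
        },
        index=pd.Index(births, name="birth_year"),
    )
    return GenerationTruth(table=table, max_age=config.max_age)


def sample_ages(
    truth: GenerationTruth,
    sample_years: Sequence[int] | None = None,
    config: SimulationConfig | None = None,
) -> pd.DataFrame:
    """Age-read sample table: one row per (sample year, age) with observed
    abundance per m2.

    In ``"poisson"`` mode the observed count is Poisson(true density x sampled
    area) / area and cohorts drawn as zero are absent from the table (missing,
    not zero, matching how field samples record cohorts).  In ``"exact"`` mode
    the true density is reported directly.  Age-1 rows are retained with
    probability ``age1_detection``; ages up to ``max_age + 2`` are emitted (the
    exponential law extrapolated), so downstream filtering has over-aged rows
    to drop.
    """
    if config is None:
        raise ValueError("config is required")
    if sample_years is None:
        sample_years = config.sample_years
    sample_years = list(sample_years)
    if not sample_years:
        raise ValueError("sample_years is empty")
    rng = _rng(config, "ages")
    area = config.core_area * config.n_cores
    rows = []
    birth_set = set(int(b) for b in truth.birth_years)
    for year in sample_years:
        for age in range(1, config.max_age + 3):
            birth = year - age
            if birth not in birth_set:
                continue
            mu = truth.abundance(birth, age)
            if config.observation == "poisson":
                count = rng.poisson(mu * area)
                observed = count / area
            else:
                observed = mu
            if age == 1 and rng.random() >= config.age1_detection:
                continue
            if observed <= 0:
                continue
            rows.append({"sample_year": int(year), "age": age, "abundance": observed})
    return pd.DataFrame(rows, columns=["sample_year", "age", "abundance"])


def simulate_annual_temperature(
    config: SimulationConfig, year_start: int = 1925, year_end: int = 2020
) -> pd.DataFrame:
    """Annual regional water-temperature index, degC.

    Mean + multidecadal cosine (peak at 1945 by default, so mid-century is warm
    and the 1970s-1980s cold) + Gaussian noise.
    """
    rng = _rng(config, "annual_temp")
    years = np.arange(year_start, year_end + 1)
    temp = (
        config.annual_temp_mean
        + config.annual_temp_amplitude
        * np.cos(2 * np.pi * (years - 1945) / config.annual_temp_period)
        + rng.normal(0.0, config.annual_temp_noise_sd, len(years))
    )
    return pd.DataFrame({"year": years, "temp": temp})


def _area_label(longitude: float) -> str:
    if longitude < 34.0:
        return "KB"
    if longitude < 37.0:
        return "DZ"
    return "SI"


def simulate_biomass_surveys(
    config: SimulationConfig, annual_temp: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Long-term biomass survey records (kg/m2).

    On the Box-Cox scale (exponent ``biomass_lambda``) the linear predictor is
    intercept + survey-specific longitude slope + period-specific slope on the
    mean temperature of the five preceding years + site random intercept +
    Gaussian noise; values are back-transformed to kg/m2.  Record counts per
    survey follow ``config.survey_design``.
    """
    rng = _rng(config, "biomass")
    lam = config.biomass_lambda
    if annual_temp is None:
        annual_temp = simulate_annual_temperature(config)
    temp_by_year = dict(zip(annual_temp["year"].astype(int), annual_temp["temp"]))

    lon_lo, lon_hi = config.longitude_range
    longitudes = np.sort(rng.uniform(lon_lo, lon_hi, config.n_sites))
    site_effects = rng.normal(0.0, config.site_sd, config.n_sites)
    lon_center = 0.5 * (lon_lo + lon_hi)

    rows = []
    for label, years, n_records in config.survey_design:
        lon_slope = config.longitude_slopes.get(label, 0.0)
        for _ in range(n_records):
            site = int(rng.integers(0, config.n_sites))
            year = int(years[rng.integers(0, len(years))])
            period = "early" if year < config.period_split else "late"
            t5 = np.mean([temp_by_year[y] for y in range(year - 5, year)])
            bc = (
                config.biomass_intercept
                + lon_slope * (longitudes[site] - lon_center)
                + config.temperature_slopes.get(period, 0.0) * (t5 - config.annual_temp_mean)
                + site_effects[site]
                + rng.normal(0.0, config.biomass_noise_sd)
            )
            # back-transform domain: lam * bc + 1 must stay positive
            if lam != 0.0:
                bc = max(bc, -1.0 / lam + 1e-9)
            biomass = float(inv_boxcox(bc, lam))
            rows.append(
                {
                    "site": f"S{site:02d}",
                    "longitude": float(longitudes[site]),
                    "area": _area_label(longitudes[site]),
                    "year": year,
                    "survey": label,
                    "biomass": biomass,
                }
            )
    return pd.DataFrame(
        rows, columns=["site", "longitude", "area", "year", "survey", "biomass"]
    )
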