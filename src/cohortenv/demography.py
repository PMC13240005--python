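"""Cohort survivorship demography.

Age-read samples (sample year, age, abundance per m2) are rearranged into a
generation matrix (birth year x sampling year), filtered by the inclusion
rules of the monitoring design, and each retained generation's abundance decay
is fitted by ordinary least squares of log abundance on age:

    log N(a) = N0 + z * a

``z`` (the slope) is a proxy of the generation's per-year death rate and ``N0``
(the intercept at age 0) a proxy of its recruitment success — the Type III
survivorship assumption that cohort numbers decline exponentially with age.
Missing age-specific abundances are imputed from the fitted line, and the
resulting demographic matrix (N0, z, N2..N10 per generation) is screened for
density dependence via correlations of N0 with z and with the age-specific
abundances.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FilterReport",
    "SurvivorshipFit",
    "DemographicMatrix",
    "build_generation_matrix",
    "filter_generations",
    "fit_survivorship",
    "fit_all_generations",
    "impute_missing",
    "density_dependence_diagnostics",
    "last_detection_years",
]


def build_generation_matrix(samples: pd.DataFrame) -> pd.DataFrame:
    """Pivot age-read samples into a birth-year x sampling-year matrix.

    Birth year = sampling year - age.  Multiple observations of one (sampling
    year, age) cell are averaged.  Rows with non-integer or negative ages are
    rejected with a warning; ages 1 and above any maximum are retained here and
    handled by :func:`filter_generations`.
    """
    if samples is None or len(samples) == 0:
        raise ValueError("empty sample table")
    df = samples.copy()
    ages = pd.to_numeric(df["age"], errors="coerce")
    ok = ages.notna() & (ages > 0) & (np.mod(ages, 1) == 0)
    if not ok.all():
        bad = df.loc[~ok]
        warnings.warn(
            f"rejected {len(bad)} sample row(s) with non-integer or non-positive age",
            stacklevel=2,
        )
        df = df.loc[ok]
    if len(df) == 0:
        raise ValueError("all sample rows rejected: no valid integer ages")
    df = df.assign(
        age=ages[ok].astype(int),
        birth_year=lambda t: t["sample_year"].astype(int) - t["age"],
    )
    gm = (
        df.groupby(["birth_year", "sample_year"])["abundance"]
        .mean()
        .unstack("sample_year")
        .sort_index()
    )
    gm.index.name = "birth_year"
    gm.columns.name = "sample_year"
    return gm


@dataclass
class FilterReport:
    """Per-rule accounting of the generation inclusion filters.

    ``dropped_age_rule`` counts generations left without any cell once ages
    outside [min_age, max_age] are removed; the three dropped counts plus
    ``surviving`` add up to ``total``.
    """

    total: int
    dropped_age_rule: int
    dropped_birth_year_rule: int
    dropped_record_years_rule: int
    surviving: int
    cells_dropped_age: int
    min_birth_year: int
    min_record_years: int
    min_age: int
    max_age: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def filter_generations(
    gm: pd.DataFrame,
    min_birth_year: int = 1999,
    min_record_years: int = 4,
    min_age: int = 2,
    max_age: int = 10,
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the inclusion rules and report what each rule removed.

    Cells at ages below ``min_age`` (age-1 individuals are unreliable at the
    sieve size) or above ``max_age`` (older individuals are vanishingly rare)
    are blanked.  A generation is kept only if it was born in or after
    ``min_birth_year`` and remains recorded in at least ``min_record_years``
    distinct sampling years.
    """
    if gm is None or gm.size == 0:
        raise ValueError("empty generation matrix")
    out = gm.copy().astype(float)
    total = len(out)
    cells_dropped = 0
    for birth in out.index:
        for year in out.columns:
            age = int(year) - int(birth)
            if not math.isnan(out.at[birth, year]) and not (min_age <= age <= max_age):
                out.at[birth, year] = np.nan
                cells_dropped += 1

    has_cells = out.notna().any(axis=1)
    dropped_age = int((~has_cells).sum())
    out = out.loc[has_cells]

    born_ok = out.index >= min_birth_year
    dropped_birth = int((~born_ok).sum())
    out = out.loc[born_ok]

    enough_years = out.notna().sum(axis=1) >= min_record_years
    dropped_years = int((~enough_years).sum())
    out = out.loc[enough_years]

    report = FilterReport(
        total=total,
        dropped_age_rule=dropped_age,
        dropped_birth_year_rule=dropped_birth,
        dropped_record_years_rule=dropped_years,
        surviving=len(out),
        cells_dropped_age=cells_dropped,
        min_birth_year=min_birth_year,
        min_record_years=min_record_years,
        min_age=min_age,
        max_age=max_age,
    )
    if len(out) == 0:
        binding = max(
            ("age", dropped_age),
            ("birth-year", dropped_birth),
            ("record-years", dropped_years),
            key=lambda t: t[1],
        )[0]
        raise ValueError(
            f"no generations survive filtering; the {binding} rule removed the most "
            f"({report.as_dict()})"
        )
    out = out.dropna(axis=1, how="all")
    return out, report


@dataclass
class SurvivorshipFit:
    """OLS fit of log abundance on age for one generation."""

    birth_year: int
    n0: float  #: intercept at age 0, log count per m2
    z: float  #: slope per year on the log scale
    r_squared: float
    n_points: int
    log_base: float = math.e

    def predict(self, age: float) -> float:
        """Fitted log abundance at ``age``: N0 + z * age, exactly."""
        return self.n0 + self.z * age


def fit_survivorship(
    series: pd.Series | list[tuple[float, float]],
    birth_year: int | None = None,
    log_base: float = math.e,
    min_points: int = 4,
) -> SurvivorshipFit:
    """Fit ``log N(a) = N0 + z * a`` by ordinary least squares.

    Parameters
    ----------
    series
        Either a Series indexed by age with abundances as values (NaNs are
        ignored), or a list of ``(age, abundance)`` pairs.  All abundances must
        be strictly positive — zeros are a missing-data question and belong to
        the imputation policy, not the regression.
    """
    if isinstance(series, pd.Series):
        s = series.dropna()
        ages = s.index.to_numpy(dtype=float)
        abundances = s.to_numpy(dtype=float)
    else:
        arr = np.asarray(list(series), dtype=float)
        ages, abundances = arr[:, 0], arr[:, 1]
    if len(ages) < min_points:
        raise ValueError(
            f"survivorship fit needs >= {min_points} points, got {len(ages)}"
            + (f" (generation {birth_year})" if birth_year is not None else "")
        )
    if np.any(abundances <= 0):
        raise ValueError(
            "non-positive abundance reached fit_survivorship; zeros must be handled "
            "by the missing-data policy (treated as missing or pseudo-counted) first"
        )
    y = np.log(abundances) / math.log(log_base)
    if np.ptp(ages) == 0:
        raise ValueError("all observations at a single age; slope undefined")
    res = stats.linregress(ages, y)
    return SurvivorshipFit(
        birth_year=int(birth_year) if birth_year is not None else -1,
        n0=float(res.intercept),
        z=float(res.slope),
        r_squared=float(res.rvalue**2),
        n_points=len(ages),
        log_base=log_base,
    )


def fit_all_generations(
    gm: pd.DataFrame, log_base: float = math.e, min_points: int = 4
) -> dict[int, SurvivorshipFit]:
    """Fit every generation of a filtered generation matrix."""
    fits = {}
    for birth in gm.index:
        row = gm.loc[birth].dropna()
        ages = pd.Series(
            row.to_numpy(), index=[int(y) - int(birth) for y in row.index]
        )
        fits[int(birth)] = fit_survivorship(
            ages, birth_year=int(birth), log_base=log_base, min_points=min_points
        )
    return fits


@dataclass
class DemographicMatrix:
    """Generations x (N0, z, N2..N10) on the log scale, fully imputed.

    ``provenance`` mirrors the N2..N10 block of ``data`` with per-cell flags
    "observed", "imputed" or "fitted".
    """

    data: pd.DataFrame
    provenance: pd.DataFrame
    log_base: float = math.e
    mode: str = "observed_plus_imputed"

    age_columns: tuple = field(init=False)

    def __post_init__(self) -> None:
        self.age_columns = tuple(c for c in self.data.columns if c.startswith("N") and c != "N0")

    @property
    def n_imputed(self) -> int:
        return int((self.provenance == "imputed").to_numpy().sum())


def impute_missing(
    gm: pd.DataFrame,
    fits: dict[int, SurvivorshipFit],
    min_age: int = 2,
    max_age: int = 10,
    mode: str = "observed_plus_imputed",
) -> DemographicMatrix:
    """Assemble the demographic matrix, filling gaps from the fitted lines.

    In the default ``"observed_plus_imputed"`` mode, observed cells carry the
    log of the measured abundance and only the sampling gaps receive the fitted
    value ``N0 + z * a``; in ``"fitted"`` mode every age column is the fitted
    value (provenance flagged accordingly).
    """
    if mode not in ("observed_plus_imputed", "fitted"):
        raise ValueError(f"unknown mode {mode!r}")
    missing_fits = [b for b in gm.index if int(b) not in fits]
    if missing_fits:
        raise ValueError(f"no survivorship fit for generations: {missing_fits}")
    ages = list(range(min_age, max_age + 1))
    cols = ["N0", "z"] + [f"N{a}" for a in ages]
    log_base = next(iter(fits.values())).log_base

    data = {}
    prov = {}
    for birth in gm.index:
        fit = fits[int(birth)]
        row = {"N0": fit.n0, "z": fit.z}
        prow = {}
        obs = gm.loc[birth]
        for a in ages:
            year = int(birth) + a
            value = obs.get(year, np.nan) if year in obs.index else np.nan
            if mode == "fitted" or pd.isna(value):
                row[f"N{a}"] = fit.predict(a)
                prow[f"N{a}"] = "fitted" if mode == "fitted" else "imputed"
            else:
                row[f"N{a}"] = math.log(value) / math.log(log_base)
                prow[f"N{a}"] = "observed"
        data[int(birth)] = row
        prov[int(birth)] = prow

    data_df = pd.DataFrame.from_dict(data, orient="index")[cols]
    prov_df = pd.DataFrame.from_dict(prov, orient="index")[[f"N{a}" for a in ages]]
    data_df.index.name = prov_df.index.name = "birth_year"
    return DemographicMatrix(data=data_df, provenance=prov_df, log_base=log_base, mode=mode)


def density_dependence_diagnostics(dm: DemographicMatrix) -> pd.DataFrame:
    """Pearson correlations of N0 with z and with each age column.

    A strong negative r(N0, z) across generations together with positive
    r(N0, N2..N4) is the signature of density-dependent mortality: abundant
    cohorts start high but die faster.  Zero-variance columns yield an
    undefined (NaN) correlation with a warning.
    """
    df = dm.data
    if len(df) < 4:
        raise ValueError(f"need >= 4 generations for diagnostics, got {len(df)}")
    n0 = df["N0"].to_numpy()
    rows = []
    for col in ["z"] + [c for c in dm.age_columns]:
        y = df[col].to_numpy()
        if np.ptp(y) == 0 or np.ptp(n0) == 0:
            warnings.warn(f"zero variance in {col!r}; correlation undefined", stacklevel=2)
            rows.append({"column": col, "r": np.nan, "p": np.nan})
            continue
        r, p = stats.pearsonr(n0, y)
        rows.append({"column": col, "r": float(r), "p": float(p)})
    return pd.DataFrame(rows).set_index("column")


def last_detection_years(gm: pd.DataFrame) -> pd.Series:
    """Last sampling year with a recorded (non-missing) cell per generation."""
    out = {}
    for birth in gm.index:
        row = gm.loc[birth].dropna()
        if len(row) == 0:
            continue
        out[int(birth)] = int(max(int(y) for y in row.index))
    return pd.Series(out, name="last_year").rename_axis("birth_year")
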