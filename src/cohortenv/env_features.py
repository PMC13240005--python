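"""Seasonal environmental features per generation.

Monthly station series (air temperature, sea-surface temperature, wind speed,
wave height) are reduced to seasonal means using the hydrological season
convention for the Barents Sea coast: winter spans November-April and is
attributed to the year containing January-April (so November and December
belong to the *following* year's winter), spring is May-June, summer is
July-August and autumn is September-October.

Each generation (birth-year cohort) is described by 24 features:

* 16 birth-year features — the four variables averaged over each of the four
  seasons of the year of birth;
* 8 lifespan features — air and water temperature averaged over each season
  across the years from birth to last detection (mean of yearly seasonal
  means, giving each year equal weight).
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SEASONS",
    "SEASON_ORDER",
    "BIRTH_VARIABLES",
    "LIFESPAN_VARIABLES",
    "CoverageError",
    "season_mean",
    "birth_year_features",
    "lifespan_features",
    "build_env_matrix",
    "feature_columns",
]

#: season -> tuple of (year offset, month); winter of year y reaches back into
#: November and December of year y - 1.
SEASONS: dict[str, tuple[tuple[int, int], ...]] = {
    "winter": ((-1, 11), (-1, 12), (0, 1), (0, 2), (0, 3), (0, 4)),
    "spring": ((0, 5), (0, 6)),
    "summer": ((0, 7), (0, 8)),
    "autumn": ((0, 9), (0, 10)),
}

SEASON_ORDER: tuple[str, ...] = ("winter", "spring", "summer", "autumn")

#: variables entering the 16 birth-year features, in output order
BIRTH_VARIABLES: tuple[str, ...] = ("air_temp", "water_temp", "wave", "wind")

#: variables entering the 8 lifespan features, in output order
LIFESPAN_VARIABLES: tuple[str, ...] = ("air_temp", "water_temp")


class CoverageError(ValueError):
    """A month required by a seasonal average is absent from the series."""


def _monthly_lookup(series: pd.DataFrame, variable: str) -> dict[tuple[int, int], float]:
    if variable not in series.columns:
        raise KeyError(f"variable {variable!r} not in series columns {list(series.columns)}")
    return {
        (int(y), int(m)): float(v)
        for y, m, v in zip(series["year"], series["month"], series[variable])
    }


def season_mean(
    series: pd.DataFrame,
    variable: str,
    season: str,
    year: int,
    _lookup: dict[tuple[int, int], float] | None = None,
) -> float:
    """Arithmetic mean of ``variable`` over the months of ``season`` of ``year``.

    Winter of year *y* draws November and December from year *y* - 1.  A missing
    month raises :class:`CoverageError` naming the (year, month) gap rather than
    silently averaging a shortened season.
    """
    if season not in SEASONS:
        raise KeyError(f"unknown season {season!r}; expected one of {SEASON_ORDER}")
    lookup = _lookup if _lookup is not None else _monthly_lookup(series, variable)
    values = []
    for offset, month in SEASONS[season]:
        key = (year + offset, month)
        if key not in lookup:
            raise CoverageError(
                f"series lacks {variable} for year={key[0]} month={key[1]} "
                f"(needed for {season} of {year})"
            )
        values.append(lookup[key])
    return float(np.mean(values))


def feature_columns() -> list[str]:
    """Names of the 24 feature columns in canonical order.

    Variable-major, season-minor; the 16 birth-year columns precede the 8
    lifespan columns.  Names encode variable, season and averaging window,
    e.g. ``water_temp_spring_birth`` and ``water_temp_summer_life``.
    """
    cols = [f"{v}_{s}_birth" for v in BIRTH_VARIABLES for s in SEASON_ORDER]
    cols += [f"{v}_{s}_life" for v in LIFESPAN_VARIABLES for s in SEASON_ORDER]
    return cols


def birth_year_features(series: pd.DataFrame, birth_year: int) -> pd.Series:
    """The 16 birth-year features: 4 variables x 4 seasons of the year of birth."""
    out = {}
    for variable in BIRTH_VARIABLES:
        lookup = _monthly_lookup(series, variable)
        for season in SEASON_ORDER:
            out[f"{variable}_{season}_birth"] = season_mean(
                series, variable, season, birth_year, _lookup=lookup
            )
    return pd.Series(out)


def lifespan_features(series: pd.DataFrame, birth_year: int, last_year: int) -> pd.Series:
    """The 8 lifespan features: air/water temperature per season averaged over
    the years from birth to last detection (inclusive), as the mean of yearly
    seasonal means."""
    if last_year < birth_year:
        raise ValueError(f"last_year {last_year} precedes birth_year {birth_year}")
    out = {}
    years = range(birth_year, last_year + 1)
    for variable in LIFESPAN_VARIABLES:
        lookup = _monthly_lookup(series, variable)
        for season in SEASON_ORDER:
            yearly = [
                season_mean(series, variable, season, y, _lookup=lookup) for y in years
            ]
            out[f"{variable}_{season}_life"] = float(np.mean(yearly))
    return pd.Series(out)


def build_env_matrix(
    series: pd.DataFrame,
    generations: Sequence[tuple[int, int]] | Iterable[tuple[int, int]],
) -> pd.DataFrame:
    """Assemble the generations x 24 environmental feature matrix.

    Parameters
    ----------
    series
        Monthly series with columns ``year, month, air_temp, water_temp, wind,
        wave``; must cover November of the year before each birth year through
        the last detection year of each generation.
    generations
        Iterable of ``(birth_year, last_detection_year)`` pairs.

    Returns
    -------
    DataFrame indexed by birth year with exactly 24 columns in canonical order.
    """
    generations = list(generations)
    if not generations:
        raise ValueError("no generations supplied")
    rows = {}
    uncovered = []
    for birth, last in generations:
        try:
            row = pd.concat(
                [birth_year_features(series, birth), lifespan_features(series, birth, last)]
            )
        except CoverageError as exc:
            uncovered.append(f"generation {birth}: {exc}")
            continue
        rows[birth] = row
    if uncovered:
        raise CoverageError("; ".join(uncovered))
    matrix = pd.DataFrame.from_dict(rows, orient="index")
    matrix = matrix[feature_columns()]
    matrix.index.name = "birth_year"
    return matrix
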