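"""CSV readers/writers with the package's fixed column conventions."""

from __future__ import annotations

import hashlib
from pathlib import Path

import pandas as pd

ENV_COLUMNS = ["year", "month", "air_temp", "water_temp", "wind", "wave"]
AGE_SAMPLE_COLUMNS = ["sample_year", "age", "abundance"]
BIOMASS_COLUMNS = ["site", "longitude", "area", "year", "survey", "biomass"]
ANNUAL_TEMP_COLUMNS = ["year", "temp"]


def _read(path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return df


def read_env_series(path) -> pd.DataFrame:
    return _read(path, ENV_COLUMNS)


def read_age_samples(path) -> pd.DataFrame:
    return _read(path, AGE_SAMPLE_COLUMNS)


def read_biomass_records(path) -> pd.DataFrame:
    return _read(path, BIOMASS_COLUMNS)


def read_annual_temperature(path) -> pd.DataFrame:
    return _read(path, ANNUAL_TEMP_COLUMNS)


def write_table(df: pd.DataFrame, path, index: bool = False) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=index)
    return path


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
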