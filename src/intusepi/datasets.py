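"""Accessors for the small reference tables shipped with the package.

These are the published desk-scale inputs: the stratum table of national
and in-database bed counts with half-year case counts for 2007 and 2008,
the per-age-group admission counts, the overall case-count margins, and
the pathological-lead-point vocabulary.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import pandas as pd


def _data_path(name: str) -> Path:
    ref = importlib.resources.files("intusepi.data").joinpath(name)
    with importlib.resources.as_file(ref) as path:
        return Path(path)


def table1_path(year: int) -> Path:
    if year not in (2007, 2008):
        raise ValueError(f"shipped stratum tables cover 2007 and 2008, not {year}")
    return _data_path(f"table1_{year}.csv")


def load_table1(year: int) -> pd.DataFrame:
    """Stratum inputs (national beds, database beds, half-year cases)."""
    return pd.read_csv(table1_path(year))


def load_age_table() -> pd.DataFrame:
    """Per-age-group all-cause admissions, cases and secondary cases."""
    return pd.read_csv(_data_path("age_table.csv"))


def load_case_counts() -> dict[str, int]:
    """Overall case-count margins (total cases, male, enema successes...)."""
    df = pd.read_csv(_data_path("case_counts.csv"))
    return dict(zip(df["key"], df["value"].astype(int)))


def load_lead_points() -> pd.DataFrame:
    """Published lead-point tabulation (group, cause, patients, age range)."""
    return pd.read_csv(_data_path("lead_points.csv"))
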