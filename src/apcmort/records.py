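"""Tabular death-record ledger used by the correction and rate stages.

A record set is a long table with one row per (region, year, age_group,
icd_revision, cause_code) stratum carrying a real-valued death count —
real-valued because proportional redistribution of ill-defined deaths
produces fractional counts, which are carried at full precision and only
rounded for display.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .grid import make_age_labels

COLUMNS = ["region", "year", "age_group", "icd_revision", "cause_code", "deaths"]


@dataclass
class DeathRecordSet:
    """Validated wrapper around the long-format death-count table."""

    df: pd.DataFrame
    year_range: tuple[int, int] = (1980, 2019)
    age_labels: list[str] = field(default_factory=make_age_labels)

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"record table missing columns: {missing}")
        self.df = self.df[list(self.df.columns)].copy()
        self.df["deaths"] = self.df["deaths"].astype(float)
        self.df["year"] = self.df["year"].astype(int)
        self.df["icd_revision"] = self.df["icd_revision"].astype(int)
        self.validate()

    def validate(self) -> None:
        if (self.df["deaths"] < 0).any():
            bad = self.df[self.df["deaths"] < 0].head()
            raise ValueError(f"negative death counts:\n{bad}")
        lo, hi = self.year_range
        out = self.df[(self.df["year"] < lo) | (self.df["year"] > hi)]
        if len(out):
            raise ValueError(
                f"years outside study window {lo}-{hi}: {sorted(out['year'].unique())}")
        bad_ages = set(self.df["age_group"]) - set(self.age_labels)
        if bad_ages:
            raise ValueError(f"unknown age groups: {sorted(bad_ages)}")

    @property
    def total_deaths(self) -> float:
        return float(self.df["deaths"].sum())

    def copy(self) -> "DeathRecordSet":
        return DeathRecordSet(self.df.copy(), self.year_range, list(self.age_labels))

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, **kw) -> "DeathRecordSet":
        return cls(pd.read_csv(path), **kw)


@dataclass
class PopulationTable:
    """Person-years at risk per (region, year, age_group)."""

    df: pd.DataFrame
    age_labels: list[str] = field(default_factory=make_age_labels)

    def __post_init__(self) -> None:
        missing = [c for c in ("region", "year", "age_group", "person_years")
                   if c not in self.df.columns]
        if missing:
            raise ValueError(f"population table missing columns: {missing}")
        if (self.df["person_years"] < 0).any():
            raise ValueError("negative person-years")
        dup = self.df.duplicated(["region", "year", "age_group"])
        if dup.any():
            raise ValueError("duplicate (region, year, age_group) rows")

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, **kw) -> "PopulationTable":
        return cls(pd.read_csv(path), **kw)
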