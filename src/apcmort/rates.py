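"""Descriptive mortality rates: age-specific and standardized rates,
triennial smoothing, and aggregation of corrected records onto the
5-year x 5-year Lexis grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .causes import CauseMap
from .correction import classify_records
from .grid import (LexisTable, make_age_labels, make_period_labels, period_of)
from .records import DeathRecordSet, PopulationTable

RATE_SCALE = 100_000.0


@dataclass
class StandardPopulation:
    """Age weights for direct standardization, normalized to sum 1."""

    weights: pd.Series  # index: age_group labels

    def __post_init__(self) -> None:
        w = pd.Series(self.weights, dtype=float)
        if (w < 0).any():
            raise ValueError("negative standard-population weights")
        total = w.sum()
        if total <= 0:
            raise ValueError("standard-population weights sum to zero")
        self.weights = w / total

    @classmethod
    def who_world(cls, min_age: int = 10) -> "StandardPopulation":
        """The WHO world standard restricted to the study ages (10+ by
        default) and renormalized; the two oldest classes are pooled into
        the open-ended 80+ group used by the grid."""
        with resources.files("apcmort.data").joinpath(
                "who_standard_population.csv").open() as fh:
            df = pd.read_csv(fh, comment="#")
        df["start"] = df["age_group"].str.extract(r"^(\d+)").astype(int)
        df = df[df["start"] >= min_age]
        labels = make_age_labels()
        top = int(labels[-1].split(" ")[0])
        df["label"] = np.where(df["start"] >= top, labels[-1], df["age_group"])
        w = df.groupby("label")["percent"].sum()
        w = w.reindex([l for l in labels if l in w.index])
        return cls(w)


def age_specific_rate(deaths: float, person_years: float,
                      scale: float = RATE_SCALE) -> float:
    """Rate per ``scale`` person-years.  Zero person-years with zero deaths
    yields 0 with a warning; with positive deaths it is an error."""
    if person_years < 0:
        raise ValueError("negative person-years")
    if person_years == 0:
        if deaths > 0:
            raise ValueError("deaths observed with zero person-years")
        warnings.warn("zero person-years and zero deaths: rate reported as 0",
                      stacklevel=2)
        return 0.0
    return scale * deaths / person_years


def direct_standardize(age_rates: pd.Series | dict,
                       standard: StandardPopulation) -> float:
    """Directly standardized rate: sum of weight x age-specific rate.

    Weights are renormalized internally, so pre- and un-normalized
    standards give the same answer.  Every age group carrying standard
    weight must be present in ``age_rates``.
    """
    rates = pd.Series(age_rates, dtype=float)
    missing = [a for a in standard.weights.index if a not in rates.index]
    if missing:
        raise ValueError(f"age groups missing from rates: {missing}")
    return float((standard.weights * rates[standard.weights.index]).sum())


def moving_average(series, window: int = 3, trim: bool = False) -> np.ndarray:
    """Centered moving average (triennial by default).

    Endpoints use the available symmetric partial window (a 2-term mean for
    window 3) so the smoothed series keeps the input length, which is the
    convention used for plotted rate series; ``trim=True`` drops the
    partial-window endpoints instead.
    """
    x = np.asarray(series, dtype=float)
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    if x.size < window:
        raise ValueError(f"series length {x.size} shorter than window {window}")
    half = window // 2
    out = np.empty_like(x)
    for t in range(x.size):
        lo, hi = max(0, t - half), min(x.size, t + half + 1)
        out[t] = x[lo:hi].mean()
    return out[half:-half] if trim else out


def build_lexis(records: DeathRecordSet, pop: PopulationTable, mechanism: str,
                cause_map: CauseMap | None = None, region: str | None = None,
                age_labels: list[str] | None = None,
                period_labels: list[str] | None = None) -> LexisTable:
    """Aggregate suicide-intent deaths of one mechanism onto the Lexis grid.

    Records should already be corrected.  Years or ages outside the grid
    raise, listing the offenders; person-years are summed over the five
    calendar years of each period.
    """
    if mechanism not in ("HSS", "AUT", "FA"):
        raise ValueError(f"unknown mechanism: {mechanism!r}")
    age_labels = age_labels or make_age_labels()
    period_labels = period_labels or make_period_labels()
    df = classify_records(records, cause_map)
    if region is not None:
        df = df[df["region"] == region]
        popdf = pop.df[pop.df["region"] == region]
    else:
        popdf = pop.df
    df = df[(df["mechanism"] == mechanism) & (df["intent"] == "suicide")]

    ai = {a: i for i, a in enumerate(age_labels)}
    pj = {p: j for j, p in enumerate(period_labels)}
    deaths = np.zeros((len(age_labels), len(period_labels)))
    for _, r in df.groupby(["age_group", "period"], as_index=False)["deaths"].sum().iterrows():
        deaths[ai[r["age_group"]], pj[r["period"]]] += r["deaths"]

    bad_years = [y for y in popdf["year"].unique()
                 if not _in_window(y, period_labels)]
    if bad_years:
        raise ValueError(f"population years outside the grid: {sorted(bad_years)}")
    bad_ages = sorted(set(popdf["age_group"]) - set(age_labels))
    if bad_ages:
        raise ValueError(f"population age groups outside the grid: {bad_ages}")

    py = np.zeros_like(deaths)
    for _, r in popdf.iterrows():
        py[ai[r["age_group"]], pj[period_of(int(r["year"]))]] += r["person_years"]

    return LexisTable(deaths, py, age_labels, period_labels,
                      region=region or "all", mechanism=mechanism)


def _in_window(year: int, period_labels: list[str]) -> bool:
    start = int(period_labels[0].split(" ")[0])
    end = int(period_labels[-1].split(" to ")[-1])
    return start <= year <= end


def period_rate_table(lexis: LexisTable, standard: StandardPopulation,
                      scale: float = RATE_SCALE) -> pd.DataFrame:
    """Quinquennial crude and standardized rates, one row per period plus a
    whole-window SAR row (the layout of published period-rate tables)."""
    rows = []
    for j, p in enumerate(lexis.period_labels):
        age_rates = pd.Series(
            scale * lexis.deaths[:, j] / lexis.person_years[:, j],
            index=lexis.age_labels)
        rows.append({
            "period": p,
            "crude": scale * lexis.deaths[:, j].sum() / lexis.person_years[:, j].sum(),
            "standardized": direct_standardize(age_rates, standard),
        })
    all_rates = pd.Series(
        scale * lexis.deaths.sum(axis=1) / lexis.person_years.sum(axis=1),
        index=lexis.age_labels)
    rows.append({
        "period": "SAR",
        "crude": scale * lexis.deaths.sum() / lexis.person_years.sum(),
        "standardized": direct_standardize(all_rates, standard),
    })
    return pd.DataFrame(rows)


def annual_rate_series(records: DeathRecordSet, pop: PopulationTable,
                       mechanism: str, cause_map: CauseMap | None = None,
                       region: str | None = None, smooth: bool = True,
                       scale: float = RATE_SCALE) -> pd.Series:
    """Crude annual rate series for one mechanism, optionally smoothed with
    the triennial moving average used for plotted trends."""
    df = classify_records(records, cause_map)
    if region is not None:
        df = df[df["region"] == region]
        popdf = pop.df[pop.df["region"] == region]
    else:
        popdf = pop.df
    df = df[(df["mechanism"] == mechanism) & (df["intent"] == "suicide")]
    d = df.groupby("year")["deaths"].sum()
    n = popdf.groupby("year")["person_years"].sum()
    years = sorted(n.index)
    rate = pd.Series(
        [scale * d.get(y, 0.0) / n[y] for y in years], index=years, name=mechanism)
    if smooth:
        rate[:] = moving_average(rate.to_numpy())
    return rate
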