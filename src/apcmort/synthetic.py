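"""Synthetic vital-registration data with a known age-period-cohort surface.

The generator emulates the structure of national mortality-information
microdata aggregated to (region, year, age group, cause code) counts:
suicide deaths of one mechanism are drawn cell-wise from a Poisson law
whose log rate is an age curve plus an annual drift plus zero-slope period
and cohort curvatures, on a single-year calendar grid that later bins to
the 5-year Lexis cells.  A degradation step then re-codes a fraction of
suicides to same-mechanism undetermined/accident/assault codes and thins
the remainder binomially to mimic incomplete registration coverage —
the exact inverse of the correction pipeline, so parameter recovery can
be scored against truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .causes import CauseMap
from .grid import (N_AGE, N_PERIOD, PERIOD_START, cohort_index, decade_of,
                   make_age_labels)
from .records import DeathRecordSet, PopulationTable

SLOPE_TOL = 1e-10


def zero_slope(values, weights=None) -> np.ndarray:
    """Project a vector onto the orthogonal complement of {constant, linear},
    so it carries curvature only (weighted least-squares slope exactly 0)."""
    v = np.asarray(values, dtype=float)
    n = v.size
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    g = np.column_stack([np.ones(n), np.arange(n, dtype=float)])
    coef, *_ = np.linalg.lstsq(g * np.sqrt(w)[:, None], v * np.sqrt(w), rcond=None)
    return v - g @ coef


def _ls_slope(values: np.ndarray) -> float:
    t = np.arange(values.size, dtype=float)
    t = t - t.mean()
    return float(t @ values / (t @ t))


def default_age_curve(n_age: int = N_AGE, base_rate: float = 1.5e-5,
                      log_span: float = 1.0) -> np.ndarray:
    """Gently increasing log baseline rates around ``base_rate`` per
    person-year (1.5 per 100,000 by default, the order of magnitude of
    method-specific female suicide rates)."""
    return np.log(base_rate) + np.linspace(-log_span / 2, log_span / 2, n_age)


def default_period_curvature(n_period: int = N_PERIOD) -> np.ndarray:
    # mild mid-window bump, detrended so it cannot masquerade as drift
    raw = 0.05 * np.sin(np.linspace(0, np.pi, n_period))
    return zero_slope(raw)


def default_cohort_curvature(n_cohort: int = N_AGE + N_PERIOD - 1) -> np.ndarray:
    raw = 0.10 * np.cos(np.linspace(0, 2 * np.pi, n_cohort))
    return zero_slope(raw)


def default_coverage(region: str = "R1") -> dict[tuple[str, str], float]:
    """Registration coverage improving by decade, the pattern reported for
    female death registration in under-covered regions."""
    return {(region, "1980s"): 0.85, (region, "1990s"): 0.90,
            (region, "2000s"): 0.95, (region, "2010s"): 0.98}


@dataclass
class SyntheticScenario:
    """True generating surface plus degradation parameters.

    ``age_curve`` holds log baseline rates per age group (absorbing the
    grand mean), ``annual_drift`` the log rate ratio per calendar year, and
    the two curvature vectors are zero-slope by construction so the drift
    is identified against them.  ``population_base`` is person-years per
    (single calendar year, age group) cell; a 5 x 5 Lexis cell therefore
    holds five times that exposure.
    """

    age_curve: np.ndarray = field(default_factory=default_age_curve)
    annual_drift: float = float(np.log(1.02))
    period_curvature: np.ndarray = field(default_factory=default_period_curvature)
    cohort_curvature: np.ndarray = field(default_factory=default_cohort_curvature)
    population_base: float = 5e5
    misclass_fractions: dict = field(default_factory=lambda: {
        "undetermined": 0.10, "accident": 0.05, "assault": 0.02})
    coverage: dict = field(default_factory=default_coverage)
    seed: int = 0
    n_age: int = N_AGE
    n_period: int = N_PERIOD
    region: str = "R1"
    mechanism: str = "HSS"
    period_start: int = PERIOD_START
    icd10_from_year: int = 1996  # revision switch year in the emitted ledger

    def __post_init__(self) -> None:
        self.age_curve = np.asarray(self.age_curve, dtype=float)
        self.period_curvature = np.asarray(self.period_curvature, dtype=float)
        self.cohort_curvature = np.asarray(self.cohort_curvature, dtype=float)
        self.validate()

    @property
    def n_cohort(self) -> int:
        return self.n_age + self.n_period - 1

    def validate(self) -> None:
        if self.age_curve.size != self.n_age:
            raise ValueError("age_curve length != number of age groups")
        if self.period_curvature.size != self.n_period:
            raise ValueError("period_curvature length != number of periods")
        if self.cohort_curvature.size != self.n_cohort:
            raise ValueError(
                "cohort_curvature length != I + J - 1 "
                f"({self.cohort_curvature.size} vs {self.n_cohort})")
        for name, v in (("period_curvature", self.period_curvature),
                        ("cohort_curvature", self.cohort_curvature)):
            if abs(_ls_slope(v)) > SLOPE_TOL:
                raise ValueError(
                    f"{name} has least-squares slope {_ls_slope(v):.2e}; "
                    "must be 0 so drift is identified (use zero_slope())")
        fr = self.misclass_fractions
        bad = {k: f for k, f in fr.items() if not (0.0 <= f < 1.0)}
        if bad:
            raise ValueError(f"misclassification fractions outside [0, 1): {bad}")
        if sum(fr.values()) >= 1.0:
            raise ValueError("misclassification fractions must sum to < 1")
        for key, c in self.coverage.items():
            if not (0.0 < c <= 1.0):
                raise ValueError(f"coverage for {key} is {c}; must be in (0, 1]")
        if not np.isscalar(self.population_base) or self.population_base < 0:
            raise ValueError("population_base must be a non-negative scalar")

    # -- true surface ------------------------------------------------------
    def true_log_rate(self, i: int, j: int) -> float:
        """Log rate of 1-based Lexis cell (i, j); constant within the cell."""
        k = cohort_index(i, j, self.n_age)
        mid_year = self.period_start + 5 * (j - 1) + 2
        anchor = self.period_start + 5 * self.n_period // 2  # window midpoint
        return float(self.age_curve[i - 1]
                     + self.annual_drift * (mid_year - anchor)
                     + self.period_curvature[j - 1]
                     + self.cohort_curvature[k - 1])

    def true_lexis_rates(self) -> np.ndarray:
        return np.exp([[self.true_log_rate(i, j)
                        for j in range(1, self.n_period + 1)]
                       for i in range(1, self.n_age + 1)])

    # -- (de)serialization -------------------------------------------------
    def to_yaml(self, path) -> None:
        d = asdict(self)
        for key in ("age_curve", "period_curvature", "cohort_curvature"):
            d[key] = [float(x) for x in d[key]]
        d["coverage"] = {f"{r}|{dec}": float(c)
                         for (r, dec), c in self.coverage.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticScenario":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "coverage" in d:
            d["coverage"] = {tuple(k.split("|")): v
                             for k, v in d["coverage"].items()}
        return cls(**d)

    def rng_streams(self) -> tuple[np.random.Generator, np.random.Generator]:
        """Two deterministic child streams: one for simulation, one for
        degradation, so the stages stay reproducible when run separately."""
        children = np.random.SeedSequence(self.seed).spawn(2)
        return (np.random.default_rng(children[0]),
                np.random.default_rng(children[1]))


def simulate_scenario(scenario: SyntheticScenario,
                      cause_map: CauseMap | None = None
                      ) -> tuple[DeathRecordSet, PopulationTable]:
    """Draw true suicide counts on the single-year grid.

    Each Lexis cell's deaths follow Poisson(N exp(mu + a_i + b_j + g_k));
    the cell's log rate applies uniformly to its five calendar years.
    Counts are emitted against the mechanism's suicide code of the ICD
    revision in force that year.  Deterministic given the scenario seed.
    """
    scenario.validate()
    cm = cause_map or CauseMap.load_packaged()
    rng, _ = scenario.rng_streams()
    ages = make_age_labels(scenario.n_age)
    n_years = 5 * scenario.n_period

    rows, pop_rows = [], []
    for y in range(scenario.period_start, scenario.period_start + n_years):
        j = (y - scenario.period_start) // 5 + 1
        rev = 10 if y >= scenario.icd10_from_year else 9
        for i in range(1, scenario.n_age + 1):
            n_py = float(scenario.population_base)
            if n_py < 0:
                raise ValueError("negative person-years")
            lam = n_py * np.exp(scenario.true_log_rate(i, j))
            if not np.isfinite(lam):
                raise ValueError(
                    f"non-finite Poisson rate in cell (age {ages[i-1]!r}, "
                    f"year {y}): exp overflow in the true log rate")
            deaths = int(rng.poisson(lam))
            if deaths:
                rows.append({
                    "region": scenario.region, "year": y,
                    "age_group": ages[i - 1], "icd_revision": rev,
                    "cause_code": cm.code_for(scenario.mechanism, "suicide", rev),
                    "deaths": float(deaths),
                })
            pop_rows.append({
                "region": scenario.region, "year": y,
                "age_group": ages[i - 1], "person_years": n_py,
            })

    rec_df = pd.DataFrame(rows, columns=["region", "year", "age_group",
                                         "icd_revision", "cause_code", "deaths"])
    year_range = (scenario.period_start, scenario.period_start + n_years - 1)
    return (DeathRecordSet(rec_df, year_range, ages),
            PopulationTable(pd.DataFrame(pop_rows), ages))


def degrade_records(records: DeathRecordSet, scenario: SyntheticScenario,
                    cause_map: CauseMap | None = None) -> DeathRecordSet:
    """Re-code and thin a suicide-only ledger.

    Each suicide death is independently re-coded to the same-mechanism
    undetermined / accident / assault code with the scenario's fractions
    (multinomial split per cell), then retained with probability equal to
    the registration coverage of its (region, decade).  Deterministic given
    the scenario seed; uses a stream independent of the simulation draw.
    """
    scenario.validate()
    cm = cause_map or CauseMap.load_packaged()
    _, rng = scenario.rng_streams()
    fr = scenario.misclass_fractions
    intents = ["suicide", "undetermined", "accident", "assault"]
    probs = np.array([1.0 - sum(fr.values()),
                      fr.get("undetermined", 0.0),
                      fr.get("accident", 0.0),
                      fr.get("assault", 0.0)])

    out = []
    for _, row in records.df.sort_values(
            ["region", "year", "age_group", "cause_code"]).iterrows():
        rev = int(row["icd_revision"])
        mech, intent = cm.map_cause(row["cause_code"], rev)
        if intent != "suicide":
            raise ValueError(
                f"degrade_records expects suicide-coded input; got "
                f"{row['cause_code']} ({mech}/{intent})")
        split = rng.multinomial(int(round(row["deaths"])), probs)
        cov = scenario.coverage.get((row["region"], decade_of(int(row["year"]))), 1.0)
        for intent_out, n_int in zip(intents, split):
            if n_int == 0:
                continue
            kept = int(rng.binomial(n_int, cov)) if cov < 1.0 else int(n_int)
            if kept:
                out.append({
                    "region": row["region"], "year": int(row["year"]),
                    "age_group": row["age_group"], "icd_revision": rev,
                    "cause_code": cm.code_for(mech, intent_out, rev),
                    "deaths": float(kept),
                })
    df = pd.DataFrame(out, columns=["region", "year", "age_group",
                                    "icd_revision", "cause_code", "deaths"])
    return DeathRecordSet(df, records.year_range, list(records.age_labels))


def coverage_factors_frame(scenario: SyntheticScenario) -> pd.DataFrame:
    """Scenario coverage as the (region, decade, coverage) CSV layout the
    correction stage consumes."""
    return pd.DataFrame([
        {"region": r, "decade": d, "coverage": c}
        for (r, d), c in sorted(scenario.coverage.items())])
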