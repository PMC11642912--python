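"""Lexis grid vocabulary: 5-year age groups, quinquennial periods, synthetic cohorts.

The study design is a 15 x 8 Lexis grid (ages 10-14 through 80+, periods
1980-1984 through 2015-2019) whose diagonals index K = I + J - 1 = 22
synthetic birth cohorts labelled 1900-1904 through 2005-2009.  Cohort
labels follow the convention k = j - i + I with i ascending in age and j
ascending in period, so the oldest cohort sits in the top-left corner
(oldest age, earliest period).  Because cells are 5x5 years, each synthetic
cohort actually spans ten birth years; the 5-year label names its midpoint
quinquennium.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: study window defaults
AGE_START = 10
AGE_TOP = 80
PERIOD_START = 1980
PERIOD_END = 2019
N_AGE = 15
N_PERIOD = 8


def make_age_labels(n: int = N_AGE, start: int = AGE_START, width: int = 5) -> list[str]:
    """Age-group labels ``"10 to 14" ... "80 years or older"`` (open-ended top)."""
    labels = [
        f"{start + width * i} to {start + width * i + width - 1}" for i in range(n - 1)
    ]
    labels.append(f"{start + width * (n - 1)} years or older")
    return labels


def make_period_labels(n: int = N_PERIOD, start: int = PERIOD_START, width: int = 5) -> list[str]:
    """Period labels ``"1980 to 1984" ... "2015 to 2019"``."""
    return [f"{start + width * j} to {start + width * j + width - 1}" for j in range(n)]


def make_cohort_labels(n_age: int = N_AGE, n_period: int = N_PERIOD,
                       period_start: int = PERIOD_START, age_start: int = AGE_START,
                       age_top: int = AGE_TOP, width: int = 5) -> list[str]:
    """Cohort labels along Lexis diagonals, oldest first.

    The oldest cohort is (earliest period start) - (top age), e.g.
    1980 - 80 = 1900, giving "1900 to 1904"; there are I + J - 1 of them.
    """
    k = n_age + n_period - 1
    first = period_start - age_top
    return [f"{first + width * i} to {first + width * i + width - 1}" for i in range(k)]


def cohort_index(i: int, j: int, n_age: int = N_AGE) -> int:
    """Diagonal cohort index k = j - i + I for 1-based i (age) and j (period)."""
    return j - i + n_age


def age_group_of(age: int, n: int = N_AGE, start: int = AGE_START, width: int = 5) -> str:
    """Map a single age in years to its 5-year group label.

    Ages below ``start`` raise ValueError (the study population begins at 10).
    """
    if age < start:
        raise ValueError(f"age {age} below study window start {start}")
    i = min((age - start) // width, n - 1)
    return make_age_labels(n, start, width)[i]


def period_of(year: int, n: int = N_PERIOD, start: int = PERIOD_START, width: int = 5) -> str:
    """Map a calendar year to its quinquennium label; out-of-window years raise."""
    if not (start <= year < start + n * width):
        raise ValueError(f"year {year} outside study window {start}-{start + n * width - 1}")
    return make_period_labels(n, start, width)[(year - start) // width]


def decade_of(year: int) -> str:
    """Decade label used by coverage factors, e.g. 1987 -> '1980s'."""
    return f"{(year // 10) * 10}s"


@dataclass
class LexisTable:
    """Death counts and person-years on an age x period grid with cohort diagonals.

    ``deaths`` and ``person_years`` are I x J arrays aligned with
    ``age_labels`` (ascending age) and ``period_labels`` (ascending time).
    Cohort labels run along diagonals: cell (i, j) belongs to cohort
    k = j - i + I (1-based).
    """

    deaths: np.ndarray
    person_years: np.ndarray
    age_labels: list[str] = field(default_factory=make_age_labels)
    period_labels: list[str] = field(default_factory=make_period_labels)
    cohort_labels: list[str] | None = None
    region: str = "all"
    mechanism: str = ""

    def __post_init__(self) -> None:
        self.deaths = np.asarray(self.deaths, dtype=float)
        self.person_years = np.asarray(self.person_years, dtype=float)
        i, j = self.deaths.shape
        if self.person_years.shape != (i, j):
            raise ValueError("deaths and person_years shapes differ")
        if len(self.age_labels) != i or len(self.period_labels) != j:
            raise ValueError("label lengths do not match grid dimensions")
        if self.cohort_labels is None:
            if (self.age_labels == make_age_labels(i)
                    and len(self.period_labels) == j):
                start = int(self.period_labels[0].split(" ")[0])
                self.cohort_labels = make_cohort_labels(
                    i, j, period_start=start,
                    age_top=AGE_START + 5 * (i - 1))
            else:
                self.cohort_labels = [f"c{k}" for k in range(1, i + j)]
        if len(self.cohort_labels) != i + j - 1:
            raise ValueError(
                f"expected {i + j - 1} cohort labels, got {len(self.cohort_labels)}")
        if np.any(self.deaths < 0):
            raise ValueError("negative death counts")
        if np.any(self.person_years < 0):
            raise ValueError("negative person-years")
        if np.any((self.deaths > 0) & (self.person_years <= 0)):
            raise ValueError("deaths observed in cells with no person-years")

    @property
    def n_age(self) -> int:
        return self.deaths.shape[0]

    @property
    def n_period(self) -> int:
        return self.deaths.shape[1]

    @property
    def n_cohort(self) -> int:
        return self.n_age + self.n_period - 1

    def cohort_of_cell(self, i: int, j: int) -> str:
        """Cohort label of 0-based cell (i, j)."""
        return self.cohort_labels[cohort_index(i + 1, j + 1, self.n_age) - 1]

    def to_frame(self) -> pd.DataFrame:
        """Long-format view: one row per cell with cohort label attached."""
        rows = []
        for i, a in enumerate(self.age_labels):
            for j, p in enumerate(self.period_labels):
                rows.append({
                    "age_group": a,
                    "period": p,
                    "cohort": self.cohort_of_cell(i, j),
                    "deaths": self.deaths[i, j],
                    "person_years": self.person_years[i, j],
                })
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, age_labels: list[str] | None = None,
                   period_labels: list[str] | None = None, **kw) -> "LexisTable":
        """Rebuild the grid from the long format written by :meth:`to_frame`."""
        age_labels = age_labels or make_age_labels()
        period_labels = period_labels or sorted(df["period"].unique())
        d = np.zeros((len(age_labels), len(period_labels)))
        n = np.zeros_like(d)
        ai = {a: i for i, a in enumerate(age_labels)}
        pj = {p: j for j, p in enumerate(period_labels)}
        for _, r in df.iterrows():
            d[ai[r["age_group"]], pj[r["period"]]] = r["deaths"]
            n[ai[r["age_group"]], pj[r["period"]]] = r["person_years"]
        return cls(d, n, age_labels, period_labels, **kw)
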