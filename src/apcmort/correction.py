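"""Two-stage correction of death records: redistribution of ill-defined
intent, then inflation for incomplete registration coverage.

Stage 1 (``redistribute_garbage``) reallocates deaths whose intent is
undetermined (and sequelae of self-inflicted injury) to the determined
intents — suicide, accident, assault — proportionally to the determined-
intent distribution observed within a stratum, by default
(region, period, age_group, mechanism).  Strata with garbage deaths but no
determined deaths are progressively coarsened (drop age, then period)
until a determined distribution exists; every reallocation is logged.

Stage 2 (``apply_coverage``) divides counts by the registration-coverage
fraction of the record's region and decade, inflating for deaths the vital
system never captured.  Coverage factors are inputs (estimated elsewhere
by death-distribution methods such as SEG-adj), one value per region and
decade.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .causes import CauseMap
from .grid import decade_of, period_of
from .records import DeathRecordSet

DETERMINED = ("suicide", "accident", "assault")
DEFAULT_GARBAGE = ("undetermined", "sequelae")
DEFAULT_STRATA = ("region", "period", "age_group", "mechanism")


@dataclass
class CoverageFactors:
    """Map (region, decade) -> registration coverage in (0, 1]."""

    factors: dict[tuple[str, str], float]

    def __post_init__(self) -> None:
        for (region, decade), c in self.factors.items():
            if not (0.0 < c <= 1.0):
                raise ValueError(
                    f"coverage for ({region}, {decade}) is {c}; must be in (0, 1]")

    def get(self, region: str, decade: str) -> float:
        try:
            return self.factors[(region, decade)]
        except KeyError:
            raise KeyError(
                f"no coverage factor for region={region!r}, decade={decade!r}"
            ) from None

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CoverageFactors":
        return cls({(str(r.region), str(r.decade)): float(r.coverage)
                    for r in df.itertuples()})

    @classmethod
    def from_csv(cls, path) -> "CoverageFactors":
        return cls.from_frame(pd.read_csv(path, comment="#"))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"region": r, "decade": d, "coverage": c}
             for (r, d), c in sorted(self.factors.items())])


@dataclass
class CorrectionAudit:
    """Per-stratum before/after trail of every correction applied."""

    entries: list[dict] = field(default_factory=list)

    def log(self, stage: str, stratum, before: float, after: float, note: str = "") -> None:
        self.entries.append({
            "stage": stage, "stratum": str(stratum),
            "before": before, "after": after, "note": note,
        })

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def classify_records(records: DeathRecordSet, cause_map: CauseMap | None = None) -> pd.DataFrame:
    """Attach mechanism/intent/period columns; out-of-scope codes are kept
    and flagged so they pass through corrections untouched."""
    cm = cause_map or CauseMap.load_packaged()
    df = records.df.copy()
    cache: dict[tuple[str, int], tuple[str, str]] = {}

    def lookup(code: str, rev: int) -> tuple[str, str]:
        key = (code, rev)
        if key not in cache:
            cache[key] = cm.map_cause(code, rev)
        return cache[key]

    mapped = [lookup(c, r) for c, r in zip(df["cause_code"], df["icd_revision"])]
    df["mechanism"] = [m for m, _ in mapped]
    df["intent"] = [i for _, i in mapped]
    df["period"] = [period_of(y) for y in df["year"]]
    return df


def _det_shares(group: pd.DataFrame, external_fraction: float = 0.0) -> pd.Series | None:
    """Determined-intent distribution of a stratum.  When a fraction of
    accident/assault deaths is itself treated as misclassified, only the
    retained (1 - fraction) share counts toward the target distribution."""
    det = group[group["intent"].isin(DETERMINED)].groupby("intent")["deaths"].sum()
    det = det.reindex(DETERMINED, fill_value=0.0)
    det[["accident", "assault"]] *= (1.0 - external_fraction)
    total = det.sum()
    if total <= 0:
        return None
    return det[det > 0] / total


def redistribute_garbage(
    records: DeathRecordSet,
    cause_map: CauseMap | None = None,
    strata_keys: tuple[str, ...] = DEFAULT_STRATA,
    garbage_intents: tuple[str, ...] = DEFAULT_GARBAGE,
    external_fraction: float = 0.0,
    assign_orphans_to_suicide: bool = False,
    audit: CorrectionAudit | None = None,
) -> DeathRecordSet:
    """Proportionally reallocate garbage-coded deaths to determined intents.

    Within each stratum, deaths with intent in ``garbage_intents`` are
    split across suicide/accident/assault in proportion to the stratum's
    determined counts; suicide counts can only grow.  ``external_fraction``
    additionally treats that fraction of accident and assault deaths as
    garbage (default 0: only undetermined and sequelae move).  Sequelae of
    self-inflicted injury carry no mechanism and are allocated to suicide,
    split across mechanisms pro rata to the stratum's suicide counts.

    Strata with garbage but no determined deaths fall back to coarser
    strata (drop age_group, then period); if no determined distribution
    exists anywhere in the region the garbage is left in place unless
    ``assign_orphans_to_suicide`` is set.  Every fallback is logged, never
    silent.  Total deaths are conserved exactly.
    """
    if not (0.0 <= external_fraction <= 1.0):
        raise ValueError(f"external_fraction must be in [0, 1]: {external_fraction}")
    cm = cause_map or CauseMap.load_packaged()
    audit = audit if audit is not None else CorrectionAudit()
    df = classify_records(records, cm)

    is_garbage = df["intent"].isin([g for g in garbage_intents if g != "sequelae"])
    is_seq = df["intent"].eq("sequelae") if "sequelae" in garbage_intents else \
        pd.Series(False, index=df.index)

    # coarsening ladder for the fallback rule
    ladders = [list(strata_keys)]
    if "age_group" in strata_keys:
        ladders.append([k for k in strata_keys if k != "age_group"])
    if "period" in strata_keys:
        ladders.append([k for k in ladders[-1] if k != "period"])

    out_rows: list[dict] = []
    kept = df.copy()

    def emit(base_row: pd.Series, mechanism: str, intent: str, deaths: float) -> None:
        rev = int(base_row["icd_revision"])
        try:
            code = cm.code_for(mechanism, intent, rev)
        except KeyError:
            code = base_row["cause_code"]
        out_rows.append({
            "region": base_row["region"], "year": int(base_row["year"]),
            "age_group": base_row["age_group"], "icd_revision": rev,
            "cause_code": code, "deaths": deaths,
            "mechanism": mechanism, "intent": intent,
        })

    def shares_for(row: pd.Series, mech_specific: bool) -> tuple[pd.Series | None, str]:
        """Determined-intent shares (or suicide-by-mechanism shares for
        sequelae), walking down the coarsening ladder."""
        for keys in ladders:
            mask = pd.Series(True, index=df.index)
            for k in keys:
                if k == "mechanism" and not mech_specific:
                    continue
                mask &= df[k] == row[k]
            group = df[mask]
            if mech_specific:
                s = _det_shares(group, external_fraction)
                if s is not None:
                    return s, ",".join(keys)
            else:
                sui = group[group["intent"] == "suicide"]
                bym = sui.groupby("mechanism")["deaths"].sum()
                if bym.sum() > 0:
                    return bym / bym.sum(), ",".join(keys)
        return None, "none"

    # ordinary garbage: undetermined (and optional external_fraction slices)
    moving = df[is_garbage].copy()
    moving["_move"] = moving["deaths"]
    if external_fraction > 0:
        ext = df[df["intent"].isin(("accident", "assault"))].copy()
        ext["_move"] = ext["deaths"] * external_fraction
        kept.loc[ext.index, "deaths"] -= ext["_move"].values
        moving = pd.concat([moving, ext])
    kept.loc[df.index[is_garbage], "deaths"] = 0.0

    for idx, row in moving.iterrows():
        g = row["_move"]
        if g <= 0:
            continue
        shares, level = shares_for(row, mech_specific=True)
        if shares is None:
            if assign_orphans_to_suicide and row["mechanism"] in ("HSS", "AUT", "FA"):
                emit(row, row["mechanism"], "suicide", g)
                audit.log("redistribute", tuple(row[list(strata_keys)]), g, g,
                          "no determined deaths anywhere; assigned to suicide")
            else:
                kept.loc[idx, "deaths"] += g  # leave in place, logged
                audit.log("redistribute", tuple(row[list(strata_keys)]), g, g,
                          "no determined deaths anywhere; left unredistributed")
            continue
        for intent, s in shares.items():
            emit(row, row["mechanism"], intent, g * s)
        if level != ",".join(ladders[0]):
            audit.log("redistribute", tuple(row[list(strata_keys)]), g, g,
                      f"fallback to coarser stratum ({level})")

    # sequelae of self-inflicted injury: mechanism-unspecific, by definition
    # late deaths of suicidal acts -> allocated to suicide across mechanisms
    seq = df[is_seq]
    kept.loc[seq.index, "deaths"] = 0.0
    for idx, row in seq.iterrows():
        g = row["deaths"]
        if g <= 0:
            continue
        shares, level = shares_for(row, mech_specific=False)
        if shares is None:
            kept.loc[idx, "deaths"] = g
            audit.log("redistribute", tuple(row[[k for k in strata_keys
                                                 if k != "mechanism"]]), g, g,
                      "no suicide deaths anywhere; sequelae left unredistributed")
            continue
        for mech, s in shares.items():
            emit(row, mech, "suicide", g * s)

    frames = [kept[kept["deaths"] > 0]]
    if out_rows:
        frames.append(pd.DataFrame(out_rows))
    merged = pd.concat(frames, ignore_index=True)
    agg = (merged.groupby(
        ["region", "year", "age_group", "icd_revision", "cause_code"],
        as_index=False)["deaths"].sum())

    before, after = records.total_deaths, float(agg["deaths"].sum())
    audit.log("redistribute", "TOTAL", before, after,
              "conservation check" if abs(before - after) < 1e-6 else "MISMATCH")
    result = DeathRecordSet(agg, records.year_range, list(records.age_labels))
    result.audit = audit  # type: ignore[attr-defined]
    return result


def apply_coverage(records: DeathRecordSet, factors: CoverageFactors,
                   audit: CorrectionAudit | None = None) -> DeathRecordSet:
    """Inflate counts for under-registration: deaths / coverage(region, decade).

    Coverage is resolved at decade resolution; a missing (region, decade)
    factor is an error naming the stratum, as is any factor outside (0, 1].
    """
    audit = audit if audit is not None else CorrectionAudit()
    df = records.df.copy()
    decades = df["year"].map(decade_of)
    cov = pd.Series(
        [factors.get(r, d) for r, d in zip(df["region"], decades)], index=df.index)
    before = float(df["deaths"].sum())
    df["deaths"] = df["deaths"] / cov
    audit.log("coverage", "TOTAL", before, float(df["deaths"].sum()))
    result = DeathRecordSet(df, records.year_range, list(records.age_labels))
    result.audit = audit  # type: ignore[attr-defined]
    return result


def correct_records(records: DeathRecordSet, factors: CoverageFactors,
                    cause_map: CauseMap | None = None,
                    **redistribute_kw) -> DeathRecordSet:
    """Full correction: redistribution first, then coverage inflation."""
    audit = redistribute_kw.pop("audit", None) or CorrectionAudit()
    step1 = redistribute_garbage(records, cause_map, audit=audit, **redistribute_kw)
    return apply_coverage(step1, factors, audit=audit)
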