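"""End-to-end orchestration: correct -> rates -> APC fit per (region,
mechanism), plus the report arithmetic (drift trend table, proportional-
mortality comparisons).
"""

from __future__ import annotations

import json
import pathlib
from dataclasses import dataclass, asdict

import pandas as pd

from .causes import CauseMap, MECHANISMS
from .correction import (CorrectionAudit, CoverageFactors, classify_records,
                         correct_records)
from .rates import StandardPopulation, build_lexis, period_rate_table
from .apc import REF_COHORT, REF_PERIOD, estimable_decomposition
from .records import DeathRecordSet, PopulationTable


def proportional_mortality_change(share_early: float, share_late: float) -> float:
    """Percent change between two proportional-mortality shares (both in
    percent): 100 * (late - early) / early, sign preserved."""
    if not (0.0 < share_early <= 100.0):
        raise ValueError(f"share_early must be in (0, 100]: {share_early}")
    if not (0.0 < share_late <= 100.0):
        raise ValueError(f"share_late must be in (0, 100]: {share_late}")
    return 100.0 * (share_late - share_early) / share_early


def mechanism_shares(records: DeathRecordSet, years: tuple[int, int],
                     cause_map: CauseMap | None = None) -> pd.Series:
    """Each mechanism's percent share of all method-specific suicides in a
    year window (proportional mortality)."""
    df = classify_records(records, cause_map)
    df = df[(df["intent"] == "suicide") & df["year"].between(*years)]
    by = df.groupby("mechanism")["deaths"].sum()
    total = by.sum()
    if total <= 0:
        raise ValueError(f"no suicides in window {years}")
    return 100.0 * by / total


@dataclass
class RunConfig:
    """Paths and options driving one full pipeline run."""

    records_path: str
    population_path: str
    coverage_path: str
    outdir: str
    cause_map_path: str | None = None
    mechanisms: tuple[str, ...] = MECHANISMS
    regions: tuple[str, ...] | None = None
    ref_period: str = REF_PERIOD
    ref_cohort: str = REF_COHORT
    drift_to: str = "cohort"
    detrend_weights: str = "uniform"
    external_fraction: float = 0.0
    assign_orphans_to_suicide: bool = False
    min_standard_age: int = 10
    seed: int = 0

    def validate(self) -> None:
        for p in (self.records_path, self.population_path, self.coverage_path):
            if not pathlib.Path(p).exists():
                raise FileNotFoundError(p)
        unknown = set(self.mechanisms) - set(MECHANISMS)
        if unknown:
            raise ValueError(f"unknown mechanisms: {sorted(unknown)}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute correction, rate tables and APC fits; write the CSV bundle,
    audit log and manifest under ``config.outdir``.

    Each (region, mechanism) pair is fitted independently.  Any stage error
    aborts with a stage-tagged message; outputs written before the failure
    are flagged stale in the manifest.
    """
    config.validate()
    out = pathlib.Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": {}, "stale": False,
                      "cause_map_version": 1, "standard_population_version": 1}

    def stage(name: str):
        manifest["stages"][name] = "started"
        return name

    try:
        name = stage("load")
        records = DeathRecordSet.from_csv(config.records_path)
        pop = PopulationTable.from_csv(config.population_path)
        factors = CoverageFactors.from_csv(config.coverage_path)
        cm = (CauseMap.from_frame(pd.read_csv(config.cause_map_path, comment="#"))
              if config.cause_map_path else CauseMap.load_packaged())
        std = StandardPopulation.who_world(config.min_standard_age)
        manifest["stages"][name] = "ok"

        name = stage("correct")
        audit = CorrectionAudit()
        corrected = correct_records(
            records, factors, cm, audit=audit,
            external_fraction=config.external_fraction,
            assign_orphans_to_suicide=config.assign_orphans_to_suicide)
        corrected.to_csv(out / "corrected_records.csv")
        audit.to_csv(out / "correction_audit.csv")
        manifest["stages"][name] = "ok"

        regions = config.regions or tuple(sorted(corrected.df["region"].unique()))
        results = {}
        for region in regions:
            for mech in config.mechanisms:
                name = stage(f"rates:{region}:{mech}")
                lexis = build_lexis(corrected, pop, mech, cm, region=region)
                if lexis.deaths.sum() == 0:
                    manifest["stages"][name] = "skipped: no deaths"
                    continue
                prefix = out / f"{region}_{mech}"
                prefix.mkdir(exist_ok=True)
                lexis.to_frame().to_csv(prefix / "lexis.csv", index=False)
                period_rate_table(lexis, std).to_csv(
                    prefix / "period_rates.csv", index=False)
                manifest["stages"][name] = "ok"

                name = stage(f"fit:{region}:{mech}")
                apc = estimable_decomposition(
                    lexis, config.ref_period, config.ref_cohort,
                    config.drift_to, config.detrend_weights)
                apc.save(prefix)
                results[(region, mech)] = apc
                manifest["stages"][name] = "ok"

        name = stage("report")
        trend_rows = [{
            "region": r, "mechanism": m,
            "annual_rr": apc.drift["annual_rr"],
            "lo": apc.drift["lo"], "hi": apc.drift["hi"],
            "trend": apc.drift["trend"],
        } for (r, m), apc in results.items()]
        pd.DataFrame(trend_rows).to_csv(out / "drift_trends.csv", index=False)
        manifest["stages"][name] = "ok"
    except Exception as exc:
        manifest["stale"] = True
        manifest["error"] = f"stage {name}: {exc}"
        (out / "manifest.json").write_text(_stable_json(manifest))
        raise RuntimeError(f"pipeline failed at stage {name}: {exc}") from exc

    (out / "manifest.json").write_text(_stable_json(manifest))
    return results


def _stable_json(obj) -> str:
    return json.dumps(obj, indent=2, sort_keys=True, default=str)
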