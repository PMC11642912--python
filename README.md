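# apcmort

Age–period–cohort (APC) analysis of method-specific suicide mortality from
vital-registration count data. The package is aimed at epidemiologists who
work with cause-of-death ledgers of uneven quality — e.g. national mortality
information systems where intent is often coded as "undetermined" and
registration coverage is below one — and who want defensible period and
cohort trend estimates per suicide mechanism (hanging/strangulation/
suffocation, autointoxication, firearm) and region.

## What it does

1. **Cause mapping** — ICD-9/ICD-10 external-cause codes are classified
   into mechanism × intent cells (suicide, accident, assault,
   undetermined-intent, sequelae of self-inflicted injury) from a packaged,
   versioned code-range table.
2. **Record correction** — deaths with undetermined intent (and sequelae)
   are redistributed to the determined intents proportionally to the
   determined-intent distribution of their stratum
   (region × period × age × mechanism, with a logged coarsening fallback
   for empty strata); counts are then divided by the registration-coverage
   fraction of the record's region and decade. Coverage factors are inputs
   (produced elsewhere by death-distribution methods such as SEG-adj).
3. **Rates** — age-specific rates per 100 000, direct standardization with
   the WHO world standard population (restricted to ages 10+), triennial
   moving averages, and aggregation onto the 15 × 8 Lexis grid
   (ages 10–14 … 80+, periods 1980–1984 … 2015–2019) whose diagonals index
   K = I + J − 1 = 22 synthetic birth cohorts (1900–1904 … 2005–2009).
4. **APC modelling** — Poisson regression of cell counts with log
   person-years offset,

   log E[r_ij] = μ + α_i + β_j + γ_k,   k = j − i + I.

   Because cohort = period − age, the individual slopes of α, β, γ are not
   identified; the package reports the estimable functions: the **drift**
   (total linear trend, β_L + γ_L, as an annual rate ratio with Wald 95%
   CI, classified Upward / Downward / Stationary), **curvature-only period
   and cohort relative risks** anchored at reference categories
   (period 2000–2004, cohort 1950–1954; RR ≡ 1 there), and the
   **longitudinal age curve** (α_L + β_L, fitted rates per 100 000). Six
   nested models (age, age-drift ×2, age-cohort, age-period, full APC) are
   compared by deviance, AIC and likelihood-ratio tests.
5. **Synthetic data** — a generator draws Poisson death counts under a
   known APC surface, re-codes a fraction of suicides to same-mechanism
   garbage codes, and thins records binomially to mimic under-coverage, so
   every stage is testable and parameter recovery can be scored against
   truth.

## Worked example

```python
import numpy as np
from apcmort import (SyntheticScenario, simulate_scenario, degrade_records,
                     correct_records, CoverageFactors, build_lexis,
                     nested_deviance_table, estimable_decomposition)
from apcmort.synthetic import coverage_factors_frame

sc = SyntheticScenario(seed=3)              # true annual drift RR = 1.02
records, pop = simulate_scenario(sc)        # clean suicide ledger
degraded = degrade_records(records, sc)     # miscoding + under-coverage
factors = CoverageFactors.from_frame(coverage_factors_frame(sc))
corrected = correct_records(degraded, factors, external_fraction=1.0)

lexis = build_lexis(corrected, pop, "HSS")
apc = estimable_decomposition(lexis)
d = apc.drift
print(f"deaths: true {records.total_deaths:.0f}, observed "
      f"{degraded.total_deaths:.0f}, corrected {corrected.total_deaths:.1f}")
print(f"drift: {d['annual_rr']:.4f} ({d['lo']:.4f}-{d['hi']:.4f}) {d['trend']}")
```

prints

```
deaths: true 4701, observed 4370, corrected 4704.0
drift: 1.0175 (1.0147-1.0203) Upward
```

The degradation hid ~7% of deaths behind garbage codes and under-coverage;
the correction stage restores the total to within 0.1%, and the fitted
annual drift's confidence interval covers the generating value 1.02 —
i.e. rates in this scenario rise about 2% per year after netting out age
structure and cohort curvature. `apc.period_rr`, `apc.cohort_rr` and
`apc.age_curve` hold the relative-risk curves; `apc.deviance_table` the
six-model comparison.

The same pipeline is scriptable from the shell:

```bash
apcmort simulate --seed 3 --outdir sim/
apcmort all --records sim/records.csv --population sim/population.csv \
    --coverage sim/coverage.csv --mechanisms HSS --external-fraction 1.0 \
    --outdir out/
```

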