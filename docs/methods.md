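# Methods

## The model

Death counts D_ij in age group i (I = 15 five-year groups, 10–14 … 80+) and
period j (J = 8 quinquennia, 1980–1984 … 2015–2019) are modelled as
Poisson with mean N_ij · exp(μ + α_i + β_j + γ_k), where N_ij is
person-years at risk and k = j − i + I indexes the K = I + J − 1 = 22
diagonal birth cohorts (1900–1904 … 2005–2009). Effects are one free
parameter per 5-year category (factor coding); the grid is categorical and
per-category relative risks are the quantity of interest, so no smoothing
basis is used (a spline variant would fit the same framework but is not
implemented).

Because k = j − i + I exactly, adding c·j to the period effects,
subtracting c·k from the cohort effects and adjusting the age effects by
c·i leaves every fitted value unchanged: the three linear slopes are not
separately identified. The package never reports them. It reports the
estimable functions only:

- **drift** δ = β_L + γ_L, the total linear trend of log rates per
  calendar year, shown as the annual rate ratio exp(δ);
- **curvatures**: period and cohort effects projected onto the orthogonal
  complement of {constant, linear-in-index}, hence with zero (weighted)
  mean and slope by construction;
- **fitted rates** and the **longitudinal age curve** α_L + β_L (fitted
  rates per 100 000 along the reference cohort).

Rather than fitting the rank-deficient factor design and post-processing,
the full model is parameterized directly in estimable terms: an age factor
(I columns), one linear drift column in calendar years anchored at the
reference period, and period/cohort curvature bases (J−2 and K−2 columns)
built by QR as the weighted orthogonal complement of the constant and
linear index vectors. This design is full rank, IRLS (statsmodels Poisson
GLM with log person-years offset) is stable on it, the drift coefficient
is itself the annual log rate ratio, and every reported quantity —
relative risks re-anchored so the reference category is exactly 1, the
age curve, the drift — is a linear contrast of the coefficients with a
delta-method Wald 95% interval. Reference categories get the degenerate
interval [1, 1]. Reassembling age + period + cohort components reproduces
the full model's fitted rates to floating-point accuracy regardless of the
identification choices, which is verified in the test suite.

**Drift allocation.** The drift can be displayed inside the cohort RRs
(default, `drift_to="cohort"`: period RRs show curvature only and the age
curve is longitudinal) or inside the period RRs (`drift_to="period"`: age
curve cross-sectional at the reference period). Fitted rates and deviances
are identical either way; outputs are flagged with the convention used.
Both are exposed because published APC figures rarely state the allocation
their software used.

**Detrending weights.** The curvature projection needs an inner product on
category indices. Default is uniform weighting; person-years weighting is
available. The drift/curvature split depends on this choice, fitted rates
do not.

**Nested models.** Six models are fitted in the conventional ladder: age;
age-drift (drift in cohort time); age-cohort; age-period-cohort;
age-period; age-drift (drift in period time). The two age-drift rows span
the same column space (the age factor absorbs the difference between the
two time anchors) and must agree in deviance — a built-in consistency
check. Likelihood-ratio p-values compare each row with its neighbour above
(direction reversing after the full model); AIC comes from the Poisson
log-likelihood. The table reports both criteria without an automatic
verdict, since deviance tests and AIC can disagree.

**Drift estimator.** The headline drift is the full-model coefficient; the
age-drift submodel's estimate is reported alongside for comparison. The
two differ when curvature is present; the full-model estimate conditions
on it.

**Trend classification.** Annual RR with 95% CI entirely above 1 is
Upward, entirely below 1 Downward, otherwise Stationary.

**Dispersion.** Plain Poisson likelihood, no overdispersion adjustment;
the residual deviance / df ratio is carried in the fit bundle as a
diagnostic. Zero-count cells are retained (valid under the Poisson
likelihood); cells with zero person-years are excluded; a factor level
with no deaths at all is reported as separation rather than silently
driven to −∞.

## Record correction

Correction precedes all rate and model computation and has two stages, in
this order.

1. **Intent redistribution.** Deaths coded to undetermined intent are
   reallocated to the determined intents (suicide, accident, assault)
   proportionally to the determined-intent distribution within their
   stratum, by default region × 5-year period × age group × mechanism.
   Sequelae of self-inflicted injury carry no mechanism code; being by
   definition late deaths of intentional self-harm they are allocated to
   suicide, split across mechanisms pro rata to the stratum's suicide
   counts. A stratum with garbage but no determined deaths is coarsened
   (drop age, then period) until a determined distribution exists; if none
   exists anywhere the garbage is left in place (or, only if explicitly
   enabled, assigned to suicide). Every fallback is logged to an audit
   trail; totals are conserved exactly and suicide counts never decrease.
   An optional `external_fraction` g additionally treats a fraction of
   accident/assault deaths as misclassified; the determined target
   distribution then counts accident/assault at their retained (1−g)
   weight, so that supplying the generating fractions makes the stage the
   exact expectation-inverse of the synthetic degradation. The default
   g = 0 redistributes only undetermined-intent and sequelae deaths.
   Fractional counts are carried as reals throughout; rounding is a
   display concern only.
2. **Coverage inflation.** Counts are divided by the registration-coverage
   fraction of their region and decade. Factors are inputs in (0, 1], one
   per (region, decade); a missing factor aborts the run naming the
   stratum. Estimating coverage itself (death-distribution methods) is out
   of scope.

## Rates

Age-specific rates are scale · D/N (default per 100 000). Direct
standardization uses the WHO world standard population, packaged as the
published percentage table, restricted to ages 10+ (the study population)
and renormalized, with the 80–84 and 85+ classes pooled into the open
80+ group; the alternative of keeping all ages with zero rates below 10 is
available via `min_age=0`. Triennial moving averages are centered; the two
endpoints use the available 2-term partial window so smoothed series keep
their length for plotting (an option trims them instead). Quinquennial
period rates are aggregate Σ D / Σ N over the five years of the period.

Synthetic 5-year cohorts built from 5 × 5-year cells genuinely span ten
birth years; labels follow the convention of naming the central 5-year
quinquennium, so the oldest cell (age 80+, period 1980–1984) belongs to
cohort "1900 to 1904" and the youngest (10–14, 2015–2019) to
"2005 to 2009".

## Synthetic data generator

The generator emulates a national mortality-information system's
aggregated ledger: one region, counts per single calendar year × age
group × ICD code, with the ICD-9→ICD-10 revision switch in 1996. Default
study conditions: a gently increasing age curve around 1.5 per 100 000
(log span 1 across the 15 age groups), annual drift RR 1.02, small
zero-slope period (amplitude ≈ 0.05 on the log scale) and cohort
(≈ 0.10) curvatures, 5 × 10⁵ person-years per age-year cell (≈ 4 700
deaths per 40-year run, the order of a regional method-specific series),
misclassification fractions 0.10 to undetermined, 0.05 to accident and
0.02 to assault of the same mechanism, and coverage improving by decade
(0.85, 0.90, 0.95, 0.98). The within-cell log rate is uniform (no
gradient inside a 5-year cell), matching the modelled resolution; the
drift is anchored at the window midpoint so baseline rates stay near the
age curve.

Degradation draws a multinomial intent split per cell and then binomial
retention at the cell's (region, decade) coverage, on a random stream
deterministically separated from the simulation stream, so
simulate/degrade are individually reproducible given the scenario seed.

What the generator does **not** emulate: multiple regions in one table
(multi-region studies are lists of scenarios, fitted independently),
background accident/assault mortality (every garbage death is a true
suicide, which is why the round-trip correction uses external fraction 1),
record-level covariates, census-interpolation error in denominators, and
secular changes in coding practice. Passing tests therefore show the
machinery is correct and the estimators recover known truth under
Poisson/binomial sampling — not that any particular real-world correction
assumption holds.

## Numerical choices

- IRLS: maxiter 200, tolerance 1e-10; non-convergence raises with the
  iteration trace.
- Deviance uses the 0·log 0 = 0 convention.
- Wald CIs on the log scale (z = 1.96); reference categories exactly 1
  with CI [1, 1].
- Curvature bases via QR on the weighted design; detrending verified to
  1e-8 in tests.
- Problem sizes in the validation runs: the identifiability and nesting
  checks use the default scenario (120 cells, ≈ 4 700 deaths); deviance
  nesting is checked over 50 random scenarios at 2 × 10⁵ person-years per
  age-year cell; drift recovery over 100 replicates of the full pipeline;
  the correction round-trip at 1.2 × 10⁷ person-years per age-year cell
  (≈ 1.1 × 10⁵ deaths), chosen so Monte-Carlo error is well inside the
  2% acceptance band.

## Known limitations

- The proportional-redistribution scheme assumes garbage deaths share the
  intent distribution of determined deaths within a stratum; if
  misclassification is differential (e.g. suicides preferentially hidden),
  corrected counts are still biased.
- Coverage factors are taken as known constants; their sampling error is
  not propagated into rate or model CIs.
- No overdispersion adjustment: intervals are too narrow if the Poisson
  assumption fails (the dispersion diagnostic flags this).
- Synthetic cohorts overlap (10-year span under 5-year labels), a known
  feature of tabulated APC analyses, not corrected here.
- Wald intervals can be poor in cells with very few deaths (oldest
  cohorts); the reference-cohort choice mitigates but does not remove
  this.
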