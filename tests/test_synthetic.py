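"""Synthetic-data generator: Poisson sampling, degradation, determinism."""

import numpy as np
import pandas as pd
import pytest

from apcmort import (CoverageFactors, SyntheticScenario, correct_records,
                     degrade_records, simulate_scenario, zero_slope)
from apcmort.correction import classify_records
from apcmort.synthetic import coverage_factors_frame, _ls_slope


def flat_scenario(**kw):
    """No age/period/cohort structure: constant rate everywhere."""
    defaults = dict(
        age_curve=np.full(15, np.log(1e-5)),
        annual_drift=0.0,
        period_curvature=np.zeros(8),
        cohort_curvature=np.zeros(22),
        population_base=1e7 / 5,  # 1e7 person-years per 5-year Lexis cell
        misclass_fractions={"undetermined": 0.0, "accident": 0.0, "assault": 0.0},
        coverage={("R1", d): 1.0 for d in ("1980s", "1990s", "2000s", "2010s")},
        seed=7)
    defaults.update(kw)
    return SyntheticScenario(**defaults)


def test_zero_rate_gives_zero_deaths():
    sc = flat_scenario(age_curve=np.full(15, -np.inf))
    records, pop = simulate_scenario(sc)
    assert records.total_deaths == 0.0
    assert (pop.df["person_years"] > 0).all()


def test_pooled_rate_matches_poisson_expectation():
    # constant rate 1e-5 -> pooled empirical rate within 3 Poisson SE of
    # 1.0 per 100,000
    sc = flat_scenario()
    records, pop = simulate_scenario(sc)
    total_py = pop.df["person_years"].sum()
    expected = 1e-5 * total_py
    se = np.sqrt(expected)
    assert abs(records.total_deaths - expected) < 3 * se
    rate = 1e5 * records.total_deaths / total_py
    assert abs(rate - 1.0) < 3 * 1e5 * se / total_py


def test_overflowing_rate_rejected():
    sc = flat_scenario(age_curve=np.full(15, 800.0))
    with pytest.raises(ValueError, match="non-finite"):
        simulate_scenario(sc)


def test_curvature_slope_invariant_enforced():
    with pytest.raises(ValueError, match="slope"):
        flat_scenario(period_curvature=np.linspace(-0.1, 0.1, 8))
    v = zero_slope(np.linspace(-0.1, 0.1, 8) + np.random.default_rng(0).normal(0, 1, 8))
    assert abs(_ls_slope(v)) < 1e-10


def test_fraction_validation():
    with pytest.raises(ValueError, match="sum"):
        flat_scenario(misclass_fractions={"undetermined": 0.6, "accident": 0.5,
                                          "assault": 0.0})
    with pytest.raises(ValueError, match="\\[0, 1\\)"):
        flat_scenario(misclass_fractions={"undetermined": 1.0, "accident": 0.0,
                                          "assault": 0.0})


def test_determinism_byte_identical(scenario):
    r1, p1 = simulate_scenario(scenario)
    r2, p2 = simulate_scenario(scenario)
    pd.testing.assert_frame_equal(r1.df, r2.df)
    pd.testing.assert_frame_equal(p1.df, p2.df)
    d1 = degrade_records(r1, scenario)
    d2 = degrade_records(r2, scenario)
    pd.testing.assert_frame_equal(d1.df, d2.df)


def test_degrade_identity_when_clean():
    sc = flat_scenario()
    records, _ = simulate_scenario(sc)
    out = degrade_records(records, sc)
    merged = (records.df.groupby(["year", "age_group"])["deaths"].sum()
              .compare(out.df.groupby(["year", "age_group"])["deaths"].sum()))
    assert merged.empty


def test_binomial_thinning():
    sc = flat_scenario(coverage={("R1", d): 0.5 for d in
                                 ("1980s", "1990s", "2000s", "2010s")})
    records, _ = simulate_scenario(sc)
    n = records.total_deaths
    out = degrade_records(records, sc)
    sd = np.sqrt(n * 0.5 * 0.5)
    assert abs(out.total_deaths - 0.5 * n) < 3 * sd


def test_misclassification_shares():
    sc = flat_scenario(misclass_fractions={"undetermined": 0.2,
                                           "accident": 0.0, "assault": 0.0})
    records, _ = simulate_scenario(sc)
    out = degrade_records(records, sc)
    df = classify_records(out)
    by = df.groupby("intent")["deaths"].sum()
    n = records.total_deaths
    share = by.get("suicide", 0.0) / n
    sd = np.sqrt(0.8 * 0.2 / n)
    assert abs(share - 0.8) < 3 * sd
    assert by.get("undetermined", 0.0) + by.get("suicide", 0.0) == n


def test_degrade_rejects_non_suicide_input():
    sc = flat_scenario()
    records, _ = simulate_scenario(sc)
    bad = records.copy()
    # first rows predate the ICD-10 switch, so use the ICD-9 garbage code
    bad.df.loc[bad.df.index[0], "cause_code"] = "E983"
    with pytest.raises(ValueError, match="suicide-coded"):
        degrade_records(bad, sc)


def test_round_trip_recovers_totals(scenario, simulated, degraded, corrected):
    """simulate -> degrade -> correct with the true fractions/coverage
    recovers pooled totals to within Monte-Carlo error."""
    records, _ = simulated
    rel_bias = corrected.total_deaths / records.total_deaths - 1.0
    assert abs(rel_bias) < 0.02


def test_scenario_yaml_round_trip(tmp_path, scenario):
    path = tmp_path / "scenario.yaml"
    scenario.to_yaml(path)
    back = SyntheticScenario.from_yaml(path)
    np.testing.assert_allclose(back.age_curve, scenario.age_curve)
    assert back.coverage == scenario.coverage
    assert back.seed == scenario.seed
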