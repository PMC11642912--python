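"""Poisson APC fitting, estimable functions, identifiability invariants."""

import itertools

import numpy as np
import pytest
from scipy import optimize

from apcmort import (LexisTable, SeparationError, SyntheticScenario,
                     classify_trend, estimable_decomposition, fit_poisson_glm,
                     nested_deviance_table, poisson_deviance,
                     simulate_scenario, build_lexis)
from apcmort.apc import build_design, decomposition_fitted_rates, drift_from_fit
from apcmort.synthetic import zero_slope


def test_saturated_model_zero_deviance(toy_lexis):
    fit = fit_poisson_glm(toy_lexis, ("cell",),
                          ref_period="p2", ref_cohort="c3")
    assert fit.deviance == pytest.approx(0.0, abs=1e-8)
    np.testing.assert_allclose(fit.fitted_rates * 1e5, toy_lexis.deaths,
                               rtol=1e-8)


def test_common_rate_closed_form():
    # one age level on a 2-cell table acts as an intercept-only model:
    # MLE of the common rate is sum(D)/sum(N) with closed-form deviance
    lex = LexisTable(np.array([[2.0, 4.0]]), np.array([[100.0, 100.0]]),
                     age_labels=["a1"], period_labels=["p1", "p2"],
                     cohort_labels=["c1", "c2"])
    fit = fit_poisson_glm(lex, ("age",), ref_period="p1", ref_cohort="c1")
    assert fit.fitted_rates[0, 0] == pytest.approx(0.03)
    d = np.array([2.0, 4.0])
    mu = np.array([3.0, 3.0])
    assert fit.deviance == pytest.approx(
        2 * np.sum(d * np.log(d / mu)), rel=1e-10)
    assert fit.deviance == pytest.approx(poisson_deviance(d, mu), rel=1e-12)


def test_irls_matches_direct_likelihood_maximization(toy_lexis):
    """Independent oracle: minimize the Poisson deviance over the same
    full-model design with a generic optimizer."""
    fit = fit_poisson_glm(toy_lexis, ("age", "drift", "period", "cohort"),
                          ref_period="p2", ref_cohort="c3")
    X, _ = build_design(toy_lexis, ("age", "drift", "period", "cohort"),
                        ref_period="p2", ref_cohort="c3")
    d = toy_lexis.deaths.ravel()
    n = toy_lexis.person_years.ravel()

    def dev(beta):
        return poisson_deviance(d, n * np.exp(X @ beta))

    x0 = np.zeros(X.shape[1])
    x0[:3] = np.log(d.reshape(3, 3).mean(axis=1) / 1e5)
    res = optimize.minimize(dev, x0, method="Nelder-Mead",
                            options={"maxiter": 20000, "xatol": 1e-10,
                                     "fatol": 1e-12})
    assert abs(fit.deviance - res.fun) < 1e-6


def test_age_effect_recovery():
    sc = SyntheticScenario(annual_drift=0.0,
                           period_curvature=np.zeros(8),
                           cohort_curvature=np.zeros(22),
                           seed=11)
    records, pop = simulate_scenario(sc)
    lex = build_lexis(records, pop, sc.mechanism)
    fit = fit_poisson_glm(lex, ("age",))
    sl = fit.design.slices["age"]
    est = fit.params[sl]
    se = np.sqrt(np.diag(fit.cov)[sl])
    inside = np.abs(est - sc.age_curve) < 3 * se
    assert inside.mean() >= 13 / 15  # 3-SE band, allow rare excursions


def test_deviance_nesting(lexis):
    tab = nested_deviance_table(lexis)
    dev = dict(zip(tab["model"], tab["deviance"]))
    assert dev["age"] >= dev["age-drift (cohort)"] - 1e-8
    assert dev["age-drift (cohort)"] >= dev["age-cohort"] - 1e-8
    assert dev["age-cohort"] >= dev["age-period-cohort"] - 1e-8
    assert dev["age-drift (period)"] >= dev["age-period"] - 1e-8
    assert dev["age-period"] >= dev["age-period-cohort"] - 1e-8
    # the two age-drift parameterizations span the same model space
    assert dev["age-drift (cohort)"] == pytest.approx(
        dev["age-drift (period)"], rel=1e-10)
    assert {"deviance", "df", "aic", "lrt_p"} <= set(tab.columns)


def test_reference_categories_anchored(lexis):
    apc = estimable_decomposition(lexis, deviance_table=nested_deviance_table(lexis))
    prr = apc.period_rr.set_index("period")
    crr = apc.cohort_rr.set_index("cohort")
    for col in ("rr", "lo", "hi"):
        assert prr.loc["2000 to 2004", col] == 1.0
        assert crr.loc["1950 to 1954", col] == 1.0
    assert ((apc.period_rr["lo"] <= apc.period_rr["rr"])
            & (apc.period_rr["rr"] <= apc.period_rr["hi"])).all()
    assert ((apc.cohort_rr["lo"] <= apc.cohort_rr["rr"])
            & (apc.cohort_rr["rr"] <= apc.cohort_rr["hi"])).all()


@pytest.mark.parametrize("weights", ["uniform", "person_years"])
def test_detrended_log_rr_slope_zero(lexis, weights):
    apc = estimable_decomposition(lexis, drift_to="cohort",
                                  detrend_weights=weights,
                                  deviance_table=_dummy_table())
    # with drift allocated to cohort the period log-RRs are pure curvature
    log_rr = np.log(apc.period_rr["rr"].to_numpy())
    t = np.arange(log_rr.size, dtype=float)
    w = (np.ones_like(t) if weights == "uniform"
         else lexis.person_years.sum(axis=0))
    tw = t - np.average(t, weights=w)
    slope = np.sum(w * tw * log_rr) / np.sum(w * tw * tw)
    assert abs(slope) < 1e-8


def _dummy_table():
    import pandas as pd
    return pd.DataFrame()


def test_fitted_rates_invariant_to_identification_choices(lexis):
    variants = list(itertools.product(
        ["cohort", "period"], ["uniform", "person_years"],
        [("2000 to 2004", "1950 to 1954"), ("1990 to 1994", "1970 to 1974")]))
    rates = []
    for drift_to, weights, (rp, rc) in variants:
        apc = estimable_decomposition(
            lexis, ref_period=rp, ref_cohort=rc, drift_to=drift_to,
            detrend_weights=weights, deviance_table=_dummy_table())
        rates.append(apc.full_model.fitted_rates)
        recon = decomposition_fitted_rates(apc)
        np.testing.assert_allclose(recon, apc.full_model.fitted_rates,
                                   rtol=1e-8)
    base = rates[0]
    for r in rates[1:]:
        np.testing.assert_allclose(r, base, rtol=1e-8)


def test_drift_equals_sum_of_removed_linear_parts(lexis):
    """The drift coefficient must equal the total linear slope of the
    unconstrained period and cohort factor effects (beta_L + gamma_L) —
    a combination that is invariant to the unidentified linear
    reparameterization.  The factor effects are recovered by decomposing
    the fitted log-rate surface over the raw age/period/cohort indicator
    basis (minimum-norm least squares); the surface lies exactly in that
    space, so the decomposition is exact."""
    apc = estimable_decomposition(lexis, deviance_table=_dummy_table())
    delta = apc.drift["log_drift_per_year"]

    I, J, K = lexis.n_age, lexis.n_period, lexis.n_cohort
    from apcmort.grid import cohort_index
    cells = [(i, j) for i in range(I) for j in range(J)]
    ii = np.array([c[0] for c in cells])
    jj = np.array([c[1] for c in cells])
    kk = np.array([cohort_index(i + 1, j + 1, I) - 1 for i, j in cells])
    X = np.hstack([
        (ii[:, None] == np.arange(I)).astype(float),
        (jj[:, None] == np.arange(J)).astype(float),
        (kk[:, None] == np.arange(K)).astype(float)])
    log_mu = np.log(apc.full_model.fitted_rates.ravel())
    params, *_ = np.linalg.lstsq(X, log_mu, rcond=None)
    np.testing.assert_allclose(X @ params, log_mu, atol=1e-10)

    def slope(v):
        t = np.arange(v.size) - (v.size - 1) / 2
        return float(t @ v / (t @ t))

    beta_l = slope(params[I:I + J]) / 5.0     # per year
    gamma_l = slope(params[I + J:]) / 5.0
    assert beta_l + gamma_l == pytest.approx(delta, abs=1e-8)


def test_pure_drift_scenario_flat_curvatures():
    sc = SyntheticScenario(annual_drift=np.log(1.03),
                           period_curvature=np.zeros(8),
                           cohort_curvature=np.zeros(22),
                           population_base=2e6, seed=5)
    records, pop = simulate_scenario(sc)
    lex = build_lexis(records, pop, sc.mechanism)
    apc = estimable_decomposition(lex, deviance_table=_dummy_table())
    d = apc.drift
    se = (np.log(d["hi"]) - np.log(d["annual_rr"])) / 1.959963984540054
    assert abs(d["log_drift_per_year"] - np.log(1.03)) < 3 * se
    # curvature RRs hover around 1 (period side carries no drift here)
    assert np.abs(np.log(apc.period_rr["rr"])).max() < 0.08
    assert drift_from_fit(apc.full_model)["annual_rr"] == pytest.approx(
        d["annual_rr"], rel=1e-12)


def test_structural_zero_age_row_flagged():
    deaths = np.ones((15, 8))
    deaths[3, :] = 0.0
    lex = LexisTable(deaths, np.full((15, 8), 1e5))
    with pytest.raises(SeparationError, match="25 to 29"):
        fit_poisson_glm(lex, ("age",))


@pytest.mark.parametrize("rr,ci,expected", [
    (1.030, (1.020, 1.040), "Upward"),
    (0.998, (0.996, 1.001), "Stationary"),
    (0.963, (0.948, 0.971), "Downward"),
])
def test_classify_trend(rr, ci, expected):
    assert classify_trend(rr, ci) == expected


def test_classify_trend_rejects_inverted_ci():
    with pytest.raises(ValueError):
        classify_trend(1.0, (1.1, 0.9))


def test_missing_reference_rejected(lexis):
    with pytest.raises(ValueError, match="not on the grid"):
        estimable_decomposition(lexis, ref_period="2050 to 2054",
                                deviance_table=_dummy_table())
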