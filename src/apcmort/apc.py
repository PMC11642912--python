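"""Poisson age-period-cohort models identified through estimable functions.

The log rate is modelled as mu + a_i + b_j + g_k on the Lexis grid.  The
three time scales are linearly dependent (cohort = period - age), so the
individual slopes of a, b, g are not identified; what is identified is the
set of estimable functions: fitted rates, curvatures (detrended effects),
the drift (total linear time slope, b_L + g_L), and the longitudinal age
trend (a_L + b_L).  The full model is therefore parameterized directly in
estimable terms: an age factor, a single linear drift term in calendar
time, and period/cohort curvature bases constrained to zero (weighted)
mean and slope.  That design is full rank, its drift coefficient is the
annual log rate ratio, and period/cohort relative risks follow as linear
contrasts with delta-method Wald intervals.

Six nested models — age, age-drift (cohort-anchored), age-cohort,
age-period-cohort, age-period, age-drift (period-anchored) — are compared
by residual deviance, AIC and likelihood-ratio tests; the two age-drift
parameterizations span the same model space and share one deviance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .grid import LexisTable, cohort_index
from .rates import RATE_SCALE

REF_PERIOD = "2000 to 2004"
REF_COHORT = "1950 to 1954"
MODEL_NAMES = ("age", "age-drift (cohort)", "age-cohort",
               "age-period-cohort", "age-period", "age-drift (period)")

TrendClass = str  # one of "Upward", "Downward", "Stationary"


class ConvergenceError(RuntimeError):
    """IRLS failed to converge; carries the deviance trace."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace


class SeparationError(RuntimeError):
    """A factor level has no deaths, so its effect diverges to -infinity."""


def classify_trend(annual_rr: float, ci: tuple[float, float]) -> TrendClass:
    """Label a drift estimate Upward / Downward / Stationary from its CI.

    Upward means the 95% CI lies entirely above RR 1, Downward entirely
    below, Stationary otherwise.
    """
    lo, hi = ci
    if not (0 < lo <= annual_rr <= hi):
        raise ValueError(
            f"inconsistent CI: need 0 < {lo} <= {annual_rr} <= {hi}")
    if lo > 1.0:
        return "Upward"
    if hi < 1.0:
        return "Downward"
    return "Stationary"


# ---------------------------------------------------------------------------
# design construction


def _curvature_basis(n: int, weights: np.ndarray) -> np.ndarray:
    """n x (n-2) basis of the weighted orthogonal complement of
    span{constant, linear index}: any combination has weighted mean 0 and
    weighted least-squares slope 0 on the category index."""
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("detrending weights must be positive")
    g = np.column_stack([np.ones(n), np.arange(n, dtype=float)])
    sw = np.sqrt(w)
    q, _ = np.linalg.qr(np.column_stack([g * sw[:, None], np.eye(n)]))
    # first two columns span W^(1/2)G; remaining n-2 are its complement
    return q[:, 2:n] / sw[:, None]


@dataclass
class DesignInfo:
    terms: tuple[str, ...]
    columns: list[str]
    slices: dict[str, slice]
    ref_period: str
    ref_cohort: str
    drift_time: str
    detrend_weights: str
    basis_period: np.ndarray | None = None
    basis_cohort: np.ndarray | None = None
    j_ref: int = 0  # 0-based reference indices
    k_ref: int = 0


def build_design(lexis: LexisTable, terms, ref_period: str = REF_PERIOD,
                 ref_cohort: str = REF_COHORT, drift_time: str = "period",
                 detrend_weights: str = "uniform") -> tuple[np.ndarray, DesignInfo]:
    """Design matrix on the flattened grid (age-major order).

    Terms: "age" (factor, no intercept), "drift" (linear in calendar years,
    anchored at the reference period or cohort per ``drift_time``),
    "period"/"cohort" — factor dummies dropping the reference when drift is
    absent, zero-mean zero-slope curvature bases when it is present —
    and "cell" (saturated, one indicator per cell).
    """
    terms = tuple(terms)
    I, J = lexis.n_age, lexis.n_period
    K = lexis.n_cohort
    cells = [(i, j) for i in range(I) for j in range(J)]
    ii = np.array([c[0] for c in cells])
    jj = np.array([c[1] for c in cells])
    kk = np.array([cohort_index(i + 1, j + 1, I) - 1 for i, j in cells])

    if ref_period not in lexis.period_labels:
        raise ValueError(f"reference period {ref_period!r} not on the grid")
    if ref_cohort not in lexis.cohort_labels:
        raise ValueError(f"reference cohort {ref_cohort!r} not on the grid")
    j_ref = lexis.period_labels.index(ref_period)
    k_ref = lexis.cohort_labels.index(ref_cohort)

    if detrend_weights == "uniform":
        wp = np.ones(J)
        wk = np.ones(K)
    elif detrend_weights == "person_years":
        wp = np.array([lexis.person_years[:, j].sum() for j in range(J)])
        wk = np.bincount(kk, weights=lexis.person_years.ravel(), minlength=K)
        wk = np.where(wk > 0, wk, wk[wk > 0].min())
    else:
        raise ValueError(f"unknown detrend_weights: {detrend_weights!r}")

    full = {"age", "drift", "period", "cohort"} <= set(terms)
    blocks, names, slices = [], [], {}
    basis_p = basis_c = None

    def add(name: str, block: np.ndarray, colnames: list[str]) -> None:
        start = sum(b.shape[1] for b in blocks)
        blocks.append(block)
        names.extend(colnames)
        slices[name] = slice(start, start + block.shape[1])

    if "cell" in terms:
        add("cell", np.eye(I * J), [f"cell[{i},{j}]" for i, j in cells])
    if "age" in terms:
        A = (ii[:, None] == np.arange(I)[None, :]).astype(float)
        add("age", A, [f"age[{a}]" for a in lexis.age_labels])
    if "drift" in terms:
        if drift_time == "period":
            t = 5.0 * (jj - j_ref)
        elif drift_time == "cohort":
            t = 5.0 * (kk - k_ref)
        else:
            raise ValueError(f"unknown drift_time: {drift_time!r}")
        add("drift", t[:, None], ["drift_per_year"])
    if "period" in terms:
        if full:
            basis_p = _curvature_basis(J, wp)
            add("period", basis_p[jj, :], [f"perCurv{c}" for c in range(J - 2)])
        else:
            P = (jj[:, None] == np.arange(J)[None, :]).astype(float)
            keep = [j for j in range(J) if j != j_ref]
            add("period", P[:, keep],
                [f"period[{lexis.period_labels[j]}]" for j in keep])
    if "cohort" in terms:
        if full:
            basis_c = _curvature_basis(K, wk)
            add("cohort", basis_c[kk, :], [f"cohCurv{c}" for c in range(K - 2)])
        else:
            C = (kk[:, None] == np.arange(K)[None, :]).astype(float)
            keep = [k for k in range(K) if k != k_ref]
            add("cohort", C[:, keep],
                [f"cohort[{lexis.cohort_labels[k]}]" for k in keep])

    if not blocks:
        raise ValueError("no model terms given")
    X = np.hstack(blocks)
    info = DesignInfo(terms, names, slices, ref_period, ref_cohort,
                      drift_time, detrend_weights, basis_p, basis_c,
                      j_ref, k_ref)
    return X, info


# ---------------------------------------------------------------------------
# fitting


@dataclass
class FittedModel:
    """Poisson GLM fit bundle on a Lexis grid."""

    name: str
    params: np.ndarray
    cov: np.ndarray
    deviance: float
    df_resid: int
    aic: float
    fitted_rates: np.ndarray  # I x J, per person-year
    design: DesignInfo
    lexis: LexisTable
    converged: bool

    def rate_per(self, scale: float = RATE_SCALE) -> np.ndarray:
        return self.fitted_rates * scale


def fit_poisson_glm(lexis: LexisTable, terms, name: str | None = None,
                    **design_kw) -> FittedModel:
    """Maximum-likelihood Poisson fit with log person-years offset (IRLS).

    Cells with zero person-years are excluded with a warning baked into the
    error paths; zero-death cells are retained.  A factor level whose cells
    hold no deaths at all is flagged as separation (its MLE diverges).
    """
    X, info = build_design(lexis, terms, **design_kw)
    d = lexis.deaths.ravel()
    n = lexis.person_years.ravel()
    keep = n > 0
    if not keep.all():
        X, d, n = X[keep], d[keep], n[keep]

    # structural-zero screen: a factor level with no deaths has a divergent MLE
    factor_terms = [t for t in ("age", "cell") if t in info.slices]
    if "period" in info.slices and info.basis_period is None:
        factor_terms.append("period")
    if "cohort" in info.slices and info.basis_cohort is None:
        factor_terms.append("cohort")
    for term in factor_terms:
        sl = info.slices[term]
        block = X[:, sl]
        level_d = block.T @ d
        dead = np.where((level_d == 0) & (block.sum(axis=0) > 0))[0]
        if dead.size:
            bad = [info.columns[sl.start + int(z)] for z in dead]
            raise SeparationError(
                f"no deaths in factor level(s) {bad}; "
                "the Poisson MLE diverges for these cells")

    model = sm.GLM(d, X, family=sm.families.Poisson(), exposure=n)
    res = model.fit(maxiter=200, tol=1e-10)
    converged = bool(getattr(res, "converged", True))
    if not converged:
        raise ConvergenceError(
            f"IRLS did not converge for model {name or terms}",
            trace=getattr(res, "fit_history", None))

    mu = np.full(lexis.deaths.size, np.nan)
    mu[keep] = res.predict()  # fitted counts
    rates = np.where(lexis.person_years.ravel() > 0,
                     mu / np.where(lexis.person_years.ravel() > 0,
                                   lexis.person_years.ravel(), 1.0), 0.0)
    return FittedModel(
        name=name or "+".join(info.terms),
        params=np.asarray(res.params, dtype=float),
        cov=np.asarray(res.cov_params(), dtype=float),
        deviance=float(res.deviance),
        df_resid=int(res.df_resid),
        aic=float(res.aic),
        fitted_rates=rates.reshape(lexis.deaths.shape),
        design=info, lexis=lexis, converged=converged)


def poisson_deviance(d: np.ndarray, mu: np.ndarray) -> float:
    """2 sum[ d log(d/mu) - (d - mu) ] with the 0 log 0 = 0 convention."""
    d = np.asarray(d, dtype=float)
    mu = np.asarray(mu, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(d > 0, d * np.log(d / mu), 0.0)
    return float(2.0 * np.sum(term - (d - mu)))


def nested_deviance_table(lexis: LexisTable, ref_period: str = REF_PERIOD,
                          ref_cohort: str = REF_COHORT,
                          detrend_weights: str = "uniform") -> pd.DataFrame:
    """Deviance/AIC table for the six nested submodels with sequential LRTs.

    Rows follow the conventional ladder age, age-drift, age-cohort, APC,
    age-period, age-drift; each likelihood-ratio p-value compares a row with
    its neighbour above (the nesting reverses direction after the full
    model, where age-period and the second age-drift are reductions).
    """
    kw = dict(ref_period=ref_period, ref_cohort=ref_cohort,
              detrend_weights=detrend_weights)
    fits = [
        fit_poisson_glm(lexis, ("age",), name=MODEL_NAMES[0], **kw),
        fit_poisson_glm(lexis, ("age", "drift"), name=MODEL_NAMES[1],
                        drift_time="cohort", **kw),
        fit_poisson_glm(lexis, ("age", "cohort"), name=MODEL_NAMES[2], **kw),
        fit_poisson_glm(lexis, ("age", "drift", "period", "cohort"),
                        name=MODEL_NAMES[3], **kw),
        fit_poisson_glm(lexis, ("age", "period"), name=MODEL_NAMES[4], **kw),
        fit_poisson_glm(lexis, ("age", "drift"), name=MODEL_NAMES[5],
                        drift_time="period", **kw),
    ]
    rows = []
    for idx, f in enumerate(fits):
        if idx == 0:
            p = np.nan
        else:
            prev = fits[idx - 1]
            # after the full model the neighbour above is the larger model
            small, big = (f, prev) if f.df_resid >= prev.df_resid else (prev, f)
            ddev = small.deviance - big.deviance
            ddf = small.df_resid - big.df_resid
            p = float(stats.chi2.sf(max(ddev, 0.0), ddf)) if ddf > 0 else np.nan
        rows.append({"model": f.name, "deviance": f.deviance,
                     "df": f.df_resid, "aic": f.aic, "lrt_p": p})
    return pd.DataFrame(rows)


def drift_from_fit(fit: FittedModel) -> dict:
    """Annual drift RR with Wald 95% CI from any fit containing a drift term."""
    if "drift" not in fit.design.slices:
        raise ValueError("model has no drift term")
    idx = fit.design.slices["drift"].start
    est = float(fit.params[idx])
    se = float(np.sqrt(fit.cov[idx, idx]))
    z = 1.959963984540054
    rr, lo, hi = np.exp(est), np.exp(est - z * se), np.exp(est + z * se)
    return {"annual_rr": float(rr), "lo": float(lo), "hi": float(hi),
            "log_drift_per_year": est, "se": se,
            "trend": classify_trend(float(rr), (float(lo), float(hi)))}


# ---------------------------------------------------------------------------
# estimable decomposition


@dataclass
class APCFit:
    """Estimable-function summary of the full age-period-cohort model."""

    deviance_table: pd.DataFrame
    age_curve: pd.DataFrame      # age_group, rate (per 100k), lo, hi
    drift: dict                  # annual_rr, lo, hi, trend, source
    period_rr: pd.DataFrame      # period, rr, lo, hi
    cohort_rr: pd.DataFrame      # cohort, rr, lo, hi
    options: dict
    full_model: FittedModel
    dispersion: float = field(default=np.nan)

    def save(self, outdir) -> None:
        """Serialize as the CSV bundle plus a JSON run manifest."""
        import pathlib
        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.deviance_table.to_csv(out / "deviance_table.csv", index=False)
        self.age_curve.to_csv(out / "age_curve.csv", index=False)
        self.period_rr.to_csv(out / "period_rr.csv", index=False)
        self.cohort_rr.to_csv(out / "cohort_rr.csv", index=False)
        pd.DataFrame([self.drift]).to_csv(out / "drift.csv", index=False)
        manifest = dict(self.options)
        manifest.update({
            "converged": self.full_model.converged,
            "deviance": self.full_model.deviance,
            "df_resid": self.full_model.df_resid,
            "dispersion": None if np.isnan(self.dispersion) else self.dispersion,
        })
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _lincomb_ci(L: np.ndarray, params: np.ndarray, cov: np.ndarray,
                z: float = 1.959963984540054) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    est = L @ params
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", L, cov, L), 0.0))
    return est, est - z * se, est + z * se


def estimable_decomposition(fit: FittedModel | LexisTable,
                            ref_period: str = REF_PERIOD,
                            ref_cohort: str = REF_COHORT,
                            drift_to: str = "cohort",
                            detrend_weights: str = "uniform",
                            scale: float = RATE_SCALE,
                            deviance_table: pd.DataFrame | None = None) -> APCFit:
    """Drift, curvature relative risks and the longitudinal age curve.

    The drift is the identified total slope (period + cohort linear parts),
    reported as annual RR = exp(slope per year) with a delta-method Wald
    interval.  Period and cohort effects are curvature-only (zero weighted
    mean and slope under ``detrend_weights``) re-anchored so the reference
    category's RR is exactly 1 with a degenerate [1, 1] interval.  The
    drift is allocated to cohort RRs by default (``drift_to='cohort'``:
    period RRs show curvature only and the age curve is the longitudinal
    age trend, i.e. fitted rates along the reference cohort); with
    ``drift_to='period'`` the period RRs carry the drift and the age curve
    is cross-sectional at the reference period.  Whatever the allocation,
    age + period + cohort components reproduce the full model's fitted
    rates exactly.
    """
    if drift_to not in ("cohort", "period"):
        raise ValueError(f"drift_to must be 'cohort' or 'period': {drift_to!r}")

    if isinstance(fit, LexisTable):
        lexis = fit
        fit = None
    else:
        lexis = fit.lexis
    needs_refit = (
        fit is None
        or set(fit.design.terms) != {"age", "drift", "period", "cohort"}
        or fit.design.ref_period != ref_period
        or fit.design.ref_cohort != ref_cohort
        or fit.design.detrend_weights != detrend_weights
        or fit.design.drift_time != "period")
    if needs_refit:
        fit = fit_poisson_glm(lexis, ("age", "drift", "period", "cohort"),
                              name="age-period-cohort", ref_period=ref_period,
                              ref_cohort=ref_cohort, drift_time="period",
                              detrend_weights=detrend_weights)

    info = fit.design
    I, J, K = lexis.n_age, lexis.n_period, lexis.n_cohort
    p = fit.params.size
    sl_a, sl_d = info.slices["age"], info.slices["drift"]
    sl_p, sl_c = info.slices["period"], info.slices["cohort"]
    Mp, Mc = info.basis_period, info.basis_cohort
    j_ref, k_ref = info.j_ref, info.k_ref

    # drift: annual log-RR is the drift coefficient itself
    Ld = np.zeros((1, p))
    Ld[0, sl_d.start] = 1.0
    d_est, d_lo, d_hi = _lincomb_ci(Ld, fit.params, fit.cov)
    annual_rr = float(np.exp(d_est[0]))
    ci = (float(np.exp(d_lo[0])), float(np.exp(d_hi[0])))
    drift = {
        "annual_rr": annual_rr, "lo": ci[0], "hi": ci[1],
        "trend": classify_trend(annual_rr, ci), "source": "full model",
        "log_drift_per_year": float(d_est[0]),
    }
    # comparison estimate from the age-drift submodel
    ad = fit_poisson_glm(lexis, ("age", "drift"), name="age-drift",
                         ref_period=ref_period, ref_cohort=ref_cohort,
                         drift_time="period")
    sl = ad.design.slices["drift"]
    se_ad = float(np.sqrt(ad.cov[sl.start, sl.start]))
    drift["age_drift_model_rr"] = float(np.exp(ad.params[sl.start]))
    drift["age_drift_model_lo"] = float(np.exp(ad.params[sl.start] - 1.959963984540054 * se_ad))
    drift["age_drift_model_hi"] = float(np.exp(ad.params[sl.start] + 1.959963984540054 * se_ad))

    # period contrasts
    Lp = np.zeros((J, p))
    Lp[:, sl_p] = Mp - Mp[j_ref]
    if drift_to == "period":
        Lp[:, sl_d.start] = 5.0 * (np.arange(J) - j_ref)
    est, lo, hi = _lincomb_ci(Lp, fit.params, fit.cov)
    period_rr = pd.DataFrame({
        "period": lexis.period_labels,
        "rr": np.exp(est), "lo": np.exp(lo), "hi": np.exp(hi)})

    # cohort contrasts
    Lc = np.zeros((K, p))
    Lc[:, sl_c] = Mc - Mc[k_ref]
    if drift_to == "cohort":
        Lc[:, sl_d.start] = 5.0 * (np.arange(K) - k_ref)
    est, lo, hi = _lincomb_ci(Lc, fit.params, fit.cov)
    cohort_rr = pd.DataFrame({
        "cohort": lexis.cohort_labels,
        "rr": np.exp(est), "lo": np.exp(lo), "hi": np.exp(hi)})

    # age curve absorbing the anchoring constants (and, for cohort-allocated
    # drift, the age-linear remainder: the longitudinal age trend)
    La = np.zeros((I, p))
    La[:, sl_a] = np.eye(I)
    La[:, sl_p] += Mp[j_ref]
    La[:, sl_c] += Mc[k_ref]
    if drift_to == "cohort":
        i0 = I + (j_ref + 1) - (k_ref + 1)  # age index on the ref diagonal
        La[:, sl_d.start] = 5.0 * (np.arange(1, I + 1) - i0)
    est, lo, hi = _lincomb_ci(La, fit.params, fit.cov)
    age_curve = pd.DataFrame({
        "age_group": lexis.age_labels,
        "rate": scale * np.exp(est),
        "lo": scale * np.exp(lo), "hi": scale * np.exp(hi)})

    if deviance_table is None:
        deviance_table = nested_deviance_table(
            lexis, ref_period, ref_cohort, detrend_weights)

    dispersion = fit.deviance / fit.df_resid if fit.df_resid > 0 else np.nan
    options = {
        "ref_period": ref_period, "ref_cohort": ref_cohort,
        "drift_to": drift_to, "detrend_weights": detrend_weights,
        "scale": scale, "region": lexis.region, "mechanism": lexis.mechanism,
    }
    return APCFit(deviance_table, age_curve, drift, period_rr, cohort_rr,
                  options, fit, dispersion)


def decomposition_fitted_rates(apc: APCFit) -> np.ndarray:
    """Reassemble cell rates from the reported age/period/cohort components;
    equals the full model's fitted rates up to floating-point error."""
    lexis = apc.full_model.lexis
    I, J = lexis.n_age, lexis.n_period
    a = np.log(apc.age_curve["rate"].to_numpy() / apc.options["scale"])
    pp = np.log(apc.period_rr["rr"].to_numpy())
    cc = np.log(apc.cohort_rr["rr"].to_numpy())
    out = np.empty((I, J))
    for i in range(I):
        for j in range(J):
            k = cohort_index(i + 1, j + 1, I) - 1
            out[i, j] = np.exp(a[i] + pp[j] + cc[k])
    return out
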