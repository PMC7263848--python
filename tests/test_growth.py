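import numpy as np
import pandas as pd
import pytest
import scipy.optimize as sopt

import deerheat as dh
from deerheat.growth import GrowthFitError, reml_correction

from conftest import dense_mvn_loglik, random_small_instance


# ---------------------------------------------------------------------------
# growth function


@pytest.mark.parametrize(
    "asym, r0, lrc, t, expected, tol",
    [
        (50.0, 9.0, -4.1, 0.0, 9.0, 1e-12),  # f(0) = R0
        (37.0, 37.0, -2.0, 55.0, 37.0, 1e-12),  # flat degenerate curve
        (50.0, 9.0, -4.1, 143.0, 46.17, 0.01),
    ],
)
def test_eval_growth_values(asym, r0, lrc, t, expected, tol):
    assert dh.eval_growth(asym, r0, lrc, t) == pytest.approx(expected, abs=tol)


def test_growth_curve_shape():
    """f is monotone in t, bounded by (R0, Asym), and tends to Asym."""
    t = np.linspace(0, 1000, 400)
    y = dh.eval_growth(50.0, 9.0, -4.1, t)
    assert np.all(np.diff(y) > 0)
    assert y.min() >= 9.0 and y.max() <= 50.0
    assert dh.eval_growth(50.0, 9.0, -4.1, 1e6) == pytest.approx(50.0)


# ---------------------------------------------------------------------------
# linear predictors


def _one_record(sex="female", mother_wt=99.0):
    return pd.DataFrame(
        {"sex": [sex], "mother_wt_kg": [mother_wt], "calf_age_d": [10.0],
         "calf_wt_kg": [15.0], "cohort": [2001], "mother_id": ["m"],
         "calf_id": ["c"], "thi": [67.0]}
    )


def test_build_linear_predictors():
    spec0 = dh.GrowthModelSpec(random_effects=("calf",))
    p0 = dh.GrowthParams([50.0], [9.0], [-4.1], {"calf": 1.0}, 1.0)
    a, r, l = dh.build_linear_predictors(_one_record(), spec0, p0)
    assert a[0] == 50.0 and r[0] == 9.0 and l[0] == -4.1

    spec = dh.GrowthModelSpec(
        asym_terms=("mother_wt_kg", "thi:sex"), random_effects=("calf",)
    )
    p = dh.GrowthParams([50.0, 0.3, 5.0], [9.0], [-4.1], {"calf": 1.0}, 1.0)
    a_f, *_ = dh.build_linear_predictors(_one_record("female"), spec, p)
    assert a_f[0] == pytest.approx(50.0 + 0.3 * 99.0)  # interaction drops out
    a_m, *_ = dh.build_linear_predictors(_one_record("male"), spec, p)
    assert a_m[0] == pytest.approx(50.0 + 0.3 * 99.0 + 5.0 * 67.0)


def test_missing_covariate_is_named():
    spec = dh.GrowthModelSpec(asym_terms=("nonexistent",), random_effects=("calf",))
    p = dh.GrowthParams([50.0, 1.0], [9.0], [-4.1], {"calf": 1.0}, 1.0)
    with pytest.raises(KeyError, match="nonexistent"):
        dh.build_linear_predictors(_one_record(), spec, p)


# ---------------------------------------------------------------------------
# marginal likelihood


def test_marginal_loglik_matches_dense_oracle():
    """Profiled-GLS/Woodbury likelihood vs an explicit dense MVN density
    on random small instances (random specs, groupings and parameters)."""
    rng = np.random.default_rng(42)
    for _ in range(25):
        records, spec, params = random_small_instance(rng)
        fast = dh.marginal_loglik(records, spec, params, criterion="ML")
        oracle = dense_mvn_loglik(records, spec, params)
        assert fast == pytest.approx(oracle, abs=1e-8)


def test_marginal_loglik_no_random_effects_is_iid_gaussian():
    rng = np.random.default_rng(3)
    records, spec, params = random_small_instance(rng)
    params.sigma_groups = {g: 0.0 for g in params.sigma_groups}
    a, r, l = dh.build_linear_predictors(records, spec, params)
    resid = records["calf_wt_kg"].to_numpy() - dh.eval_growth(
        a, r, l, records["calf_age_d"].to_numpy()
    )
    n, s2 = len(resid), params.sigma_resid**2
    iid = -0.5 * (n * np.log(2 * np.pi * s2) + resid @ resid / s2)
    assert dh.marginal_loglik(records, spec, params) == pytest.approx(iid, abs=1e-8)


def test_reml_is_ml_plus_correction():
    rng = np.random.default_rng(7)
    records, spec, params = random_small_instance(rng)
    # evaluate both criteria through the public API and assert the
    # decomposition REML = ML(at GLS coefficients) + correction term
    reml = dh.marginal_loglik(records, spec, params, criterion="REML")
    corr = reml_correction(records, spec, params)
    from deerheat.growth import _ModelMatrices, _gls_core

    mats = _ModelMatrices(records, spec)
    sg = np.array([params.sigma_groups.get(g, 0.0) for g, _ in mats.groups])
    ml_at_gls, *_ = _gls_core(mats, params.beta_lrc, sg, params.sigma_resid, "ML")
    assert reml == pytest.approx(ml_at_gls + corr, abs=1e-8)
    # without random effects and with the correction removed, REML == ML
    params.sigma_groups = {g: 0.0 for g in params.sigma_groups}
    reml0 = dh.marginal_loglik(records, spec, params, criterion="REML")
    corr0 = reml_correction(records, spec, params)
    mats0 = _ModelMatrices(records, spec)
    ml0, *_ = _gls_core(mats0, params.beta_lrc, np.zeros(len(mats0.groups)),
                        params.sigma_resid, "ML")
    assert reml0 - corr0 == pytest.approx(ml0, abs=1e-8)


# ---------------------------------------------------------------------------
# self-start


def test_self_start_recovers_generating_values():
    t = np.arange(0.0, 141.0, 20.0)
    y = dh.eval_growth(50.0, 9.0, -4.1, t)
    a0, r0, l0 = dh.self_start(t, y)
    # refit from the self-start on noise-free data
    popt, _ = sopt.curve_fit(
        lambda tt, a, r, l: dh.eval_growth(a, r, l, tt), t, y, p0=[a0, r0, l0]
    )
    assert np.allclose(popt, [50.0, 9.0, -4.1], atol=1e-4)


def test_self_start_degenerate_inputs():
    t = np.arange(0.0, 60.0, 10.0)
    with pytest.raises(GrowthFitError):
        dh.self_start(t, np.full_like(t, 20.0))  # constant
    with pytest.raises(GrowthFitError):
        dh.self_start(t, 50.0 - t / 3.0)  # strictly decreasing
    with pytest.raises(GrowthFitError):
        dh.self_start([0, 1], [1, 2])  # too few records


# ---------------------------------------------------------------------------
# fitting


@pytest.fixture(scope="module")
def tiny_fit():
    design = dh.HerdDesign(n_pairs=25, n_cohorts=3, n_mothers=15)
    _, records, _ = dh.simulate_study(design, seed=5)
    spec = dh.GrowthModelSpec(
        asym_terms=("sex",), r0_terms=("sex",), lrc_terms=("sex",),
        random_effects=("cohort", "mother", "calf"),
    )
    fit = dh.fit_growth(records, spec, criterion="ML")
    return records, spec, fit


def test_fit_zero_variance_matches_pooled_nls():
    """With no between-animal heterogeneity the mixed fit collapses to
    plain nonlinear least squares."""
    design = dh.HerdDesign(n_pairs=30, n_cohorts=3, n_mothers=20)
    truth = dh.TrueParams(
        growth_spec=dh.GrowthModelSpec(random_effects=("cohort", "mother", "calf")),
        growth=dh.GrowthParams([50.0], [9.0], [-4.1],
                               {"cohort": 0.0, "mother": 0.0, "calf": 0.0}, 1.0),
    )
    _, records, _ = dh.simulate_study(design, params=truth, seed=9)
    spec = truth.growth_spec
    fit = dh.fit_growth(records, spec, criterion="ML")
    assert all(sd < 0.8 for sd in fit.params.sigma_groups.values())

    t = records["calf_age_d"].to_numpy()
    y = records["calf_wt_kg"].to_numpy()
    popt, _ = sopt.curve_fit(
        lambda tt, a, r, l: dh.eval_growth(a, r, l, tt), t, y,
        p0=list(dh.self_start(t, y)),
    )
    assert fit.params.beta_asym[0] == pytest.approx(popt[0], abs=0.3)
    assert fit.params.beta_r0[0] == pytest.approx(popt[1], abs=0.3)
    assert fit.params.beta_lrc[0] == pytest.approx(popt[2], abs=0.03)


def test_refit_from_solution_is_fixed_point(tiny_fit):
    records, spec, fit = tiny_fit
    refit = dh.fit_growth(records, spec, criterion="ML", start=fit.params)
    assert np.allclose(refit.params.beta_asym, fit.params.beta_asym, atol=1e-6)
    assert np.allclose(refit.params.beta_r0, fit.params.beta_r0, atol=1e-6)
    assert np.allclose(refit.params.beta_lrc, fit.params.beta_lrc, atol=1e-6)
    assert refit.loglik == pytest.approx(fit.loglik, abs=1e-6)


def test_aic_and_df_conventions(tiny_fit):
    records, spec, fit = tiny_fit
    p_total = spec.n_fixed + len(fit.params.sigma_groups) + 1
    assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * p_total)
    n_calf = records["calf_id"].nunique()
    assert (fit.coef_table["df"] == len(records) - n_calf - spec.n_fixed).all()


def test_coefficient_t_and_p(tiny_fit):
    _, _, fit = tiny_fit
    tab = dh.coefficient_tests(fit)
    ok = tab["se"].gt(0) & np.isfinite(tab["se"])
    assert ok.any()
    assert np.allclose(tab.loc[ok, "t"], tab.loc[ok, "estimate"] / tab.loc[ok, "se"])
    assert ((tab["p"] >= 0) & (tab["p"] <= 1)).all()


def test_t_value_printed_precision():
    # coefficient-table arithmetic: estimate 0.186, se 0.059 -> t = 3.15
    assert 0.186 / 0.059 == pytest.approx(3.15, abs=0.02)


def test_predict_trajectory_linearity(tiny_fit):
    records, spec, fit = tiny_fit
    p0 = dh.predict_trajectory(fit, {"sex": "female"}, t_grid=[0.0])
    # at t=0 the prediction is the R0 linear predictor
    assert p0["predicted_kg"].iloc[0] == pytest.approx(fit.params.beta_r0[0], abs=1e-9)
    with pytest.raises(KeyError, match="unknown covariate"):
        dh.predict_trajectory(fit, {"bogus": 1.0})


def test_predict_trajectory_thi_shift():
    """Two scenarios differing by +1 in THI shift the asymptote by exactly
    the THI coefficient (plus the interaction for males)."""
    design = dh.HerdDesign(n_pairs=25, n_cohorts=3, n_mothers=15)
    _, records, _ = dh.simulate_study(design, seed=6)
    spec = dh.GrowthModelSpec(
        asym_terms=("thi", "thi:sex"), lrc_terms=(), random_effects=("calf",)
    )
    fit = dh.fit_growth(records, spec, criterion="ML", compute_lrc_se=False)
    b_thi = fit.coef_table.query("block=='asym' and term=='thi'")["estimate"].iloc[0]
    b_int = fit.coef_table.query("block=='asym' and term=='thi:sex'")["estimate"].iloc[0]
    big_t = [5000.0]  # far out on the curve, prediction ~ Asym
    for sex, slope in (("female", b_thi), ("male", b_thi + b_int)):
        lo = dh.predict_trajectory(fit, {"thi": 67.0, "sex": sex}, big_t)
        hi = dh.predict_trajectory(fit, {"thi": 68.0, "sex": sex}, big_t)
        got = hi["predicted_kg"].iloc[0] - lo["predicted_kg"].iloc[0]
        assert got == pytest.approx(slope, abs=1e-6)
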