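import numpy as np
import pandas as pd
import pytest
import scipy.linalg as sla

import deerheat as dh
from deerheat import gam
from deerheat.gam import GamError, by_factor_smooth, centering_transform


# ---------------------------------------------------------------------------
# bases


def test_spline_penalty_null_space():
    """Constants and linears are unpenalized; curvature is penalized."""
    x = np.linspace(0, 10, 60)
    basis, penalty, knots, _ = gam.spline_basis(x, k=6)
    ev = np.linalg.eigvalsh(penalty)
    assert ev.min() > -1e-9  # positive semi-definite
    assert (ev < 1e-9).sum() == 2  # null space of dimension 2
    # coefficient vectors of constant and linear functions are penalty-free
    for coefs in (np.ones(6), knots.copy()):
        assert coefs @ penalty @ coefs == pytest.approx(0.0, abs=1e-9)
    quad = np.sin(knots)
    assert quad @ penalty @ quad > 1e-3


def test_spline_needs_enough_distinct_values():
    with pytest.raises(GamError, match="distinct"):
        gam.spline_basis(np.array([1.0, 1.0, 2.0]), k=4)


def test_sin_recovery():
    x = np.linspace(0, 2 * np.pi, 200)
    df = pd.DataFrame({"x": x, "y": np.sin(x)})
    fit = gam.fit_gam(df, parametric_terms=(), smooth_specs=[gam.SmoothSpec("x", k=10)],
                      response="y", fixed_lambdas={"x": 1e-6})
    pred = gam.predict_gam(fit, df[["x"]], centered=False)
    assert np.abs(pred["pred"].to_numpy() - np.sin(x)).max() < 0.05


def test_random_effect_smooth_basics():
    basis, pen, levels = gam.random_effect_smooth(["a", "b", "a", "c"])
    assert basis.shape == (4, 3)
    assert np.array_equal(pen, np.eye(3))
    with pytest.raises(GamError, match="2 levels"):
        gam.random_effect_smooth(["a", "a"])


def test_unpenalized_re_basis_gives_group_means():
    rng = np.random.default_rng(0)
    g = np.repeat(["a", "b"], 10)
    y = np.where(g == "a", 4.0, 7.0) + rng.normal(0, 0.1, 20)
    basis, _, _ = gam.random_effect_smooth(g)
    est, *_ = np.linalg.lstsq(basis, y, rcond=None)
    assert est[0] == pytest.approx(y[:10].mean())
    assert est[1] == pytest.approx(y[10:].mean())


def test_re_smooth_full_shrinkage():
    rng = np.random.default_rng(1)
    df = pd.DataFrame({"g": np.repeat(list("abcde"), 10).astype(str),
                       "y": rng.normal(5, 2, 50)})
    fit = gam.fit_gam(df, parametric_terms=(), smooth_specs=[gam.SmoothSpec("g", type="re")],
                      response="y", fixed_lambdas={"g": 1e12})
    assert np.abs(fit.coefficients[1:]).max() < 1e-6


def test_re_smooth_matches_closed_form_ridge():
    """At a given lambda the 're' smooth equals the ridge/BLUP solution."""
    rng = np.random.default_rng(2)
    g = np.repeat(np.arange(10), 8)
    y = 5.0 + rng.normal(0, 2.0, 10)[g] + rng.normal(0, 1.0, 80)
    df = pd.DataFrame({"g": g.astype(str), "y": y})
    lam = 1.0 / 4.0
    fit = gam.fit_gam(df, parametric_terms=(), smooth_specs=[gam.SmoothSpec("g", type="re")],
                      response="y", fixed_lambdas={"g": lam})
    x = np.column_stack([np.ones(80), np.eye(10)[g]])
    s = np.diag([0.0] + [lam] * 10)
    oracle = sla.solve(x.T @ x + s, x.T @ y)
    got = np.r_[fit.parametric_table["estimate"].iloc[0], fit.coefficients[1:]]
    assert np.abs(got - oracle).max() < 1e-8


def test_by_factor_smooth():
    rng = np.random.default_rng(3)
    df = pd.DataFrame({"x": rng.uniform(0, 1, 60),
                       "sex": np.repeat(["female", "male"], 30)})
    terms = by_factor_smooth(df, "x", "sex", k=4)
    assert [t.label for t in terms] == ["x x sex (female)", "x x sex (male)"]
    # all-female indicator zeroes the male block
    df_f = df.assign(sex="female")
    terms_f = by_factor_smooth(df_f.iloc[:30], "x", "sex", k=4)
    assert len(terms_f) == 1  # only one level present
    male_cols = terms[1].predict_columns(df_f)
    assert np.abs(male_cols).max() == 0.0
    with pytest.raises(GamError, match="level"):
        by_factor_smooth(df.iloc[:33], "x", "sex", k=4)  # male level starved


def test_lambda_infinity_collapses_to_linear_oracle():
    rng = np.random.default_rng(4)
    x = rng.uniform(0, 1, 120)
    y = 2 + 3 * x + rng.normal(0, 0.3, 120)
    df = pd.DataFrame({"x": x, "y": y})
    fit = gam.fit_gam(df, parametric_terms=(), smooth_specs=[gam.SmoothSpec("x", k=5)],
                      response="y", fixed_lambdas={"x": np.inf})
    coef = np.polyfit(x, y, 1)
    rss_lin = np.sum((y - np.polyval(coef, x)) ** 2)
    rss_gam = (1 - fit.deviance_explained) * np.sum((y - y.mean()) ** 2)
    assert rss_gam == pytest.approx(rss_lin, abs=1e-8)


def test_zero_noise_linear_deviance():
    x = np.linspace(0, 1, 50)
    df = pd.DataFrame({"x": x, "y": 1.0 + 2.0 * x})
    fit = gam.fit_gam(df, parametric_terms=(), smooth_specs=[gam.SmoothSpec("x", k=4)],
                      response="y", fixed_lambdas={"x": 1.0})
    assert fit.deviance_explained == pytest.approx(1.0, abs=1e-10)


def test_reml_recovers_random_intercept_sd():
    """REML sigma for an 're' smooth matches the generating mixed model."""
    rng = np.random.default_rng(5)
    n_m, per = 150, 10
    g = np.repeat(np.arange(n_m), per)
    sigma_b, sigma = 5.0, 1.5
    y = 99.0 + rng.normal(0, sigma_b, n_m)[g] + rng.normal(0, sigma, n_m * per)
    df = pd.DataFrame({"mother": g.astype(str), "y": y})
    fit = gam.fit_gam(df, parametric_terms=(),
                      smooth_specs=[gam.SmoothSpec("mother", type="re")],
                      response="y", seed=1)
    assert fit.variance_components["mother"] == pytest.approx(sigma_b, rel=0.25)
    assert fit.sigma_resid == pytest.approx(sigma, rel=0.15)


def test_edf_bounds_and_nested_deviance():
    rng = np.random.default_rng(6)
    n = 200
    df = pd.DataFrame({
        "x1": rng.uniform(0, 1, n), "x2": rng.uniform(0, 1, n),
    })
    df["y"] = np.sin(3 * df.x1) + 0.5 * df.x2**2 + rng.normal(0, 0.2, n)
    lams = {"x1": 1.0, "x2": 1.0}
    f1 = gam.fit_gam(df, (), [gam.SmoothSpec("x1", k=4)], "y", fixed_lambdas=lams)
    f2 = gam.fit_gam(df, (), [gam.SmoothSpec("x1", k=4), gam.SmoothSpec("x2", k=4)],
                     "y", fixed_lambdas=lams)
    assert f2.deviance_explained >= f1.deviance_explained - 1e-12
    for fit, k in ((f1, 4), (f2, 4)):
        for _, row in fit.smooth_table.iterrows():
            assert 0 < row["edf"] <= k - 1 + 1e-8


def test_reml_trace_monotone():
    rng = np.random.default_rng(7)
    df = pd.DataFrame({"x": rng.uniform(0, 1, 150)})
    df["y"] = np.cos(4 * df.x) + rng.normal(0, 0.3, 150)
    fit = gam.fit_gam(df, (), [gam.SmoothSpec("x", k=6)], "y", n_restarts=1)
    tr = np.asarray(fit.reml_trace)
    if tr.size > 1:
        assert np.all(np.diff(tr) <= 1e-6)


def test_predict_gam_centering_and_se(small_study):
    _, records, _ = small_study
    fit = gam.fit_gam(
        records, parametric_terms=("sex",),
        smooth_specs=[gam.SmoothSpec("calf_age_d", k=3),
                      gam.SmoothSpec("mother_id", type="re")],
        response="mother_wt_kg", seed=0,
    )
    means = pd.DataFrame({"calf_age_d": [records["calf_age_d"].mean()]})
    out_f = gam.predict_gam(fit, means.assign(sex="female"))
    out_m = gam.predict_gam(fit, means.assign(sex="male"))
    assert (out_f["se"] > 0).all()
    # sexes differ by exactly the parametric coefficient here (no by-smooth)
    sex_coef = fit.parametric_table.query("term=='sex (male)'")["estimate"].iloc[0]
    assert out_m["pred"].iloc[0] - out_f["pred"].iloc[0] == pytest.approx(sex_coef, abs=1e-8)
    with pytest.warns(UserWarning, match="extrapolating"):
        gam.predict_gam(fit, pd.DataFrame({"calf_age_d": [1e4], "sex": ["female"]}))


def test_centering_transform_orthogonality():
    rng = np.random.default_rng(8)
    basis, *_ = gam.spline_basis(rng.uniform(0, 5, 40), k=5)
    z = centering_transform(basis)
    centered = basis @ z
    assert np.abs(centered.sum(axis=0)).max() < 1e-8
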