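"""Asymptotic nonlinear mixed-effects model for calf growth.

The weight of calf i at age t (days) follows the exponential-asymptotic
curve

    f(t) = Asym + (R0 - Asym) * exp(-exp(lrc) * t)

where Asym is the horizontal asymptote (kg), R0 the weight at t = 0 (kg)
and lrc the natural log of the rate constant.  Each of the three curve
parameters is a linear combination of per-record covariates (sex enters
as a 0/1 male indicator, female being the reference level; interactions
multiply the indicator by the covariate), and Gaussian random intercepts
for calf cohort, mother and calf identity shift the asymptote.

Writing s_i = 1 - exp(-exp(lrc_i) * t_i), the model is linear in the
Asym- and R0-block coefficients given lrc_i:

    y_i = s_i * x^A_i . beta_A + (1 - s_i) * x^R_i . beta_R
          + s_i * (b_cohort + b_mother + b_calf) + eps_i,

so the marginal covariance is V = sigma^2 I + sum_g sigma_g^2 (D_s Z_g)(D_s Z_g)^T
with D_s = diag(s) and Z_g the indicator matrix of grouping factor g, and
the exact marginal (or restricted) Gaussian likelihood is available in
closed form: no Laplace approximation is needed.  Fitting maximises the
likelihood over (beta_L, log sigma_g, log sigma) by quasi-Newton, with
(beta_A, beta_R) profiled out by generalised least squares at every step;
the Woodbury identity keeps each evaluation at O(n + q^3) for q total
random-effect levels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.optimize as sopt
import scipy.sparse as sp
from scipy import stats

logger = logging.getLogger(__name__)

BLOCKS = ("asym", "r0", "lrc")

#: data-frame columns used by the model machinery
RESPONSE_COL = "calf_wt_kg"
TIME_COL = "calf_age_d"
GROUP_COLS = {"cohort": "cohort", "mother": "mother_id", "calf": "calf_id"}

_SIGMA_FLOOR_LOG = -10.0  # boundary: sigma reported at exp(-10) * sd(y)


class GrowthFitError(RuntimeError):
    """Raised when self-starting or likelihood maximisation fails."""


def eval_growth(asym, r0, lrc, t):
    """Exponential-asymptotic growth curve f(t) = Asym + (R0-Asym)e^(-e^lrc t).

    Equivalently r0*(1-s) + asym*s with s = 1 - exp(-exp(lrc)*t).  Total
    on valid inputs (t >= 0); vectorised over any argument.
    """
    asym = np.asarray(asym, dtype=float)
    r0 = np.asarray(r0, dtype=float)
    lrc = np.asarray(lrc, dtype=float)
    t = np.asarray(t, dtype=float)
    decay = np.exp(-np.minimum(np.exp(np.minimum(lrc, 50.0)) * t, 700.0))
    out = asym + (r0 - asym) * decay
    return out if out.ndim else float(out)


def _growth_s(lrc, t):
    """Saturation fraction s = 1 - exp(-exp(lrc) t) in [0, 1)."""
    return 1.0 - np.exp(-np.minimum(np.exp(np.minimum(lrc, 50.0)) * np.asarray(t, float), 700.0))


# ---------------------------------------------------------------------------
# model specification


@dataclass(frozen=True)
class GrowthModelSpec:
    """Covariate structure of the three curve parameters.

    Each block lists per-record covariate terms beyond the always-present
    intercept.  ``sex`` denotes the male indicator; ``"x:sex"`` the
    interaction of covariate x with it.  Random intercepts (subset of
    cohort/mother/calf) act on the asymptote only.
    """

    asym_terms: tuple = ()
    r0_terms: tuple = ()
    lrc_terms: tuple = ()
    random_effects: tuple = ("cohort", "mother", "calf")

    def __post_init__(self):
        for attr in ("asym_terms", "r0_terms", "lrc_terms", "random_effects"):
            object.__setattr__(self, attr, tuple(getattr(self, attr)))
        for g in self.random_effects:
            if g not in GROUP_COLS:
                raise ValueError(f"unknown random-effect grouping factor {g!r}")
        for blk in BLOCKS:
            terms = self.block_terms(blk)
            if len(set(terms)) != len(terms):
                raise ValueError(f"duplicate term in block {blk!r}")

    def block_terms(self, block: str) -> tuple:
        """Terms of a block including the leading intercept."""
        return ("1",) + {"asym": self.asym_terms, "r0": self.r0_terms, "lrc": self.lrc_terms}[block]

    def with_terms(self, term: str, blocks=BLOCKS) -> "GrowthModelSpec":
        """Copy of the spec with `term` appended to the named blocks."""
        kw = {}
        for blk in blocks:
            attr = {"asym": "asym_terms", "r0": "r0_terms", "lrc": "lrc_terms"}[blk]
            cur = getattr(self, attr)
            if term in cur:
                raise ValueError(f"term {term!r} already present in block {blk!r}")
            kw[attr] = cur + (term,)
        return replace(self, **kw)

    @property
    def n_fixed(self) -> int:
        return sum(len(self.block_terms(b)) for b in BLOCKS)


@dataclass
class GrowthParams:
    """Parameter values of a growth model (generator truth or estimates).

    Coefficients are kg per covariate unit for the Asym and R0 blocks and
    on the log-rate scale for lrc; sigmas are random-intercept and residual
    standard deviations in kg.
    """

    beta_asym: np.ndarray
    beta_r0: np.ndarray
    beta_lrc: np.ndarray
    sigma_groups: dict  # e.g. {"cohort": 5.40, "mother": 5.93, "calf": 8.04}
    sigma_resid: float

    def __post_init__(self):
        self.beta_asym = np.atleast_1d(np.asarray(self.beta_asym, dtype=float))
        self.beta_r0 = np.atleast_1d(np.asarray(self.beta_r0, dtype=float))
        self.beta_lrc = np.atleast_1d(np.asarray(self.beta_lrc, dtype=float))
        if any(s < 0 for s in self.sigma_groups.values()) or self.sigma_resid < 0:
            raise ValueError("standard deviations must be >= 0")


def _term_column(records: pd.DataFrame, term: str) -> np.ndarray:
    """Evaluate one covariate term on a record table."""
    if term == "1":
        return np.ones(len(records))
    if ":" in term:
        parts = term.split(":")
        col = np.ones(len(records))
        for p in parts:
            col = col * _term_column(records, p)
        return col
    if term == "sex":
        return (records["sex"].astype(str).str.lower() == "male").to_numpy(dtype=float)
    if term not in records.columns:
        raise KeyError(f"covariate {term!r} missing from records")
    return records[term].to_numpy(dtype=float)


def design_matrix(records: pd.DataFrame, terms) -> np.ndarray:
    return np.column_stack([_term_column(records, t) for t in terms])


def build_linear_predictors(records, spec: GrowthModelSpec, params: GrowthParams,
                            random_effects=None):
    """Per-record (Asym_i, R0_i, lrc_i) from the spec's linear predictors.

    `random_effects` optionally maps grouping factor -> {level: intercept}
    to add conditional asymptote shifts; by default predictions are at the
    population level (random effects zero).
    """
    xa = design_matrix(records, spec.block_terms("asym"))
    xr = design_matrix(records, spec.block_terms("r0"))
    xl = design_matrix(records, spec.block_terms("lrc"))
    asym = xa @ params.beta_asym
    r0 = xr @ params.beta_r0
    lrc = xl @ params.beta_lrc
    if random_effects:
        for g, levels in random_effects.items():
            col = records[GROUP_COLS[g]]
            asym = asym + col.map(levels).fillna(0.0).to_numpy(dtype=float)
    return asym, r0, lrc


# ---------------------------------------------------------------------------
# likelihood machinery


class _ModelMatrices:
    """Precomputed design objects for one (records, spec) pair."""

    def __init__(self, records: pd.DataFrame, spec: GrowthModelSpec):
        self.spec = spec
        self.y = records[RESPONSE_COL].to_numpy(dtype=float)
        self.t = records[TIME_COL].to_numpy(dtype=float)
        self.n = len(records)
        self.xa = design_matrix(records, spec.block_terms("asym"))
        self.xr = design_matrix(records, spec.block_terms("r0"))
        self.xl = design_matrix(records, spec.block_terms("lrc"))
        self.groups = []
        self.z_list = []
        for g in spec.random_effects:
            codes, levels = pd.factorize(records[GROUP_COLS[g]], sort=True)
            if len(levels) < 1:
                raise ValueError(f"grouping factor {g!r} has no levels")
            z = sp.csr_matrix(
                (np.ones(self.n), (np.arange(self.n), codes)),
                shape=(self.n, len(levels)),
            )
            self.groups.append((g, levels))
            self.z_list.append(z)
        self.group_sizes = [len(lv) for _, lv in self.groups]
        self.q = sum(self.group_sizes)

    def scaled_z(self, s, sigma_groups_arr):
        """(U, lam) for the groups with positive sd: U = D_s Z, lam per column."""
        active = [i for i, sg in enumerate(sigma_groups_arr) if sg > 0]
        if not active:
            return None, None
        z = sp.hstack([self.z_list[i] for i in active], format="csr")
        lam = np.repeat(
            np.asarray(sigma_groups_arr, dtype=float)[active] ** 2,
            [self.group_sizes[i] for i in active],
        )
        return z.multiply(s[:, None]).tocsr(), lam

    @property
    def p_fixed(self):
        return self.xa.shape[1] + self.xr.shape[1] + self.xl.shape[1]


def _gls_core(mats: _ModelMatrices, beta_l, sigma_groups_arr, sigma, criterion):
    """Profiled marginal log-likelihood via Woodbury + GLS.

    Returns (loglik, beta_fixed, XtVinvX, quad_resid) where beta_fixed
    stacks the GLS estimates of (beta_A, beta_R).
    """
    n = mats.n
    lrc = mats.xl @ np.asarray(beta_l, dtype=float)
    s = _growth_s(lrc, mats.t)
    x = np.hstack([s[:, None] * mats.xa, (1.0 - s)[:, None] * mats.xr])
    y = mats.y
    sig2 = sigma**2

    u, lam = mats.scaled_z(s, sigma_groups_arr) if mats.q else (None, None)
    if u is not None:
        q = u.shape[1]
        m = (u.T @ u).toarray()
        a = m + np.diag(sig2 / lam)
        try:
            cho = sla.cho_factor(a, lower=True, check_finite=False)
        except sla.LinAlgError as exc:  # pragma: no cover - numerically rare
            raise GrowthFitError(
                "singular marginal covariance; consider a variance floor"
            ) from exc
        uty = u.T @ y
        utx = u.T @ x
        sol_y = sla.cho_solve(cho, uty, check_finite=False)
        sol_x = sla.cho_solve(cho, utx, check_finite=False)
        ytvy = (y @ y - uty @ sol_y) / sig2
        xtvy = (x.T @ y - utx.T @ sol_y) / sig2
        xtvx = (x.T @ x - utx.T @ sol_x) / sig2
        logdet_v = (
            2.0 * (n - q) * np.log(sigma)
            + np.sum(np.log(lam))
            + 2.0 * np.sum(np.log(np.diag(cho[0])))
        )
    else:
        ytvy = y @ y / sig2
        xtvy = x.T @ y / sig2
        xtvx = x.T @ x / sig2
        logdet_v = 2.0 * n * np.log(sigma)

    try:
        cho_x = sla.cho_factor(xtvx, check_finite=False)
    except sla.LinAlgError as exc:
        raise GrowthFitError("singular fixed-effect information (X'V^-1X)") from exc
    beta = sla.cho_solve(cho_x, xtvy, check_finite=False)
    quad = ytvy - beta @ xtvy  # r' V^-1 r at the GLS solution
    ll = -0.5 * (n * np.log(2 * np.pi) + logdet_v + quad)
    if criterion == "REML":
        p = x.shape[1]
        logdet_xtvx = 2.0 * np.sum(np.log(np.diag(cho_x[0])))
        ll += -0.5 * logdet_xtvx + 0.5 * p * np.log(2 * np.pi)
    return ll, beta, xtvx, quad


def reml_correction(records, spec, params):
    """The REML adjustment term: -1/2 log|X'V^-1 X| + (p/2) log 2pi.

    Exposed so the ML/REML decomposition can be asserted directly:
    restricted loglik = marginal loglik (at the GLS coefficients) + this.
    """
    mats = _ModelMatrices(records, spec)
    sg = np.array([params.sigma_groups.get(g, 0.0) for g, _ in mats.groups])
    ml, *_ = _gls_core(mats, params.beta_lrc, sg, params.sigma_resid, "ML")
    reml, *_ = _gls_core(mats, params.beta_lrc, sg, params.sigma_resid, "REML")
    return reml - ml


def marginal_loglik(records, spec: GrowthModelSpec, params: GrowthParams,
                    criterion: str = "ML") -> float:
    """Exact marginal Gaussian log-likelihood of the mixed growth model.

    ML evaluates the multivariate-normal density of the weights at the
    supplied coefficients; REML evaluates the restricted likelihood (the
    residual is taken at the GLS coefficient solution, and the standard
    -1/2 log|X'V^-1X| correction is added).
    """
    if criterion not in ("ML", "REML"):
        raise ValueError("criterion must be 'ML' or 'REML'")
    mats = _ModelMatrices(records, spec)
    sg = np.array([params.sigma_groups.get(g, 0.0) for g, _ in mats.groups])
    sigma = params.sigma_resid
    if sigma <= 0:
        raise ValueError("residual sd must be positive")
    if criterion == "REML":
        ll, *_ = _gls_core(mats, params.beta_lrc, sg, sigma, "REML")
        return float(ll)
    # ML at the *given* beta_A / beta_R (not profiled)
    n = mats.n
    lrc = mats.xl @ params.beta_lrc
    s = _growth_s(lrc, mats.t)
    mu = s * (mats.xa @ params.beta_asym) + (1.0 - s) * (mats.xr @ params.beta_r0)
    r = mats.y - mu
    sig2 = sigma**2
    u, lam = mats.scaled_z(s, sg) if mats.q else (None, None)
    if u is not None:
        q = u.shape[1]
        m = (u.T @ u).toarray()
        a = m + np.diag(sig2 / lam)
        try:
            cho = sla.cho_factor(a, lower=True, check_finite=False)
        except sla.LinAlgError as exc:
            raise GrowthFitError(
                "singular marginal covariance; consider a variance floor"
            ) from exc
        utr = u.T @ r
        quad = (r @ r - utr @ sla.cho_solve(cho, utr, check_finite=False)) / sig2
        logdet_v = (
            2.0 * (n - q) * np.log(sigma)
            + np.sum(np.log(lam))
            + 2.0 * np.sum(np.log(np.diag(cho[0])))
        )
    else:
        quad = r @ r / sig2
        logdet_v = 2.0 * n * np.log(sigma)
    return float(-0.5 * (n * np.log(2 * np.pi) + logdet_v + quad))


# ---------------------------------------------------------------------------
# self-starting initial values


def self_start(t, y):
    """Initial (asym0, r00, lrc0) for the asymptotic curve.

    Takes asym0 = 1.05 * max(y), regresses log(asym0 - y) on t for slope b
    and intercept a, and returns lrc0 = log(-b), r00 = asym0 - exp(a).
    Mirrors the usual self-starting initialisation for asymptotic
    regression.  Raises on data incompatible with a rising saturating
    curve (constant or non-increasing y, slope b >= 0).
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size < 4 or np.unique(t).size < 3:
        raise GrowthFitError("cannot self-start: need >= 4 records over >= 3 ages")
    asym0 = 1.05 * y.max()
    resid = asym0 - y
    if np.any(resid <= 0):
        raise GrowthFitError("cannot self-start: asymptote margin exhausted")
    b, a = np.polyfit(t, np.log(resid), 1)
    if not np.isfinite(b) or b >= 0:
        raise GrowthFitError("cannot self-start: data do not rise toward an asymptote")
    lrc0 = float(np.log(-b))
    r00 = float(asym0 - np.exp(a))
    return float(asym0), r00, lrc0


# ---------------------------------------------------------------------------
# fitting


@dataclass
class FittedGrowthModel:
    """A fitted mixed growth model: estimates, tests and diagnostics."""

    spec: GrowthModelSpec
    params: GrowthParams
    criterion: str
    loglik: float
    aic: float
    n_obs: int
    coef_table: pd.DataFrame  # block, term, estimate, se, df, t, p
    varcomp_table: pd.DataFrame  # group, sd (+ residual row)
    converged: bool
    n_iter: int
    boundary_groups: tuple
    training_means: dict = field(default_factory=dict)

    @property
    def p_total(self) -> int:
        return self.spec.n_fixed + len(self.params.sigma_groups) + 1


def _theta_split(theta, p_l, n_g):
    beta_l = theta[:p_l]
    log_sg = theta[p_l : p_l + n_g]
    log_s = theta[p_l + n_g]
    return beta_l, np.exp(log_sg), np.exp(log_s)


def fit_growth(
    records: pd.DataFrame,
    spec: GrowthModelSpec,
    criterion: str = "ML",
    start: GrowthParams | None = None,
    max_iter: int = 500,
    compute_lrc_se: bool = True,
) -> FittedGrowthModel:
    """Maximise the marginal (or restricted) likelihood of the growth model.

    The outer quasi-Newton search runs over the lrc-block coefficients and
    the log standard deviations; the Asym/R0 coefficients are profiled by
    GLS at every step (the curve is linear in them given lrc).  Variance
    parameters are optimised on the log scale with a lower boundary at
    exp(-10) * sd(y); estimates on the boundary are reported as 0 with a
    boundary flag.  Standard errors come from the GLS covariance for the
    Asym/R0 blocks and from a numeric Hessian of the profiled likelihood
    for the lrc block; t-tests use df = n - (#calf levels) - (#fixed
    coefficients).
    """
    if criterion not in ("ML", "REML"):
        raise ValueError("criterion must be 'ML' or 'REML'")
    mats = _ModelMatrices(records, spec)
    p_a, p_r, p_l = mats.xa.shape[1], mats.xr.shape[1], mats.xl.shape[1]
    n_g = len(mats.groups)
    sd_y = float(np.std(mats.y))
    if sd_y <= 0:
        raise GrowthFitError("response has zero variance")
    log_floor = np.log(sd_y) + _SIGMA_FLOOR_LOG

    if start is not None:
        theta0 = np.concatenate(
            [
                start.beta_lrc,
                np.log(np.maximum(
                    [start.sigma_groups.get(g, sd_y / 4) for g, _ in mats.groups],
                    np.exp(log_floor),
                )),
                [np.log(max(start.sigma_resid, np.exp(log_floor)))],
            ]
        )
    else:
        _, _, lrc0 = self_start(mats.t, mats.y)
        beta_l0 = np.zeros(p_l)
        beta_l0[0] = lrc0
        theta0 = np.concatenate(
            [beta_l0, np.full(n_g, np.log(sd_y / 4)), [np.log(sd_y / 4)]]
        )

    trace = []

    def negll(theta):
        beta_l, sg, sig = _theta_split(theta, p_l, n_g)
        try:
            ll, *_ = _gls_core(mats, beta_l, sg, sig, "ML")
        except GrowthFitError:
            return 1e12
        trace.append(float(ll))
        return -ll

    # Maximum likelihood jointly over the lrc-block coefficients and the
    # log standard deviations; (beta_A, beta_R) profiled by GLS inside.
    bounds = [(None, None)] * p_l + [(log_floor, None)] * (n_g + 1)
    res = sopt.minimize(
        negll,
        theta0,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": max_iter, "ftol": 1e-11, "gtol": 1e-6},
    )
    if not res.success and res.status != 1:  # status 1 = maxiter
        raise GrowthFitError(
            f"likelihood maximisation failed: {res.message}; trace tail "
            f"{trace[-5:]}"
        )
    if res.status == 1:
        raise GrowthFitError(
            f"no convergence after {max_iter} iterations; trace tail {trace[-5:]}"
        )
    n_outer = res.nit

    beta_l, sg, sig = _theta_split(res.x, p_l, n_g)

    if criterion == "REML":
        # Restricted likelihood is a criterion for the variance parameters
        # only: re-estimate the sigmas by REML at the ML mean solution
        # (the Asym/R0 blocks are re-profiled by GLS under the REML
        # variances when the final estimates are extracted below).
        sg, sig, n_extra = _reml_variance_step(mats, beta_l, sg, sig, log_floor, max_iter)
        n_outer += n_extra
    ll, beta_fix, xtvx, _ = _gls_core(mats, beta_l, sg, sig, criterion)
    beta_a, beta_r = beta_fix[:p_a], beta_fix[p_a : p_a + p_r]

    boundary = tuple(
        g for (g, _), lv in zip(mats.groups, np.log(sg)) if lv <= log_floor + 1e-6
    )
    sigma_groups = {
        g: (0.0 if g in boundary else float(s))
        for (g, _), s in zip(mats.groups, sg)
    }
    if np.log(sig) <= log_floor + 1e-6:
        logger.warning("residual sd estimated on the boundary")

    params = GrowthParams(
        beta_asym=beta_a,
        beta_r0=beta_r,
        beta_lrc=beta_l,
        sigma_groups=sigma_groups,
        sigma_resid=float(sig),
    )

    # --- standard errors -------------------------------------------------
    cov_fix = sla.inv(xtvx)
    se_fix = np.sqrt(np.maximum(np.diag(cov_fix), 0.0))
    if compute_lrc_se:
        se_l = _lrc_se(mats, beta_l, sg, sig, criterion)
    else:
        se_l = np.full(p_l, np.nan)

    n_calf = (
        mats.group_sizes[list(spec.random_effects).index("calf")]
        if "calf" in spec.random_effects
        else 0
    )
    df = mats.n - n_calf - spec.n_fixed
    rows = []
    for blk, terms, est, se in (
        ("asym", spec.block_terms("asym"), beta_a, se_fix[:p_a]),
        ("r0", spec.block_terms("r0"), beta_r, se_fix[p_a : p_a + p_r]),
        ("lrc", spec.block_terms("lrc"), beta_l, se_l),
    ):
        for term, e, s in zip(terms, est, se):
            tval = e / s if (np.isfinite(s) and s > 0) else (0.0 if e == 0 else np.nan)
            p = 2 * stats.t.sf(abs(tval), df) if np.isfinite(tval) else np.nan
            rows.append(
                {"block": blk, "term": ("intercept" if term == "1" else term),
                 "estimate": e, "se": s, "df": df, "t": tval, "p": p}
            )
    coef_table = pd.DataFrame(rows)

    vrows = [{"group": g, "sd": sigma_groups[g]} for g, _ in mats.groups]
    vrows.append({"group": "residual", "sd": float(sig)})
    varcomp = pd.DataFrame(vrows)

    p_total = spec.n_fixed + n_g + 1
    aic = -2.0 * ll + 2.0 * p_total

    means = {}
    for blk in BLOCKS:
        for term in spec.block_terms(blk):
            if term in ("1",):
                continue
            base_terms = term.split(":") if ":" in term else [term]
            for bt in base_terms:
                if bt not in means and bt != "sex":
                    means[bt] = float(records[bt].mean())
    means[TIME_COL] = float(records[TIME_COL].mean())

    return FittedGrowthModel(
        spec=spec,
        params=params,
        criterion=criterion,
        loglik=float(ll),
        aic=float(aic),
        n_obs=mats.n,
        coef_table=coef_table,
        varcomp_table=varcomp,
        converged=True,
        n_iter=n_outer,
        boundary_groups=boundary,
        training_means=means,
    )


def _reml_variance_step(mats, beta_l, sg, sig, log_floor, max_iter):
    """REML re-estimation of the standard deviations at a fixed mean."""
    n_g = len(sg)

    def neg_reml_var(ls):
        try:
            ll, *_ = _gls_core(mats, beta_l, np.exp(ls[:n_g]), np.exp(ls[n_g]), "REML")
        except GrowthFitError:
            return 1e12
        return -ll

    res = sopt.minimize(
        neg_reml_var,
        np.concatenate([np.log(np.maximum(sg, np.exp(log_floor))), [np.log(sig)]]),
        method="L-BFGS-B",
        bounds=[(log_floor, None)] * (n_g + 1),
        options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-7},
    )
    if not res.success and res.status != 1:
        raise GrowthFitError(f"REML variance step failed: {res.message}")
    return np.exp(res.x[:n_g]), float(np.exp(res.x[n_g])), res.nit


def _lrc_se(mats, beta_l, sg, sig, criterion, h_rel=1e-4):
    """Numeric-Hessian standard errors of the lrc-block coefficients.

    Central second differences of the profiled log-likelihood with the
    variance parameters held at their estimates (conditional
    approximation); the GLS profiling of the Asym/R0 blocks means their
    uncertainty is propagated automatically.
    """
    p_l = len(beta_l)

    def f(b):
        ll, *_ = _gls_core(mats, b, sg, sig, criterion)
        return ll

    h = h_rel * np.maximum(np.abs(beta_l), 1e-2)
    hess = np.empty((p_l, p_l))
    f0 = f(beta_l)
    fp = np.empty(p_l)
    fm = np.empty(p_l)
    for i in range(p_l):
        e = np.zeros(p_l)
        e[i] = h[i]
        fp[i] = f(beta_l + e)
        fm[i] = f(beta_l - e)
        hess[i, i] = (fp[i] - 2 * f0 + fm[i]) / h[i] ** 2
    for i in range(p_l):
        for j in range(i + 1, p_l):
            e = np.zeros(p_l)
            e[i], e[j] = h[i], h[j]
            fpp = f(beta_l + e)
            e[i], e[j] = -h[i], -h[j]
            fmm = f(beta_l + e)
            hess[i, j] = hess[j, i] = (
                fpp - fp[i] - fp[j] + 2 * f0 - fm[i] - fm[j] + fmm
            ) / (2 * h[i] * h[j])
    info = -hess
    try:
        cov = sla.inv(info)
        d = np.diag(cov)
        if np.any(d <= 0):
            raise sla.LinAlgError
        return np.sqrt(d)
    except sla.LinAlgError:
        logger.warning("singular lrc information; standard errors reported as NaN")
        return np.full(p_l, np.nan)


def coefficient_tests(model: FittedGrowthModel) -> pd.DataFrame:
    """Per-coefficient (estimate, se, df, t, p) table of a fitted model."""
    return model.coef_table.copy()


def predict_trajectory(
    model: FittedGrowthModel,
    scenario: dict | None = None,
    t_grid=None,
) -> pd.DataFrame:
    """Population-level predicted weight over an age grid for a scenario.

    The scenario fixes covariate values (e.g. {"thi": 67, "sex": "male"});
    covariates it does not mention are filled with their training means,
    following the convention of plotting a response with the other
    explanatory variables held at their means.  Calf age tracks the time
    axis.  Random effects are set to zero.
    """
    if t_grid is None:
        t_grid = np.arange(0.0, 144.0)
    t_grid = np.asarray(t_grid, dtype=float)
    scenario = dict(scenario or {})
    sex = scenario.pop("sex", "female")
    cols = {"sex": sex, TIME_COL: t_grid}
    needed = set()
    for blk in BLOCKS:
        for term in model.spec.block_terms(blk):
            for part in term.split(":"):
                if part not in ("1", "sex"):
                    needed.add(part)
    for name in scenario:
        if name not in needed and name != TIME_COL:
            raise KeyError(f"unknown covariate {name!r} for this model spec")
    for name in needed:
        if name == TIME_COL:
            continue
        cols[name] = scenario.get(name, model.training_means.get(name))
        if cols[name] is None:
            raise KeyError(f"covariate {name!r} not in scenario or training means")
    frame = pd.DataFrame(cols)
    asym, r0, lrc = build_linear_predictors(frame, model.spec, model.params)
    pred = eval_growth(asym, r0, lrc, t_grid)
    return pd.DataFrame({"t": t_grid, "predicted_kg": pred, "sex": sex})


def write_coef_csv(model: FittedGrowthModel, path) -> None:
    model.coef_table.to_csv(path, index=False)


def write_varcomp_csv(model: FittedGrowthModel, path) -> None:
    model.varcomp_table.to_csv(path, index=False)
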