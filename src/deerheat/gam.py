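"""Penalized-regression-spline additive model for mother weight.

Mother weight through lactation has no accepted parametric form, so it is
modelled additively: a parametric intercept and sex-of-calf effect, plus
low-rank penalized spline smooths of calf age, mother age and heat
covariates (basis size k = 3 or 4), factor-by smooths giving each sex its
own deviation curve, and "re" (random-effect) smooths for mother, cohort
and calf identity — factor levels penalized by a multiple of the identity
matrix, which is exactly a Gaussian random intercept with variance
sigma_b^2 = sigma^2 / lambda.

Spline smooths use the cubic-regression-spline basis: k knots at
quantiles of the covariate, cardinal natural-cubic-spline basis
functions, and the integrated-squared-second-derivative penalty
S = D' B^-1 D built from divided differences of the knot spacings, whose
null space spans constants and linears.  Every spline smooth carries a
sum-to-zero constraint (absorbed by reparameterisation, so a k = 3 smooth
contributes two free coefficients) to keep the intercept identifiable.

All smoothing parameters are chosen jointly by restricted maximum
likelihood: for a candidate log-lambda vector the penalized least-squares
fit is computed from precomputed cross-products, and the Gaussian REML
score

    (n - M_p) log(2 pi sigma^2) + ||y - X b||^2/sigma^2 + b'S b/sigma^2
        + log|X'X + S| - log|S|_+

(with sigma^2 profiled out analytically, M_p the dimension of the total
penalty null space) is minimised by quasi-Newton from a few seeded
restarts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.optimize as sopt
from scipy import stats

logger = logging.getLogger(__name__)


class GamError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# bases and penalties


def _crs_matrices(knots):
    """(D, B) divided-difference and bending matrices of a natural cubic spline."""
    h = np.diff(knots)
    k = len(knots)
    d = np.zeros((k - 2, k))
    b = np.zeros((k - 2, k - 2))
    for i in range(k - 2):
        d[i, i] = 1.0 / h[i]
        d[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
        d[i, i + 2] = 1.0 / h[i + 1]
        b[i, i] = (h[i] + h[i + 1]) / 3.0
        if i + 1 < k - 2:
            b[i, i + 1] = b[i + 1, i] = h[i + 1] / 6.0
    return d, b


def _crs_design(x, knots, f_full):
    """Evaluate the cardinal natural-cubic-spline basis at points x.

    `f_full` maps knot values to knot second derivatives (k x k, zero
    first/last rows).  Points beyond the boundary knots are extended
    linearly using the boundary value and slope.
    """
    x = np.asarray(x, dtype=float)
    k = len(knots)
    h = np.diff(knots)
    lo, hi = knots[0], knots[-1]
    xc = np.clip(x, lo, hi)
    j = np.clip(np.searchsorted(knots, xc, side="right") - 1, 0, k - 2)
    xj, hj = knots[j], h[j]
    r = (xc - xj) / hj
    cm = ((1 - r) ** 3 - (1 - r)) * hj**2 / 6.0
    cp = (r**3 - r) * hj**2 / 6.0
    n = len(x)
    out = np.zeros((n, k))
    out[np.arange(n), j] += 1 - r
    out[np.arange(n), j + 1] += r
    out += cm[:, None] * f_full[j] + cp[:, None] * f_full[j + 1]
    # linear extension outside the knot range
    outside = (x < lo) | (x > hi)
    if np.any(outside):
        for side, knot in ((x < lo, lo), (x > hi, hi)):
            idx = np.nonzero(side)[0]
            if idx.size == 0:
                continue
            eps = 1e-6 * (hi - lo)
            b0 = _crs_design(np.array([knot]), knots, f_full)[0]
            b1 = _crs_design(
                np.array([knot + (eps if knot == lo else -eps)]), knots, f_full
            )[0]
            slope = (b1 - b0) / (eps if knot == lo else -eps)
            out[idx] = b0[None, :] + (x[idx] - knot)[:, None] * slope[None, :]
    return out


def spline_basis(x, k):
    """Cubic regression spline basis and curvature penalty on k knots.

    Knots sit at quantiles of x.  Returns (basis, penalty, knots, f_full)
    where basis is n x k, penalty = D'B^-1 D is positive semi-definite
    with a null space spanning constants and linears, and f_full allows
    re-evaluating the basis at new points.
    """
    x = np.asarray(x, dtype=float)
    if k < 3:
        raise GamError("spline basis needs k >= 3")
    ux = np.unique(x)
    if ux.size < k:
        raise GamError(f"need at least k={k} distinct covariate values, got {ux.size}")
    knots = np.quantile(ux, np.linspace(0, 1, k))
    knots = np.unique(knots)
    if len(knots) < k:  # heavy ties at quantiles; fall back to even spread
        knots = np.linspace(ux.min(), ux.max(), k)
    d, b = _crs_matrices(knots)
    f = sla.solve(b, d, assume_a="pos")
    f_full = np.vstack([np.zeros(len(knots)), f, np.zeros(len(knots))])
    basis = _crs_design(x, knots, f_full)
    penalty = d.T @ f
    penalty = 0.5 * (penalty + penalty.T)
    return basis, penalty, knots, f_full


def centering_transform(basis):
    """Sum-to-zero reparameterisation: Z with columns spanning {b: 1'Bb = 0}."""
    c = basis.mean(axis=0)[None, :]
    q, _ = sla.qr(c.T, mode="full")
    return q[:, 1:]  # k x (k-1)


def random_effect_smooth(factor):
    """Indicator basis + identity penalty for a factor ('re' smooth).

    Penalizing the level coefficients with lambda*I is equivalent to a
    Gaussian random intercept with sigma_b^2 = sigma^2/lambda.
    """
    codes, levels = pd.factorize(pd.Series(factor), sort=True)
    if len(levels) < 2:
        raise GamError("random-effect smooth needs a factor with >= 2 levels")
    n = len(codes)
    basis = np.zeros((n, len(levels)))
    basis[np.arange(n), codes] = 1.0
    return basis, np.eye(len(levels)), levels


# ---------------------------------------------------------------------------
# smooth specifications and term builders


@dataclass(frozen=True)
class SmoothSpec:
    """One smooth term: covariate, basis size, and smooth type.

    type: "spline" (centered cubic regression spline), "by" (one centered
    spline per level of `by`), or "re" (random-effect smooth of a factor).
    """

    covariate: str
    k: int = 3
    type: str = "spline"
    by: str | None = None

    def __post_init__(self):
        if self.type not in ("spline", "by", "re"):
            raise ValueError(f"unknown smooth type {self.type!r}")
        if self.type == "by" and not self.by:
            raise ValueError("factor-by smooth needs a 'by' factor")


class _Term:
    """A fitted design block with enough state to rebuild columns at predict."""

    def __init__(self, label, columns, penalty, is_re=False, null_dim=0):
        self.label = label
        self.columns = columns
        self.penalty = penalty
        self.is_re = is_re
        self.null_dim = null_dim
        self.slice = None  # assigned when assembled
        self.null_restrict = None  # set when lambda is pinned at +inf
        ev = np.linalg.eigvalsh(penalty)
        pos = ev[ev > max(ev.max(), 1.0) * 1e-10]
        self.rank = len(pos)
        self.logdet_plus = float(np.sum(np.log(pos)))

    def restrict_to_null_space(self):
        """lambda -> infinity limit: keep only the unpenalized directions.

        The penalized range of the smooth is dropped exactly, so e.g. a
        spline collapses to its linear part and an 're' smooth to nothing.
        """
        ev, vec = np.linalg.eigh(self.penalty)
        null = vec[:, ev < max(ev.max(), 1.0) * 1e-10]
        self.null_restrict = null
        self.columns = self.columns @ null
        self.penalty = np.zeros((null.shape[1], null.shape[1]))
        self.rank = 0
        self.logdet_plus = 0.0

    def predict_columns(self, df):  # pragma: no cover - overridden
        raise NotImplementedError


class _SplineTerm(_Term):
    def __init__(self, label, df, covariate, k, by=None, by_level=None):
        x = df[covariate].to_numpy(dtype=float)
        basis, penalty, knots, f_full = spline_basis(x, k)
        z = centering_transform(basis)
        cols = basis @ z
        pen = z.T @ penalty @ z
        pen = 0.5 * (pen + pen.T)
        self.covariate = covariate
        self.knots = knots
        self.f_full = f_full
        self.z = z
        self.by = by
        self.by_level = by_level
        self.x_range = (x.min(), x.max())
        if by is not None:
            ind = (df[by].astype(str) == str(by_level)).to_numpy(dtype=float)
            cols = cols * ind[:, None]
            # deviation-from-main-effect smooth: penalize the whole block
            # (curvature + ridge) so its linear part is identifiable
            # against the shared main-effect smooth and shrinks to zero
            scale = max(np.trace(pen), 1.0) / pen.shape[0]
            pen = pen + scale * np.eye(pen.shape[0])
        super().__init__(label, cols, pen, is_re=False,
                         null_dim=int(k - 1 - np.linalg.matrix_rank(pen)))

    def predict_columns(self, df):
        x = df[self.covariate].to_numpy(dtype=float)
        lo, hi = self.x_range
        if np.any((x < lo) | (x > hi)):
            warnings.warn(
                f"extrapolating smooth of {self.covariate!r} outside training range",
                stacklevel=2,
            )
        cols = _crs_design(x, self.knots, self.f_full) @ self.z
        if self.by is not None:
            ind = (df[self.by].astype(str) == str(self.by_level)).to_numpy(dtype=float)
            cols = cols * ind[:, None]
        return cols


class _ReTerm(_Term):
    def __init__(self, label, df, covariate):
        basis, pen, levels = random_effect_smooth(df[covariate])
        self.covariate = covariate
        self.levels = levels
        super().__init__(label, basis, pen, is_re=True, null_dim=0)

    def predict_columns(self, df):
        # random-effect smooths are set to zero at prediction time
        return np.zeros((len(df), self.columns.shape[1]))


def by_factor_smooth(df, covariate, factor, k):
    """One centered spline block per factor level (shared knots).

    Each level with fewer than k distinct covariate values raises, naming
    the level.  The shared main-effect smooth is expected to remain in
    the model alongside these deviation blocks.
    """
    levels = sorted(df[factor].astype(str).unique())
    terms = []
    for lev in levels:
        sub = df.loc[df[factor].astype(str) == lev, covariate]
        if sub.nunique() < k:
            raise GamError(
                f"level {lev!r} of {factor!r} has fewer than k={k} distinct "
                f"{covariate!r} values"
            )
        terms.append(
            _SplineTerm(f"{covariate} x {factor} ({lev})", df, covariate, k,
                        by=factor, by_level=lev)
        )
    return terms


# ---------------------------------------------------------------------------
# fitting


@dataclass
class GamFit:
    """Fitted additive model: coefficients, smooth summaries, diagnostics."""

    parametric_table: pd.DataFrame  # term, estimate, se, t, p
    smooth_table: pd.DataFrame  # term, type, coefficients, edf, F, p
    lambdas: dict
    variance_components: dict  # sd of each 're' smooth
    sigma_resid: float
    deviance_explained: float
    aic: float
    reml_score: float
    n_obs: int
    edf_total: float
    reml_trace: list = field(default_factory=list)
    _state: dict = field(default_factory=dict, repr=False)

    @property
    def coefficients(self):
        return self._state["beta"]


def _build_parametric(df, terms):
    cols = [np.ones(len(df))]
    names = ["intercept"]
    for t in terms:
        if t == "sex":
            cols.append((df["sex"].astype(str).str.lower() == "male").to_numpy(float))
            names.append("sex (male)")
        else:
            cols.append(df[t].to_numpy(dtype=float))
            names.append(t)
    return np.column_stack(cols), names


def _expand_smooths(df, smooth_specs):
    terms = []
    for spec in smooth_specs:
        if spec.type == "spline":
            terms.append(_SplineTerm(spec.covariate, df, spec.covariate, spec.k))
        elif spec.type == "re":
            terms.append(_ReTerm(spec.covariate, df, spec.covariate))
        else:
            terms.extend(by_factor_smooth(df, spec.covariate, spec.by, spec.k))
    return terms


def fit_gam(
    records: pd.DataFrame,
    parametric_terms=("sex",),
    smooth_specs=(),
    response: str = "mother_wt_kg",
    fixed_lambdas: dict | None = None,
    n_restarts: int = 3,
    seed: int = 0,
) -> GamFit:
    """Fit the additive model with REML smoothing-parameter selection.

    `fixed_lambdas` maps smooth labels to fixed smoothing parameters
    (useful for oracle comparisons, e.g. lambda -> infinity collapses a
    spline to its linear null space); all other lambdas are optimised.
    """
    y = records[response].to_numpy(dtype=float)
    n = len(y)
    xp, pnames = _build_parametric(records, parametric_terms)
    terms = _expand_smooths(records, smooth_specs)
    fixed_lambdas = dict(fixed_lambdas or {})
    for t in terms:
        if np.isinf(fixed_lambdas.get(t.label, 0.0)):
            t.restrict_to_null_space()
            fixed_lambdas[t.label] = 1.0  # penalty now zero; value inert

    blocks = [xp] + [t.columns for t in terms]
    x = np.hstack(blocks)
    pos = xp.shape[1]
    for t in terms:
        t.slice = slice(pos, pos + t.columns.shape[1])
        pos += t.columns.shape[1]
    q = pos

    xtx = x.T @ x
    xty = x.T @ y
    yty = float(y @ y)
    m_p = xp.shape[1] + sum(t.null_dim for t in terms)

    free = [i for i, t in enumerate(terms) if t.label not in fixed_lambdas]
    lam_full = np.ones(len(terms))
    for i, t in enumerate(terms):
        if t.label in fixed_lambdas:
            lam_full[i] = fixed_lambdas[t.label]

    def assemble_penalty(lam):
        s = np.zeros((q, q))
        logdet_plus = 0.0
        for t, lv in zip(terms, lam):
            s[t.slice, t.slice] += lv * t.penalty
            logdet_plus += t.rank * np.log(lv) + t.logdet_plus
        return s, logdet_plus

    def reml_parts(lam):
        s, logdet_s = assemble_penalty(lam)
        a = xtx + s
        try:
            cho = sla.cho_factor(a, check_finite=False)
        except sla.LinAlgError as exc:
            raise GamError(
                "rank-deficient penalized design; check for aliased columns "
                f"among {pnames + [t.label for t in terms]}"
            ) from exc
        beta = sla.cho_solve(cho, xty, check_finite=False)
        rss = yty - 2 * beta @ xty + beta @ xtx @ beta
        pen = beta @ s @ beta
        rssp = max(rss + pen, 1e-300)
        sig2 = rssp / max(n - m_p, 1)
        logdet_a = 2.0 * np.sum(np.log(np.diag(cho[0])))
        score = (
            (n - m_p) * np.log(2 * np.pi * sig2)
            + rssp / sig2
            + logdet_a
            - logdet_s
        )
        return score, beta, cho, rss, sig2

    trace = []

    def objective(rho_free):
        lam = lam_full.copy()
        lam[free] = np.exp(rho_free)
        try:
            score, *_ = reml_parts(lam)
        except GamError:
            return 1e12
        return score

    if free:
        rng = np.random.default_rng(seed)
        best = None
        starts = [np.zeros(len(free))]
        for _ in range(max(n_restarts - 1, 0)):
            starts.append(rng.normal(0.0, 2.0, size=len(free)))
        for s0 in starts:
            local = []
            res = sopt.minimize(
                objective,
                s0,
                method="L-BFGS-B",
                bounds=[(-20.0, 25.0)] * len(free),
                callback=lambda xk: local.append(float(objective(xk))),
                options={"maxiter": 200, "ftol": 1e-12},
            )
            if res.fun >= 1e12:
                raise GamError(f"REML optimisation failed; trace {local[-5:]}")
            if best is None or res.fun < best.fun - 1e-9:
                best = res
                trace = local
        lam_full[free] = np.exp(best.x)

    score, beta, cho, rss, sig2 = reml_parts(lam_full)

    # effective degrees of freedom: diag of F = (X'X + S)^-1 X'X
    ainv_xtx = sla.cho_solve(cho, xtx, check_finite=False)
    edf_vec = np.diag(ainv_xtx)
    edf_total = float(edf_vec.sum())
    vb = sig2 * sla.cho_solve(cho, np.eye(q), check_finite=False)

    tss = float(((y - y.mean()) ** 2).sum())
    dev_expl = 1.0 - rss / tss if tss > 0 else np.nan
    sig2_ml = rss / n
    loglik = -0.5 * n * (np.log(2 * np.pi * max(sig2_ml, 1e-300)) + 1.0)
    aic = -2.0 * loglik + 2.0 * (edf_total + 1.0)

    prows = []
    for j, name in enumerate(pnames):
        se = float(np.sqrt(max(vb[j, j], 0.0)))
        tval = beta[j] / se if se > 0 else np.nan
        p = 2 * stats.t.sf(abs(tval), max(n - edf_total, 1)) if np.isfinite(tval) else np.nan
        prows.append({"term": name, "estimate": beta[j], "se": se, "t": tval, "p": p})

    srows = []
    lambdas = {}
    varcomp = {}
    for t, lv in zip(terms, lam_full):
        lambdas[t.label] = float("inf") if t.null_restrict is not None else float(lv)
        bj = beta[t.slice]
        vj = vb[t.slice, t.slice]
        edf_j = float(edf_vec[t.slice].sum())
        try:
            if bj.size == 0:
                raise sla.LinAlgError
            fstat = float(bj @ sla.solve(vj, bj, assume_a="pos") / max(edf_j, 1e-8))
        except sla.LinAlgError:
            fstat = np.nan
        pval = (
            float(stats.f.sf(fstat, max(edf_j, 1e-8), max(n - edf_total, 1)))
            if np.isfinite(fstat)
            else np.nan
        )
        if t.is_re and t.null_restrict is None:
            varcomp[t.label] = float(np.sqrt(sig2 / lv))
        srows.append(
            {
                "term": t.label,
                "type": "re" if t.is_re else "spline",
                "coefficients": bj.copy(),
                "edf": edf_j,
                "F": fstat,
                "p": pval,
            }
        )

    return GamFit(
        parametric_table=pd.DataFrame(prows),
        smooth_table=pd.DataFrame(srows),
        lambdas=lambdas,
        variance_components=varcomp,
        sigma_resid=float(np.sqrt(sig2)),
        deviance_explained=float(dev_expl),
        aic=float(aic),
        reml_score=float(score),
        n_obs=n,
        edf_total=edf_total,
        reml_trace=trace,
        _state={
            "beta": beta,
            "vb": vb,
            "terms": terms,
            "pnames": pnames,
            "parametric_terms": tuple(parametric_terms),
            "y_mean": float(y.mean()),
            "training_means": {
                c: float(records[c].mean())
                for c in records.columns
                if records[c].dtype.kind in "if"
            },
        },
    )


def predict_gam(fit: GamFit, scenario: pd.DataFrame, centered: bool = True):
    """Centered predictions with pointwise standard errors on a scenario grid.

    Covariates absent from the scenario are fixed at training means;
    random-effect smooths contribute zero.  When `centered`, the training
    mean response is subtracted (the convention used when plotting a
    response against one covariate).
    """
    st = fit._state
    df = scenario.copy()
    if "sex" not in df.columns:
        df["sex"] = "female"
    for c, m in st["training_means"].items():
        if c not in df.columns:
            df[c] = m
    xp, _ = _build_parametric(df, st["parametric_terms"])
    blocks = [xp]
    for t in st["terms"]:
        cols = t.predict_columns(df)
        if t.null_restrict is not None and cols.shape[1] != t.columns.shape[1]:
            cols = cols @ t.null_restrict
        blocks.append(cols)
    x = np.hstack(blocks)
    pred = x @ st["beta"]
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", x, st["vb"], x), 0.0))
    out = df.copy()
    out["pred"] = pred - (st["y_mean"] if centered else 0.0)
    out["se"] = se
    return out
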