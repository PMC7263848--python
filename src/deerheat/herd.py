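"""Synthetic weather and mother--calf herd generator.

Emulates the design of a 19-cohort captive red deer study: 583
mother--calf pairs from a pool of 150 mothers, births centred on 23 May
(sd 10.2 d), weekly weighing (interval mean 8.2 d, sd 3.52, clipped to
1--22 d) from birth to forced weaning at day 143, mother ages 1--17
(mean 5.9, sd 3.64), and Mediterranean continental weather with July
means near 24.5 degC, 46% humidity and 28 MJ m^-2 solar radiation.

Calf weights are drawn from the exponential-asymptotic mixed growth
model itself (true coefficients default to the fitted-model magnitudes:
asymptote random-intercept sds 5.40 / 5.93 / 8.04 kg for cohort, mother
and calf, residual sd 1.41 kg), so a fit of the generated table is a
direct parameter-recovery experiment.  Mother weight follows a declared
stand-in process: Normal(99, 12) kg baseline at parturition, a mild
mid-lactation rise (~+0.6 kg near day 50) declining to about -2.3 kg by
weaning, a sex-of-calf penalty, a piecewise heat response in THIWS and
Gaussian noise.  All randomness flows from one seed through named
substreams, so adding a generator does not perturb the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import weather as wx
from .growth import GrowthModelSpec, GrowthParams, build_linear_predictors, eval_growth, _growth_s

BIRTH_DOY_MEAN = 143  # 23 May in a non-leap year


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent named RNG substream derived from one top-level seed."""
    key = zlib.crc32(name.encode("utf8"))
    return np.random.default_rng(np.random.SeedSequence(int(seed) % 2**31, spawn_key=(key,)))


@dataclass
class HerdDesign:
    """Study-design parameters of the simulated herd."""

    n_pairs: int = 583
    n_cohorts: int = 19
    n_mothers: int = 150
    start_year: int = 2000
    birth_doy_mean: float = BIRTH_DOY_MEAN
    birth_doy_sd: float = 10.2
    lactation_days: int = 143
    interval_mean: float = 8.2
    interval_sd: float = 3.52
    interval_min: float = 1.0
    interval_max: float = 22.0
    mother_age_mean: float = 5.9
    mother_age_sd: float = 3.64
    mother_age_min: float = 1.0
    mother_age_max: float = 17.0
    sex_ratio: float = 0.5

    def __post_init__(self):
        if min(self.birth_doy_sd, self.interval_sd, self.mother_age_sd) < 0:
            raise ValueError("standard deviations must be >= 0")


#: final-model covariate structure of the calf growth analysis (THI variant)
FINAL_GROWTH_SPEC = GrowthModelSpec(
    asym_terms=("mother_wt_kg", "sex", "mother_age_yr", "calf_age_d", "thi", "thi:sex"),
    r0_terms=("mother_wt_kg", "sex", "mother_age_yr", "calf_age_d"),
    lrc_terms=("mother_wt_kg", "sex", "mother_age_yr", "calf_age_d", "thi", "thi:sex"),
    random_effects=("cohort", "mother", "calf"),
)


def default_growth_truth() -> GrowthParams:
    """Generator truth for the growth process (final-model magnitudes)."""
    return GrowthParams(
        beta_asym=[50.433, 0.299, -0.443, -0.724, -0.169, 0.186, 0.179],
        beta_r0=[6.129, 0.025, 0.683, 0.059, -0.004],
        beta_lrc=[-4.100, -0.001, 0.117, 0.008, -0.001, -0.009, -0.002],
        sigma_groups={"cohort": 5.40, "mother": 5.93, "calf": 8.04},
        sigma_resid=1.41,
    )


@dataclass
class MotherWeightParams:
    """Stand-in process for the mother-weight trajectory (synthetic)."""

    baseline_mean: float = 99.0
    baseline_sd: float = 12.0
    trend_a: float = 0.028856  # kg/day; peaks ~+0.66 kg near day 46
    trend_b: float = -3.1426e-4  # kg/day^2; reaches ~-2.3 kg at day 143
    male_penalty: float = -0.45
    male_extra_decline: float = -0.5  # additional kg by weaning for male calves
    thiws_rise: float = 1.2  # kg gained over THIWS 65 -> 107
    thiws_drop: float = -0.5  # kg lost over THIWS 107 -> 130
    noise_sd: float = 1.5


@dataclass
class TrueParams:
    """Complete generator truth: growth model + mother-weight process."""

    growth_spec: GrowthModelSpec = field(default_factory=lambda: FINAL_GROWTH_SPEC)
    growth: GrowthParams = field(default_factory=default_growth_truth)
    mother: MotherWeightParams = field(default_factory=MotherWeightParams)


def _seasonal(doy, mean, amplitude, peak_doy=201):
    return mean + amplitude * np.cos(2 * np.pi * (np.asarray(doy, float) - peak_doy) / 365.25)


def generate_weather(start_year: int, n_years: int, seed: int = 0,
                     noise_scale: float = 1.0) -> pd.DataFrame:
    """Daily weather over a span of calendar years.

    Sinusoidal annual cycles plus day-level Gaussian noise, calibrated so
    the July means approximate 24.5 degC, 46.2% humidity and
    28.1 MJ m^-2 solar radiation with annual-mean wind near 2.35 m s^-1
    (summer minimum near 1.92).  `noise_scale=0` returns the
    deterministic seasonal curves.
    """
    if n_years < 1:
        raise ValueError("span must cover at least one year")
    rng = substream(seed, "weather")
    dates = pd.date_range(f"{start_year}-01-01", f"{start_year + n_years - 1}-12-31", freq="D")
    doy = dates.dayofyear.to_numpy()
    n = len(dates)
    t_mean = _seasonal(doy, 14.0, 10.6) + noise_scale * rng.normal(0, 2.5, n)
    t_max = t_mean + 8.5 + np.abs(noise_scale * rng.normal(0, 1.5, n))
    hr = np.clip(_seasonal(doy, 64.0, -18.0) + noise_scale * rng.normal(0, 9.0, n), 5.0, 100.0)
    solar = np.clip(_seasonal(doy, 16.6, 11.7) + noise_scale * rng.normal(0, 3.5, n), 0.5, None)
    wind = np.clip(_seasonal(doy, 2.35, -0.43) + noise_scale * rng.normal(0, 0.7, n), 0.1, None)
    return pd.DataFrame(
        {"date": dates, "t_mean": t_mean, "t_max": t_max, "hr": hr,
         "wind": wind, "solar": solar}
    )


def _truncated_normal(rng, mean, sd, lo, hi, size):
    """Rejection sampling from a truncated normal (exact, seeded)."""
    if sd == 0:
        return np.full(size, float(np.clip(mean, lo, hi)))
    out = np.empty(size)
    todo = np.arange(size)
    while todo.size:
        draw = rng.normal(mean, sd, todo.size)
        ok = (draw >= lo) & (draw <= hi)
        out[todo[ok]] = draw[ok]
        todo = todo[~ok]
    return out


def generate_herd(design: HerdDesign, seed: int = 0):
    """Mother--calf pairs and their weighing schedule.

    Returns (pairs, schedule): `pairs` has one row per mother--calf pair
    (calf_id, mother_id, cohort, sex, birth_date, mother_age_yr), with
    pairs spread evenly across cohorts and mothers reused across, but not
    within, cohorts; `schedule` has one row per planned weighing
    (calf_id, date, calf_age_d), starting at birth (day 0) and advancing
    by truncated-normal intervals until the weaning day.
    """
    rng_assign = substream(seed, "herd-assign")
    rng_birth = substream(seed, "herd-birth")
    rng_age = substream(seed, "herd-age")
    rng_sched = substream(seed, "herd-schedule")

    base, extra = divmod(design.n_pairs, design.n_cohorts)
    cohort_sizes = [base + (1 if i < extra else 0) for i in range(design.n_cohorts)]
    mothers = [f"M{i:03d}" for i in range(1, design.n_mothers + 1)]

    rows = []
    calf_no = 0
    for ci, size in enumerate(cohort_sizes):
        year = design.start_year + ci
        if size > design.n_mothers:
            raise ValueError("cohort larger than the mother pool")
        chosen = rng_assign.choice(mothers, size=size, replace=False)
        doys = np.rint(
            _truncated_normal(rng_birth, design.birth_doy_mean, design.birth_doy_sd,
                              32.0, 320.0, size)
        ).astype(int)
        sexes = np.where(rng_assign.random(size) < design.sex_ratio, "male", "female")
        ages = np.rint(
            _truncated_normal(rng_age, design.mother_age_mean, design.mother_age_sd,
                              design.mother_age_min, design.mother_age_max, size)
        )
        for m, doy, sex, age in zip(chosen, doys, sexes, ages):
            calf_no += 1
            rows.append(
                {
                    "calf_id": f"C{calf_no:04d}",
                    "mother_id": m,
                    "cohort": year,
                    "sex": sex,
                    "birth_date": pd.Timestamp(f"{year}-01-01") + pd.Timedelta(days=int(doy) - 1),
                    "mother_age_yr": float(age),
                }
            )
    pairs = pd.DataFrame(
        rows,
        columns=["calf_id", "mother_id", "cohort", "sex", "birth_date", "mother_age_yr"],
    )

    sched_rows = []
    for _, p in pairs.iterrows():
        day = 0
        while day <= design.lactation_days:
            sched_rows.append(
                {"calf_id": p["calf_id"], "date": p["birth_date"] + pd.Timedelta(days=day),
                 "calf_age_d": float(day)}
            )
            step = _truncated_normal(
                rng_sched, design.interval_mean, design.interval_sd,
                design.interval_min, design.interval_max, 1,
            )[0]
            day += max(int(round(step)), 1)
    schedule = pd.DataFrame(sched_rows, columns=["calf_id", "date", "calf_age_d"])
    return pairs, schedule


def _mother_weight_curve(t, thiws, male, mp: MotherWeightParams):
    trend = mp.trend_a * t + mp.trend_b * t**2
    sexeff = np.where(male, mp.male_penalty + mp.male_extra_decline * t / 143.0, 0.0)
    heat = (
        mp.thiws_rise * (np.clip(thiws, 65.0, 107.0) - 65.0) / 42.0
        + mp.thiws_drop * np.clip(thiws - 107.0, 0.0, 23.0) / 23.0
    )
    return trend + sexeff + heat


def simulate_weights(pairs: pd.DataFrame, schedule: pd.DataFrame,
                     exposures: pd.DataFrame, params: TrueParams,
                     seed: int = 0) -> pd.DataFrame:
    """Longitudinal weighing table from the growth model's own structure.

    Draws cohort/mother/calf asymptote intercepts from their Normal laws,
    builds per-event linear predictors from the true coefficient spec,
    evaluates the growth curve plus residual noise, and attaches a
    simulated mother-weight trajectory.  Every scheduled event must carry
    exposure covariates (missing ones raise).
    """
    rng_re = substream(seed, "weights-ranef")
    rng_eps = substream(seed, "weights-resid")
    rng_mom = substream(seed, "weights-mother")

    rec = schedule.merge(pairs, on="calf_id", how="left")
    rec = rec.merge(
        exposures, on=["calf_id", "date"], how="left", suffixes=("", "_exp"),
        validate="one_to_one",
    )
    expo_cols = [c for c in wx.EXPOSURE_VARS if c in rec.columns]
    if rec[expo_cols].isna().any().any():
        bad = rec.loc[rec[expo_cols].isna().any(axis=1), ["calf_id", "date"]]
        raise ValueError(f"missing exposure for events {bad.head(5).to_dict('records')}")

    gp = params.growth
    intercepts = {}
    for g, col in (("cohort", "cohort"), ("mother", "mother_id"), ("calf", "calf_id")):
        sd = gp.sigma_groups.get(g, 0.0)
        levels = sorted(rec[col].unique())
        intercepts[g] = dict(zip(levels, rng_re.normal(0.0, sd, len(levels))))

    male = (rec["sex"] == "male").to_numpy()
    t = rec["calf_age_d"].to_numpy(dtype=float)

    # mother weight first: it is a covariate of the growth truth
    mw_base = {
        m: rng_mom.normal(params.mother.baseline_mean, params.mother.baseline_sd)
        for m in sorted(pairs["mother_id"].unique())
    }
    thiws = rec["thiws"].to_numpy(dtype=float) if "thiws" in rec else np.full(len(rec), 100.0)
    mw = (
        rec["mother_id"].map(mw_base).to_numpy(dtype=float)
        + _mother_weight_curve(t, thiws, male, params.mother)
        + rng_mom.normal(0.0, params.mother.noise_sd, len(rec))
    )
    rec["mother_wt_kg"] = mw

    asym, r0, lrc = build_linear_predictors(rec, params.growth_spec, gp)
    s = _growth_s(lrc, t)
    ran = np.zeros(len(rec))
    for g, col in (("cohort", "cohort"), ("mother", "mother_id"), ("calf", "calf_id")):
        ran += rec[col].map(intercepts[g]).to_numpy(dtype=float)
    y = eval_growth(asym + ran, r0, lrc, t) + rng_eps.normal(0.0, gp.sigma_resid, len(rec))
    # note: random intercepts shift the asymptote, hence scale with s
    rec["calf_wt_kg"] = y

    cols = [
        "calf_id", "mother_id", "cohort", "sex", "date", "birth_date",
        "calf_age_d", "calf_wt_kg", "mother_age_yr", "mother_wt_kg", *expo_cols,
    ]
    return rec[cols]


def validate_weigh_records(df: pd.DataFrame, lactation_days: int = 143) -> pd.DataFrame:
    """Validate a weighing table (ages in range, positive weights, sexes)."""
    required = ["calf_id", "mother_id", "cohort", "sex", "date", "calf_age_d",
                "calf_wt_kg", "mother_age_yr", "mother_wt_kg"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"weighing table missing columns {missing}")
    if len(df) == 0:
        return df
    if not df["sex"].astype(str).str.lower().isin(["female", "male"]).all():
        raise ValueError("sex must be 'female' or 'male'")
    ages = df["calf_age_d"].to_numpy(dtype=float)
    if np.any((ages < 0) | (ages > lactation_days)):
        raise ValueError(f"calf ages outside [0, {lactation_days}]")
    if np.any(df["calf_wt_kg"].to_numpy(dtype=float) <= 0):
        raise ValueError("non-positive calf weights")
    if np.any(df["mother_wt_kg"].to_numpy(dtype=float) <= 0):
        raise ValueError("non-positive mother weights")
    return df


def simulate_study(design: HerdDesign | None = None,
                   params: TrueParams | None = None,
                   seed: int = 0,
                   exposure_mode: str = "interval-mean"):
    """Full synthetic study: weather, herd, exposures and weights.

    Returns (weather_with_indices, records, manifest).  The weather span
    covers every cohort year plus the following January in case a late
    birth pushes lactation past the new year.
    """
    design = design or HerdDesign()
    params = params or TrueParams()
    weather = generate_weather(design.start_year, design.n_cohorts + 1, seed=seed)
    weather = wx.add_indices(wx.validate_weather(weather))
    pairs, schedule = generate_herd(design, seed=seed)
    if len(pairs) == 0:
        records = pd.DataFrame(
            columns=["calf_id", "mother_id", "cohort", "sex", "date", "birth_date",
                     "calf_age_d", "calf_wt_kg", "mother_age_yr", "mother_wt_kg",
                     *wx.EXPOSURE_VARS]
        )
    else:
        events = schedule.merge(pairs[["calf_id", "birth_date"]], on="calf_id")
        exposures = wx.assign_exposure(events, weather, mode=exposure_mode)
        records = simulate_weights(
            pairs, schedule,
            exposures[["calf_id", "date", *wx.EXPOSURE_VARS]],
            params, seed=seed,
        )
    manifest = {
        "seed": int(seed),
        "exposure_mode": exposure_mode,
        "design": asdict(design),
        "true_params": {
            "growth_spec": {
                "asym_terms": list(params.growth_spec.asym_terms),
                "r0_terms": list(params.growth_spec.r0_terms),
                "lrc_terms": list(params.growth_spec.lrc_terms),
                "random_effects": list(params.growth_spec.random_effects),
            },
            "beta_asym": params.growth.beta_asym.tolist(),
            "beta_r0": params.growth.beta_r0.tolist(),
            "beta_lrc": params.growth.beta_lrc.tolist(),
            "sigma_groups": params.growth.sigma_groups,
            "sigma_resid": params.growth.sigma_resid,
            "mother_weight_standin": asdict(params.mother),
        },
        "n_records": int(len(records)),
    }
    return weather, records, manifest
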