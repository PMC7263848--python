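"""Daily weather ingestion, heat-stress indices and exposure assignment.

The two indices implemented here are the classical temperature--humidity
index (THI), which combines daily mean air temperature T (degC) and relative
humidity Hr (%),

    THI = 0.8*T + 0.01*Hr*(T - 14.4) + 46.4,

and its extension THIWS, which adds convective cooling by wind speed
W (m s^-1) and radiative heat load by accumulated solar radiation
SR (MJ m^-2 per day),

    THIWS = 4.51 + THI - 1.992*W + 1.887*SR.

Both are dimensionless.  The module also summarises a daily series into
monthly climatologies, extracts index quantiles used as prediction
scenarios, and averages daily conditions over the interval between
successive weighings of a calf ("exposure assignment").
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

WEATHER_COLUMNS = ["date", "t_mean", "t_max", "hr", "wind", "solar"]

#: physical-environment variables carried through exposure assignment
EXPOSURE_VARS = ["t_mean", "hr", "wind", "solar", "thi", "thiws"]


class WeatherValidationError(ValueError):
    """Raised when a daily weather record violates its physical bounds."""


def compute_thi(t, hr):
    """Temperature--humidity index from daily mean temperature and humidity.

    Parameters
    ----------
    t : array_like
        Daily mean air temperature, degC.
    hr : array_like
        Daily mean relative humidity, % in [0, 100].

    Returns
    -------
    ndarray or float
        Dimensionless THI.  At T = 14.4 degC the humidity term vanishes.
    """
    t = np.asarray(t, dtype=float)
    hr = np.asarray(hr, dtype=float)
    if np.any((hr < 0) | (hr > 100)):
        bad = np.atleast_1d(hr)
        idx = np.nonzero((bad < 0) | (bad > 100))[0]
        raise WeatherValidationError(
            f"relative humidity outside [0, 100] at positions {idx.tolist()}"
        )
    out = 0.8 * t + 0.01 * hr * (t - 14.4) + 46.4
    return out if out.ndim else float(out)


def compute_thiws(thi, w, sr):
    """Wind- and radiation-adjusted heat index.

    Parameters
    ----------
    thi : array_like
        Temperature--humidity index.
    w : array_like
        Daily mean wind speed, m s^-1, >= 0.
    sr : array_like
        Accumulated daily solar radiation, MJ m^-2, >= 0.
    """
    thi = np.asarray(thi, dtype=float)
    w = np.asarray(w, dtype=float)
    sr = np.asarray(sr, dtype=float)
    if np.any(w < 0):
        raise WeatherValidationError("negative wind speed")
    if np.any(sr < 0):
        raise WeatherValidationError("negative solar radiation")
    out = 4.51 + thi - 1.992 * w + 1.887 * sr
    return out if out.ndim else float(out)


def validate_weather(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a daily weather table and return it sorted by date.

    Requires one record per calendar day, strictly increasing dates,
    Hr in [0, 100], W >= 0, SR >= 0 and, when present, t_max >= t_mean.
    """
    missing = [c for c in WEATHER_COLUMNS if c not in df.columns and c != "t_max"]
    if missing:
        raise WeatherValidationError(f"weather table missing columns {missing}")
    df = df.copy()
    df["date"] = pd.to_datetime(df["date"])
    df = df.sort_values("date").reset_index(drop=True)
    if df["date"].duplicated().any():
        dups = df.loc[df["date"].duplicated(), "date"].dt.date.tolist()
        raise WeatherValidationError(f"duplicate weather dates {dups[:5]}")
    bad_hr = df.index[(df["hr"] < 0) | (df["hr"] > 100)]
    if len(bad_hr):
        d = df.loc[bad_hr[0], "date"].date()
        raise WeatherValidationError(f"humidity out of [0,100] on {d}")
    bad_w = df.index[df["wind"] < 0]
    if len(bad_w):
        raise WeatherValidationError(
            f"negative wind speed on {df.loc[bad_w[0], 'date'].date()}"
        )
    bad_sr = df.index[df["solar"] < 0]
    if len(bad_sr):
        raise WeatherValidationError(
            f"negative solar radiation on {df.loc[bad_sr[0], 'date'].date()}"
        )
    if "t_max" in df.columns and df["t_max"].notna().any():
        bad = df.index[df["t_max"].notna() & (df["t_max"] < df["t_mean"])]
        if len(bad):
            raise WeatherValidationError(
                f"t_max < t_mean on {df.loc[bad[0], 'date'].date()}"
            )
    return df


def read_weather_csv(path) -> pd.DataFrame:
    """Read and validate a daily weather CSV (`date,t_mean,t_max,hr,wind,solar`)."""
    return validate_weather(pd.read_csv(path))


def add_indices(weather: pd.DataFrame) -> pd.DataFrame:
    """Append `thi` and `thiws` columns to a validated weather table."""
    out = weather.copy()
    out["thi"] = compute_thi(out["t_mean"].to_numpy(), out["hr"].to_numpy())
    out["thiws"] = compute_thiws(
        out["thi"].to_numpy(), out["wind"].to_numpy(), out["solar"].to_numpy()
    )
    return out


def write_indices_csv(weather: pd.DataFrame, path) -> None:
    df = weather[["date", "thi", "thiws"]].copy()
    df["date"] = pd.to_datetime(df["date"]).dt.strftime("%Y-%m-%d")
    df.to_csv(path, index=False)


def monthly_summary(weather: pd.DataFrame, variables=None) -> pd.DataFrame:
    """Across-year monthly climatology: mean and SE of monthly means and maxima.

    For each calendar month and variable the per-year monthly mean and
    monthly maximum are computed, then averaged across the years that
    contain at least one day in that month; the SE uses n = number of
    contributing years (SE = 0 with a warning when a single year
    contributes).  Output is long format:
    `month,variable,stat,mean,se,n_years` with stat in {mean, max}.
    """
    if variables is None:
        variables = [c for c in weather.columns if c not in ("date",)]
    df = weather.copy()
    df["date"] = pd.to_datetime(df["date"])
    df["_year"] = df["date"].dt.year
    df["_month"] = df["date"].dt.month
    rows = []
    single_year_months = []
    for month in range(1, 13):
        sub = df[df["_month"] == month]
        if sub.empty:
            logger.warning("no weather days in month %d; omitted from summary", month)
            continue
        per_year = sub.groupby("_year")[list(variables)].agg(["mean", "max"])
        n_years = len(per_year)
        if n_years == 1:
            single_year_months.append(month)
        for var in variables:
            for stat in ("mean", "max"):
                vals = per_year[(var, stat)].to_numpy(dtype=float)
                se = 0.0 if n_years == 1 else float(np.std(vals, ddof=1) / np.sqrt(n_years))
                rows.append(
                    {
                        "month": month,
                        "variable": var,
                        "stat": stat,
                        "mean": float(np.mean(vals)),
                        "se": se,
                        "n_years": n_years,
                    }
                )
    if single_year_months:
        warnings.warn(
            f"single contributing year in months {single_year_months}; SE reported as 0",
            stacklevel=2,
        )
    return pd.DataFrame(rows)


def index_quantiles(values, probs) -> np.ndarray:
    """Quantiles of pooled index values, used as prediction scenarios.

    Uses linear interpolation of order statistics (numpy's default
    convention).  `probs` must lie strictly inside (0, 1).
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("empty pooled set: no index values to take quantiles of")
    probs = np.atleast_1d(np.asarray(probs, dtype=float))
    if np.any((probs <= 0) | (probs >= 1)):
        raise ValueError("quantile probabilities must lie in (0, 1)")
    return np.quantile(values, probs)


def _fill_short_gaps(daily: pd.DataFrame, max_gap: int = 3) -> pd.DataFrame:
    """Reindex to a full daily calendar, interpolating gaps of <= max_gap days."""
    daily = daily.set_index("date")
    full = pd.date_range(daily.index.min(), daily.index.max(), freq="D")
    if len(full) == len(daily):
        return daily
    re = daily.reindex(full)
    isna = re.iloc[:, 0].isna().to_numpy()
    # locate runs of missing days
    run = 0
    for flag in isna:
        run = run + 1 if flag else 0
        if run > max_gap:
            missing = re.index[isna].date.tolist()
            raise WeatherValidationError(
                f"weather gap longer than {max_gap} days; missing dates include "
                f"{missing[:6]}"
            )
    re = re.interpolate(method="time", limit_area="inside")
    re.index.name = "date"
    return re


@dataclass
class ExposureWindow:
    """Half-open exposure interval (start, end] for one weighing event."""

    start: pd.Timestamp
    end: pd.Timestamp
    n_days: int


def assign_exposure(
    events: pd.DataFrame,
    daily: pd.DataFrame,
    mode: str = "interval-mean",
    fixed_window: int = 7,
) -> pd.DataFrame:
    """Assign per-weighing heat-exposure covariates from the daily series.

    Modes
    -----
    ``same-day``
        The weighing day's values verbatim.
    ``interval-mean`` (default)
        Mean over the days since the calf's previous weighing: the window
        is (previous weighing date, weighing date], anchored at the birth
        date (inclusive) for the first weighing.  Body-weight change
        integrates conditions since the last measurement, hence the default.
    ``fixed-window``
        Mean over the `fixed_window` days ending on the weighing date.

    `events` needs columns calf_id, date and (for interval-mean) birth_date;
    `daily` must carry the EXPOSURE_VARS columns plus date.  Returns the
    events with exposure means, window bounds and n_days appended.
    """
    if mode not in ("same-day", "interval-mean", "fixed-window"):
        raise ValueError(f"unknown exposure mode {mode!r}")
    daily = daily.copy()
    daily["date"] = pd.to_datetime(daily["date"])
    cols = [c for c in EXPOSURE_VARS if c in daily.columns]
    grid = _fill_short_gaps(daily[["date", *cols]])
    events = events.copy()
    events["date"] = pd.to_datetime(events["date"])

    missing = events.loc[
        (events["date"] < grid.index.min()) | (events["date"] > grid.index.max()),
        "date",
    ]
    if len(missing):
        raise WeatherValidationError(
            "weighing dates outside weather coverage: "
            f"{sorted(set(missing.dt.date))[:6]}"
        )

    arr = grid[cols].to_numpy(dtype=float)
    # prefix sums over the daily calendar -> O(1) window means
    csum = np.vstack([np.zeros(arr.shape[1]), np.cumsum(arr, axis=0)])
    day0 = grid.index.min()
    pos = (events["date"] - day0).dt.days.to_numpy()

    if mode == "same-day":
        start_pos = pos
    elif mode == "fixed-window":
        start_pos = np.maximum(pos - fixed_window + 1, 0)
    else:
        events = events.sort_values(["calf_id", "date"], kind="stable")
        pos = (events["date"] - day0).dt.days.to_numpy()
        prev = events.groupby("calf_id")["date"].shift()
        if "birth_date" in events.columns:
            birth = pd.to_datetime(events["birth_date"])
            prev = prev.fillna(birth - pd.Timedelta(days=1))
        else:
            prev = prev.fillna(events["date"] - pd.Timedelta(days=1))
        start_pos = np.maximum((prev - day0).dt.days.to_numpy() + 1, 0)
        start_pos = np.minimum(start_pos, pos)

    means = (csum[pos + 1] - csum[start_pos]) / (pos - start_pos + 1)[:, None]
    out = events.reset_index(drop=True)
    for j, c in enumerate(cols):
        out[c] = means[:, j]
    out["window_start"] = day0 + pd.to_timedelta(start_pos, unit="D")
    out["window_end"] = out["date"]
    out["n_days"] = pos - start_pos + 1
    return out
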