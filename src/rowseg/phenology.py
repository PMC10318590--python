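"""Thermal time (growing degree days) and growth-stage assignment.

Daily GDD uses a 10 degC base with both temperatures capped into [10, 30] degC
before averaging, so a single day contributes between 0 and 20 GDD.  Cumulative
GDD from planting aligns flights across years into three growth-stage windows:
vegetative [0, 650), flowering [650, 900), grain filling [900, inf).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DataError

BASE_TEMP_C = 10.0
CAP_TEMP_C = 30.0

#: Half-open GDD windows; a boundary value belongs to the later stage.
STAGE_WINDOWS: dict[str, tuple[float, float]] = {
    "vegetative": (0.0, 650.0),
    "flowering": (650.0, 900.0),
    "grain_filling": (900.0, np.inf),
}


def daily_gdd(t_max: float, t_min: float) -> float:
    """GDD accumulated on one day from its max/min temperature (degC).

    Both temperatures are clamped into [10, 30] degC, then
    ``(t_max + t_min)/2 - 10``.

    Raises
    ------
    DataError
        If ``t_max < t_min``.
    """
    t_max = np.asarray(t_max, dtype=float)
    t_min = np.asarray(t_min, dtype=float)
    if np.any(t_max < t_min):
        raise DataError("daily_gdd: t_max < t_min")
    hi = np.clip(t_max, BASE_TEMP_C, CAP_TEMP_C)
    lo = np.clip(t_min, BASE_TEMP_C, CAP_TEMP_C)
    out = (hi + lo) / 2.0 - BASE_TEMP_C
    return float(out) if out.ndim == 0 else out


def cumulative_gdd(weather: pd.DataFrame, planting_date, flight_date) -> float:
    """Sum of daily GDD from planting through flight date, both inclusive.

    ``weather`` needs columns ``date``, ``tmax_c``, ``tmin_c`` with one row per
    day; a gap inside the interval raises :class:`DataError` naming the missing
    date.
    """
    planting_date = pd.Timestamp(planting_date)
    flight_date = pd.Timestamp(flight_date)
    if flight_date < planting_date:
        raise DataError("cumulative_gdd: flight_date precedes planting_date")
    dates = pd.to_datetime(weather["date"])
    sel = weather.loc[(dates >= planting_date) & (dates <= flight_date)]
    expected = pd.date_range(planting_date, flight_date, freq="D")
    have = set(pd.to_datetime(sel["date"]))
    for d in expected:
        if d not in have:
            raise DataError(f"cumulative_gdd: weather series missing {d.date()}")
    vals = daily_gdd(sel["tmax_c"].to_numpy(), sel["tmin_c"].to_numpy())
    return float(np.sum(vals))


def assign_stage(gdd: float) -> str:
    """Growth-stage name for a cumulative GDD value (half-open windows)."""
    if gdd < 0:
        raise DataError("assign_stage: gdd must be >= 0")
    for name, (lo, hi) in STAGE_WINDOWS.items():
        if lo <= gdd < hi:
            return name
    raise AssertionError("unreachable: windows cover [0, inf)")


def synthesize_weather(
    start_date,
    n_days: int,
    t_max: float = 28.0,
    t_min: float = 16.0,
    rng: np.random.Generator | None = None,
    daily_sd: float = 2.0,
) -> pd.DataFrame:
    """Simple stationary weather series for synthetic trials (12 GDD/day mean)."""
    dates = pd.date_range(pd.Timestamp(start_date), periods=n_days, freq="D")
    if rng is None:
        tmax = np.full(n_days, t_max)
        tmin = np.full(n_days, t_min)
    else:
        shift = rng.normal(0.0, daily_sd, size=n_days)
        tmax = t_max + shift
        tmin = t_min + shift  # shared shift keeps t_max >= t_min
    return pd.DataFrame({"date": dates, "tmax_c": tmax, "tmin_c": tmin})
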