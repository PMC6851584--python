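"""Winter climate-change indicator classification and counting.

A "winter" is the dormant season 1 November - 31 May, labeled by the
calendar year in which it ends (Nov 2000 - May 2001 is winter 2001). Each
day is classified against twelve threshold indicators:

===================  =============================================
thaw                 tmax > 0 degC
ice                  tmax < 0 degC
frost                tmin < 0 degC
extreme_cold         tmin < -18 degC (also Pine Beetle Kill Day)
hwa_kill             tmin < -30 degC (Hemlock Woolly Adelgid Kill Day)
snowmaking           tmin < -5 degC (also Mosquito Kill Day); additionally
                     counted before 25 Dec and through 28 Feb
snow_covered         modeled SWE > 0 mm
bare_ground          modeled SWE = 0 mm
rain_on_snow         liquid precipitation > 0 mm and SWE > 0 mm
frozen_ground        tmax < 0 degC and SWE = 0 mm (Bare Ground Ice Day)
mud                  tmax > 0 degC and SWE = 0 mm (Bare Ground Thaw Day)
===================  =============================================

All inequalities are strict. A day whose required inputs are missing is
*undefined* for that indicator and excluded from both the count and that
indicator's valid-day denominator; counts are raw day counts, never rescaled
to a standard winter length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .snow_model import SnowParams, partition_precipitation
from .station_io import StationSeries, require_valid

#: indicator -> denominator group
INDICATORS: dict[str, str] = {
    "thaw": "tmax",
    "ice": "tmax",
    "frost": "tmin",
    "extreme_cold": "tmin",
    "hwa_kill": "tmin",
    "snowmaking": "tmin",
    "snowmaking_before_dec25": "tmin",
    "snowmaking_before_feb28": "tmin",
    "snow_covered": "swe",
    "bare_ground": "swe",
    "rain_on_snow": "rain_swe",
    "frozen_ground": "tmax_swe",
    "mud": "tmax_swe",
}

#: aliases used in reports; both names refer to the same counted series
ALIASES = {
    "pine_beetle_kill": "extreme_cold",
    "mosquito_kill": "snowmaking",
    "bare_ground_ice": "frozen_ground",
    "bare_ground_thaw": "mud",
}

DENOM_GROUPS = ("tmax", "tmin", "swe", "rain_swe", "tmax_swe")


@dataclass(frozen=True)
class ThresholdConfig:
    """Indicator thresholds and window boundaries (degC, mm, dates)."""

    t_thaw: float = 0.0  # tmax strictly above
    t_ice: float = 0.0  # tmax strictly below
    t_frost: float = 0.0  # tmin strictly below
    t_extreme_cold: float = -18.0
    t_hwa_kill: float = -30.0
    t_snowmaking: float = -5.0
    snow_cover_mm: float = 0.0  # swe strictly above
    christmas_month_day: tuple[int, int] = (12, 25)  # exclusive cutoff
    february_month_day: tuple[int, int] = (2, 28)  # inclusive cutoff
    winter_start: tuple[int, int] = (11, 1)
    winter_end: tuple[int, int] = (5, 31)

    def __post_init__(self) -> None:
        if not (
            self.t_hwa_kill
            < self.t_extreme_cold
            < self.t_snowmaking
            < self.t_frost
        ):
            raise ValueError(
                "cold thresholds must nest: hwa < extreme_cold < snowmaking < frost"
            )


DEFAULT_THRESHOLDS = ThresholdConfig()


def assign_winter(date) -> int | None:
    """Map a calendar date to its winter label (ending year), or None.

    Nov/Dec belong to the winter ending next year; Jan-May to the winter
    ending this year; Jun-Oct to no winter.
    """
    ts = pd.Timestamp(date)
    if ts.month >= 11:
        return ts.year + 1
    if ts.month <= 5:
        return ts.year
    return None


def assign_winters(dates: pd.DatetimeIndex) -> np.ndarray:
    """Vectorized :func:`assign_winter`; NaN for out-of-window dates."""
    month = dates.month.to_numpy()
    year = dates.year.to_numpy().astype(float)
    out = np.where(month >= 11, year + 1, np.where(month <= 5, year, np.nan))
    return out


def winter_window_index(winter_year: int) -> pd.DatetimeIndex:
    """All calendar dates of one winter (1 Nov - 31 May; 212 or 213 days)."""
    return pd.date_range(
        start=pd.Timestamp(winter_year - 1, 11, 1),
        end=pd.Timestamp(winter_year, 5, 31),
        freq="D",
    )


def classify_day(
    tmin: float,
    tmax: float,
    swe: float,
    rain: float,
    thr: ThresholdConfig = DEFAULT_THRESHOLDS,
) -> dict[str, bool | None]:
    """Classify one day; missing inputs (NaN) yield None for dependent flags.

    ``rain`` is the liquid component of that day's precipitation (from
    :func:`winterclim.snow_model.partition_precipitation`); ``swe`` the
    modeled snow water equivalent.
    """

    def _flag(value, *inputs):
        return None if any(np.isnan(x) for x in inputs) else bool(value)

    tmin = float(tmin) if tmin is not None else np.nan
    tmax = float(tmax) if tmax is not None else np.nan
    swe = float(swe) if swe is not None else np.nan
    rain = float(rain) if rain is not None else np.nan
    snow_cov = swe > thr.snow_cover_mm
    bare = swe <= thr.snow_cover_mm
    return {
        "thaw": _flag(tmax > thr.t_thaw, tmax),
        "ice": _flag(tmax < thr.t_ice, tmax),
        "frost": _flag(tmin < thr.t_frost, tmin),
        "extreme_cold": _flag(tmin < thr.t_extreme_cold, tmin),
        "hwa_kill": _flag(tmin < thr.t_hwa_kill, tmin),
        "snowmaking": _flag(tmin < thr.t_snowmaking, tmin),
        "snow_covered": _flag(snow_cov, swe),
        "bare_ground": _flag(bare, swe),
        "rain_on_snow": _flag(rain > 0 and snow_cov, rain, swe),
        "frozen_ground": _flag(tmax < thr.t_ice and bare, tmax, swe),
        "mud": _flag(tmax > thr.t_thaw and bare, tmax, swe),
    }


def classify_days(
    series: StationSeries,
    swe: pd.DataFrame | None = None,
    thr: ThresholdConfig = DEFAULT_THRESHOLDS,
    snow_params: SnowParams = SnowParams(),
) -> pd.DataFrame:
    """Vectorized day classification over a whole series.

    Returns a nullable-boolean frame (pd.NA = undefined) with one column per
    base indicator, indexed like the series. ``swe`` is the output of
    :func:`winterclim.snow_model.simulate_swe`; pass None when no snow model
    is available, leaving snow indicators undefined.
    """
    df = series.data
    tmin = df["tmin"].to_numpy()
    tmax = df["tmax"].to_numpy()
    tavg = (tmin + tmax) / 2.0
    rain, _ = partition_precipitation(tavg, df["prcp"].to_numpy(), snow_params)

    if swe is None:
        swe_vals = np.full(len(df), np.nan)
    else:
        if not swe.index.equals(df.index):
            raise ValueError("swe series does not align with station dates")
        swe_vals = np.where(
            swe["defined"].to_numpy(), swe["swe"].to_numpy(), np.nan
        )

    def masked(cond: np.ndarray, *inputs: np.ndarray) -> pd.arrays.BooleanArray:
        undef = np.zeros(len(cond), dtype=bool)
        for x in inputs:
            undef |= np.isnan(x)
        return pd.arrays.BooleanArray(cond & ~undef, undef)

    snow_cov = swe_vals > thr.snow_cover_mm
    bare = ~snow_cov
    out = pd.DataFrame(
        {
            "thaw": masked(tmax > thr.t_thaw, tmax),
            "ice": masked(tmax < thr.t_ice, tmax),
            "frost": masked(tmin < thr.t_frost, tmin),
            "extreme_cold": masked(tmin < thr.t_extreme_cold, tmin),
            "hwa_kill": masked(tmin < thr.t_hwa_kill, tmin),
            "snowmaking": masked(tmin < thr.t_snowmaking, tmin),
            "snow_covered": masked(snow_cov, swe_vals),
            "bare_ground": masked(bare, swe_vals),
            "rain_on_snow": masked((rain > 0) & snow_cov, rain, swe_vals),
            "frozen_ground": masked((tmax < thr.t_ice) & bare, tmax, swe_vals),
            "mud": masked((tmax > thr.t_thaw) & bare, tmax, swe_vals),
        },
        index=df.index,
    )
    return out


def _window_masks(dates: pd.DatetimeIndex, thr: ThresholdConfig):
    """Boolean masks for the snowmaking count windows."""
    month = dates.month.to_numpy()
    day = dates.day.to_numpy()
    cm, cd = thr.christmas_month_day
    # strictly before 25 Dec: only Nov/Dec days qualify
    before_xmas = (month >= 11) & ((month < cm) | ((month == cm) & (day < cd)))
    fm, fd = thr.february_month_day
    # through 28 Feb inclusive: Nov-Dec plus Jan/Feb up to the cutoff
    before_feb = (
        (month >= 11)
        | (month < fm)
        | ((month == fm) & (day <= fd))
    )
    return before_xmas, before_feb


def count_winter_indicators(
    flags: pd.DataFrame,
    thr: ThresholdConfig = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Aggregate day flags into per-winter counts and denominators.

    One row per winter (index = winter ending year). Each indicator column
    holds the number of days the flag was True; ``den_<group>`` columns hold
    the number of days the group's inputs were defined. An indicator whose
    denominator is zero is reported missing (pd.NA), never zero. Duplicate
    dates raise.
    """
    if flags.index.duplicated().any():
        raise ValueError("duplicate dates in day flags")
    winters = assign_winters(flags.index)
    in_winter = ~np.isnan(winters)
    flags = flags.loc[in_winter]
    winters = winters[in_winter].astype(int)
    before_xmas, before_feb = _window_masks(flags.index, thr)

    cols: dict[str, pd.Series] = {}
    group = pd.Index(winters, name="winter_year")
    base = [c for c in INDICATORS if c in flags.columns]
    for name in base:
        vals = flags[name]
        cols[name] = vals.fillna(False).astype(int).groupby(group).sum()
    sm = flags["snowmaking"]
    cols["snowmaking_before_dec25"] = (
        (sm.fillna(False) & before_xmas).astype(int).groupby(group).sum()
    )
    cols["snowmaking_before_feb28"] = (
        (sm.fillna(False) & before_feb).astype(int).groupby(group).sum()
    )
    den_members = {
        "tmax": "thaw",
        "tmin": "frost",
        "swe": "snow_covered",
        "rain_swe": "rain_on_snow",
        "tmax_swe": "mud",
    }
    for grp, member in den_members.items():
        cols[f"den_{grp}"] = (
            flags[member].notna().astype(int).groupby(group).sum()
        )

    out = pd.DataFrame(cols)
    # zero-denominator counts are unknown, not zero
    for name, grp in INDICATORS.items():
        if name in out.columns:
            out[name] = out[name].astype("Int64")
            out.loc[out[f"den_{grp}"] == 0, name] = pd.NA
    out.index.name = "winter_year"
    return out


def build_indicator_matrix(
    series: StationSeries,
    swe: pd.DataFrame | None = None,
    validity: pd.DataFrame | None = None,
    thr: ThresholdConfig = DEFAULT_THRESHOLDS,
    snow_params: SnowParams = SnowParams(),
) -> pd.DataFrame:
    """Per-winter indicator counts for one station (rows = winters).

    ``validity`` is the per-winter QC verdict frame from
    :func:`winterclim.qc_gapfill.screen_completeness`; winters failing QC
    for temperature have all temperature-dependent indicators masked, and
    winters failing for precipitation have rain-on-snow masked. Only winters
    present in ``validity`` (when given) are returned.
    """
    require_valid(series)
    flags = classify_days(series, swe=swe, thr=thr, snow_params=snow_params)
    counts = count_winter_indicators(flags, thr=thr)
    if validity is not None:
        validity = validity.set_index("winter_year")
        counts = counts.loc[counts.index.isin(validity.index)]
        bad_temp = validity["valid_temp"].reindex(counts.index) == False  # noqa: E712
        bad_prcp = validity["valid_prcp"].reindex(counts.index) == False  # noqa: E712
        temp_cols = [
            c for c, g in INDICATORS.items() if g in ("tmin", "tmax", "tmax_swe")
        ]
        counts.loc[bad_temp.to_numpy(), temp_cols] = pd.NA
        counts.loc[
            (bad_temp | bad_prcp).to_numpy(), ["rain_on_snow"]
        ] = pd.NA
    return counts
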