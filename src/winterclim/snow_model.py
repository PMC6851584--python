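"""Degree-day (temperature-index) snow water equivalent model.

Daily snow accumulation and melt driven by mean temperature
``tavg = (tmin + tmax) / 2`` and precipitation. Precipitation phase is a
linear mix between an all-snow threshold ``t_snow`` and an all-rain
threshold ``t_rain``; melt is proportional to degrees above ``t_melt`` with
factor ``ddf`` (mm per degree-day); a small liquid store (rain plus
meltwater, capped at ``retain_frac`` of the pack) can refreeze on cold days.
Mass is conserved exactly: on every step,
``delta(swe + liquid) = snow + rain_in - runoff``.

The modeled SWE series replaces sparse observed snow depth for all
snow-cover indicators; "snow covered" downstream means modeled SWE above a
configurable trace threshold (default 0, i.e. strictly positive SWE).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import product

import numpy as np
import pandas as pd

from .station_io import StationSeries


class CalibrationError(RuntimeError):
    """No usable observed snow-depth days to calibrate against."""


@dataclass(frozen=True)
class SnowParams:
    """Degree-day model parameters.

    Defaults are central literature values for temperature-index snow
    models on daily data; all are configurable and :func:`calibrate_snow_params`
    can refit them against observed snow depth.
    """

    t_rain: float = 2.0  # degC, at/above: all rain
    t_snow: float = 0.0  # degC, at/below: all snow
    t_melt: float = 0.0  # degC, melt base
    ddf: float = 2.5  # mm/degC/day
    retain_frac: float = 0.05  # liquid holding capacity, fraction of SWE
    refreeze_factor: float = 1.0  # mm/degC/day

    def __post_init__(self) -> None:
        if self.t_snow > self.t_rain:
            raise ValueError("t_snow must be <= t_rain")
        if self.ddf <= 0:
            raise ValueError("ddf must be > 0")
        if not 0.0 <= self.retain_frac <= 1.0:
            raise ValueError("retain_frac must be in [0, 1]")
        if self.refreeze_factor < 0:
            raise ValueError("refreeze_factor must be >= 0")


@dataclass
class SweState:
    """Snowpack state: frozen water (swe) and retained liquid, both mm."""

    swe: float = 0.0
    liquid: float = 0.0


@dataclass
class DayFluxes:
    snow: float
    rain: float
    melt: float
    refreeze: float
    runoff: float


def partition_precipitation(tavg, prcp, params: SnowParams = SnowParams()):
    """Split precipitation into (rain, snow) mm by daily mean temperature.

    All snow at/below ``t_snow``, all rain at/above ``t_rain``, linear mix
    between; rain + snow == prcp exactly. Accepts scalars or arrays; NaN
    temperature yields NaN in both outputs.
    """
    tavg = np.asarray(tavg, dtype=float)
    prcp = np.asarray(prcp, dtype=float)
    if params.t_rain == params.t_snow:
        frac_snow = np.where(tavg <= params.t_snow, 1.0, 0.0)
    else:
        frac_snow = np.clip(
            (params.t_rain - tavg) / (params.t_rain - params.t_snow), 0.0, 1.0
        )
    frac_snow = np.where(np.isnan(tavg), np.nan, frac_snow)
    snow = frac_snow * prcp
    rain = prcp - snow
    if rain.ndim == 0:
        return float(rain), float(snow)
    return rain, snow


def step_swe(
    state: SweState, tavg: float, prcp: float, params: SnowParams
) -> tuple[SweState, DayFluxes]:
    """Advance the pack by one day; returns new state and day fluxes.

    Missing forcing (NaN tavg or prcp) carries the state forward unchanged
    with zero fluxes — callers flag such days as undefined.
    """
    if np.isnan(tavg) or np.isnan(prcp):
        return SweState(state.swe, state.liquid), DayFluxes(
            np.nan, np.nan, np.nan, np.nan, np.nan
        )
    rain, snow = partition_precipitation(tavg, prcp, params)
    swe = state.swe + snow
    melt = min(swe, params.ddf * max(0.0, tavg - params.t_melt))
    swe -= melt
    liquid_in = state.liquid + melt + rain
    capacity = params.retain_frac * swe
    liquid = min(liquid_in, capacity)
    runoff = liquid_in - liquid
    refreeze = min(
        liquid, params.refreeze_factor * max(0.0, params.t_melt - tavg)
    )
    swe += refreeze
    liquid -= refreeze
    return SweState(swe, liquid), DayFluxes(snow, rain, melt, refreeze, runoff)


def simulate_swe(
    series: StationSeries,
    params: SnowParams = SnowParams(),
    init: SweState | None = None,
    return_fluxes: bool = False,
) -> pd.DataFrame:
    """Run the degree-day model over a station series.

    Returns a frame indexed like ``series.data`` with columns ``swe`` (mm)
    and ``defined`` (bool; False where forcing was missing and the state was
    carried forward). The pack is re-initialized empty at every 1 August
    (hydrological-year start), so winters are independent of record start
    and no phantom pack survives a snow-free summer. With ``return_fluxes``,
    rain/snow/melt/refreeze/runoff columns are included.
    """
    df = series.data
    tavg = ((df["tmin"] + df["tmax"]) / 2.0).to_numpy()
    prcp = df["prcp"].to_numpy()
    dates = df.index
    reset = (dates.month == 8) & (dates.day == 1)

    n = len(df)
    swe_out = np.empty(n)
    defined = np.empty(n, dtype=bool)
    flux_cols = (
        {k: np.full(n, np.nan) for k in ("rain", "snow", "melt", "refreeze", "runoff")}
        if return_fluxes
        else None
    )
    liquid_out = np.empty(n) if return_fluxes else None
    state = SweState() if init is None else replace(init)
    for i in range(n):
        if reset[i]:
            state = SweState()
        state, fx = step_swe(state, tavg[i], prcp[i], params)
        swe_out[i] = state.swe
        defined[i] = not (np.isnan(tavg[i]) or np.isnan(prcp[i]))
        if flux_cols is not None:
            for k in ("rain", "snow", "melt", "refreeze", "runoff"):
                flux_cols[k][i] = getattr(fx, k)
            liquid_out[i] = state.liquid
    out = pd.DataFrame({"swe": swe_out, "defined": defined}, index=dates)
    if flux_cols is not None:
        for k, v in flux_cols.items():
            out[k] = v
        out["liquid"] = liquid_out
    return out


_GRID_FIELDS = ("t_rain", "t_snow", "t_melt", "ddf", "retain_frac", "refreeze_factor")


def calibrate_snow_params(
    series: StationSeries,
    grid: dict[str, list[float]],
    defaults: SnowParams = SnowParams(),
) -> tuple[SnowParams, float]:
    """Exhaustive grid search for parameters matching observed snow presence.

    The score is the fraction of days on which observed snow presence
    (depth > 0) agrees with modeled presence (swe > 0), over days with both
    an observation and defined forcing. Ties break toward ``defaults`` if
    present among the best, else toward the first candidate in grid order.

    ``grid`` maps any subset of parameter names to candidate lists;
    unspecified parameters stay at their default values.
    """
    obs = series.data["snow_depth"]
    if obs.notna().sum() == 0:
        raise CalibrationError("no observed snow-depth days to calibrate against")
    names = [f for f in _GRID_FIELDS if f in grid]
    combos = list(product(*(grid[f] for f in names)))
    best_params, best_score = None, -1.0
    any_usable = False
    for combo in combos:
        try:
            params = replace(defaults, **dict(zip(names, combo)))
        except ValueError:
            continue  # invalid corner of the grid (e.g. t_snow > t_rain)
        sim = simulate_swe(series, params)
        usable = obs.notna().to_numpy() & sim["defined"].to_numpy()
        if not usable.any():
            continue
        any_usable = True
        agree = (obs.to_numpy()[usable] > 0) == (
            sim["swe"].to_numpy()[usable] > 0
        )
        score = float(agree.mean())
        if score > best_score:
            best_params, best_score = params, score
        elif score == best_score and params == defaults:
            best_params = params
    if not any_usable:
        raise CalibrationError("no days with both observation and forcing")
    return best_params, best_score
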