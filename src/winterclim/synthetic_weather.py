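"""Synthetic daily station weather with known structure and injected trends.

The generator produces mid-latitude station series — sinusoidal seasonal
temperature cycle, AR(1) day-to-day noise, independent wet-day occurrence
with Gamma-distributed amounts, and temperature-dependent precipitation
phase — plus configurable linear warming trends, so every downstream stage
(QC, snow model, indicator counting, trend statistics) can be tested
against a ground truth. It deliberately omits spatial correlation between
stations and any coupling of precipitation occurrence to temperature beyond
phase partitioning.

Records run from 1 August of ``start_year`` through 31 July of
``start_year + n_years``, giving exactly ``n_years`` complete winters
(labeled ``start_year+1 .. start_year+n_years``) and aligning with the snow
model's hydrological-year initialization.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal, stats

from .snow_model import SnowParams, partition_precipitation, simulate_swe
from .station_io import StationMeta, StationSeries

PERIOD_DAYS = 365.25  # seasonal period evaluated on real calendar dates


@dataclass(frozen=True)
class GenParams:
    """Generator parameters for one synthetic station.

    Temperature model: daily mean
    ``mean_temp - amplitude * cos(2*pi*(t - coldest_doy)/365.25)`` plus
    shared AR(1) noise; ``tmax/tmin = mean +/- diurnal_range/2``, each with
    its own linear trend in degC per decade. ``noise_sd`` is the marginal
    (stationary) standard deviation of the AR(1) noise. Precipitation:
    Bernoulli(``p_wet``) occurrence with Gamma(shape, scale) amounts (mm),
    independent of temperature; snowfall is the snow fraction of the amount
    at the default phase-partition thresholds.
    """

    n_years: int = 100
    start_year: int = 1916
    mean_temp: float = 6.0  # degC annual mean
    amplitude: float = 15.0  # degC seasonal half-range
    coldest_doy: int = 20  # mid-January minimum
    diurnal_range: float = 10.0  # degC
    noise_sd: float = 4.0  # degC, marginal SD of AR(1) noise
    ar1: float = 0.7
    trend_tmin: float = 0.0  # degC/decade
    trend_tmax: float = 0.0  # degC/decade
    p_wet: float = 0.35
    wet_gamma_shape: float = 0.75
    wet_gamma_scale: float = 9.0  # mm
    seed: int = 0
    with_snow_depth: bool = False  # model-derived depth for gap-fill tests

    def __post_init__(self) -> None:
        if self.n_years < 2:
            raise ValueError("n_years must be >= 2")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.diurnal_range <= 0:
            raise ValueError("diurnal_range must be > 0")
        if not 0.0 <= self.p_wet <= 1.0:
            raise ValueError("p_wet must be in [0, 1]")
        if not 0.0 <= self.ar1 < 1.0:
            raise ValueError("ar1 must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class MissSpec:
    """Missingness specification for :func:`inject_missingness`.

    ``frac_missing`` maps variable names to target missing fractions;
    blocks of missing days have geometric lengths with the given mean.
    ``unreported_zero_snow`` emulates observers leaving snow depth blank on
    snow-free days: every day whose true depth is exactly 0 is blanked
    (days with snow are never touched by this mechanism).
    """

    frac_missing: dict[str, float] | None = None
    block_length_mean: float = 3.0
    unreported_zero_snow: bool = False

    def __post_init__(self) -> None:
        for v, f in (self.frac_missing or {}).items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"frac_missing[{v!r}] must be in [0, 1]")
        if self.block_length_mean < 1.0:
            raise ValueError("block_length_mean must be >= 1")


def seasonal_mean_temp(dates: pd.DatetimeIndex, params: GenParams) -> np.ndarray:
    """Deterministic seasonal daily-mean temperature (no noise, no trend)."""
    origin = pd.Timestamp(params.start_year, 1, 1)
    t = (dates - origin).days.to_numpy().astype(float)
    phase = 2.0 * np.pi * (t - (params.coldest_doy - 1)) / PERIOD_DAYS
    return params.mean_temp - params.amplitude * np.cos(phase)


def generate_daily_series(
    params: GenParams,
    meta: StationMeta | None = None,
    snow_params: SnowParams = SnowParams(),
) -> StationSeries:
    """Generate one synthetic station series (bit-identical per seed)."""
    if meta is None:
        meta = StationMeta("SYN0001", 45.0, -72.0, "synthetic station")
    rng = np.random.default_rng(params.seed)
    dates = pd.date_range(
        start=pd.Timestamp(params.start_year, 8, 1),
        end=pd.Timestamp(params.start_year + params.n_years, 7, 31),
        freq="D",
    )
    n = len(dates)
    origin = pd.Timestamp(params.start_year, 1, 1)
    years_elapsed = (dates - origin).days.to_numpy().astype(float) / PERIOD_DAYS

    tmean = seasonal_mean_temp(dates, params)
    if params.noise_sd > 0:
        innov_sd = params.noise_sd * np.sqrt(1.0 - params.ar1**2)
        innov = rng.normal(0.0, innov_sd, size=n)
        innov[0] = rng.normal(0.0, params.noise_sd)  # stationary start
        # AR(1) recursion x_t = ar1*x_{t-1} + e_t via IIR filter
        noise = signal.lfilter([1.0], [1.0, -params.ar1], innov)
        tmean = tmean + noise
    half = params.diurnal_range / 2.0
    tmax = tmean + half + params.trend_tmax * years_elapsed / 10.0
    tmin = tmean - half + params.trend_tmin * years_elapsed / 10.0

    wet = rng.random(n) < params.p_wet
    amounts = rng.gamma(params.wet_gamma_shape, params.wet_gamma_scale, size=n)
    prcp = np.where(wet, amounts, 0.0)
    tavg = (tmin + tmax) / 2.0
    _, snowfall = partition_precipitation(tavg, prcp, snow_params)

    # quantize to the 0.1-unit resolution real station records report;
    # rounding is monotone, so tmin <= tmax and snowfall <= prcp survive,
    # and written CSVs round-trip bit-identically
    df = pd.DataFrame(
        {
            "tmin": np.round(tmin, 1),
            "tmax": np.round(tmax, 1),
            "prcp": np.round(prcp, 1),
            "snowfall": np.round(snowfall, 1),
            "snow_depth": np.nan,
        },
        index=pd.DatetimeIndex(dates, name="date"),
    )
    series = StationSeries(meta=meta, data=df)
    if params.with_snow_depth:
        swe = simulate_swe(series, snow_params)
        series.data["snow_depth"] = np.round(swe["swe"].to_numpy(), 1)
    return series


def inject_missingness(
    series: StationSeries, spec: MissSpec, seed: int
) -> StationSeries:
    """Blank values in geometric-length blocks until target fractions are hit.

    The realized missing count per variable equals the target count exactly
    when reachable (the final block is truncated); the input series is not
    modified. With ``unreported_zero_snow``, zero-depth days are
    additionally blanked.
    """
    rng = np.random.default_rng(seed)
    out = series.copy()
    df = out.data
    n = len(df)
    p_block = 1.0 / spec.block_length_mean
    for var, frac in (spec.frac_missing or {}).items():
        if frac <= 0:
            continue
        observed = df[var].notna().to_numpy()
        target = int(round(frac * n))
        mask = np.zeros(n, dtype=bool)
        # cap iterations to guard against degenerate all-missing inputs
        for _ in range(100 * n):
            hit = int(mask.sum())
            if hit >= target:
                break
            start = int(rng.integers(0, n))
            length = int(rng.geometric(p_block))
            block = np.zeros(n, dtype=bool)
            block[start : start + length] = True
            gain = block & ~mask
            excess = hit + int(gain.sum()) - target
            if excess > 0:
                keep = np.flatnonzero(gain)[: int(gain.sum()) - excess]
                gain = np.zeros(n, dtype=bool)
                gain[keep] = True
            mask |= gain
        df.loc[mask, var] = np.nan
        del observed
    if spec.unreported_zero_snow:
        zero_days = (df["snow_depth"] == 0).to_numpy()
        df.loc[zero_days, "snow_depth"] = np.nan
    return out


def expected_frost_days(params: GenParams, t_frost: float = 0.0) -> float:
    """Expected Frost Days per winter under the generator, no trend.

    Sums P(tmin < t_frost) = Phi((t_frost - mu_d)/sigma) over a
    representative (non-leap) winter window, with mu_d the seasonal-mean
    tmin and sigma the marginal noise SD. Used to translate a target
    indicator trend into an equivalent temperature trend.
    """
    window = pd.date_range("2001-11-01", "2002-05-31", freq="D")
    base = replace(params, start_year=2001)
    mu = seasonal_mean_temp(window, base) - params.diurnal_range / 2.0
    if params.noise_sd == 0:
        return float((mu < t_frost).sum())
    return float(stats.norm.cdf((t_frost - mu) / params.noise_sd).sum())


def frost_trend_to_tmin_trend(
    params: GenParams,
    target_days_per_decade: float,
    t_frost: float = 0.0,
    n_decades: float | None = None,
) -> float:
    """tmin trend (degC/decade) producing a given Frost-Day trend (d/decade).

    Solves the secant condition over the record length: find the
    temperature trend T such that the expected frost count changes by
    ``target * n_decades`` days between the first and last winter,
    ``F(T * n_decades) - F(0) = target * n_decades`` with F the expected
    count under a uniform tmin offset. The secant (rather than the tangent
    at zero offset) absorbs the curvature of F over a century-scale record.
    """
    from scipy.optimize import brentq

    if n_decades is None:
        n_decades = params.n_years / 10.0

    def shifted(delta: float) -> float:
        return expected_frost_days(
            replace(params, mean_temp=params.mean_temp + delta), t_frost
        )

    f0 = shifted(0.0)

    def g(trend: float) -> float:
        return (shifted(trend * n_decades) - f0) / n_decades - target_days_per_decade

    return float(brentq(g, -8.0, 8.0, xtol=1e-10))
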