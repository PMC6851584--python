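"""Ground-truth validation experiments for the pipeline.

Each function runs a self-contained simulation experiment against the
synthetic weather generator or against independent brute-force oracles and
returns the measured quantities. They back the package's validation suite
and the reproducibility script; problem sizes default to the values used
there.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .indicators import build_indicator_matrix
from .snow_model import (
    SnowParams,
    SweState,
    calibrate_snow_params,
    simulate_swe,
    step_swe,
)
from .station_io import StationMeta
from .synthetic_weather import (
    GenParams,
    frost_trend_to_tmin_trend,
    generate_daily_series,
)
from .trend_stats import mann_kendall, regional_kendall, sen_slope

# ---------------------------------------------------------------------------
# brute-force oracles (deliberately naive; independent of trend_stats)


def brute_force_kendall_s(x) -> int:
    """O(n^2) pairwise sign sum via explicit Python loops."""
    x = list(x)
    s = 0
    for i in range(len(x)):
        for j in range(i + 1, len(x)):
            if x[j] > x[i]:
                s += 1
            elif x[j] < x[i]:
                s -= 1
    return s


def brute_force_sen_slope(x, t) -> float:
    """Median of the explicitly enumerated pairwise-slope multiset, /decade."""
    x, t = list(x), list(t)
    slopes = []
    for i in range(len(x)):
        for j in range(i + 1, len(x)):
            if t[j] != t[i]:
                slopes.append((x[j] - x[i]) / (t[j] - t[i]))
    return float(np.median(slopes)) * 10.0


def kendall_oracle_agreement(n_series: int = 500, seed: int = 0) -> dict:
    """Fraction of random short series (ties included) on which the
    implementation matches the brute-force S and Sen-slope oracles."""
    rng = np.random.default_rng(seed)
    s_ok = sen_ok = 0
    for _ in range(n_series):
        n = int(rng.integers(4, 13))
        x = rng.integers(0, 6, size=n).astype(float)  # small ints force ties
        t = np.arange(n, dtype=float)
        res = mann_kendall(x, t)
        if res.S == brute_force_kendall_s(x):
            s_ok += 1
        if np.isclose(res.sen_slope, brute_force_sen_slope(x, t), rtol=0, atol=0):
            sen_ok += 1
    return {
        "s_agreement": s_ok / n_series,
        "sen_agreement": sen_ok / n_series,
        "n": n_series,
    }


def type_i_error(
    n_years: int = 100, n_reps: int = 2000, alpha: float = 0.05, seed: int = 0
) -> dict:
    """Mann-Kendall rejection rate on i.i.d. Gaussian annual series."""
    rng = np.random.default_rng(seed)
    rejected = 0
    for _ in range(n_reps):
        x = rng.normal(size=n_years)
        if mann_kendall(x, alpha=alpha).p < alpha:
            rejected += 1
    return {"rejection_rate": rejected / n_reps, "n": n_reps}


# ---------------------------------------------------------------------------
# trend recovery through the generator + indicator path


def _frost_counts(gen: GenParams, meta: StationMeta | None = None):
    series = generate_daily_series(gen, meta=meta)
    mat = build_indicator_matrix(series, swe=None)
    return (
        mat["frost"].to_numpy(dtype=float),
        mat.index.to_numpy(dtype=float),
    )


def frost_trend_recovery(
    target_slope: float = -1.5,
    n_reps: int = 200,
    n_stations_regional: int = 5,
    n_years: int = 100,
    seed: int = 0,
    base: GenParams | None = None,
) -> dict:
    """Inject a Frost-Day trend of ``target_slope`` d/decade and recover it.

    The equivalent tmin trend is derived analytically from the generator's
    seasonal cycle and noise level. Measures (a) the mean Sen slope of
    annual Frost-Day counts over ``n_reps`` single-station replicates, and
    (b) the fraction of replicates in which the regional Kendall test over
    ``n_stations_regional`` independent such stations detects the trend
    (p < 0.05).
    """
    base = base or GenParams(n_years=n_years)
    tmin_trend = frost_trend_to_tmin_trend(base, target_slope)
    gen = dataclasses.replace(base, trend_tmin=tmin_trend, n_years=n_years)
    rng = np.random.default_rng(seed)

    slopes = []
    for _ in range(n_reps):
        vals, yrs = _frost_counts(
            dataclasses.replace(gen, seed=int(rng.integers(2**31)))
        )
        slopes.append(sen_slope(vals, yrs))

    detected = 0
    for _ in range(n_reps):
        blocks = {}
        for b in range(n_stations_regional):
            blocks[f"S{b}"] = _frost_counts(
                dataclasses.replace(gen, seed=int(rng.integers(2**31)))
            )
        res = regional_kendall(blocks)
        if res.p < 0.05 and res.sen_slope < 0:
            detected += 1
    return {
        "target_slope": target_slope,
        "tmin_trend_equiv": tmin_trend,
        "mean_sen_slope": float(np.mean(slopes)),
        "sd_sen_slope": float(np.std(slopes)),
        "regional_detection_rate": detected / n_reps,
        "n_reps": n_reps,
    }


# ---------------------------------------------------------------------------
# snow-model properties


def snow_mass_balance(n_steps: int = 10_000, seed: int = 0) -> dict:
    """Max |mass-balance residual| over randomized single steps (mm)."""
    rng = np.random.default_rng(seed)
    params = SnowParams()
    state = SweState()
    max_resid = 0.0
    min_swe = np.inf
    for i in range(n_steps):
        if rng.random() < 0.01:  # occasional fresh pack
            state = SweState()
        tavg = float(rng.normal(-2.0, 8.0))
        prcp = float(rng.gamma(0.7, 8.0)) if rng.random() < 0.4 else 0.0
        new, fx = step_swe(state, tavg, prcp, params)
        resid = abs(
            (new.swe + new.liquid)
            - (state.swe + state.liquid)
            - (fx.snow + fx.rain - fx.runoff)
        )
        max_resid = max(max_resid, resid)
        min_swe = min(min_swe, new.swe)
        state = new
    return {"max_residual_mm": max_resid, "min_swe_mm": float(min_swe), "n": n_steps}


def ddf_monotonicity(
    ddfs=(1.0, 2.0, 3.0, 5.0), n_years: int = 3, seed: int = 0
) -> dict:
    """Check that raising the melt factor never raises SWE on any day."""
    series = generate_daily_series(GenParams(n_years=n_years, seed=seed))
    prev = None
    violations = 0
    for ddf in ddfs:
        swe = simulate_swe(series, SnowParams(ddf=ddf))["swe"].to_numpy()
        if prev is not None:
            violations += int((swe > prev + 1e-9).sum())
        prev = swe
    return {"violations": violations, "n_days": len(series.data) * (len(ddfs) - 1)}


def calibration_self_recovery(seed: int = 0) -> dict:
    """Grid-search calibration on model-generated 'observed' depth.

    The observations are produced by the model at known parameters that sit
    inside the search grid; calibration must return them with perfect
    snow-presence agreement.
    """
    truth = SnowParams(ddf=4.0, t_melt=1.0)
    series = generate_daily_series(GenParams(n_years=4, seed=seed))
    sim = simulate_swe(series, truth)
    series.data["snow_depth"] = sim["swe"].to_numpy()
    grid = {"ddf": [1.5, 2.5, 4.0, 6.0], "t_melt": [-1.0, 0.0, 1.0]}
    params, score = calibrate_snow_params(series, grid)
    return {
        "recovered": params.ddf == truth.ddf and params.t_melt == truth.t_melt,
        "agreement": score,
    }


# ---------------------------------------------------------------------------
# end-to-end subregion sign pattern


def subregion_sign_pattern(
    n_seeds: int = 200,
    n_years: int = 100,
    stations_per_subregion: int = 3,
    target_slope: float = -1.5,
    seed: int = 0,
) -> dict:
    """Warming injected only in west/east; central left trend-free.

    For each seed, nine synthetic stations (three per subregion) are
    generated and the regional Kendall test is run on annual Frost-Day
    counts per subregion. Success for a seed means: significant negative
    regional trend in west AND east, no significant trend in central.
    Returns the fraction of seeds with the full pattern (plus per-region
    rates).
    """
    base = GenParams(n_years=n_years)
    tmin_trend = frost_trend_to_tmin_trend(base, target_slope)
    lons = {"west": -92.0, "central": -82.0, "east": -70.0}
    rng = np.random.default_rng(seed)
    hits = {"west": 0, "central_ns": 0, "east": 0, "pattern": 0}
    for _ in range(n_seeds):
        verdicts = {}
        for region, lon in lons.items():
            trend = 0.0 if region == "central" else tmin_trend
            gen = dataclasses.replace(base, trend_tmin=trend)
            blocks = {}
            for b in range(stations_per_subregion):
                sid = f"{region}{b}"
                meta = StationMeta(sid, 45.0, lon)
                blocks[sid] = _frost_counts(
                    dataclasses.replace(gen, seed=int(rng.integers(2**31))),
                    meta=meta,
                )
            res = regional_kendall(blocks)
            verdicts[region] = (res.significant, res.sen_slope)
        w_ok = verdicts["west"][0] and verdicts["west"][1] < 0
        e_ok = verdicts["east"][0] and verdicts["east"][1] < 0
        c_ok = not verdicts["central"][0]
        hits["west"] += w_ok
        hits["east"] += e_ok
        hits["central_ns"] += c_ok
        hits["pattern"] += w_ok and e_ok and c_ok
    return {
        "pattern_fraction": hits["pattern"] / n_seeds,
        "west_fraction": hits["west"] / n_seeds,
        "east_fraction": hits["east"] / n_seeds,
        "central_ns_fraction": hits["central_ns"] / n_seeds,
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# indicator-engine checks


def truth_table_agreement() -> dict:
    """Exhaustive day-classification check against directly coded inequalities.

    Evaluates every combination of temperatures straddling the -30/-18/-5/0
    degC boundaries, SWE straddling bare/covered, and rain on/off, and
    compares the classifier with the plainly written truth table.
    """
    import itertools

    from .indicators import classify_day

    def oracle(tmax, tmin, swe, rain):
        def undef(*xs):
            return any(np.isnan(x) for x in xs)

        return {
            "thaw": None if undef(tmax) else tmax > 0,
            "ice": None if undef(tmax) else tmax < 0,
            "frost": None if undef(tmin) else tmin < 0,
            "extreme_cold": None if undef(tmin) else tmin < -18,
            "hwa_kill": None if undef(tmin) else tmin < -30,
            "snowmaking": None if undef(tmin) else tmin < -5,
            "snow_covered": None if undef(swe) else swe > 0,
            "bare_ground": None if undef(swe) else swe == 0,
            "rain_on_snow": None if undef(rain, swe) else (rain > 0 and swe > 0),
            "frozen_ground": None if undef(tmax, swe) else (tmax < 0 and swe == 0),
            "mud": None if undef(tmax, swe) else (tmax > 0 and swe == 0),
        }

    temps = [-31.0, -30.0, -29.9, -18.1, -18.0, -17.9, -5.1, -5.0, -4.9,
             -0.1, 0.0, 0.1, 5.0, np.nan]
    swes = [0.0, 0.1, 20.0, np.nan]
    rains = [0.0, 0.1, 5.0, np.nan]
    n = agree = 0
    for tmax, tmin, swe, rain in itertools.product(temps, temps, swes, rains):
        if not np.isnan(tmax) and not np.isnan(tmin) and tmin > tmax:
            continue
        n += 1
        agree += classify_day(tmin, tmax, swe, rain) == oracle(tmax, tmin, swe, rain)
    return {"agreement": agree / n, "n": n}


def indicator_count_invariants(
    n_stations: int = 10, n_years: int = 100, seed: int = 0
) -> dict:
    """Per-winter partition/nesting identities over many synthetic winters.

    Checks, for every winter of every station: frost >= ice; the
    -30/-18/-5/0 degC count nesting; snow_covered + bare_ground equals the
    SWE denominator; rain_on_snow <= snow_covered;
    frozen_ground + mud <= bare_ground. Returns the number of violated
    (winter, identity) pairs and the number of winters checked.
    """
    from .indicators import classify_days, count_winter_indicators

    rng = np.random.default_rng(seed)
    violations = 0
    n_winters = 0
    for _ in range(n_stations):
        gen = GenParams(
            n_years=n_years,
            seed=int(rng.integers(2**31)),
            noise_sd=float(rng.uniform(3.0, 9.0)),
            mean_temp=float(rng.uniform(2.0, 9.0)),
        )
        series = generate_daily_series(gen)
        swe = simulate_swe(series)
        mat = count_winter_indicators(classify_days(series, swe=swe))
        n_winters += len(mat)
        checks = [
            (mat["ice"] <= mat["frost"]),
            (mat["hwa_kill"] <= mat["extreme_cold"]),
            (mat["extreme_cold"] <= mat["snowmaking"]),
            (mat["snowmaking"] <= mat["frost"]),
            (mat["snow_covered"] + mat["bare_ground"] == mat["den_swe"]),
            (mat["rain_on_snow"] <= mat["snow_covered"]),
            (mat["frozen_ground"] + mat["mud"] <= mat["bare_ground"]),
        ]
        for ok in checks:
            violations += int((~ok.fillna(True)).sum())
    return {"violations": violations, "n_winters": n_winters}
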