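"""Winter assignment, day classification (vs truth table), counting invariants."""

import itertools

import numpy as np
import pandas as pd
import pytest

from winterclim import GenParams, generate_daily_series
from winterclim.indicators import (
    DEFAULT_THRESHOLDS,
    INDICATORS,
    assign_winter,
    build_indicator_matrix,
    classify_day,
    classify_days,
    count_winter_indicators,
    winter_window_index,
)
from winterclim.snow_model import simulate_swe

from conftest import make_series


@pytest.mark.parametrize(
    "date, expected",
    [
        ("2000-11-01", 2001),  # window start
        ("2000-12-31", 2001),
        ("2001-01-01", 2001),
        ("2001-05-31", 2001),  # window end
        ("2001-06-15", None),  # summer
        ("2001-10-31", None),
    ],
)
def test_assign_winter_labels_by_ending_year(date, expected):
    assert assign_winter(date) == expected


def test_winter_window_length_follows_calendar():
    assert len(winter_window_index(2001)) == 212  # Feb 2001 non-leap
    assert len(winter_window_index(2004)) == 213  # Feb 2004 leap


def _truth_table(tmax, tmin, swe, rain):
    """Independent oracle: the indicator inequalities written out directly."""

    def undef_if(*xs):
        return any(np.isnan(x) for x in xs)

    out = {}
    out["thaw"] = None if undef_if(tmax) else tmax > 0
    out["ice"] = None if undef_if(tmax) else tmax < 0
    out["frost"] = None if undef_if(tmin) else tmin < 0
    out["extreme_cold"] = None if undef_if(tmin) else tmin < -18
    out["hwa_kill"] = None if undef_if(tmin) else tmin < -30
    out["snowmaking"] = None if undef_if(tmin) else tmin < -5
    out["snow_covered"] = None if undef_if(swe) else swe > 0
    out["bare_ground"] = None if undef_if(swe) else swe == 0
    out["rain_on_snow"] = None if undef_if(rain, swe) else (rain > 0 and swe > 0)
    out["frozen_ground"] = None if undef_if(tmax, swe) else (tmax < 0 and swe == 0)
    out["mud"] = None if undef_if(tmax, swe) else (tmax > 0 and swe == 0)
    return out


def test_classify_day_matches_truth_table_on_boundary_grid():
    """Exhaustive agreement over a grid spanning every threshold boundary."""
    temps = [-31.0, -30.0, -29.9, -18.1, -18.0, -17.9, -5.1, -5.0, -4.9,
             -0.1, 0.0, 0.1, 5.0, np.nan]
    swes = [0.0, 0.1, 20.0, np.nan]
    rains = [0.0, 0.1, 5.0, np.nan]
    checked = 0
    for tmax, tmin, swe, rain in itertools.product(temps, temps, swes, rains):
        if not np.isnan(tmax) and not np.isnan(tmin) and tmin > tmax:
            continue  # invalid record, quarantined upstream
        got = classify_day(tmin, tmax, swe, rain)
        want = _truth_table(tmax, tmin, swe, rain)
        assert got == want, (tmin, tmax, swe, rain)
        checked += 1
    assert checked > 1500


@pytest.mark.parametrize(
    "tmin, tmax, swe, rain, true_flags, false_flags",
    [
        (-6, -2, 10, 0,
         ["ice", "frost", "snowmaking", "snow_covered"],
         ["thaw", "bare_ground", "rain_on_snow", "mud"]),
        (-1, 5, 0, 0,
         ["thaw", "frost", "bare_ground", "mud"],
         ["ice", "snow_covered", "frozen_ground"]),
        (-3, 0, 0, 0,  # exactly 0: strict inequalities exclude both
         ["frost", "bare_ground"],
         ["thaw", "ice", "frozen_ground", "mud"]),
        (-2, 1, 20, 5, ["rain_on_snow", "snow_covered", "thaw"], ["bare_ground"]),
    ],
)
def test_classify_day_documented_cases(tmin, tmax, swe, rain, true_flags, false_flags):
    flags = classify_day(tmin, tmax, swe, rain)
    for f in true_flags:
        assert flags[f] is True, f
    for f in false_flags:
        assert flags[f] is False, f


def test_vectorized_classification_agrees_with_scalar(long_series):
    swe = simulate_swe(long_series)
    frame = classify_days(long_series, swe=swe)
    rng = np.random.default_rng(0)
    from winterclim.snow_model import partition_precipitation

    for i in rng.integers(0, len(frame), size=60):
        rec = long_series.data.iloc[i]
        tavg = (rec["tmin"] + rec["tmax"]) / 2
        rain, _ = partition_precipitation(tavg, rec["prcp"])
        swe_val = swe["swe"].iloc[i] if swe["defined"].iloc[i] else np.nan
        want = _truth_table(rec["tmax"], rec["tmin"], swe_val, rain)
        got = {
            k: (None if pd.isna(frame[k].iloc[i]) else bool(frame[k].iloc[i]))
            for k in want
        }
        assert got == want


def _uniform_winter(tmin, tmax, swe_mm, wy=2001):
    window = winter_window_index(wy)
    n = len(window)
    series = make_series(
        window, tmin=np.full(n, tmin), tmax=np.full(n, tmax), prcp=np.zeros(n)
    )
    swe = pd.DataFrame(
        {"swe": np.full(n, float(swe_mm)), "defined": True}, index=window
    )
    return series, swe


def test_uniform_cold_winter_counts():
    series, swe = _uniform_winter(-10.0, -5.0, 30.0)
    flags = classify_days(series, swe=swe)
    counts = count_winter_indicators(flags).loc[2001]
    for ind in ("ice", "frost", "snowmaking", "snow_covered"):
        assert counts[ind] == 212
    assert counts["thaw"] == 0 and counts["mud"] == 0
    assert counts["den_tmin"] == 212 and counts["den_swe"] == 212


def test_snowmaking_windows():
    """A snowmaking day on 24 Dec counts before-Christmas; 26 Dec does not;
    the February window includes 28 Feb and excludes 1 Mar."""
    window = winter_window_index(2001)
    n = len(window)
    tmin = np.full(n, 0.0)  # never cold enough
    for d in ("2000-12-24", "2000-12-26", "2001-02-28", "2001-03-01"):
        tmin[window.get_loc(pd.Timestamp(d))] = -10.0
    series = make_series(window, tmin=tmin, tmax=tmin + 10, prcp=np.zeros(n))
    counts = count_winter_indicators(classify_days(series)).loc[2001]
    assert counts["snowmaking"] == 4
    assert counts["snowmaking_before_dec25"] == 1
    assert counts["snowmaking_before_feb28"] == 3  # 24 Dec, 26 Dec, 28 Feb


def test_all_missing_tmin_reports_missing_not_zero():
    window = winter_window_index(2001)
    n = len(window)
    series = make_series(window, tmax=np.full(n, -2.0), prcp=np.zeros(n))
    counts = count_winter_indicators(classify_days(series)).loc[2001]
    assert counts["den_tmin"] == 0
    assert pd.isna(counts["frost"])
    assert counts["ice"] == 212  # tmax-based indicators unaffected


def test_duplicate_dates_rejected():
    series = make_series(
        ["2001-01-01", "2001-01-01"], tmin=[-1, -1], tmax=[1, 1]
    )
    flags = classify_days(series)
    with pytest.raises(ValueError, match="duplicate"):
        count_winter_indicators(flags)


def test_count_nesting_and_partition_invariants_on_random_winters():
    """Per-winter identities over many synthetic winters:
    nesting of cold thresholds, snow/bare partition, thaw+ice+boundary=den."""
    for seed in range(4):
        series = generate_daily_series(GenParams(n_years=8, seed=seed, noise_sd=8.0))
        swe = simulate_swe(series)
        flags = classify_days(series, swe=swe)
        mat = count_winter_indicators(flags)
        assert (mat["ice"] <= mat["frost"]).all()
        assert (mat["hwa_kill"] <= mat["extreme_cold"]).all()
        assert (mat["extreme_cold"] <= mat["snowmaking"]).all()
        assert (mat["snowmaking"] <= mat["frost"]).all()
        assert (mat["snow_covered"] + mat["bare_ground"] == mat["den_swe"]).all()
        assert (mat["rain_on_snow"] <= mat["snow_covered"]).all()
        assert (mat["frozen_ground"] + mat["mud"] <= mat["bare_ground"]).all()
        assert (mat["snowmaking_before_dec25"] <= mat["snowmaking"]).all()
        assert (mat["snowmaking_before_feb28"] <= mat["snowmaking"]).all()
        # thaw + ice + #exact-zero tmax days exhaust the tmax denominator
        df = series.data
        winters = mat.index
        for wy in winters:
            window = winter_window_index(wy)
            zeros = int((df["tmax"].reindex(window) == 0).sum())
            assert mat.loc[wy, "thaw"] + mat.loc[wy, "ice"] + zeros == mat.loc[wy, "den_tmax"]


def test_lowering_extreme_cold_threshold_never_increases_count(long_series):
    from winterclim.indicators import ThresholdConfig

    prev = None
    for t in (-10.0, -15.0, -18.0, -25.0):
        thr = ThresholdConfig(t_extreme_cold=t)
        mat = count_winter_indicators(classify_days(long_series, thr=thr), thr=thr)
        total = int(mat["extreme_cold"].sum())
        if prev is not None:
            assert total <= prev
        prev = total


def test_matrix_respects_per_variable_validity(long_series):
    from winterclim.qc_gapfill import screen_completeness

    swe = simulate_swe(long_series)
    report, _ = screen_completeness(long_series)
    # force one winter invalid for temperature only
    report.loc[report.index[2], "valid_temp"] = False
    wy = int(report.iloc[2]["winter_year"])
    mat = build_indicator_matrix(long_series, swe=swe, validity=report)
    assert pd.isna(mat.loc[wy, "frost"]) and pd.isna(mat.loc[wy, "thaw"])
    assert not pd.isna(mat.loc[wy, "snow_covered"])  # SWE-only indicator survives
    assert len(mat) == len(report)


def test_full_synthetic_station_has_complete_matrix():
    series = generate_daily_series(GenParams(n_years=20, seed=9))
    swe = simulate_swe(series)
    mat = build_indicator_matrix(series, swe=swe)
    assert len(mat) == 20
    assert not mat[list(INDICATORS)].isna().any().any()
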