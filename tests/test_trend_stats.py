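"""Mann-Kendall, Sen slope, acf screen, regional Kendall, summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from winterclim.experiments import brute_force_kendall_s, brute_force_sen_slope
from winterclim.trend_stats import (
    assign_subregion,
    autocorr_screen,
    kendall_var_s,
    mann_kendall,
    regional_kendall,
    sen_slope,
    summarize_levels,
    summarize_trends,
)


def test_monotone_series_closed_form():
    res = mann_kendall(np.arange(1.0, 11.0))
    assert res.S == 45
    assert res.var_S == 125.0
    assert res.z == pytest.approx(44 / np.sqrt(125))
    assert res.p == pytest.approx(8.2e-5, rel=0.02)
    assert res.significant


def test_constant_series_is_null():
    res = mann_kendall(np.full(10, 3.0))
    assert res.S == 0 and res.z == 0.0 and res.p == 1.0
    assert sen_slope(np.full(10, 3.0)) == 0.0


def test_small_series_brute_force():
    assert mann_kendall([3, 1, 2, 2], alpha=0.05).S == brute_force_kendall_s([3, 1, 2, 2])
    # the spec's 3-point S value, via the same pairwise definition
    assert brute_force_kendall_s([3, 1, 2]) == -1


def test_insufficient_data():
    res = mann_kendall([1.0, 2.0, 3.0])
    assert not res.sufficient and not res.significant


def test_missing_values_omitted_pairwise_on_true_year_axis():
    x = np.array([1.0, np.nan, 3.0, 4.0, np.nan, 6.0])
    t = np.arange(2000, 2006, dtype=float)
    res = mann_kendall(x, t)
    assert res.n == 4
    assert res.sen_slope == pytest.approx(10.0)  # 1 unit/yr despite gaps


@settings(max_examples=150, deadline=None, derandomize=True)
@given(
    st.lists(st.integers(min_value=0, max_value=5), min_size=4, max_size=12)
)
def test_kendall_s_and_sen_match_oracles(xs):
    x = np.array(xs, dtype=float)
    t = np.arange(len(x), dtype=float)
    res = mann_kendall(x, t)
    assert res.S == brute_force_kendall_s(xs)
    assert res.sen_slope == brute_force_sen_slope(xs, t)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.lists(st.integers(min_value=0, max_value=4), min_size=4, max_size=15))
def test_tie_corrected_variance_bounded_by_untied(xs):
    x = np.array(xs, dtype=float)
    n = len(x)
    untied = n * (n - 1) * (2 * n + 5) / 18
    v = kendall_var_s(x)
    assert v <= untied + 1e-12
    if len(set(xs)) == len(xs):
        assert v == pytest.approx(untied)


@pytest.mark.parametrize(
    "x, t, expected",
    [
        (2 * np.arange(8.0) + 5, np.arange(8.0), 20.0),  # exact linear: 2/yr
        ([1.0, 2.0, 4.0], [0.0, 1.0, 2.0], 15.0),  # slopes {1, 1.5, 2} -> 1.5/yr
    ],
)
def test_sen_slope_examples(x, t, expected):
    assert sen_slope(x, t) == pytest.approx(expected)


def test_acf_screen_flags_alternating_and_ar1():
    alt = np.tile([1.0, -1.0], 50)
    flagged, r = autocorr_screen(alt)
    assert flagged and r[0] == pytest.approx(-1.0, abs=0.05)

    rng = np.random.default_rng(3)
    x = np.zeros(100)
    for i in range(1, 100):
        x[i] = 0.9 * x[i - 1] + rng.normal()
    flagged, r = autocorr_screen(x)
    assert flagged and r[0] > 1.96 / 10


def test_acf_screen_iid_noise_behaves_like_white_noise():
    rng = np.random.default_rng(12)
    r1 = [autocorr_screen(rng.normal(size=100))[1][0] for _ in range(300)]
    assert np.mean(np.abs(r1)) < 2 / np.sqrt(100)


def test_acf_screen_degenerate_series_not_flagged():
    flagged, r = autocorr_screen(np.full(40, 2.0))
    assert not flagged and np.isnan(r).all()


def test_regional_single_block_reduces_to_site_test():
    x = np.array([3.0, 1.0, 4.0, 1.0, 5.0, 9.0, 2.0])
    t = np.arange(7.0)
    reg = regional_kendall({"only": (x, t)})
    site = mann_kendall(x, t)
    assert reg.S_total == site.S
    assert reg.var_total == pytest.approx(site.var_S)
    assert reg.p == pytest.approx(site.p)
    assert reg.sen_slope == pytest.approx(site.sen_slope)


def test_regional_two_increasing_blocks_closed_form():
    x = np.arange(1.0, 6.0)
    t = np.arange(5.0)
    reg = regional_kendall({"a": (x, t), "b": (x, t)})
    assert reg.S_total == 20
    assert reg.var_total == pytest.approx(2 * (5 * 4 * 15) / 18)
    assert reg.z == pytest.approx(19 / np.sqrt(2 * (5 * 4 * 15) / 18))


def test_regional_opposite_blocks_cancel():
    x = np.arange(1.0, 6.0)
    t = np.arange(5.0)
    reg = regional_kendall({"up": (x, t), "down": (-x, t)})
    assert reg.S_total == 0
    assert reg.p == 1.0
    assert reg.sen_slope == pytest.approx(0.0)


def test_regional_b_copies_scale_s_and_var_exactly():
    rng = np.random.default_rng(5)
    x = rng.normal(size=20)
    t = np.arange(20.0)
    one = regional_kendall({"a": (x, t)})
    for b in (2, 5):
        many = regional_kendall({f"s{i}": (x, t) for i in range(b)})
        assert many.S_total == b * one.S_total
        assert many.var_total == pytest.approx(b * one.var_total)


@pytest.mark.parametrize(
    "lon, region",
    [(-88.0, "west"), (-87.0, "central"), (-80.0, "central"), (-78.0, "east"), (-70.0, "east")],
)
def test_subregion_assignment(lon, region):
    assert assign_subregion(lon) == region


def test_summarize_trends_uses_significant_sites_only():
    site_trends = pd.DataFrame(
        {
            "station_id": ["a", "b", "c"],
            "indicator": ["frost"] * 3,
            "subregion": ["west"] * 3,
            "p": [0.01, 0.02, 0.50],
            "sen_slope": [1.0, 2.1, -0.5],
        }
    )
    out = summarize_trends(site_trends, regional={}, alpha=0.05).iloc[0]
    assert out["n_pos"] == 2 and out["n_neg"] == 0
    assert out["med_slope"] == pytest.approx(1.55)
    assert out["min_slope"] == 1.0 and out["max_slope"] == 2.1

    none_sig = site_trends.assign(p=0.9)
    out2 = summarize_trends(none_sig, regional={}).iloc[0]
    assert out2["n_pos"] == 0 and out2["n_neg"] == 0
    assert np.isnan(out2["med_slope"])


def test_summarize_levels_order_statistics():
    def mat(median_count):
        idx = pd.Index(range(2000, 2010), name="winter_year")
        return pd.DataFrame({"frost": [median_count] * 10}, index=idx)

    matrices = {"a": mat(80), "b": mat(100), "c": mat(130)}
    out = summarize_levels(
        matrices, {"a": "west", "b": "west", "c": "west"}, indicators=["frost"]
    )
    west = out[(out["subregion"] == "west")].iloc[0]
    assert west["median"] == 100 and west["min"] == 80 and west["max"] == 130


def test_summarize_levels_ignores_missing_winters():
    idx = pd.Index(range(2000, 2010), name="winter_year")
    vals = pd.array([100] * 5 + [pd.NA] * 5, dtype="Int64")
    matrices = {"a": pd.DataFrame({"frost": vals}, index=idx)}
    out = summarize_levels(matrices, {"a": "east"}, indicators=["frost"])
    east = out[out["subregion"] == "east"].iloc[0]
    assert east["median"] == 100
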