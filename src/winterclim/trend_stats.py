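"""Nonparametric trend statistics: Mann-Kendall, Sen slope, regional
(blocked) Kendall tests, autocorrelation screening and subregion summaries.

Site-level trends use the Mann-Kendall test with tie-corrected variance and
continuity correction, with the trend magnitude from Sen's slope estimator
(median of all pairwise slopes), reported in days per decade. Regional
trends block by station: S and its variance sum across blocks under an
assumption of no cross-station correlation, and the regional Sen slope is
the median of the pooled within-block pairwise slopes. The serial-
correlation screen (sample acf to lag 30, flagged when any coefficient
leaves the 95% band) is advisory only; it reports, it never blocks a test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.tsa.stattools import acf as _sm_acf


@dataclass(frozen=True)
class TrendResult:
    """Mann-Kendall + Sen slope result for one site series."""

    n: int
    S: int
    var_S: float
    z: float
    p: float
    sen_slope: float  # days per decade
    alpha: float
    sufficient: bool = True

    @property
    def significant(self) -> bool:
        return self.sufficient and self.p < self.alpha


@dataclass(frozen=True)
class RegionalTrendResult:
    """Blocked (regional) Kendall result across stations."""

    n_blocks: int
    S_total: int
    var_total: float
    z: float
    p: float
    sen_slope: float  # days per decade, pooled pairwise slopes
    alpha: float
    sufficient: bool = True

    @property
    def significant(self) -> bool:
        return self.sufficient and self.p < self.alpha


def _clean(values, times=None):
    x = np.asarray(values, dtype=float)
    if times is None:
        t = np.arange(len(x), dtype=float)
    else:
        t = np.asarray(times, dtype=float)
    keep = ~np.isnan(x)
    return x[keep], t[keep]


def kendall_s(x: np.ndarray) -> int:
    """Kendall sum S = sum_{i<j} sign(x_j - x_i)."""
    x = np.asarray(x, dtype=float)
    diff = np.sign(x[None, :] - x[:, None])
    return int(np.triu(diff, k=1).sum())


def kendall_var_s(x: np.ndarray) -> float:
    """Tie-corrected variance of S:
    [n(n-1)(2n+5) - sum_t t(t-1)(2t+5)] / 18 over tie-group sizes t."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    _, counts = np.unique(x, return_counts=True)
    ties = counts[counts > 1].astype(float)
    tie_term = float((ties * (ties - 1) * (2 * ties + 5)).sum())
    return (n * (n - 1) * (2 * n + 5) - tie_term) / 18.0


def _mk_z(S: int, var_S: float) -> float:
    if var_S <= 0 or S == 0:
        return 0.0
    return (S - np.sign(S)) / np.sqrt(var_S)  # continuity correction


def mann_kendall(values, times=None, alpha: float = 0.05) -> TrendResult:
    """Mann-Kendall trend test with Sen slope, on the actual time axis.

    Missing values are omitted pairwise (their times drop out with them);
    fewer than 4 usable points gives an insufficient-data result. The
    p value uses the normal approximation with continuity correction.
    """
    x, t = _clean(values, times)
    n = len(x)
    if n < 4:
        return TrendResult(n, 0, 0.0, 0.0, 1.0, np.nan, alpha, sufficient=False)
    S = kendall_s(x)
    var_S = kendall_var_s(x)
    z = _mk_z(S, var_S)
    p = 2.0 * stats.norm.sf(abs(z))
    slope = sen_slope(x, t)
    return TrendResult(n, S, var_S, z, p, slope, alpha)


def pairwise_slopes(values, times=None) -> np.ndarray:
    """All (x_j - x_i)/(t_j - t_i) for i < j with distinct times."""
    x, t = _clean(values, times)
    dx = x[None, :] - x[:, None]
    dt = t[None, :] - t[:, None]
    iu = np.triu_indices(len(x), k=1)
    dx, dt = dx[iu], dt[iu]
    ok = dt != 0
    return dx[ok] / dt[ok]

def sen_slope(values, times=None) -> float:
    """Sen's slope: median pairwise slope, scaled to days per decade."""
    slopes = pairwise_slopes(values, times)
    if len(slopes) == 0:
        return np.nan
    return float(np.median(slopes)) * 10.0


def autocorr_screen(values, max_lag: int = 30):
    """Advisory serial-correlation screen on a (mean-removed) series.

    Returns ``(flagged, r)`` where ``r`` holds sample autocorrelations at
    lags 1..max_lag and ``flagged`` is True when any |r_k| exceeds the 95%
    band 1.96/sqrt(n). A zero-variance series is not flagged and returns
    NaN coefficients.
    """
    x, _ = _clean(values)
    n = len(x)
    if n <= max_lag + 1:
        raise ValueError(f"need more than {max_lag + 1} points")
    if np.var(x) == 0:
        return False, np.full(max_lag, np.nan)
    r = _sm_acf(x, nlags=max_lag, fft=True)[1:]
    flagged = bool((np.abs(r) > 1.96 / np.sqrt(n)).any())
    return flagged, r


def regional_kendall(
    blocks: dict[str, tuple[np.ndarray, np.ndarray]], alpha: float = 0.05
) -> RegionalTrendResult:
    """Regional Kendall test blocking by station.

    ``blocks`` maps station id to (values, times). S and var(S) sum over
    blocks with at least 4 usable points (no cross-block covariance); the
    regional Sen slope pools every within-block pairwise slope and takes
    one median, scaled to days per decade.
    """
    S_total, var_total, used = 0, 0.0, 0
    pooled = []
    for vals, times in blocks.values():
        x, t = _clean(vals, times)
        if len(x) < 4:
            continue
        S_total += kendall_s(x)
        var_total += kendall_var_s(x)
        pooled.append(pairwise_slopes(x, t))
        used += 1
    if used == 0:
        return RegionalTrendResult(
            0, 0, 0.0, 0.0, 1.0, np.nan, alpha, sufficient=False
        )
    z = _mk_z(S_total, var_total)
    p = 2.0 * stats.norm.sf(abs(z))
    slope = float(np.median(np.concatenate(pooled))) * 10.0
    return RegionalTrendResult(used, S_total, var_total, z, p, slope, alpha)


# --- subregions -------------------------------------------------------------

SUBREGIONS = ("west", "central", "east")
#: longitude bounds (degrees, negative west): west < -87 <= central < -78 <= east
WEST_BOUND = -87.0
EAST_BOUND = -78.0


def assign_subregion(longitude: float) -> str:
    """west / central / east by station longitude.

    Boundary meridians belong to the eastern of the two regions they
    separate (-87 is central, -78 is east).
    """
    if not -180.0 <= longitude <= 180.0:
        raise ValueError(f"longitude out of range: {longitude}")
    if longitude < WEST_BOUND:
        return "west"
    if longitude < EAST_BOUND:
        return "central"
    return "east"


def summarize_trends(
    site_trends: pd.DataFrame,
    regional: dict[tuple[str, str], RegionalTrendResult],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Subregion trend roll-up in the style of a regional summary table.

    ``site_trends`` needs columns station_id, indicator, subregion, p,
    sen_slope. For each (indicator, subregion): counts of significant
    positive/negative sites, median/min/max Sen slope over significant
    sites only, and the regional slope (NaN-marked not-significant when the
    regional p >= alpha).
    """
    rows = []
    for (ind, sub), grp in site_trends.groupby(["indicator", "subregion"]):
        sig = grp[grp["p"] < alpha]
        slopes = sig["sen_slope"].to_numpy(dtype=float)
        reg = regional.get((ind, sub))
        rows.append(
            {
                "indicator": ind,
                "subregion": sub,
                "n_sites": len(grp),
                "n_pos": int((slopes > 0).sum()),
                "n_neg": int((slopes < 0).sum()),
                "med_slope": float(np.median(slopes)) if len(slopes) else np.nan,
                "min_slope": float(slopes.min()) if len(slopes) else np.nan,
                "max_slope": float(slopes.max()) if len(slopes) else np.nan,
                "reg_slope": reg.sen_slope if reg is not None else np.nan,
                "reg_p": reg.p if reg is not None else np.nan,
                "reg_significant": (
                    bool(reg.significant) if reg is not None else False
                ),
            }
        )
    return pd.DataFrame(rows)


def summarize_levels(
    matrices: dict[str, pd.DataFrame],
    subregion_of: dict[str, str],
    indicators: list[str] | None = None,
) -> pd.DataFrame:
    """Long-term level summary: per subregion, the median and range across
    stations of each station's long-term median annual indicator count.
    Missing winters are excluded from station medians.
    """
    from .indicators import INDICATORS

    indicators = indicators or list(INDICATORS)
    rows = []
    station_medians: dict[str, dict[str, float]] = {}
    for sid, mat in matrices.items():
        station_medians[sid] = {
            ind: float(mat[ind].dropna().median())
            if ind in mat and mat[ind].notna().any()
            else np.nan
            for ind in indicators
        }
    for sub in SUBREGIONS:
        sids = [s for s, r in subregion_of.items() if r == sub and s in station_medians]
        for ind in indicators:
            meds = np.array(
                [station_medians[s][ind] for s in sids], dtype=float
            )
            meds = meds[~np.isnan(meds)]
            rows.append(
                {
                    "indicator": ind,
                    "subregion": sub,
                    "n_sites": len(meds),
                    "median": float(np.median(meds)) if len(meds) else np.nan,
                    "min": float(meds.min()) if len(meds) else np.nan,
                    "max": float(meds.max()) if len(meds) else np.nan,
                }
            )
    return pd.DataFrame(rows)
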