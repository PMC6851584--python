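"""Record-completeness screening and snow gap-filling.

Completeness is judged per winter (the full 1 Nov - 31 May calendar window,
212 or 213 days): a winter is valid for a variable when its missing
fraction is at or below the configured threshold, and a station passes when
it has enough valid winters of temperature and/or precipitation.

Snow gap-filling repairs two well-known pathologies of cooperative-observer
snow records — snowfall left blank on dry days, and snow depth left blank
instead of recorded as zero when no snow is on the ground — plus short
interior depth gaps. Observed values are never altered and every filled
value is flagged imputed; the operation is idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .indicators import assign_winters, winter_window_index
from .snow_model import SnowParams
from .station_io import StationSeries, require_valid


@dataclass(frozen=True)
class QcParams:
    """Completeness thresholds (fractions per winter, counts per station)."""

    max_missing_frac_temp: float = 0.10
    max_missing_frac_prcp: float = 0.10
    min_valid_winters: int = 90

    def __post_init__(self) -> None:
        for f in (self.max_missing_frac_temp, self.max_missing_frac_prcp):
            if not 0.0 <= f <= 1.0:
                raise ValueError("missing fractions must be in [0, 1]")
        if self.min_valid_winters < 2:
            raise ValueError("min_valid_winters must be >= 2")


@dataclass(frozen=True)
class GapfillRules:
    """Snow gap-fill configuration. ``k`` bounds repairable gap lengths (days)."""

    k: int = 7
    #: tmax above this (degC) on a no-precip-report day implies rain, not snow
    rain_tmax: float = 2.0


def screen_completeness(
    series: StationSeries, qc: QcParams = QcParams()
) -> tuple[pd.DataFrame, bool]:
    """Per-winter validity verdicts plus the station-level pass/fail.

    Returns a frame with columns winter_year, missing fraction per variable,
    valid_temp, valid_prcp — one row per winter the record touches — and a
    boolean: True when the number of winters valid for temperature and/or
    precipitation reaches ``min_valid_winters``. Missing fractions are taken
    over the full calendar winter window, so winters truncated at the record
    edges count their uncovered days as missing.
    """
    require_valid(series)
    winters = assign_winters(series.data.index)
    years = sorted({int(w) for w in winters if not np.isnan(w)})
    rows = []
    for wy in years:
        window = winter_window_index(wy)
        chunk = series.data.reindex(window)
        frac = {
            v: float(chunk[v].isna().mean())
            for v in ("tmin", "tmax", "prcp", "snowfall", "snow_depth")
        }
        valid_temp = (
            max(frac["tmin"], frac["tmax"]) <= qc.max_missing_frac_temp
        )
        valid_prcp = frac["prcp"] <= qc.max_missing_frac_prcp
        rows.append(
            {
                "station_id": series.meta.station_id,
                "winter_year": wy,
                **{f"missing_frac_{v}": f for v, f in frac.items()},
                "valid_temp": valid_temp,
                "valid_prcp": valid_prcp,
            }
        )
    report = pd.DataFrame(rows)
    if report.empty:
        return report, False
    n_valid = int((report["valid_temp"] | report["valid_prcp"]).sum())
    return report, n_valid >= qc.min_valid_winters


def _fill_runs(depth: np.ndarray, k: int):
    """Find fills for maximal interior NaN runs of length <= k.

    Returns (values, fill_mask). Runs flanked by two zeros fill with zero;
    runs flanked by two positives fill by linear interpolation; mixed
    flanks are left missing (no stated rule covers them).
    """
    n = len(depth)
    out = depth.copy()
    filled = np.zeros(n, dtype=bool)
    isna = np.isnan(depth)
    i = 0
    while i < n:
        if not isna[i]:
            i += 1
            continue
        j = i
        while j < n and isna[j]:
            j += 1
        run = j - i  # gap [i, j)
        if i > 0 and j < n and run <= k:
            left, right = depth[i - 1], depth[j]
            if left == 0 and right == 0:
                out[i:j] = 0.0
                filled[i:j] = True
            elif left > 0 and right > 0:
                out[i:j] = left + (right - left) * np.arange(1, run + 1) / (
                    run + 1
                )
                filled[i:j] = True
        i = j
    return out, filled


def gapfill_snow(
    series: StationSeries, rules: GapfillRules = GapfillRules()
) -> StationSeries:
    """Apply the snow gap-fill rules; returns a new flagged series.

    (a) missing snowfall is set to 0 on days whose precipitation was 0, or
    whose precipitation is unreported but tmax clearly indicates rain-phase
    conditions would not have produced snow anyway (tmax > ``rain_tmax``);
    (b) missing snow depth flanked by observed zeros within ``k`` days on
    both sides is set to 0 (the unreported-zero repair); (c) interior depth
    gaps of length <= ``k`` flanked by positive observations are linearly
    interpolated. The input is not modified; fills are marked in
    ``imputed``.
    """
    require_valid(series)
    out = series.copy()
    df = out.data
    imputed = pd.DataFrame(
        False, index=df.index, columns=df.columns
    ) if out.imputed is None else out.imputed

    # rule a: dry-day snowfall zeros
    sf_missing = df["snowfall"].isna()
    dry = df["prcp"] == 0
    warm_noreport = df["prcp"].isna() & (df["tmax"] > rules.rain_tmax)
    fill_a = (sf_missing & (dry | warm_noreport)).to_numpy()
    df.loc[fill_a, "snowfall"] = 0.0
    imputed.loc[fill_a, "snowfall"] = True

    # rules b + c: depth runs. Gaps here are runs of missing values on the
    # *recorded* dates; absent calendar dates are genuine record gaps and
    # are not invented.
    depth, filled = _fill_runs(df["snow_depth"].to_numpy(), rules.k)
    df["snow_depth"] = depth
    imputed.loc[filled, "snow_depth"] = True

    out.imputed = imputed
    return out
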