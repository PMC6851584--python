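"""Reading, writing and validating daily station weather records.

Internal conventions (fixed): temperatures in degrees Celsius, precipitation
in mm liquid equivalent, snowfall and snow depth in mm. Missing values are
NaN. Input files declare their own column names, unit scale and missing
sentinel through a :class:`CsvDialect`; everything downstream of this module
sees only the internal convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical daily-record variables, in column order
VARIABLES = ("tmin", "tmax", "prcp", "snowfall", "snow_depth")


class StationFormatError(ValueError):
    """Raised when a station file cannot be parsed under the given dialect."""


@dataclass(frozen=True)
class StationMeta:
    """Identity and location of one weather station."""

    station_id: str
    latitude: float
    longitude: float
    name: str = ""

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude out of range: {self.latitude}")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude out of range: {self.longitude}")


@dataclass
class StationSeries:
    """One station's daily records plus metadata.

    ``data`` is indexed by calendar date (strictly increasing, no
    duplicates; gaps allowed) with float columns ``tmin, tmax, prcp,
    snowfall, snow_depth`` in internal units. ``imputed`` is an optional
    same-shaped boolean frame marking gap-filled values.
    """

    meta: StationMeta
    data: pd.DataFrame
    imputed: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        df = self.data
        missing_cols = [c for c in VARIABLES if c not in df.columns]
        if missing_cols:
            raise ValueError(f"missing columns: {missing_cols}")
        if not isinstance(df.index, pd.DatetimeIndex):
            raise ValueError("data must be indexed by date")

    def copy(self) -> "StationSeries":
        return replace(
            self,
            data=self.data.copy(),
            imputed=None if self.imputed is None else self.imputed.copy(),
        )


@dataclass(frozen=True)
class CsvDialect:
    """Column mapping, unit scale and missing sentinel for a station CSV.

    ``scale`` maps internal variable names to multiplicative factors applied
    after sentinel removal (e.g. 0.1 for files storing tenths of a degree).
    """

    date_col: str = "date"
    columns: dict[str, str] = field(
        default_factory=lambda: {v: v for v in VARIABLES}
    )
    scale: dict[str, float] = field(default_factory=dict)
    sentinel: float = -9999.0
    #: pandas date format spec; None falls back to per-element inference
    date_format: str | None = "ISO8601"


DEFAULT_DIALECT = CsvDialect()

#: GHCN-Daily-style wide layout storing tenths of units
TENTHS_DIALECT = CsvDialect(scale={v: 0.1 for v in VARIABLES})


def read_station_daily(
    path,
    meta: StationMeta,
    dialect: CsvDialect = DEFAULT_DIALECT,
) -> StationSeries:
    """Read one station's daily CSV into the internal data model.

    Sentinel values become NaN, the dialect's unit scale is applied, rows
    with unparseable dates are dropped, and rows violating tmin <= tmax are
    quarantined (both temperatures set missing) with a logged warning.
    """
    try:
        raw = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - passthrough
        raise StationFormatError(f"cannot read {path}: {exc}") from exc
    needed = [dialect.date_col] + [dialect.columns[v] for v in VARIABLES]
    absent = [c for c in needed if c not in raw.columns]
    if absent:
        raise StationFormatError(
            f"{path}: header lacks required columns {absent}"
        )
    dates = pd.to_datetime(
        raw[dialect.date_col], errors="coerce", format=dialect.date_format
    )
    bad_dates = dates.isna()
    if bad_dates.any():
        logger.warning(
            "%s: dropped %d rows with unparseable dates", path, bad_dates.sum()
        )
    raw = raw.loc[~bad_dates]
    dates = dates[~bad_dates]

    df = pd.DataFrame(index=pd.DatetimeIndex(dates.values, name="date"))
    for var in VARIABLES:
        col = pd.to_numeric(raw[dialect.columns[var]], errors="coerce").values
        col = np.where(col == dialect.sentinel, np.nan, col).astype(float)
        col = col * dialect.scale.get(var, 1.0)
        df[var] = col

    # tmin > tmax cannot be repaired without fabricating data: quarantine.
    bad = (df["tmin"] > df["tmax"]).to_numpy()
    if bad.any():
        logger.warning(
            "%s: quarantined %d rows with tmin > tmax", path, int(bad.sum())
        )
        df.loc[bad, ["tmin", "tmax"]] = np.nan
    for var in ("prcp", "snowfall", "snow_depth"):
        neg = (df[var] < 0).to_numpy()
        if neg.any():
            logger.warning(
                "%s: set %d negative %s values missing", path, int(neg.sum()), var
            )
            df.loc[neg, var] = np.nan
    return StationSeries(meta=meta, data=df)


def write_station_daily(
    series: StationSeries, path, dialect: CsvDialect = DEFAULT_DIALECT
) -> None:
    """Write a StationSeries in the given CSV dialect (inverse of read).

    Values are rounded to the dialect's 0.1-unit resolution; NaN becomes the
    sentinel.
    """
    out = pd.DataFrame(
        {dialect.date_col: series.data.index.strftime("%Y-%m-%d")}
    )
    for var in VARIABLES:
        vals = series.data[var].to_numpy() / dialect.scale.get(var, 1.0)
        vals = np.round(vals, 1)
        out[dialect.columns[var]] = np.where(
            np.isnan(vals), dialect.sentinel, vals
        )
    out.to_csv(path, index=False)


def read_station_metadata(path) -> list[StationMeta]:
    """Read the station roster CSV (station_id, lat, lon, name)."""
    df = pd.read_csv(path, dtype={"station_id": str})
    for col in ("station_id", "lat", "lon"):
        if col not in df.columns:
            raise StationFormatError(f"{path}: metadata lacks column {col!r}")
    metas = [
        StationMeta(
            station_id=row.station_id,
            latitude=float(row.lat),
            longitude=float(row.lon),
            name=str(getattr(row, "name_", getattr(row, "name", ""))) or "",
        )
        for row in df.itertuples(index=False)
    ]
    ids = [m.station_id for m in metas]
    if len(set(ids)) != len(ids):
        raise StationFormatError(f"{path}: duplicate station ids")
    return metas


def write_station_metadata(metas: list[StationMeta], path) -> None:
    pd.DataFrame(
        {
            "station_id": [m.station_id for m in metas],
            "lat": [m.latitude for m in metas],
            "lon": [m.longitude for m in metas],
            "name": [m.name for m in metas],
        }
    ).to_csv(path, index=False)


def validate_series(series: StationSeries) -> dict:
    """Pure validation report for a station series.

    Returns a dict with ``duplicate_dates`` (list), ``unsorted`` (bool) and
    ``missing_fractions`` — a DataFrame of per-winter missing fractions for
    each variable over the 1 Nov - 31 May window. The series is not
    modified; duplicate dates are reported, never dropped.
    """
    from .indicators import assign_winters, winter_window_index

    idx = series.data.index
    dupes = idx[idx.duplicated()].unique().tolist()
    unsorted = not idx.is_monotonic_increasing

    winters = assign_winters(idx)
    frames = {}
    valid_winters = sorted({w for w in winters if w is not None and not np.isnan(w)})
    # fractions computed on a first-occurrence view so duplicated dates do
    # not crash the report; the duplicates themselves are listed above
    deduped = series.data[~idx.duplicated()]
    rows = []
    for w in valid_winters:
        window = winter_window_index(int(w))
        present = deduped.reindex(window)
        row = {"winter_year": int(w), "n_days": len(window)}
        for var in VARIABLES:
            row[f"missing_frac_{var}"] = float(
                present[var].isna().mean()
            )
        rows.append(row)
    frames["missing_fractions"] = pd.DataFrame(
        rows,
        columns=["winter_year", "n_days"]
        + [f"missing_frac_{v}" for v in VARIABLES],
    )
    return {
        "station_id": series.meta.station_id,
        "duplicate_dates": dupes,
        "unsorted": unsorted,
        "missing_fractions": frames["missing_fractions"],
    }


def require_valid(series: StationSeries) -> None:
    """Raise if the series violates ordering/uniqueness invariants."""
    idx = series.data.index
    if idx.duplicated().any():
        raise ValueError(
            f"{series.meta.station_id}: duplicate dates present; refusing"
        )
    if not idx.is_monotonic_increasing:
        raise ValueError(f"{series.meta.station_id}: dates not sorted")
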