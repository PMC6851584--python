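"""End-to-end pipeline: stations in, trend and level summaries out.

One :class:`PipelineConfig` drives every stage — read or synthesize daily
station series, QC screening, snow gap-filling, degree-day SWE simulation,
indicator counting, and site/regional trend statistics — deterministically
under a single seed. Each stage is a pure function of its inputs and the
config, and a run manifest records the resolved configuration hash and
per-stage record counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .indicators import (
    INDICATORS,
    ThresholdConfig,
    build_indicator_matrix,
)
from .qc_gapfill import GapfillRules, QcParams, gapfill_snow, screen_completeness
from .snow_model import SnowParams, simulate_swe
from .station_io import (
    DEFAULT_DIALECT,
    StationMeta,
    StationSeries,
    read_station_daily,
    read_station_metadata,
)
from .synthetic_weather import GenParams, MissSpec, generate_daily_series, inject_missingness
from .trend_stats import (
    RegionalTrendResult,
    assign_subregion,
    autocorr_screen,
    mann_kendall,
    regional_kendall,
    summarize_levels,
    summarize_trends,
)

logger = logging.getLogger(__name__)


@dataclass
class SyntheticStation:
    """One synthetic station: metadata plus generator overrides."""

    station_id: str
    latitude: float
    longitude: float
    gen: GenParams = field(default_factory=GenParams)
    miss: MissSpec | None = None


@dataclass
class PipelineConfig:
    """Resolved configuration for one pipeline run."""

    mode: str = "synthesize"  # "synthesize" | "read"
    synthetic_stations: list[SyntheticStation] = field(default_factory=list)
    station_files: dict[str, str] = field(default_factory=dict)
    metadata_file: str | None = None
    qc: QcParams = field(default_factory=QcParams)
    gapfill: GapfillRules = field(default_factory=GapfillRules)
    snow: SnowParams = field(default_factory=SnowParams)
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    alpha: float = 0.05
    acf_max_lag: int = 30
    seed: int = 0
    apply_qc: bool = True

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {
                    f.name: enc(getattr(obj, f.name))
                    for f in dataclasses.fields(obj)
                }
            if isinstance(obj, dict):
                return {k: enc(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [enc(v) for v in obj]
            return obj

        return enc(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def station_seed(global_seed: int, station_id: str) -> int:
    """Stable per-station substream seed (< 2^31), keyed by station id so
    adding a station never perturbs another station's data."""
    ss = np.random.SeedSequence([global_seed, zlib.crc32(station_id.encode())])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def config_from_yaml(path) -> PipelineConfig:
    """Load a pipeline config from YAML (missing keys take defaults)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    stations = []
    for s in raw.pop("synthetic_stations", []):
        gen = GenParams(**s.pop("gen", {}))
        miss = s.pop("miss", None)
        stations.append(
            SyntheticStation(
                station_id=s["station_id"],
                latitude=s.get("latitude", 45.0),
                longitude=s["longitude"],
                gen=gen,
                miss=MissSpec(**miss) if miss else None,
            )
        )
    kwargs = {}
    for key, cls in (
        ("qc", QcParams),
        ("gapfill", GapfillRules),
        ("snow", SnowParams),
        ("thresholds", ThresholdConfig),
    ):
        if key in raw:
            sub = raw.pop(key)
            for k, v in list(sub.items()):
                if isinstance(v, list):
                    sub[k] = tuple(v)
            kwargs[key] = cls(**sub)
    return PipelineConfig(synthetic_stations=stations, **kwargs, **raw)


def load_stations(config: PipelineConfig) -> dict[str, StationSeries]:
    """Stage 1: produce the per-station daily series."""
    out: dict[str, StationSeries] = {}
    if config.mode == "synthesize":
        for st in config.synthetic_stations:
            seed = station_seed(config.seed, st.station_id)
            gen = dataclasses.replace(st.gen, seed=seed)
            meta = StationMeta(st.station_id, st.latitude, st.longitude)
            series = generate_daily_series(gen, meta=meta, snow_params=config.snow)
            if st.miss is not None:
                series = inject_missingness(series, st.miss, seed=seed + 1)
            out[st.station_id] = series
    elif config.mode == "read":
        if config.metadata_file is None:
            raise ValueError("read mode requires metadata_file")
        metas = {m.station_id: m for m in read_station_metadata(config.metadata_file)}
        for sid, path in config.station_files.items():
            out[sid] = read_station_daily(path, metas[sid], DEFAULT_DIALECT)
    else:
        raise ValueError(f"unknown mode: {config.mode}")
    return out


@dataclass
class PipelineResult:
    qc_report: pd.DataFrame
    station_pass: dict[str, bool]
    indicator_matrices: dict[str, pd.DataFrame]
    site_trends: pd.DataFrame
    regional_trends: pd.DataFrame
    trend_summary: pd.DataFrame
    level_summary: pd.DataFrame
    manifest: dict


def run_pipeline(
    config: PipelineConfig, outdir: str | Path | None = None
) -> PipelineResult:
    """Run every stage; optionally write all artifacts as CSV + manifest."""
    stations = load_stations(config)
    qc_frames, station_pass = [], {}
    matrices: dict[str, pd.DataFrame] = {}
    subregion_of: dict[str, str] = {}

    for sid, series in stations.items():
        report, passed = screen_completeness(series, config.qc)
        qc_frames.append(report)
        station_pass[sid] = passed
        if config.apply_qc and not passed:
            logger.info("station %s failed completeness screening", sid)
            continue
        filled = gapfill_snow(series, config.gapfill)
        swe = simulate_swe(filled, config.snow)
        validity = report if config.apply_qc else None
        matrices[sid] = build_indicator_matrix(
            filled,
            swe=swe,
            validity=validity,
            thr=config.thresholds,
            snow_params=config.snow,
        )
        subregion_of[sid] = assign_subregion(series.meta.longitude)

    qc_report = (
        pd.concat(qc_frames, ignore_index=True) if qc_frames else pd.DataFrame()
    )

    site_rows = []
    for sid, mat in matrices.items():
        years = mat.index.to_numpy(dtype=float)
        for ind in INDICATORS:
            vals = mat[ind].to_numpy(dtype=float)
            res = mann_kendall(vals, years, alpha=config.alpha)
            acf_flag = np.nan
            n_obs = int(np.sum(~np.isnan(vals)))
            if n_obs > config.acf_max_lag + 1 and np.nanvar(vals) > 0:
                acf_flag, _ = autocorr_screen(vals, config.acf_max_lag)
            site_rows.append(
                {
                    "station_id": sid,
                    "indicator": ind,
                    "subregion": subregion_of[sid],
                    "n": res.n,
                    "S": res.S,
                    "var_S": res.var_S,
                    "z": res.z,
                    "p": res.p,
                    "sen_slope": res.sen_slope,
                    "significant": res.significant,
                    "acf_flag": acf_flag,
                }
            )
    site_trends = pd.DataFrame(site_rows)

    regional: dict[tuple[str, str], RegionalTrendResult] = {}
    reg_rows = []
    regions = ["west", "central", "east", "all"]
    for ind in INDICATORS:
        for region in regions:
            blocks = {
                sid: (
                    mat[ind].to_numpy(dtype=float),
                    mat.index.to_numpy(dtype=float),
                )
                for sid, mat in matrices.items()
                if region == "all" or subregion_of[sid] == region
            }
            if not blocks:
                continue
            res = regional_kendall(blocks, alpha=config.alpha)
            regional[(ind, region)] = res
            reg_rows.append(
                {
                    "indicator": ind,
                    "subregion": region,
                    "n_blocks": res.n_blocks,
                    "S_total": res.S_total,
                    "var_total": res.var_total,
                    "z": res.z,
                    "p": res.p,
                    "sen_slope": res.sen_slope,
                    "significant": res.significant,
                }
            )
    regional_trends = pd.DataFrame(reg_rows)

    trend_summary = (
        summarize_trends(site_trends, regional, alpha=config.alpha)
        if not site_trends.empty
        else pd.DataFrame()
    )
    level_summary = summarize_levels(matrices, subregion_of)

    manifest = {
        "winterclim_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_stations_in": len(stations),
        "n_stations_passed": len(matrices),
        "n_site_winters": int(sum(len(m) for m in matrices.values())),
        "n_site_trends": len(site_trends),
    }

    result = PipelineResult(
        qc_report=qc_report,
        station_pass=station_pass,
        indicator_matrices=matrices,
        site_trends=site_trends,
        regional_trends=regional_trends,
        trend_summary=trend_summary,
        level_summary=level_summary,
        manifest=manifest,
    )
    if outdir is not None:
        write_artifacts(result, outdir)
    return result


def write_artifacts(result: PipelineResult, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.qc_report.to_csv(outdir / "qc_report.csv", index=False)
    result.site_trends.to_csv(outdir / "site_trends.csv", index=False)
    result.regional_trends.to_csv(outdir / "regional_trends.csv", index=False)
    result.trend_summary.to_csv(outdir / "trend_summary.csv", index=False)
    result.level_summary.to_csv(outdir / "level_summary.csv", index=False)
    for sid, mat in result.indicator_matrices.items():
        mat.to_csv(outdir / f"indicators_{sid}.csv")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
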