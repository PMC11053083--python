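"""End-to-end orchestration: gen → assess → forecast → simulate → fuse → report.

Each stage is a thin function over the library modules, reading and
writing the documented CSV/JSON schemas so stages also compose via files
from the command line.  ``run_pipeline`` chains them and writes a
manifest with a checksum per artifact; fixed (config, seed) reproduce the
manifest bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import crowdsim, exposure, forecasting, fusion, streams, synthetic
from .config import PipelineConfig, load_config

__all__ = [
    "run_pipeline",
    "stage_gen",
    "stage_assess",
    "stage_forecast",
    "stage_simulate_event",
    "stage_fuse",
    "stage_report",
]

log = logging.getLogger("heattwin")


def _timed(stage):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            out = fn(*args, **kwargs)
            log.info("stage %s finished in %.2f s", stage, time.perf_counter() - t0)
            return out
        return inner
    return wrap


@_timed("gen")
def stage_gen(config: PipelineConfig, out_dir: Path) -> dict:
    """Generate the benchmark-week input bundle when no inputs are given."""
    paths = synthetic.make_benchmark_week(config.seed, out_dir / "data")
    return {k: str(v) for k, v in paths.items()}


@_timed("assess")
def stage_assess(config: PipelineConfig, meteo_path, counts_path,
                 out_dir: Path) -> dict[str, pd.DataFrame]:
    """Resample both streams to the pipeline grid and tabulate exposure."""
    width = pd.Timedelta(seconds=config.bin_width_s)
    samples = streams.read_meteo_csv(meteo_path)
    count_list = {cs.location_id: cs for cs in streams.read_counts_csv(counts_path)}
    tables: dict[str, pd.DataFrame] = {}
    for loc in config.locations:
        loc_samples = [s for s in samples if s.location_id == loc]
        if not loc_samples or loc not in count_list:
            log.warning("location %s missing from inputs; skipped", loc)
            continue
        meteo = streams.resample_meteo(loc_samples, width)
        if config.interpolate_gaps:
            meteo = streams.interpolate_meteo_gaps(meteo)
        counts = count_list[loc]
        if counts.bin_width != width:
            counts = streams.resample_counts(counts, width)
        tables[loc] = exposure.exposure_table(meteo, counts)
    out_path = out_dir / "exposure.csv"
    combined = pd.concat(
        [t.reset_index() for t in tables.values()], ignore_index=True
    ) if tables else pd.DataFrame()
    combined.to_csv(out_path, index=False)
    return tables


@_timed("forecast")
def stage_forecast(config: PipelineConfig, tables: dict[str, pd.DataFrame],
                   out_dir: Path) -> dict[str, dict[str, forecasting.Forecast]]:
    """Train per-location THI and count models; forecast the final horizon.

    The last ``horizon`` bins are held out as the forecast window and the
    models train on everything before it — the SCDT posture of predicting
    the next day from the accumulated week.
    """
    h = config.horizon
    out: dict[str, dict[str, forecasting.Forecast]] = {}
    payload: dict = {}
    for loc in sorted(tables):
        table = tables[loc]
        if len(table) <= h + 2:
            raise streams.StreamError(
                f"location {loc}: {len(table)} bins is too short for a "
                f"{h}-bin forecast window"
            )
        train = table.iloc[:-h]
        out[loc] = {}
        payload[loc] = {}
        for target, series in (
            ("thi", train["thi"]),
            ("count", train["count"]),
        ):
            order = config.order_for(target)
            if order == "auto":
                order = forecasting.auto_order(series, s=24)
                log.info("auto order for %s/%s: %s", loc, target, order)
            if target == "count":
                cs = streams.CountSeries(
                    loc, pd.Timedelta(seconds=config.bin_width_s), series
                )
                fc = forecasting.forecast_counts(
                    cs, order, h, level=config.confidence_level,
                    interpolate=config.interpolate_gaps,
                )
            else:
                fitted = forecasting.fit_sarima(
                    series, order, interpolate=config.interpolate_gaps
                )
                fc = forecasting.forecast(fitted, h, level=config.confidence_level)
            out[loc][target] = fc
            payload[loc][target] = _forecast_payload(fc)
        out[loc]["cthi"] = forecasting.forecast_cthi(
            out[loc]["thi"], out[loc]["count"]
        )
        payload[loc]["cthi"] = _forecast_payload(out[loc]["cthi"])
    (out_dir / "forecast.json").write_text(json.dumps(payload, indent=1))
    return out


def _forecast_payload(fc: forecasting.Forecast) -> dict:
    return {
        "bin_start": [t.isoformat() for t in fc.index],
        "point": [float(v) for v in fc.point],
        "lower": [float(v) for v in fc.lower],
        "upper": [float(v) for v in fc.upper],
        "confidence_level": fc.level,
        "order": str(fc.order) if fc.order else None,
        "training_r2": None if fc.training_r2 is None else float(fc.training_r2),
    }


@_timed("simulate-event")
def stage_simulate_event(config: PipelineConfig, out_dir: Path) -> streams.CountSeries | None:
    if not config.scenario_path or not config.route_path:
        return None
    scenario, route = crowdsim.load_scenario(config.scenario_path, config.route_path)
    series = crowdsim.average_runs(scenario, route, base_seed=config.seed)
    streams.write_counts_csv(series, out_dir / "event_crossings.csv")
    return series


@_timed("fuse")
def stage_fuse(config: PipelineConfig, forecasts, event, out_dir: Path):
    loc = config.event_location
    if event is None or loc is None or loc not in forecasts:
        return None
    fused = fusion.predict_event_cthi(
        forecasts[loc]["thi"], forecasts[loc]["count"], event
    )
    payload = {
        "location": loc,
        "adjusted_count": _forecast_payload(fused.adjusted_counts),
        "fused_cthi": _forecast_payload(fused.cthi),
        "provenance": list(fused.provenance),
    }
    (out_dir / "fused.json").write_text(json.dumps(payload, indent=1))
    return fused


@_timed("report")
def stage_report(tables, forecasts, fused, out_dir: Path) -> None:
    flat = {
        f"{loc}/{target}": fc
        for loc, d in forecasts.items() for target, fc in d.items()
    }
    text, summary = fusion.report(tables, flat, fused)
    (out_dir / "report.txt").write_text(text)
    (out_dir / "report.json").write_text(json.dumps(summary, indent=1))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config) -> Path:
    """Run every stage; returns the path of the manifest written last.

    ``config`` is a path to a YAML file or a ``PipelineConfig``.  Inputs
    are generated with the synthetic benchmark bundle unless the config
    points at existing meteo/count CSVs.
    """
    if not isinstance(config, PipelineConfig):
        config = load_config(config)
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    meteo_path, counts_path = config.meteo_path, config.counts_path
    if meteo_path is None or counts_path is None:
        generated = stage_gen(config, out_dir)
        meteo_path = generated["meteo"]
        counts_path = generated["counts"]
        if config.scenario_path is None:
            config.scenario_path = generated["scenario"]
            config.route_path = generated["route"]
            if config.event_location is None:
                config.event_location = "11th"

    tables = stage_assess(config, meteo_path, counts_path, out_dir)
    forecasts = stage_forecast(config, tables, out_dir)
    event = stage_simulate_event(config, out_dir)
    fused = stage_fuse(config, forecasts, event, out_dir)
    stage_report(tables, forecasts, fused, out_dir)

    artifacts = sorted(
        p for p in out_dir.rglob("*")
        if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "seed": config.seed,
        "files": {
            str(p.relative_to(out_dir)): {
                "sha256": _sha256(p),
                "bytes": p.stat().st_size,
            }
            for p in artifacts
        },
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    log.info("wrote %d artifacts to %s", len(artifacts), out_dir)
    return manifest_path
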