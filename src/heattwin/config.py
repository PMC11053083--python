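"""Pipeline configuration: a strict YAML schema with full diagnostics.

Validation collects every violation (unknown keys are rejected by name)
rather than stopping at the first, so a config can be repaired in one
pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .forecasting import SarimaOrder

__all__ = ["PipelineConfig", "ConfigError", "load_config", "validate_config"]


class ConfigError(ValueError):
    def __init__(self, diagnostics):
        self.diagnostics = list(diagnostics)
        super().__init__(
            "invalid configuration:\n  " + "\n  ".join(self.diagnostics)
        )


_KNOWN_KEYS = {
    "locations", "bin_width_s", "horizon", "confidence_level",
    "thi_order", "count_order", "scenario_path", "route_path",
    "event_location", "meteo_path", "counts_path", "output_dir",
    "seed", "log_level", "days", "interpolate_gaps",
}

# fast, robust defaults for hourly streams with a daily season
_DEFAULT_THI_ORDER = (1, 0, 0, 0, 1, 1, 24)
_DEFAULT_COUNT_ORDER = (1, 0, 1, 0, 1, 1, 24)


@dataclass
class PipelineConfig:
    """Validated end-to-end pipeline settings."""

    locations: list[str] = field(default_factory=lambda: ["10th", "11th"])
    bin_width_s: int = 3600
    horizon: int = 24
    confidence_level: float = 0.95
    thi_order: object = _DEFAULT_THI_ORDER  # "auto" or 7-tuple
    count_order: object = _DEFAULT_COUNT_ORDER
    scenario_path: str | None = None
    route_path: str | None = None
    event_location: str | None = None
    meteo_path: str | None = None
    counts_path: str | None = None
    output_dir: str = "heattwin_out"
    seed: int = 0
    log_level: str = "INFO"
    days: int = 7
    interpolate_gaps: bool = False

    def order_for(self, target: str):
        """Return the configured SarimaOrder for 'thi' or 'count', or the
        string 'auto'."""
        raw = self.thi_order if target == "thi" else self.count_order
        if isinstance(raw, str):
            return "auto"
        p, d, q, P, D, Q, s = (int(v) for v in raw)
        return SarimaOrder(p, d, q, P, D, Q, s)


def _diagnose(raw: dict) -> list[str]:
    diags: list[str] = []
    if not isinstance(raw, dict):
        return ["config root must be a mapping"]
    for key in sorted(set(raw) - _KNOWN_KEYS):
        diags.append(f"unknown key: {key!r}")
    if "locations" in raw and (
        not isinstance(raw["locations"], list) or not raw["locations"]
        or not all(isinstance(x, str) for x in raw["locations"])
    ):
        diags.append("locations: must be a non-empty list of strings")
    for key in ("bin_width_s", "horizon", "days"):
        if key in raw and (not isinstance(raw[key], int) or raw[key] <= 0):
            diags.append(f"{key}: must be a positive integer")
    if "confidence_level" in raw:
        v = raw["confidence_level"]
        if not isinstance(v, (int, float)) or not 0 < v < 1:
            diags.append("confidence_level: must be in (0, 1)")
    for key in ("thi_order", "count_order"):
        if key in raw:
            v = raw[key]
            if isinstance(v, str):
                if v != "auto":
                    diags.append(f"{key}: string value must be 'auto'")
            elif isinstance(v, (list, tuple)):
                if len(v) != 7 or not all(isinstance(x, int) for x in v):
                    diags.append(f"{key}: must be 7 integers (p,d,q,P,D,Q,s)")
                else:
                    try:
                        SarimaOrder(*[int(x) for x in v])
                    except ValueError as exc:
                        diags.append(f"{key}: {exc}")
            else:
                diags.append(f"{key}: must be 'auto' or a 7-integer list")
    if "seed" in raw and not isinstance(raw["seed"], int):
        diags.append("seed: must be an integer")
    if "log_level" in raw and raw["log_level"] not in (
        "DEBUG", "INFO", "WARNING", "ERROR"
    ):
        diags.append("log_level: must be DEBUG, INFO, WARNING or ERROR")
    if "interpolate_gaps" in raw and not isinstance(raw["interpolate_gaps"], bool):
        diags.append("interpolate_gaps: must be a boolean")
    ev = raw.get("event_location")
    locs = raw.get("locations", PipelineConfig().locations)
    if ev is not None and isinstance(locs, list) and ev not in locs:
        diags.append(f"event_location: {ev!r} not in locations")
    return diags


def validate_config(path) -> list[str]:
    """Full list of schema violations in a config file (empty = valid)."""
    try:
        raw = yaml.safe_load(Path(path).read_text())
    except OSError as exc:
        raise
    except yaml.YAMLError as exc:
        return [f"unparsable YAML: {exc}"]
    if raw is None:
        raw = {}
    return _diagnose(raw)


def load_config(path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    diags = _diagnose(raw)
    if diags:
        raise ConfigError(diags)
    cfg = PipelineConfig(**{k: v for k, v in raw.items()})
    if isinstance(cfg.thi_order, list):
        cfg.thi_order = tuple(cfg.thi_order)
    if isinstance(cfg.count_order, list):
        cfg.count_order = tuple(cfg.count_order)
    return cfg
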