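"""Fusing simulated event crossings into the statistical forecast.

A seasonal time-series model trained on ordinary weeks cannot predict the
count spike a scheduled march produces.  The adjustment here is additive:
run-averaged simulated checkpoint crossings are added to the baseline
count forecast bin by bin, the collective index is recomputed from the
adjusted counts, and every bin is tagged with its provenance so reports
can distinguish purely statistical predictions from event-adjusted ones.

After run-averaging the simulation is treated as deterministic, so the
forecast's interval bounds shift by the same additive amount as the point
forecast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exposure import classify_thi
from .forecasting import Forecast, forecast_cthi
from .streams import CountSeries, StreamError

__all__ = ["FusedForecast", "fuse_counts", "predict_event_cthi", "report"]

PROVENANCE_BASELINE = "baseline"
PROVENANCE_EVENT = "baseline+event"


@dataclass
class FusedForecast:
    """Baseline and event-adjusted forecasts side by side."""

    baseline_counts: Forecast
    event: CountSeries = field(repr=False)
    adjusted_counts: Forecast = field(repr=False)
    cthi: Forecast = field(repr=False)
    provenance: pd.Series = field(repr=False)  # per-bin provenance tag

    @property
    def event_bins(self) -> pd.DatetimeIndex:
        return self.provenance.index[self.provenance == PROVENANCE_EVENT]


def fuse_counts(baseline: Forecast, event: CountSeries) -> Forecast:
    """Add simulated event crossings to the baseline count forecast.

    Overlapping bins get the per-bin sum (point and both interval bounds
    shift by the added count); bins outside the event pass through
    unchanged.  The event series must sit on the forecast's bin grid, and
    any non-zero event bin must fall inside the forecast horizon.
    """
    if baseline.bin_width is not None and event.bin_width != baseline.bin_width:
        raise StreamError(
            f"bin width mismatch: forecast {baseline.bin_width} vs event "
            f"{event.bin_width}"
        )
    add = pd.Series(0.0, index=baseline.index)
    for t, c in event.counts.items():
        if t in add.index:
            add[t] += c
        elif c != 0:
            raise StreamError(
                f"event bin {t} with {c:.1f} crossings lies outside the "
                f"forecast horizon [{baseline.index[0]}, {baseline.index[-1]}]"
            )
    shift = add.to_numpy()
    return Forecast(
        index=baseline.index,
        point=baseline.point + shift,
        lower=baseline.lower + shift,
        upper=baseline.upper + shift,
        level=baseline.level,
        order=baseline.order,
        training_r2=baseline.training_r2,
        bin_width=baseline.bin_width,
    )


def predict_event_cthi(
    thi_fc: Forecast,
    baseline_count_fc: Forecast,
    event: CountSeries,
) -> FusedForecast:
    """Event-adjusted collective-exposure forecast with provenance tags."""
    adjusted = fuse_counts(baseline_count_fc, event)
    cthi = forecast_cthi(thi_fc, adjusted)
    touched = set(t for t, c in event.counts.items() if c != 0)
    provenance = pd.Series(
        [PROVENANCE_EVENT if t in touched else PROVENANCE_BASELINE
         for t in adjusted.index],
        index=adjusted.index,
    )
    return FusedForecast(
        baseline_counts=baseline_count_fc,
        event=event,
        adjusted_counts=adjusted,
        cthi=cthi,
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def _fmt_ts(t) -> str:
    return pd.Timestamp(t).strftime("%Y-%m-%d %H:%M")


def report(
    exposure_tables: dict[str, pd.DataFrame] | None = None,
    forecasts: dict[str, Forecast] | None = None,
    fused: FusedForecast | None = None,
) -> tuple[str, dict]:
    """Deterministic human- and machine-readable assessment summary.

    Covers, per location: peak THI and CTHI with their timestamps and the
    bins exceeding the "very warm" band; plus a baseline-vs-fused
    comparison over the event bins when a fused forecast is given.
    Identical inputs yield byte-identical text.
    """
    if not exposure_tables and not forecasts and fused is None:
        raise ValueError("report needs at least one input")
    lines: list[str] = ["# Collective heat exposure report", ""]
    summary: dict = {}

    if exposure_tables:
        summary["locations"] = {}
        lines.append("## Observed exposure")
        for loc in sorted(exposure_tables):
            table = exposure_tables[loc]
            lines.append(f"### {loc}")
            if table.empty:
                lines.append("(no aligned bins)")
                continue
            t_thi = table["thi"].idxmax()
            t_cthi = table["cthi"].idxmax()
            peak_thi = float(table["thi"].max())
            peak_cthi = float(table["cthi"].max())
            level = classify_thi(peak_thi).name
            lines.append(
                f"peak THI {peak_thi:.1f} degF ({level}) at {_fmt_ts(t_thi)}"
            )
            lines.append(
                f"peak CTHI {peak_cthi:.1f} person-degF at {_fmt_ts(t_cthi)}"
            )
            exceed = table[table["level"] != "BELOW_VERY_WARM"]
            hot_plus = table[table["level"].isin(("HOT", "VERY_HOT", "EXTREMELY_HOT"))]
            if exceed.empty:
                lines.append("no bins above the very-warm bound")
            else:
                lines.append(
                    f"{len(exceed)} bins above very warm, of which "
                    f"{len(hot_plus)} hot or worse"
                )
                worst = exceed["thi"].idxmax()
                lines.append(
                    f"worst bin {_fmt_ts(worst)}: THI "
                    f"{float(exceed.loc[worst, 'thi']):.1f} "
                    f"({exceed.loc[worst, 'level']})"
                )
            summary["locations"][loc] = {
                "peak_thi": peak_thi,
                "peak_thi_time": _fmt_ts(t_thi),
                "peak_thi_level": level,
                "peak_cthi": peak_cthi,
                "peak_cthi_time": _fmt_ts(t_cthi),
                "bins_above_very_warm": int(len(exceed)),
                "bins_hot_or_worse": int(len(hot_plus)),
            }
        lines.append("")

    if forecasts:
        summary["forecasts"] = {}
        lines.append("## Forecasts")
        for key in sorted(forecasts):
            fc = forecasts[key]
            peak_i = int(np.argmax(fc.point))
            entry = {
                "peak_point": float(fc.point[peak_i]),
                "peak_time": _fmt_ts(fc.index[peak_i]),
                "order": str(fc.order) if fc.order else None,
                "training_r2": (
                    round(float(fc.training_r2), 4)
                    if fc.training_r2 is not None else None
                ),
            }
            summary["forecasts"][key] = entry
            order_txt = f" [{entry['order']}]" if entry["order"] else ""
            lines.append(
                f"{key}: peak {entry['peak_point']:.1f} at "
                f"{entry['peak_time']}{order_txt}"
            )
        lines.append("")

    if fused is not None:
        lines.append("## Black-swan fusion")
        ev = fused.event_bins
        if len(ev) == 0:
            lines.append("no event bins; fused forecast equals baseline")
            summary["fusion"] = {"event_bins": 0}
        else:
            base = fused.baseline_counts.to_frame().loc[ev, "point"]
            adj = fused.adjusted_counts.to_frame().loc[ev, "point"]
            cthi = fused.cthi.to_frame().loc[ev, "point"]
            lines.append(
                f"{len(ev)} event bins from {_fmt_ts(ev[0])} to {_fmt_ts(ev[-1])}"
            )
            lines.append("bin              baseline  adjusted  fused CTHI")
            for t in ev:
                lines.append(
                    f"{_fmt_ts(t)}  {base[t]:8.1f}  {adj[t]:8.1f}  {cthi[t]:10.1f}"
                )
            summary["fusion"] = {
                "event_bins": int(len(ev)),
                "first_event_bin": _fmt_ts(ev[0]),
                "last_event_bin": _fmt_ts(ev[-1]),
                "added_crossings": float(adj.sum() - base.sum()),
                "peak_fused_cthi": float(cthi.max()),
                "peak_fused_cthi_time": _fmt_ts(cthi.idxmax()),
            }
        lines.append("")

    return "\n".join(lines), summary
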