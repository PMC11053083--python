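"""Time-series containers for the sensor-side of the pipeline.

Two kinds of streams feed the exposure assessment: meteorological samples
(temperature in degrees Fahrenheit and relative humidity in percent, sampled
every ~30 s by roadside sensor nodes) and passersby counts per time bin
(derived from street cameras upstream; an observed count stream here).
Both are resampled onto a common uniform bin grid before any index is
computed.

Conventions
-----------
* Timestamps are timezone-naive local time at second resolution.
* Bins are half-open ``[start, start + width)`` and anchored to the epoch
  grid (a 1-h bin always starts on the hour).
* Meteorological bins with no samples are carried as explicit gaps (NaN),
  never as zeros; count bins are dense and non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MeteoSample",
    "MeteoSeries",
    "CountSeries",
    "StreamError",
    "resample_meteo",
    "resample_counts",
    "align",
    "read_meteo_csv",
    "write_meteo_csv",
    "read_counts_csv",
    "write_counts_csv",
    "interpolate_meteo_gaps",
]

#: CSV schema for raw meteorological samples.
METEO_COLUMNS = ["time", "location_id", "temperature_f", "relative_humidity_pct"]
#: CSV schema for binned count streams.
COUNT_COLUMNS = ["bin_start", "bin_width_s", "location_id", "count"]

# Plausibility guard: Eq-style THI math is Fahrenheit-specific, so readings
# far outside the habitable range are treated as probable unit errors.
TEMP_MIN_F = -80.0
TEMP_MAX_F = 150.0


class StreamError(ValueError):
    """Invalid stream data; carries per-row diagnostics when available."""

    def __init__(self, message: str, diagnostics: Sequence[str] = ()):
        self.diagnostics = list(diagnostics)
        if self.diagnostics:
            message = message + "\n  " + "\n  ".join(self.diagnostics)
        super().__init__(message)


def _as_timedelta(width) -> pd.Timedelta:
    if isinstance(width, (int, float, np.integer, np.floating)):
        width = pd.Timedelta(seconds=float(width))
    width = pd.Timedelta(width)
    if width <= pd.Timedelta(0):
        raise StreamError(f"bin width must be positive, got {width}")
    return width


@dataclass(frozen=True)
class MeteoSample:
    """One timestamped temperature/humidity observation at a location."""

    time: pd.Timestamp
    location_id: str
    temperature: float  # °F
    relative_humidity: float  # % in [0, 100]

    def __post_init__(self):
        object.__setattr__(self, "time", pd.Timestamp(self.time))
        if not np.isfinite(self.temperature):
            raise StreamError(f"non-finite temperature at {self.time}")
        if not TEMP_MIN_F <= self.temperature <= TEMP_MAX_F:
            raise StreamError(
                f"temperature {self.temperature} °F outside plausible range "
                f"[{TEMP_MIN_F}, {TEMP_MAX_F}] — probable unit error"
            )
        if not 0.0 <= self.relative_humidity <= 100.0:
            raise StreamError(
                f"relative humidity {self.relative_humidity} outside [0, 100]"
            )


@dataclass
class MeteoSeries:
    """Binned meteorological stream for one location.

    ``frame`` is indexed by bin start and has columns ``mean_temperature``
    and ``mean_humidity``; rows of NaN mark bins with no samples.
    """

    location_id: str
    bin_width: pd.Timedelta
    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        self.bin_width = _as_timedelta(self.bin_width)
        expected = {"mean_temperature", "mean_humidity"}
        if not expected.issubset(self.frame.columns):
            raise StreamError(f"MeteoSeries frame must have columns {expected}")
        idx = self.frame.index
        if len(idx) > 1:
            deltas = np.diff(idx.asi8)
            if (deltas <= 0).any():
                raise StreamError("MeteoSeries bins must be sorted and unique")
            if (deltas % int(self.bin_width.value)).any():
                raise StreamError("MeteoSeries bins must lie on a uniform grid")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def n_gaps(self) -> int:
        return int(self.frame["mean_temperature"].isna().sum())


@dataclass
class CountSeries:
    """Passersby counts per time bin for one location.

    Counts are integers for observed data but real-valued in general:
    forecast points and Monte-Carlo run averages live in the same container.
    """

    location_id: str
    bin_width: pd.Timedelta
    counts: pd.Series = field(repr=False)

    def __post_init__(self):
        self.bin_width = _as_timedelta(self.bin_width)
        s = pd.Series(self.counts, dtype=float)
        if (s < 0).any():
            bad = s[s < 0].index[0]
            raise StreamError(f"negative count at bin {bad}")
        idx = s.index
        if len(idx) > 1:
            deltas = np.diff(idx.asi8)
            if (deltas <= 0).any():
                raise StreamError("CountSeries bins must be sorted and unique")
            if (deltas % int(self.bin_width.value)).any():
                raise StreamError("CountSeries bins must lie on a uniform grid")
        self.counts = s

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def total(self) -> float:
        return float(self.counts.sum())


def resample_meteo(samples: Iterable[MeteoSample], bin_width) -> MeteoSeries:
    """Average raw samples onto a uniform bin grid.

    Per-bin arithmetic means of temperature and humidity; interior bins
    without samples come out as NaN gaps.  Input must be time-sorted and
    belong to a single location.
    """
    bin_width = _as_timedelta(bin_width)
    samples = list(samples)
    if not samples:
        return MeteoSeries(
            location_id="",
            bin_width=bin_width,
            frame=pd.DataFrame(
                columns=["mean_temperature", "mean_humidity"],
                index=pd.DatetimeIndex([], name="bin_start"),
            ),
        )
    locs = {s.location_id for s in samples}
    if len(locs) > 1:
        raise StreamError(
            f"resample_meteo expects one location per call, got {sorted(locs)}"
        )
    times = pd.DatetimeIndex([s.time for s in samples])
    if len(times) > 1 and (np.diff(times.asi8) < 0).any():
        k = int(np.argmax(np.diff(times.asi8) < 0))
        raise StreamError(
            f"samples not time-sorted: {times[k + 1]} follows {times[k]}"
        )
    df = pd.DataFrame(
        {
            "temperature": [s.temperature for s in samples],
            "humidity": [s.relative_humidity for s in samples],
        },
        index=times,
    )
    binned = df.groupby(times.floor(bin_width)).mean()
    # dense grid over the observed span so empty interior bins become gaps
    full = pd.date_range(binned.index[0], binned.index[-1], freq=bin_width)
    binned = binned.reindex(full)
    binned.index.name = "bin_start"
    binned.columns = ["mean_temperature", "mean_humidity"]
    return MeteoSeries(location_id=locs.pop(), bin_width=bin_width, frame=binned)


def resample_counts(counts: CountSeries, new_bin_width) -> CountSeries:
    """Re-bin a count stream to a coarser grid by per-bin summation.

    ``new_bin_width`` must be an integer multiple of the input width; the
    grand total is conserved exactly.
    """
    new_bin_width = _as_timedelta(new_bin_width)
    old_ns, new_ns = int(counts.bin_width.value), int(new_bin_width.value)
    if new_ns % old_ns != 0:
        raise StreamError(
            f"new bin width {new_bin_width} is not an integer multiple "
            f"of {counts.bin_width}"
        )
    if counts.counts.empty:
        return CountSeries(counts.location_id, new_bin_width, counts.counts.copy())
    summed = counts.counts.groupby(counts.counts.index.floor(new_bin_width)).sum()
    summed.index.name = "bin_start"
    return CountSeries(counts.location_id, new_bin_width, summed)


def align(meteo: MeteoSeries, counts: CountSeries) -> pd.DataFrame:
    """Inner-join meteorological and count bins on (location, bin start).

    Returns a time-sorted frame with columns ``mean_temperature``,
    ``mean_humidity`` and ``count``; empty when the streams share no bins
    or belong to different locations.  Bin widths must match.
    """
    if meteo.bin_width != counts.bin_width:
        raise StreamError(
            f"bin width mismatch: meteo {meteo.bin_width} vs counts "
            f"{counts.bin_width}"
        )
    empty = pd.DataFrame(
        columns=["mean_temperature", "mean_humidity", "count"],
        index=pd.DatetimeIndex([], name="bin_start"),
    )
    if meteo.location_id != counts.location_id:
        return empty
    joined = meteo.frame.join(counts.counts.rename("count"), how="inner")
    joined = joined.dropna(subset=["mean_temperature", "mean_humidity"])
    if joined.empty:
        return empty
    joined.index.name = "bin_start"
    return joined.sort_index()


def interpolate_meteo_gaps(series: MeteoSeries, max_gap: int = 3) -> MeteoSeries:
    """Linearly fill missing bins, refusing runs longer than ``max_gap``."""
    frame = series.frame
    missing = frame["mean_temperature"].isna()
    if not missing.any():
        return series
    # longest run of consecutive missing bins
    runs = (missing.astype(int).groupby((~missing).cumsum()).sum()).max()
    if runs > max_gap:
        raise StreamError(
            f"gap of {int(runs)} consecutive missing bins exceeds the "
            f"interpolation limit of {max_gap}"
        )
    filled = frame.interpolate(method="time", limit_direction="both")
    return MeteoSeries(series.location_id, series.bin_width, filled)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def write_meteo_csv(samples: Iterable[MeteoSample], path) -> None:
    df = pd.DataFrame(
        {
            "time": [s.time.isoformat() for s in samples],
            "location_id": [s.location_id for s in samples],
            "temperature_f": [s.temperature for s in samples],
            "relative_humidity_pct": [s.relative_humidity for s in samples],
        },
        columns=METEO_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_meteo_csv(path) -> list[MeteoSample]:
    """Read raw meteorological samples, validating every row.

    Rows are returned sorted by (location, time) regardless of file order.
    All invalid rows are reported together, each with its 1-based data row
    number.
    """
    df = pd.read_csv(path, dtype={"location_id": str}, float_precision="round_trip")
    missing = [c for c in METEO_COLUMNS if c not in df.columns]
    if missing:
        raise StreamError(f"{path}: missing columns {missing}")
    diagnostics: list[str] = []
    samples: list[MeteoSample] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=1):
        try:
            t = pd.Timestamp(row.time)
            if pd.isna(t):
                raise ValueError("not a timestamp")
        except (ValueError, TypeError):
            diagnostics.append(f"row {row_no}: unparsable timestamp {row.time!r}")
            continue
        try:
            samples.append(
                MeteoSample(
                    time=t,
                    location_id=str(row.location_id),
                    temperature=float(row.temperature_f),
                    relative_humidity=float(row.relative_humidity_pct),
                )
            )
        except (StreamError, ValueError) as exc:
            diagnostics.append(f"row {row_no}: {exc}")
    if diagnostics:
        raise StreamError(f"{path}: {len(diagnostics)} invalid rows", diagnostics)
    samples.sort(key=lambda s: (s.location_id, s.time))
    return samples


def write_counts_csv(series: CountSeries | Iterable[CountSeries], path) -> None:
    if isinstance(series, CountSeries):
        series = [series]
    frames = []
    for cs in series:
        frames.append(
            pd.DataFrame(
                {
                    "bin_start": [t.isoformat() for t in cs.counts.index],
                    "bin_width_s": int(cs.bin_width.total_seconds()),
                    "location_id": cs.location_id,
                    "count": cs.counts.to_numpy(),
                },
                columns=COUNT_COLUMNS,
            )
        )
    out = pd.concat(frames) if frames else pd.DataFrame(columns=COUNT_COLUMNS)
    out.to_csv(path, index=False)


def read_counts_csv(path) -> list[CountSeries]:
    """Read binned count streams, one ``CountSeries`` per location."""
    df = pd.read_csv(path, dtype={"location_id": str}, float_precision="round_trip")
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise StreamError(f"{path}: missing columns {missing}")
    diagnostics: list[str] = []
    parsed = []
    for row_no, row in enumerate(df.itertuples(index=False), start=1):
        try:
            t = pd.Timestamp(row.bin_start)
            if pd.isna(t):
                raise ValueError("not a timestamp")
        except (ValueError, TypeError):
            diagnostics.append(f"row {row_no}: unparsable bin_start {row.bin_start!r}")
            continue
        count = float(row.count)
        if not np.isfinite(count) or count < 0:
            diagnostics.append(f"row {row_no}: invalid count {row.count!r}")
            continue
        parsed.append((str(row.location_id), float(row.bin_width_s), t, count))
    if diagnostics:
        raise StreamError(f"{path}: {len(diagnostics)} invalid rows", diagnostics)
    out: list[CountSeries] = []
    byloc: dict[str, list] = {}
    for loc, width, t, count in parsed:
        byloc.setdefault(loc, []).append((width, t, count))
    for loc in sorted(byloc):
        rows = sorted(byloc[loc], key=lambda r: r[1])
        widths = {r[0] for r in rows}
        if len(widths) > 1:
            raise StreamError(
                f"{path}: location {loc!r} mixes bin widths {sorted(widths)}"
            )
        s = pd.Series(
            [r[2] for r in rows],
            index=pd.DatetimeIndex([r[1] for r in rows], name="bin_start"),
        )
        out.append(CountSeries(loc, pd.Timedelta(seconds=widths.pop()), s))
    return out
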