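"""Heat-exposure indices: THI, exposure levels, and the collective CTHI.

The temperature–humidity index (THI) is an empirical heat-stress measure
combining dry-bulb temperature ``t`` (°F) and relative humidity ``RH`` (%):

    THI = t − (0.55 − 0.0055·RH)(t − 58)

At ``RH = 100`` the index equals the air temperature; at ``t = 58`` °F the
humidity term vanishes.  Above 58 °F the index rises with humidity
(perspiration evaporates less efficiently into moist air), below 58 °F it
falls.

The collective index CTHI scales the heat stress at a location by the
number of people exposed to it in a time bin:

    CTHI(t, i) = THI(t, i) × P(t, i)

where P is the passersby count.  CTHI carries units of person·°F and has
no established risk thresholds; only percentile-based flagging against a
reference window is offered, as an explicitly conventional device.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .streams import CountSeries, MeteoSeries, StreamError, align

__all__ = [
    "THI_PIVOT_F",
    "ExposureLevel",
    "ExposureRecord",
    "compute_thi",
    "classify_thi",
    "compute_cthi",
    "exposure_table",
    "flag_high_cthi",
]

#: Temperature at which humidity has no effect on the index.
THI_PIVOT_F = 58.0

_COEF_A = 0.55
_COEF_B = 0.0055

# Guard band against unit mix-ups (a Celsius reading fed where Fahrenheit
# is expected typically lands far outside a plausible °F street range).
_T_MIN, _T_MAX = -80.0, 150.0


class ExposureLevel(enum.IntEnum):
    """Ordered heat-risk categories with strict lower THI bounds (°F).

    The published scale starts at "very warm"; BELOW_VERY_WARM is this
    package's explicit floor category for THI ≤ 80.
    """

    BELOW_VERY_WARM = 0
    VERY_WARM = 1      # THI > 80: prolonged activity may cause heat cramps
    HOT = 2            # THI > 90: heat cramps/exhaustion, heat stroke possible
    VERY_HOT = 3       # THI > 105: heat stroke probable in severe cases
    EXTREMELY_HOT = 4  # THI > 128: heat stroke risk is high

    @property
    def lower_bound(self) -> float:
        return _LEVEL_BOUNDS[self]


_LEVEL_BOUNDS = {
    ExposureLevel.BELOW_VERY_WARM: -np.inf,
    ExposureLevel.VERY_WARM: 80.0,
    ExposureLevel.HOT: 90.0,
    ExposureLevel.VERY_HOT: 105.0,
    ExposureLevel.EXTREMELY_HOT: 128.0,
}

_BOUNDS_ARRAY = np.array([80.0, 90.0, 105.0, 128.0])


def compute_thi(temperature, relative_humidity):
    """Temperature–humidity index in °F.

    Accepts scalars or arrays; relative humidity must lie in [0, 100] and
    temperature in a plausible Fahrenheit range (a guard against Celsius
    inputs).
    """
    t = np.asarray(temperature, dtype=float)
    rh = np.asarray(relative_humidity, dtype=float)
    if np.any((rh < 0) | (rh > 100) | ~np.isfinite(rh)):
        raise ValueError("relative humidity must be within [0, 100]")
    if np.any(~np.isfinite(t)) or np.any((t < _T_MIN) | (t > _T_MAX)):
        raise ValueError(
            f"temperature outside [{_T_MIN}, {_T_MAX}] °F — probable unit error"
        )
    thi = t - (_COEF_A - _COEF_B * rh) * (t - THI_PIVOT_F)
    return float(thi) if thi.ndim == 0 else thi


def classify_thi(thi) -> ExposureLevel | np.ndarray:
    """Map THI to its exposure level under the strict-``>`` convention.

    A value sitting exactly on a bound belongs to the band below it:
    105.0 is HOT, anything strictly above 105 is VERY_HOT.
    """
    arr = np.asarray(thi, dtype=float)
    if np.any(~np.isfinite(arr)):
        raise ValueError("THI must be finite")
    idx = np.searchsorted(_BOUNDS_ARRAY, arr, side="left")
    if arr.ndim == 0:
        return ExposureLevel(int(idx))
    return np.array([ExposureLevel(int(i)) for i in idx.ravel()]).reshape(arr.shape)


def compute_cthi(thi, count):
    """Collective THI: the exact product THI × passersby count (person·°F)."""
    c = np.asarray(count, dtype=float)
    if np.any(c < 0):
        raise ValueError("count must be non-negative")
    out = np.asarray(thi, dtype=float) * c
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ExposureRecord:
    """One bin's exposure assessment at one location."""

    location_id: str
    bin_start: pd.Timestamp
    thi: float
    level: ExposureLevel
    count: float
    cthi: float


def exposure_table(meteo: MeteoSeries, counts: CountSeries) -> pd.DataFrame:
    """Per-bin THI, exposure level and CTHI over the aligned streams.

    Returns a time-indexed frame with columns ``mean_temperature_f``,
    ``mean_humidity_pct``, ``thi``, ``level`` (category name), ``count``
    and ``cthi``; one row per bin present in both streams.
    """
    joined = align(meteo, counts)
    thi = compute_thi(
        joined["mean_temperature"].to_numpy(),
        joined["mean_humidity"].to_numpy(),
    ) if len(joined) else np.array([])
    levels = [classify_thi(v).name for v in np.atleast_1d(thi)] if len(joined) else []
    out = pd.DataFrame(
        {
            "location_id": counts.location_id,
            "mean_temperature_f": joined["mean_temperature"],
            "mean_humidity_pct": joined["mean_humidity"],
            "thi": np.atleast_1d(thi) if len(joined) else [],
            "level": levels,
            "count": joined["count"],
        },
        index=joined.index,
    )
    out["cthi"] = compute_cthi(out["thi"].to_numpy(), out["count"].to_numpy()) if len(out) else []
    return out


def flag_high_cthi(cthi: pd.Series, reference: pd.Series | None = None,
                   top_fraction: float = 0.25) -> pd.Series:
    """Percentile-based CTHI flagging — an explicit convention, not a
    published threshold.

    Marks bins whose CTHI lies in the top ``top_fraction`` of the
    reference window (the series itself by default).  No absolute CTHI
    risk scale exists; this is the standing-in device for one.
    """
    if not 0 < top_fraction < 1:
        raise ValueError("top_fraction must be in (0, 1)")
    ref = cthi if reference is None else reference
    if ref.empty:
        raise StreamError("empty reference window for CTHI flagging")
    cutoff = float(np.quantile(ref.to_numpy(), 1 - top_fraction))
    return cthi > cutoff
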