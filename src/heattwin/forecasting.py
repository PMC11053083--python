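"""Seasonal ARIMA forecasting of THI and passersby-count streams.

Both targets are forecast separately with SARIMA models of order
``(p, d, q)(P, D, Q)_s`` fit by maximum Gaussian likelihood through the
statsmodels state-space machinery; the collective index forecast is then
the pointwise product of the two.  The seasonal period defaults to 24
(hourly bins, daily cycle).

An intercept is included whenever the model applies no differencing, so
the order ``(0,0,0)(0,0,0)_s`` degenerates to the sample-mean model.
Order selection (`auto_order`) is a deterministic stepwise AIC search in
the spirit of auto-ARIMA: the amount of ordinary differencing comes from
repeated augmented Dickey–Fuller tests and seasonal differencing from a
seasonal-strength heuristic, then small (p, q, P, Q) neighbourhoods are
explored greedily.  The chosen order is always reported so it can be
overridden manually.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.tsa.statespace.sarimax import SARIMAX
from statsmodels.tsa.stattools import adfuller

from .streams import CountSeries, StreamError

__all__ = [
    "SarimaOrder",
    "Forecast",
    "FittedSarima",
    "PRESET_ORDERS",
    "fit_sarima",
    "auto_order",
    "forecast",
    "forecast_counts",
    "forecast_cthi",
]


@dataclass(frozen=True)
class SarimaOrder:
    """A ``(p, d, q)(P, D, Q)_s`` model specification.

    ``p``/``q`` are the autoregressive and moving-average lag orders, ``d``
    the degree of ordinary differencing; capitals are the seasonal
    counterparts at period ``s``.
    """

    p: int = 0
    d: int = 0
    q: int = 0
    P: int = 0
    D: int = 0
    Q: int = 0
    s: int = 24

    def __post_init__(self):
        for name in ("p", "d", "q", "P", "D", "Q"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"order component {name} must be a non-negative integer, got {v!r}")
        if self.s < 1:
            raise ValueError(f"seasonal period s must be >= 1, got {self.s}")
        if self.d + self.D > 3:
            raise ValueError(
                f"d + D = {self.d + self.D} > 3: over-differencing guard tripped"
            )

    @property
    def nonseasonal(self) -> tuple[int, int, int]:
        return (self.p, self.d, self.q)

    @property
    def seasonal(self) -> tuple[int, int, int, int]:
        # collapse to no seasonal component at period 1
        if self.s == 1:
            return (0, 0, 0, 0)
        return (self.P, self.D, self.Q, self.s)

    def __str__(self) -> str:
        return f"({self.p},{self.d},{self.q})({self.P},{self.D},{self.Q})_{self.s}"


#: Model presets for the two pilot intersections (hourly grid, daily
#: season): THI and passersby-count models per location.
PRESET_ORDERS: dict[str, SarimaOrder] = {
    "thi_10th": SarimaOrder(2, 0, 2, 4, 0, 1, 24),
    "thi_11th": SarimaOrder(3, 1, 0, 5, 0, 0, 24),
    "count_10th": SarimaOrder(4, 1, 0, 3, 0, 1, 24),
    "count_11th": SarimaOrder(4, 2, 3, 2, 1, 1, 24),
}


@dataclass
class Forecast:
    """Point forecasts with symmetric Gaussian interval bounds per step."""

    index: pd.DatetimeIndex
    point: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float = 0.95
    order: SarimaOrder | None = None
    training_r2: float | None = None
    bin_width: pd.Timedelta | None = None

    def __post_init__(self):
        self.point = np.asarray(self.point, dtype=float)
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        n = len(self.index)
        if not (len(self.point) == len(self.lower) == len(self.upper) == n):
            raise ValueError("forecast arrays must share the index length")
        if np.any(self.lower > self.point + 1e-9) or np.any(self.point > self.upper + 1e-9):
            raise ValueError("interval bounds must bracket the point forecast")

    def __len__(self) -> int:
        return len(self.index)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"point": self.point, "lower": self.lower, "upper": self.upper},
            index=self.index,
        )


@dataclass
class FittedSarima:
    """A fitted model plus the bookkeeping needed to extend its grid."""

    results: object = field(repr=False)
    order: SarimaOrder
    training_index: pd.DatetimeIndex = field(repr=False)
    bin_width: pd.Timedelta
    training_r2: float


def _validate_series(series: pd.Series, interpolate: bool, max_gap: int = 3) -> pd.Series:
    """Reject gapped/non-uniform input, optionally interpolating short gaps."""
    if not isinstance(series.index, pd.DatetimeIndex):
        raise StreamError("series must be indexed by bin start timestamps")
    if len(series) < 2:
        raise StreamError("series too short to fit")
    deltas = np.diff(series.index.asi8)
    if (deltas <= 0).any() or len(set(deltas)) != 1:
        raise StreamError("series bins must be uniform and strictly increasing")
    if series.isna().any():
        if not interpolate:
            raise StreamError(
                f"series has {int(series.isna().sum())} missing bins; "
                "pass interpolate=True to fill gaps of up to "
                f"{max_gap} bins linearly"
            )
        missing = series.isna()
        longest = missing.astype(int).groupby((~missing).cumsum()).sum().max()
        if longest > max_gap:
            raise StreamError(
                f"gap of {int(longest)} bins exceeds interpolation limit {max_gap}"
            )
        series = series.interpolate(method="time", limit_direction="both")
    if not np.isfinite(series.to_numpy()).all():
        raise StreamError("series contains non-finite values")
    return series


def fit_sarima(
    series: pd.Series,
    order: SarimaOrder,
    interpolate: bool = False,
    maxiter: int = 50,
) -> FittedSarima:
    """Fit a SARIMA model to a uniformly-binned series.

    The series must be gap-free (or ``interpolate=True`` to fill short
    gaps).  Training R² is one minus the ratio of one-step-ahead residual
    variance to the series variance, evaluated after the differencing
    burn-in — the in-sample goodness-of-fit figure reported alongside
    forecasts.
    """
    series = _validate_series(series, interpolate)
    if len(series) < 3 * order.s and order.s > 1:
        warnings.warn(
            f"series length {len(series)} < 3 seasonal periods "
            f"({3 * order.s}); estimates may be unstable",
            UserWarning,
            stacklevel=2,
        )
    trend = "c" if (order.d + order.D) == 0 else "n"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = SARIMAX(
            series.to_numpy(),
            order=order.nonseasonal,
            seasonal_order=order.seasonal,
            trend=trend,
            enforce_stationarity=False,
            enforce_invertibility=False,
            concentrate_scale=True,
        )
        try:
            if model.k_params == 0:  # pure differencing: nothing to estimate
                results = model.filter(np.array([]))
            else:
                results = model.fit(disp=False, maxiter=maxiter)
        except (np.linalg.LinAlgError, ValueError) as exc:
            raise StreamError(f"SARIMA fit failed for order {order}: {exc}") from exc
    if not np.isfinite(results.params).all():
        raise StreamError(f"SARIMA fit diverged for order {order}")
    # skip the lag depth of the model: one-step residuals before the state
    # has seen a full cycle of every lag reflect initialization, not fit
    burn = (order.d + order.D * order.s
            + order.s * max(order.P, order.Q) + max(order.p, order.q))
    burn = min(burn, max(len(series) - 8, 0))
    resid = np.asarray(results.resid)[burn:]
    y = series.to_numpy()[burn:]
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else float("nan")
    deltas = np.diff(series.index.asi8)
    return FittedSarima(
        results=results,
        order=order,
        training_index=series.index,
        bin_width=pd.Timedelta(int(deltas[0]), unit="ns"),
        training_r2=r2,
    )


def forecast(model: FittedSarima, h: int, level: float = 0.95) -> Forecast:
    """``h``-step-ahead point forecasts with Gaussian interval bounds."""
    if h <= 0:
        raise ValueError(f"forecast horizon must be positive, got {h}")
    if not 0 < level < 1:
        raise ValueError("confidence level must be in (0, 1)")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pred = model.results.get_forecast(steps=h)
        ci = pred.conf_int(alpha=1 - level)
    ci = np.asarray(ci)
    start = model.training_index[-1] + model.bin_width
    idx = pd.date_range(start, periods=h, freq=model.bin_width)
    return Forecast(
        index=idx,
        point=np.asarray(pred.predicted_mean),
        lower=ci[:, 0],
        upper=ci[:, 1],
        level=level,
        order=model.order,
        training_r2=model.training_r2,
        bin_width=model.bin_width,
    )


def forecast_counts(
    series: CountSeries,
    order: SarimaOrder,
    h: int,
    level: float = 0.95,
    interpolate: bool = False,
) -> Forecast:
    """Fit-and-forecast for a count stream, floored at zero.

    Counts cannot be negative, so the point forecast and lower bound are
    clipped at 0 after the Gaussian fit; values stay real (run averages
    and forecasts are not integers).
    """
    if series.counts.nunique() <= 1 and series.counts.eq(0).all():
        # all-zero history: the only defensible forecast is zero
        start = series.counts.index[-1] + series.bin_width
        idx = pd.date_range(start, periods=h, freq=series.bin_width)
        z = np.zeros(h)
        return Forecast(idx, z, z, z.copy(), level, order, 1.0, series.bin_width)
    fitted = fit_sarima(series.counts, order, interpolate=interpolate)
    fc = forecast(fitted, h, level)
    fc.point = np.maximum(fc.point, 0.0)
    fc.lower = np.clip(fc.lower, 0.0, fc.point)
    fc.upper = np.maximum(fc.upper, fc.point)
    return fc


def forecast_cthi(thi_fc: Forecast, count_fc: Forecast) -> Forecast:
    """Collective-index forecast as the product of THI and count forecasts.

    Point forecasts multiply pointwise; interval bounds are the products
    of like bounds floored at zero — a deliberately conservative
    convention, since the two models are fit independently and no joint
    distribution is estimated.
    """
    if len(thi_fc) != len(count_fc) or not thi_fc.index.equals(count_fc.index):
        raise StreamError("THI and count forecasts must share the same horizon bins")
    point = thi_fc.point * count_fc.point
    lower = np.maximum(thi_fc.lower * count_fc.lower, 0.0)
    upper = np.maximum(thi_fc.upper * count_fc.upper, 0.0)
    lower = np.minimum(lower, point)
    upper = np.maximum(upper, point)
    return Forecast(
        index=thi_fc.index,
        point=point,
        lower=lower,
        upper=upper,
        level=min(thi_fc.level, count_fc.level),
        order=None,
        training_r2=None,
        bin_width=thi_fc.bin_width,
    )


# ---------------------------------------------------------------------------
# Automatic order selection
# ---------------------------------------------------------------------------

def _ndiffs(x: np.ndarray, max_d: int = 2, alpha: float = 0.05) -> int:
    """Ordinary differencing degree via repeated ADF unit-root tests."""
    d = 0
    y = x.astype(float)
    while d < max_d:
        if np.ptp(y) == 0:  # constant series is trivially stationary
            return d
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                pvalue = adfuller(y, autolag="AIC")[1]
            except (ValueError, np.linalg.LinAlgError):
                return d
        if pvalue < alpha:
            return d
        y = np.diff(y)
        d += 1
    return d


def _nsdiffs(x: np.ndarray, s: int, threshold: float = 0.64) -> int:
    """Seasonal differencing via the seasonal-strength heuristic.

    Seasonal strength is max(0, 1 − Var(remainder)/Var(seasonal+remainder))
    from a crude seasonal-means decomposition; one seasonal difference is
    taken when strength exceeds the threshold.
    """
    if s <= 1 or len(x) < 2 * s:
        return 0
    n = (len(x) // s) * s
    mat = x[:n].reshape(-1, s).astype(float)
    detrended = mat - mat.mean(axis=1, keepdims=True)
    seasonal_means = detrended.mean(axis=0)
    remainder = detrended - seasonal_means
    denom = detrended.var()
    if denom == 0:
        return 0
    strength = max(0.0, 1.0 - remainder.var() / denom)
    return 1 if strength > threshold else 0


def _aic_of(series: pd.Series, order: SarimaOrder, maxiter: int) -> float:
    try:
        fitted = fit_sarima(series, order, maxiter=maxiter)
    except (StreamError, ValueError):
        return np.inf
    aic = float(fitted.results.aic)
    return aic if np.isfinite(aic) else np.inf


def auto_order(
    series: pd.Series,
    s: int = 24,
    max_p: int = 3,
    max_q: int = 3,
    max_P: int = 2,
    max_Q: int = 2,
    maxiter: int = 50,
) -> SarimaOrder:
    """Deterministic stepwise AIC search for a SARIMA order.

    Differencing degrees are fixed first (ADF tests and the
    seasonal-strength heuristic), then (p, q, P, Q) neighbourhoods are
    explored greedily from a small set of standard starting points.  Two
    runs on the same series return the same order; the result is meant as
    a starting point open to manual adjustment.
    """
    series = _validate_series(series, interpolate=False)
    x = series.to_numpy()
    D = _nsdiffs(x, s)
    y = x.copy()
    if D:
        y = y[s:] - y[:-s]
    d = _ndiffs(y)
    seasonal_active = s > 1 and len(series) >= 2 * s

    def clamp(p, q, P, Q):
        if not seasonal_active:
            P = Q = 0
        return (
            min(max(p, 0), max_p),
            min(max(q, 0), max_q),
            min(max(P, 0), max_P),
            min(max(Q, 0), max_Q),
        )

    starts = [(2, 2, 1, 1), (0, 0, 0, 0), (1, 0, 1, 0), (0, 1, 0, 1)]
    cache: dict[tuple, float] = {}

    def score(pq: tuple) -> float:
        pq = clamp(*pq)
        if pq not in cache:
            order = SarimaOrder(pq[0], d, pq[1], pq[2], D, pq[3], s)
            cache[pq] = _aic_of(series, order, maxiter)
        return cache[pq]

    best = min((clamp(*st) for st in starts), key=score)
    improved = True
    while improved:
        improved = False
        p, q, P, Q = best
        neighbours = [
            (p + 1, q, P, Q), (p - 1, q, P, Q),
            (p, q + 1, P, Q), (p, q - 1, P, Q),
            (p, q, P + 1, Q), (p, q, P - 1, Q),
            (p, q, P, Q + 1), (p, q, P, Q - 1),
            (p + 1, q + 1, P, Q), (p - 1, q - 1, P, Q),
        ]
        for cand in neighbours:
            cand = clamp(*cand)
            if score(cand) < score(best) - 1e-9:
                best = cand
                improved = True
    if not np.isfinite(score(best)):
        attempted = sorted(cache)
        raise StreamError(
            f"no SARIMA candidate converged; attempted (p,q,P,Q) = {attempted}"
        )
    p, q, P, Q = best
    return SarimaOrder(p, d, q, P, D, Q, s)
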