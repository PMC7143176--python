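"""Monthly pollutant exposure series and lifetime-exposure summaries.

A cohort's exposure history is a single complete monthly PM2.5 series for its
area, assembled from three segments:

* *backcast* — early years with no PM2.5 monitoring, predicted from PM10 by an
  ordinary least-squares regression fitted on the overlap period;
* *observed* — the monitored monthly means;
* *forecast* — future months predicted by an ARIMA model fitted to the
  observed segment, clamped from below at 10 µg/m³ (the WHO long-term
  guideline) or at the final observed year's annual mean when that mean is
  already below 10.

The survival-weighted lifetime average E = Σ S(t)·C(t) / Σ S(t) weights each
month's concentration by the fraction of the cohort still alive, giving the
cohort's person-time-weighted lifetime dose rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .curves import SurvivalCurve

PM25_FLOOR_GUIDELINE = 10.0  # µg/m³, WHO long-term guideline
BACKCAST_MIN_POSITIVE = 0.5  # floor for negative OLS predictions


class ExposureDataError(ValueError):
    """Missing coverage, insufficient overlap or degenerate inputs."""


@dataclass(frozen=True)
class ExposureSeries:
    """Contiguous monthly mean concentrations for one area.

    ``segments`` labels each month as backcast / observed / forecast.
    """

    area_id: str
    start: pd.Period
    values: np.ndarray = field(repr=False)
    segments: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size == 0:
            raise ValueError("values must be a nonempty 1-d array")
        if np.any(vals <= 0):
            raise ExposureDataError("concentrations must be positive")
        seg = self.segments
        if seg is None:
            seg = np.full(vals.size, "observed")
        seg = np.asarray(seg, dtype=object)
        if seg.size != vals.size:
            raise ValueError("segments must match values in length")
        start = pd.Period(self.start, freq="M")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "segments", seg)
        object.__setattr__(self, "start", start)

    def __len__(self) -> int:
        return self.values.size

    @property
    def periods(self) -> pd.PeriodIndex:
        return pd.period_range(self.start, periods=len(self), freq="M")

    @property
    def end(self) -> pd.Period:
        return self.start + (len(self) - 1)

    def index_of(self, period) -> int:
        off = (pd.Period(period, freq="M") - self.start).n
        if not 0 <= off < len(self):
            raise ExposureDataError(
                f"{period} outside series coverage {self.start}..{self.end}"
            )
        return off

    def window(self, first, last) -> np.ndarray:
        """Values for the closed month window [first, last]."""
        i, j = self.index_of(first), self.index_of(last)
        if j < i:
            raise ExposureDataError("window end precedes start")
        return self.values[i : j + 1]

    def on_grid(self, origin, n_points: int) -> np.ndarray:
        """Values aligned to survival-grid points t = 0..n_points-1.

        Grid point t maps to calendar month ``origin + t``.  Raises with the
        list of missing months if the series does not cover the grid.
        """
        origin = pd.Period(origin, freq="M")
        need_first, need_last = origin, origin + (n_points - 1)
        if need_first < self.start or need_last > self.end:
            missing = []
            if need_first < self.start:
                missing.append(f"{need_first}..{min(self.start - 1, need_last)}")
            if need_last > self.end:
                missing.append(f"{max(self.end + 1, need_first)}..{need_last}")
            raise ExposureDataError("series missing months: " + ", ".join(missing))
        i = self.index_of(origin)
        return self.values[i : i + n_points]

    def concat(self, other: "ExposureSeries") -> "ExposureSeries":
        if other.start != self.end + 1:
            raise ExposureDataError("segments to concatenate are not contiguous")
        return ExposureSeries(
            self.area_id,
            self.start,
            np.concatenate([self.values, other.values]),
            np.concatenate([self.segments, other.segments]),
        )

    def to_frame(self) -> pd.DataFrame:
        per = self.periods
        return pd.DataFrame(
            {
                "area_id": self.area_id,
                "year": per.year,
                "month": per.month,
                "value": self.values,
                "segment": self.segments,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, value_col: str = "value") -> "ExposureSeries":
        df = df.sort_values(["year", "month"])
        start = pd.Period(year=int(df["year"].iloc[0]), month=int(df["month"].iloc[0]), freq="M")
        seg = df["segment"].to_numpy() if "segment" in df else None
        area = str(df["area_id"].iloc[0]) if "area_id" in df else ""
        return cls(area, start, df[value_col].to_numpy(dtype=float), seg)

    @classmethod
    def from_csv(cls, path, value_col: str = "value") -> "ExposureSeries":
        return cls.from_frame(pd.read_csv(path), value_col)


@dataclass(frozen=True)
class LifetimeExposure:
    """Survival-weighted lifetime average concentration."""

    E: float  # µg/m³
    weights: np.ndarray = field(repr=False)  # P(t), sums to 1
    horizon: int = 0  # last grid month


def backcast_pm25(
    pm25_obs: ExposureSeries,
    pm10: ExposureSeries,
    target_first,
    target_last,
) -> ExposureSeries:
    """Predict PM2.5 for unmonitored months from PM10 by OLS on the overlap.

    Fits ``pm25 = a + b * pm10`` on months where both are observed and applies
    it to the PM10 values in the closed target window.  Negative predictions
    are floored at a small positive constant.
    """
    lo = max(pm25_obs.start, pm10.start)
    hi = min(pm25_obs.end, pm10.end)
    n_overlap = (hi - lo).n + 1 if hi >= lo else 0
    if n_overlap < 24:
        raise ExposureDataError(
            f"PM2.5/PM10 overlap of {max(n_overlap, 0)} months (< 24) too short to fit"
        )
    y = pm25_obs.window(lo, hi)
    x = pm10.window(lo, hi)
    if np.ptp(x) < 1e-9:
        raise ExposureDataError("PM10 is constant over the overlap: collinear design")
    import statsmodels.api as sm

    fit = sm.OLS(y, sm.add_constant(x)).fit()
    x_new = pm10.window(target_first, target_last)
    pred = fit.predict(sm.add_constant(x_new, has_constant="add"))
    pred = np.maximum(pred, BACKCAST_MIN_POSITIVE)
    return ExposureSeries(
        pm25_obs.area_id,
        pd.Period(target_first, freq="M"),
        pred,
        np.full(pred.size, "backcast"),
    )


DEFAULT_ARIMA_ORDERS = ((0, 1, 1), (1, 1, 0), (1, 1, 1), (0, 1, 2), (2, 1, 0))


def forecast_floor(pm25: ExposureSeries) -> float:
    """Lower clamp for forecasts: 10 µg/m³, or the final calendar year's
    annual mean when that mean is already below 10."""
    per = pm25.periods
    last_year = per.year[-1]
    annual_mean = float(pm25.values[per.year == last_year].mean())
    return PM25_FLOOR_GUIDELINE if annual_mean > PM25_FLOOR_GUIDELINE else annual_mean


def forecast_pm25(
    pm25: ExposureSeries,
    horizon_months: int,
    orders=DEFAULT_ARIMA_ORDERS,
    seasonal: bool = False,
) -> ExposureSeries:
    """ARIMA forecast of future monthly means, clamped at the floor rule.

    The (p, d, q) order is chosen by AIC over a small fixed grid for
    reproducibility.  A non-convergent fit falls back to a seasonal-naive
    drift forecast.
    """
    if len(pm25) < 60:
        raise ExposureDataError("need at least 60 observed months to forecast")
    if horizon_months < 1:
        raise ValueError("horizon_months must be >= 1")
    from statsmodels.tsa.arima.model import ARIMA

    y = pm25.values
    best = None
    seasonal_order = (0, 1, 1, 12) if seasonal else (0, 0, 0, 0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for order in orders:
            try:
                res = ARIMA(y, order=order, seasonal_order=seasonal_order).fit()
                if np.isfinite(res.aic) and (best is None or res.aic < best.aic):
                    best = res
            except (ValueError, np.linalg.LinAlgError):
                continue
    if best is not None:
        pred = np.asarray(best.forecast(horizon_months))
    else:  # seasonal-naive with drift
        warnings.warn("ARIMA grid failed to converge; using seasonal-naive drift")
        drift = (y[-12:].mean() - y[-24:-12].mean()) / 12.0 if len(y) >= 24 else 0.0
        base = y[-12:]
        k = np.arange(1, horizon_months + 1)
        pred = base[(k - 1) % 12] + drift * k
    pred = np.maximum(pred, forecast_floor(pm25))
    return ExposureSeries(
        pm25.area_id,
        pm25.end + 1,
        pred,
        np.full(pred.size, "forecast"),
    )


def reconstruct_full_series(
    pm25_obs: ExposureSeries,
    pm10: ExposureSeries,
    first_month,
    last_month,
    seasonal: bool = False,
) -> ExposureSeries:
    """Backcast + observed + forecast covering [first_month, last_month]."""
    first = pd.Period(first_month, freq="M")
    last = pd.Period(last_month, freq="M")
    parts = []
    if first < pm25_obs.start:
        parts.append(backcast_pm25(pm25_obs, pm10, first, pm25_obs.start - 1))
    obs = ExposureSeries(
        pm25_obs.area_id, pm25_obs.start, pm25_obs.values, np.full(len(pm25_obs), "observed")
    )
    parts.append(obs)
    if last > pm25_obs.end:
        parts.append(forecast_pm25(pm25_obs, (last - pm25_obs.end).n, seasonal=seasonal))
    full = parts[0]
    for p in parts[1:]:
        full = full.concat(p)
    i, j = full.index_of(first), full.index_of(last)
    return ExposureSeries(full.area_id, first, full.values[i : j + 1], full.segments[i : j + 1])


def lifetime_weighted_exposure(s: SurvivalCurve, c: ExposureSeries, origin) -> LifetimeExposure:
    """Survival-weighted lifetime average E = Σ S(t)·C(t)·Δ / Σ S(t)·Δ.

    Trapezoid-consistent weights on the monthly grid, so the weights sum to 1
    exactly and a constant concentration c gives E = c for any survival curve.
    """
    n = len(s)
    cvals = c.on_grid(origin, n)
    w = s.s.copy()
    w[0] *= 0.5
    w[-1] *= 0.5
    total = w.sum()
    if total <= 0:
        raise ExposureDataError("survival curve has zero mass")
    weights = w / total
    return LifetimeExposure(E=float(weights @ cvals), weights=weights, horizon=s.horizon)


def individual_lifetime_average(
    c: ExposureSeries, start_period, follow_months: float
) -> float:
    """Mean concentration from 12 months before the start month through the
    month follow-up ended, endpoints inclusive (13 values at follow-up 0)."""
    start = pd.Period(start_period, freq="M")
    end = start + int(np.ceil(follow_months))
    return float(np.mean(c.window(start - 12, end)))
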