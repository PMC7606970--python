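"""Dew/fog event statistics and smoothed profiles from RH/temperature loggers.

Field stations in coastal desert sites record relative humidity (RH, %) and
air temperature (°C) at a fixed 30-minute cadence.  Liquid-water availability
for endolithic communities is driven by condensation events: *dew* is scored
whenever RH exceeds 95 %, *fog* whenever RH exceeds 99 %.  Because the fog
threshold is stricter, every fog interval is by construction also a dew
interval.

Thresholds are read as strict inequalities: a sample at exactly the threshold
does not trigger an event.  Missing samples (NaN RH) mark logger gaps; gaps
never count as above-threshold, so an event is terminated at a gap.  A
calendar day is counted once per event type no matter how many events touch
it, and an event spanning midnight counts toward both days.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SensorSeries",
    "Event",
    "EventSummary",
    "SiteComparison",
    "SmoothFit",
    "detect_events",
    "site_difference",
    "daily_profile",
    "kernel_smooth",
]

DEW_THRESHOLD = 95.0
FOG_THRESHOLD = 99.0


@dataclass
class SensorSeries:
    """A regular RH/temperature time series from one logger.

    Parameters
    ----------
    time : pandas.DatetimeIndex
        Strictly increasing, equally spaced timestamps (default cadence in
        the field deployment is 30 min).
    rh : ndarray
        Relative humidity in percent, within [0, 100]; NaN marks a gap.
    temp : ndarray
        Air temperature in °C; NaN marks a gap.
    label : str
        Site or probe identifier.
    """

    time: pd.DatetimeIndex
    rh: np.ndarray
    temp: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.time = pd.DatetimeIndex(self.time)
        self.rh = np.asarray(self.rh, dtype=float)
        self.temp = np.asarray(self.temp, dtype=float)
        if not (len(self.time) == len(self.rh) == len(self.temp)):
            raise ValueError("time, rh and temp must have equal length")
        if len(self.time) >= 2 and not (np.diff(self.time.asi8) > 0).all():
            raise ValueError("timestamps must be strictly increasing")
        finite = self.rh[np.isfinite(self.rh)]
        if finite.size and (finite.min() < 0 or finite.max() > 100):
            raise ValueError("rh values must lie within [0, 100]")

    def __len__(self) -> int:
        return len(self.time)

    @property
    def cadence(self) -> pd.Timedelta:
        """Sampling interval; raises if the series is irregular."""
        steps = np.unique(np.diff(self.time.asi8))
        if steps.size == 0:
            raise ValueError("series has fewer than two samples")
        if steps.size > 1:
            raise ValueError(
                "irregular cadence: resample the series to a regular grid first"
            )
        return pd.Timedelta(steps[0], unit="ns")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"timestamp": self.time, "rh": self.rh, "temp": self.temp}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, label: str = "") -> "SensorSeries":
        df = pd.read_csv(path, parse_dates=["timestamp"])
        return cls(
            time=pd.DatetimeIndex(df["timestamp"]),
            rh=df["rh"].to_numpy(float),
            temp=df["temp"].to_numpy(float),
            label=label,
        )


@dataclass(frozen=True)
class Event:
    """A maximal run of consecutive samples above an RH threshold."""

    kind: str
    start: pd.Timestamp
    end: pd.Timestamp
    duration_h: float
    n_samples: int

    def __post_init__(self) -> None:
        if self.duration_h <= 0:
            raise ValueError("event duration must be positive")


@dataclass(frozen=True)
class EventSummary:
    """Per-series event statistics: day counts and durations in hours."""

    kind: str
    n_events: int
    n_days: int
    mean_duration_h: float
    max_duration_h: float

    def to_json(self) -> str:
        return json.dumps(self.__dict__)


def detect_events(
    series: SensorSeries, threshold: float = DEW_THRESHOLD, kind: str = "dew"
) -> tuple[list[Event], EventSummary]:
    """Find maximal runs of samples with RH strictly above ``threshold``.

    Duration is run length × cadence; an event's end is the start of the
    first sample after the run.  ``n_days`` counts distinct calendar days
    overlapped by at least one event (an event spanning midnight counts
    toward both days); duration statistics are over events, not days.
    """
    if not 0 < threshold < 100:
        raise ValueError("threshold must lie in (0, 100)")
    cadence = series.cadence
    above = np.nan_to_num(series.rh, nan=-np.inf) > threshold

    events: list[Event] = []
    days: set = set()
    edges = np.flatnonzero(np.diff(np.concatenate(([False], above, [False]))))
    for start_idx, stop_idx in edges.reshape(-1, 2):
        n = stop_idx - start_idx
        start = series.time[start_idx]
        end = start + n * cadence
        events.append(
            Event(
                kind=kind,
                start=start,
                end=end,
                duration_h=n * cadence / pd.Timedelta(hours=1),
                n_samples=n,
            )
        )
        days.update(ts.date() for ts in series.time[start_idx:stop_idx])
        days.add((end - pd.Timedelta(nanoseconds=1)).date())

    durations = np.array([e.duration_h for e in events])
    summary = EventSummary(
        kind=kind,
        n_events=len(events),
        n_days=len(days),
        mean_duration_h=float(durations.mean()) if events else 0.0,
        max_duration_h=float(durations.max()) if events else 0.0,
    )
    return events, summary


@dataclass
class SiteComparison:
    """Timestamp-aligned differences between two loggers (b − a)."""

    n_pairs: int
    mean_delta_temp: float
    mean_delta_rh: float
    profile: pd.DataFrame = field(repr=False)


def site_difference(a: SensorSeries, b: SensorSeries) -> SiteComparison:
    """Paired site comparison on timestamp-aligned samples.

    Differences are ``b − a``.  The hour-of-day profile has one bin per
    cadence step within a day (48 bins at the default 30-min cadence).
    """
    if a.cadence != b.cadence:
        raise ValueError("series cadences differ; resample before comparing")
    fa = a.to_frame().set_index("timestamp")
    fb = b.to_frame().set_index("timestamp")
    joined = fa.join(fb, how="inner", lsuffix="_a", rsuffix="_b").dropna()
    if joined.empty:
        raise ValueError("series have no overlapping timestamps")
    delta = pd.DataFrame(
        {
            "dtemp": joined["temp_b"] - joined["temp_a"],
            "drh": joined["rh_b"] - joined["rh_a"],
        }
    )
    tod = delta.index - delta.index.normalize()
    profile = delta.groupby(tod).mean()
    profile.index.name = "time_of_day"
    return SiteComparison(
        n_pairs=len(delta),
        mean_delta_temp=float(delta["dtemp"].mean()),
        mean_delta_rh=float(delta["drh"].mean()),
        profile=profile,
    )


def daily_profile(series: SensorSeries) -> pd.DataFrame:
    """Mean and SD of RH and temperature by time-of-day bin.

    Returns a frame indexed by time of day with columns
    ``rh_mean, rh_sd, temp_mean, temp_sd`` (48 rows at 30-min cadence).
    """
    per_day = int(pd.Timedelta(days=1) / series.cadence)
    if len(series) < per_day:
        raise ValueError("need at least one full day of data")
    df = series.to_frame().set_index("timestamp")
    tod = df.index - df.index.normalize()
    grouped = df.groupby(tod)
    out = pd.DataFrame(
        {
            "rh_mean": grouped["rh"].mean(),
            "rh_sd": grouped["rh"].std(ddof=0),
            "temp_mean": grouped["temp"].mean(),
            "temp_sd": grouped["temp"].std(ddof=0),
        }
    )
    out.index.name = "time_of_day"
    return out


@dataclass
class SmoothFit:
    """Local-polynomial fit evaluated on a query grid.

    ``order_used`` records, per query point, the polynomial degree actually
    fitted (lower than requested where the local system was singular).
    """

    grid: np.ndarray
    fitted: np.ndarray
    order_used: np.ndarray

    @property
    def downgraded(self) -> bool:
        return bool((self.order_used < self.order_used.max()).any())


def kernel_smooth(
    x,
    y,
    bandwidth: float,
    order: int,
    x_query=None,
) -> SmoothFit:
    """Local polynomial regression with a Gaussian kernel.

    At each query point x0 a degree-``order`` polynomial is fitted by
    weighted least squares with weights exp(−((x−x0)/h)²/2); the fitted value
    is the local intercept.  ``order=0`` is the moving local average used for
    abundance-versus-depth curves; ``order=6`` reproduces the smoother used
    for the year-long daily climate profiles.  Where the local design matrix
    is rank-deficient the order is reduced until solvable, and the reduction
    recorded in ``order_used``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if order < 0:
        raise ValueError("order must be >= 0")
    if len(x) < order + 1:
        raise ValueError("need at least order + 1 observations")
    if not bandwidth > 0:
        raise ValueError("bandwidth must be positive")
    if x_query is None:
        x_query = np.linspace(x.min(), x.max(), 101)
    x_query = np.atleast_1d(np.asarray(x_query, dtype=float))

    fitted = np.empty_like(x_query)
    order_used = np.full(x_query.shape, order, dtype=int)
    for i, x0 in enumerate(x_query):
        t = (x - x0) / bandwidth
        w = np.exp(-0.5 * t**2)
        sw = np.sqrt(w)
        q = order
        while True:
            basis = np.vander(t, q + 1, increasing=True)
            a = basis * sw[:, None]
            beta, _, rank, _ = np.linalg.lstsq(a, y * sw, rcond=None)
            if rank == q + 1 or q == 0:
                break
            q -= 1
        fitted[i] = beta[0]
        order_used[i] = q
    if (order_used < order).any():
        warnings.warn(
            "singular local fit: order reduced at some query points",
            stacklevel=2,
        )
    return SmoothFit(grid=x_query, fitted=fitted, order_used=order_used)
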