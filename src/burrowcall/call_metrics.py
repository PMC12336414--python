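"""Nightly call-rate series, night filters and the accumulation plateau.

The acoustic index of this workflow is the *call rate*: seconds of a call
type recorded per plot per night, averaged across retained nights.  Nights
are retained when the recording is usable (no disruptive wind/noise) and the
moon is at most 75% full; adult metrics use nights strictly before 14 July
(one week before the earliest estimated hatch date), chick metrics nights on
or after it.

The accumulation plateau asks how many nights of recording are needed for
the running mean call rate to stabilise: nights are drawn in random order
without replacement, the running mean is recomputed after each added night,
and the plateau is the first night count at which the trailing slope of the
running-mean curve drops below 0.1 (seconds per night, per added night).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MOON_THRESHOLD",
    "PERIOD_SPLIT_DATE",
    "CallRateSeries",
    "PlateauResult",
    "filter_nights",
    "split_periods",
    "mean_call_rate",
    "build_call_rate_series",
    "accumulation_plateau",
]

#: Nights with moon fraction strictly above this are excluded.
MOON_THRESHOLD = 0.75
#: Adult call rates use nights strictly before this date; chick rates on/after.
PERIOD_SPLIT_DATE = dt.date(2023, 7, 14)


@dataclass
class CallRateSeries:
    """Retained nightly call seconds for one plot and call type."""

    plot_id: str
    call_type: str
    nightly_seconds: np.ndarray
    mean_rate: float
    n_nights: int


@dataclass
class PlateauResult:
    """Accumulation-curve outcome for one nightly series.

    ``nights_to_plateau`` is the mean, across random orderings, of the first
    night count with trailing |slope| below the threshold; an ordering that
    never reaches it is censored at the full series length (averaging only
    the successful orderings would favour lucky early hits and bias noisy
    series *down*).  ``None`` when no ordering reached the threshold at all.
    ``final_slope`` is the mean trailing slope at the full series length.
    """

    plot_id: str
    call_type: str
    nights_to_plateau: float | None
    sd_nights: float | None
    fraction_reached: float
    final_slope: float
    slope_threshold: float
    window: int
    n_orderings: int
    n_nights: int

    @property
    def reached(self) -> bool:
        return self.nights_to_plateau is not None


def filter_nights(
    records: pd.DataFrame, moon_threshold: float = MOON_THRESHOLD
) -> pd.DataFrame:
    """Retain usable nights with moon fraction <= threshold.

    Exclusion is strict (> 0.75 removed; exactly 0.75 retained).  Idempotent.
    """
    keep = records["usable"].astype(bool) & (
        records["moon_fraction"] <= moon_threshold
    )
    return records.loc[keep].reset_index(drop=True)


def split_periods(
    records: pd.DataFrame, cutoff_date: dt.date = PERIOD_SPLIT_DATE
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition night records into (adult_period, chick_period).

    Nights strictly before ``cutoff_date`` feed adult call metrics; nights on
    or after it feed chick metrics.  The split is exhaustive and disjoint.
    """
    dates = pd.to_datetime(records["date"]).dt.date
    before = records.loc[dates < cutoff_date].reset_index(drop=True)
    after = records.loc[dates >= cutoff_date].reset_index(drop=True)
    return before, after


def mean_call_rate(nightly_seconds) -> float:
    """Arithmetic mean of retained nightly call seconds.

    An empty series yields NaN (an explicit missing value): a plot with no
    retained nights has no call rate, not a zero one.
    """
    vals = np.asarray(nightly_seconds, dtype=float)
    if vals.size == 0:
        return float("nan")
    return float(vals.mean())


def build_call_rate_series(
    records: pd.DataFrame, seconds_col: str = "seconds"
) -> list[CallRateSeries]:
    """Group retained night records into per-plot, per-type rate series.

    ``records`` is long format with columns
    ``plot_id, date, call_type, <seconds_col>`` (already filtered); nights
    are ordered by date within each series.
    """
    out = []
    for (plot_id, call_type), grp in records.groupby(
        ["plot_id", "call_type"], sort=True
    ):
        grp = grp.sort_values("date")
        vals = grp[seconds_col].to_numpy(dtype=float)
        out.append(
            CallRateSeries(
                plot_id=plot_id,
                call_type=call_type,
                nightly_seconds=vals,
                mean_rate=mean_call_rate(vals),
                n_nights=len(vals),
            )
        )
    return out


def _running_mean_slopes(values: np.ndarray, window: int) -> np.ndarray:
    """Trailing OLS slopes of the running-mean curve.

    Entry ``i`` is the least-squares slope of the running mean over points
    ``n - window + 1 .. n`` where ``n = window + i`` nights.
    """
    run_mean = np.cumsum(values) / np.arange(1, len(values) + 1)
    x = np.arange(window, dtype=float)
    w = (x - x.mean()) / np.sum((x - x.mean()) ** 2)
    windows = np.lib.stride_tricks.sliding_window_view(run_mean, window)
    return windows @ w


def accumulation_plateau(
    nightly_seconds,
    slope_threshold: float = 0.1,
    n_orderings: int = 100,
    window: int = 5,
    seed=None,
    plot_id: str = "",
    call_type: str = "",
) -> PlateauResult:
    """Nights needed for the running mean call rate to stabilise.

    For each of ``n_orderings`` random night orders (without replacement),
    the running-mean curve is built and the plateau is the first night count
    ``n`` (``n >= window``) whose trailing-``window`` OLS slope has
    ``|slope| < slope_threshold``.  Results are averaged over orderings;
    orderings that never reach the threshold are reported via
    ``fraction_reached`` and the mean final slope.
    """
    vals = np.asarray(nightly_seconds, dtype=float)
    n = len(vals)
    if n < window + 1:
        raise ValueError(f"need at least window+1={window + 1} nights, got {n}")
    rng = np.random.default_rng(seed)
    plateau_ns = []
    n_reached = 0
    final_slopes = []
    for _ in range(n_orderings):
        perm = rng.permutation(n)
        slopes = _running_mean_slopes(vals[perm], window)
        final_slopes.append(slopes[-1])
        hit = np.flatnonzero(np.abs(slopes) < slope_threshold)
        if hit.size:
            plateau_ns.append(window + hit[0])
            n_reached += 1
        else:
            plateau_ns.append(n)  # censored at the series length
    reached = n_reached / n_orderings
    return PlateauResult(
        plot_id=plot_id,
        call_type=call_type,
        nights_to_plateau=float(np.mean(plateau_ns)) if n_reached else None,
        sd_nights=float(np.std(plateau_ns, ddof=1)) if len(plateau_ns) > 1 else None,
        fraction_reached=reached,
        final_slope=float(np.mean(final_slopes)),
        slope_threshold=slope_threshold,
        window=window,
        n_orderings=n_orderings,
        n_nights=n,
    )
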