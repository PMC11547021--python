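"""Ingestion, surgery alignment, baseline normalization and smoothing.

Daily step-count exports (one row per calendar day) are read into a
:class:`DailyStepSeries`, windowed to the two-years-pre / two-years-post
surgery interval, divided by the mean of the baseline year (the first year of
the pre-operative window) and smoothed with a centered 14-day sliding window.

Missing days are genuinely absent from the record: they are excluded from
window averages, never imputed as zero, because a recorded zero is real data
while absence is non-wear.
"""

from __future__ import annotations

import dataclasses
import datetime
import warnings
from typing import IO, Optional, Union

import numpy as np
import pandas as pd

from .epochs import BASELINE_YEAR, WINDOW_PRE_DAYS


@dataclasses.dataclass
class DailyStepSeries:
    """Calendar-dated raw daily step counts for one patient.

    Attributes
    ----------
    patient_id:
        Opaque identifier.
    surgery_date:
        Date of the index surgery, or ``None`` before alignment.
    data:
        Non-negative integer steps indexed by a sorted, duplicate-free
        :class:`pandas.DatetimeIndex`; days without a record are absent.
    """

    patient_id: str
    surgery_date: Optional[datetime.date]
    data: pd.Series

    def __post_init__(self) -> None:
        if not self.data.index.is_monotonic_increasing:
            self.data = self.data.sort_index()
        if self.data.index.has_duplicates:
            raise ValueError("duplicate dates must be merged before construction")
        if len(self.data) and (self.data < 0).any():
            raise ValueError("negative step counts are invalid")

    @property
    def day_index(self) -> np.ndarray:
        """Integer day offsets relative to the surgery date (negative = pre-op)."""
        if self.surgery_date is None:
            raise ValueError("series has no surgery date; align it first")
        anchor = pd.Timestamp(self.surgery_date)
        return ((self.data.index - anchor).days).to_numpy()

    def __len__(self) -> int:
        return len(self.data)


@dataclasses.dataclass
class NormalizedActivitySeries:
    """Surgery-relative, baseline-normalized (optionally smoothed) activity.

    ``values[i]`` is the activity on day ``day_index[i]`` in units of the
    patient's baseline-year mean daily steps; ``baseline_sd`` is the standard
    deviation of the raw baseline-year daily counts, the scale used by the
    secondary-decline rule.
    """

    patient_id: str
    day_index: np.ndarray
    values: np.ndarray
    baseline_mean: float
    baseline_sd: float
    smoothing_window: Optional[int] = None

    def __post_init__(self) -> None:
        self.day_index = np.asarray(self.day_index, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.day_index.shape != self.values.shape:
            raise ValueError("day_index and values must have equal length")
        if len(self.day_index) > 1 and np.any(np.diff(self.day_index) <= 0):
            raise ValueError("day_index must be strictly increasing")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be positive")

    def __len__(self) -> int:
        return len(self.day_index)


@dataclasses.dataclass(frozen=True)
class CsvDialect:
    """Column mapping for a step-count CSV export (QS Access style)."""

    date_col: str = "date"
    steps_col: str = "steps"
    date_format: Optional[str] = None


def ingest_steps_csv(
    source: Union[str, IO[str]],
    dialect: Optional[CsvDialect] = None,
    patient_id: str = "patient",
) -> DailyStepSeries:
    """Read a per-patient step-count CSV into a :class:`DailyStepSeries`.

    Duplicate dates are merged by summation (a day split across export rows
    is still one day of walking).  Non-numeric or negative step values and
    unparsable dates raise ``ValueError`` naming the offending data row
    (1-based, excluding the header).
    """
    dialect = dialect or CsvDialect()
    frame = pd.read_csv(source)
    if frame.empty:
        raise ValueError("step-count file contains no data rows")
    for col in (dialect.date_col, dialect.steps_col):
        if col not in frame.columns:
            raise ValueError(f"missing required column {col!r}")

    dates = pd.to_datetime(
        frame[dialect.date_col], format=dialect.date_format, errors="coerce"
    )
    if dates.isna().any():
        row = int(np.flatnonzero(dates.isna().to_numpy())[0]) + 1
        raise ValueError(f"unparsable date in row {row}")

    steps = pd.to_numeric(frame[dialect.steps_col], errors="coerce")
    if steps.isna().any():
        row = int(np.flatnonzero(steps.isna().to_numpy())[0]) + 1
        raise ValueError(f"non-numeric step count in row {row}")
    if (steps < 0).any():
        row = int(np.flatnonzero((steps < 0).to_numpy())[0]) + 1
        raise ValueError(f"negative step count in row {row}")

    merged = pd.Series(steps.to_numpy(dtype=np.int64), index=dates.dt.normalize())
    merged = merged.groupby(level=0).sum().sort_index()
    return DailyStepSeries(patient_id=patient_id, surgery_date=None, data=merged)


def write_steps_csv(series: DailyStepSeries, path) -> None:
    """Write a series back to the canonical two-column ``date,steps`` CSV."""
    out = pd.DataFrame(
        {"date": series.data.index.strftime("%Y-%m-%d"), "steps": series.data.to_numpy()}
    )
    out.to_csv(path, index=False)


def align_to_surgery(
    series: DailyStepSeries,
    surgery_date: Optional[datetime.date] = None,
    window_days: int = WINDOW_PRE_DAYS,
) -> DailyStepSeries:
    """Anchor a series to its surgery date and window it.

    Records outside the closed interval ``[surgery - window, surgery + window]``
    are dropped; day 0 is the surgery date.  An empty pre-operative side is
    legal (the patient's export may start post-operatively) and raises only a
    warning.
    """
    if surgery_date is None:
        surgery_date = series.surgery_date
    if surgery_date is None:
        raise ValueError("a surgery date must be supplied or present on the series")
    anchor = pd.Timestamp(surgery_date)
    offsets = (series.data.index - anchor).days
    mask = (offsets >= -window_days) & (offsets <= window_days)
    data = series.data[mask]
    if data.empty:
        raise ValueError(
            f"no records within {window_days} days of surgery {surgery_date}"
        )
    if not (offsets[mask] < 0).any():
        warnings.warn(
            f"patient {series.patient_id}: no pre-operative records in window",
            stacklevel=2,
        )
    return DailyStepSeries(series.patient_id, surgery_date, data)


def normalize_to_baseline(
    series: DailyStepSeries,
    min_baseline_days: int = 90,
    stat: str = "mean",
) -> NormalizedActivitySeries:
    """Express daily steps in units of the patient's baseline-year activity.

    The baseline year is the first year of the pre-operative window
    (days -730 through -366).  By construction the mean of the normalized
    values over recorded baseline-year days equals 1.  ``baseline_sd`` is the
    sample standard deviation of the raw baseline-year daily counts; the
    secondary-decline rule is phrased in these raw steps-per-day units.
    """
    if stat not in ("mean", "median"):
        raise ValueError("stat must be 'mean' or 'median'")
    day_index = series.day_index
    steps = series.data.to_numpy(dtype=float)
    lo, hi = BASELINE_YEAR
    in_baseline = (day_index >= lo) & (day_index <= hi)
    n_base = int(in_baseline.sum())
    if n_base < min_baseline_days:
        raise ValueError(
            f"only {n_base} recorded baseline-year days; "
            f"at least {min_baseline_days} are required"
        )
    base = steps[in_baseline]
    baseline_mean = float(np.mean(base) if stat == "mean" else np.median(base))
    if baseline_mean <= 0:
        raise ValueError("baseline mean activity is zero; cannot normalize")
    baseline_sd = float(np.std(base, ddof=1)) if n_base > 1 else 0.0
    return NormalizedActivitySeries(
        patient_id=series.patient_id,
        day_index=day_index,
        values=steps / baseline_mean,
        baseline_mean=baseline_mean,
        baseline_sd=baseline_sd,
        smoothing_window=None,
    )


def smooth(
    series: NormalizedActivitySeries, window_days: int = 14
) -> NormalizedActivitySeries:
    """Centered sliding-window mean over recorded days.

    Each day's value is replaced by the mean of the recorded values within a
    centered ``window_days`` window; missing days shrink the averaging
    denominator rather than contributing zeros.  The output is defined on the
    same day grid as the input.
    """
    if window_days < 1:
        raise ValueError("window_days must be >= 1")
    full_grid = np.arange(series.day_index[0], series.day_index[-1] + 1)
    dense = pd.Series(np.nan, index=full_grid)
    dense[series.day_index] = series.values
    smoothed = dense.rolling(window_days, center=True, min_periods=1).mean()
    return dataclasses.replace(
        series,
        values=smoothed[series.day_index].to_numpy(),
        smoothing_window=window_days,
    )
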