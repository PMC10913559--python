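"""Epoch-level ENMO intensity to daily and weekly movement-behaviour summaries.

Wrist-accelerometer ENMO (Euclidean Norm Minus One, in milligravity) is
classified per epoch into sleep / inactivity / LPA / MVPA using the
Hildebrand cut-points (< 35 mg inactivity, 35-200 mg LPA, >= 200 mg MVPA).
Night-sleep windows are taken as given input (detected upstream from raw
accelerometry); waking inactivity bouts of at least 15 minutes are
relabelled as naps, and total sleep = night sleep + naps.

A midnight-to-midnight day is valid with >= 16 h of recording; a child is
included with >= 2 valid weekdays and >= 1 valid weekend day, and the weekly
composition weights weekend days 2/5 relative to weekdays:
(5 * weekday_mean + 2 * weekend_mean) / 7, closed to 1440 min.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .coda import Composition4, close

__all__ = [
    "Label",
    "EpochSeries",
    "DayComposition",
    "WeeklySummary",
    "InclusionError",
    "classify_epochs",
    "detect_naps",
    "summarise_day",
    "weekly_average",
    "read_epoch_csv",
    "day_summaries_frame",
    "weekly_summaries_frame",
]

# ENMO intensity cut-points, milligravity.  Boundaries are inclusive upward:
# 35 mg is LPA, 200 mg is MVPA.
INACTIVITY_CUT = 35.0
MVPA_CUT = 200.0

MINUTES_PER_DAY = 1440


class Label:
    """Integer epoch labels.  NAP is kept distinct from night SLEEP so nap
    minutes can be reported separately; both count as sleep downstream."""

    MISSING = -1
    SLEEP = 0
    INACTIVITY = 1
    LPA = 2
    MVPA = 3
    NAP = 4


class InclusionError(ValueError):
    """Child fails the >=2 valid weekdays + >=1 valid weekend day rule."""


@dataclass
class EpochSeries:
    """One child-day of epoch-level ENMO covering midnight to midnight.

    ``night_windows`` are clock intervals (minutes from midnight, end
    exclusive) declared as night sleep; an interval with start > end wraps
    across midnight and covers [start, 1440) plus [0, end).
    """

    child_id: str
    date: _dt.date
    epoch_length: int  # seconds
    enmo: np.ndarray  # milligravity, one value per epoch
    night_windows: list[tuple[float, float]] = field(default_factory=list)
    recorded_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.enmo = np.asarray(self.enmo, dtype=float)
        if 60 % self.epoch_length != 0:
            raise ValueError("epoch_length must divide 60 seconds")
        expected = MINUTES_PER_DAY * 60 // self.epoch_length
        if self.enmo.shape != (expected,):
            raise ValueError(
                f"enmo must tile the civil day: expected {expected} epochs, "
                f"got {self.enmo.shape}"
            )
        if np.any(self.enmo[np.isfinite(self.enmo)] < 0):
            raise ValueError("ENMO values must be nonnegative")
        if self.recorded_mask is None:
            self.recorded_mask = np.ones(expected, dtype=bool)
        else:
            self.recorded_mask = np.asarray(self.recorded_mask, dtype=bool)
            if self.recorded_mask.shape != (expected,):
                raise ValueError("recorded_mask must match the epoch grid")

    @property
    def epochs_per_minute(self) -> int:
        return 60 // self.epoch_length

    def night_mask(self) -> np.ndarray:
        """Boolean mask of epochs whose start time lies in a night window."""
        n = self.enmo.shape[0]
        start_min = np.arange(n) / self.epochs_per_minute
        mask = np.zeros(n, dtype=bool)
        for start, end in self.night_windows:
            if start <= end:
                mask |= (start_min >= start) & (start_min < end)
            else:  # crosses midnight
                mask |= (start_min >= start) | (start_min < end)
        return mask


def classify_epochs(
    series: EpochSeries,
    inactivity_cut: float = INACTIVITY_CUT,
    mvpa_cut: float = MVPA_CUT,
) -> np.ndarray:
    """Label every epoch: night windows override intensity; unrecorded
    epochs are MISSING; waking epochs follow the ENMO cut-points."""
    enmo = series.enmo
    if np.any(enmo[series.recorded_mask] < 0):
        raise ValueError("ENMO values must be nonnegative")
    labels = np.full(enmo.shape[0], Label.INACTIVITY, dtype=np.int8)
    labels[enmo >= inactivity_cut] = Label.LPA
    labels[enmo >= mvpa_cut] = Label.MVPA
    labels[series.night_mask()] = Label.SLEEP
    labels[~series.recorded_mask] = Label.MISSING
    return labels


def detect_naps(
    labels: np.ndarray, epoch_length: int = 5, min_bout: float = 15.0
) -> np.ndarray:
    """Relabel maximal runs of waking inactivity lasting >= ``min_bout``
    minutes as naps.  Runs must be strictly consecutive — a single epoch of
    any other label breaks the bout.  Idempotent: naps are a distinct label,
    so a second pass finds no new inactivity runs.
    """
    if min_bout <= 0:
        raise ValueError("min_bout must be positive")
    labels = np.asarray(labels).copy()
    min_epochs = int(round(min_bout * 60 / epoch_length))
    is_inact = labels == Label.INACTIVITY
    # run-length encode the inactivity indicator
    edges = np.flatnonzero(np.diff(is_inact.astype(np.int8)))
    starts = np.concatenate(([0], edges + 1))
    ends = np.concatenate((edges + 1, [labels.shape[0]]))
    for s, e in zip(starts, ends):
        if is_inact[s] and (e - s) >= min_epochs:
            labels[s:e] = Label.NAP
    return labels


@dataclass
class DayComposition:
    """Minutes per behaviour for one child-day (sleep includes naps)."""

    child_id: str
    date: _dt.date
    is_weekend: bool
    mvpa: float
    lpa: float
    inactivity: float
    sleep: float
    nap_minutes: float
    recorded_hours: float
    valid: bool

    def parts(self) -> np.ndarray:
        return np.array([self.mvpa, self.lpa, self.inactivity, self.sleep])


def summarise_day(labels: np.ndarray, series: EpochSeries) -> DayComposition:
    """Daily minutes per class from labelled epochs.

    Total sleep = night sleep + naps.  A day is valid with >= 16 recorded
    hours (inclusive).  Weekend = Saturday/Sunday by the civil calendar.
    """
    labels = np.asarray(labels)
    if labels.shape != series.enmo.shape:
        raise ValueError("labels must cover the civil day epoch grid")
    epm = series.epochs_per_minute
    minutes = {
        lab: np.count_nonzero(labels == lab) / epm
        for lab in (Label.SLEEP, Label.NAP, Label.INACTIVITY, Label.LPA, Label.MVPA)
    }
    recorded_hours = np.count_nonzero(series.recorded_mask) / epm / 60.0
    return DayComposition(
        child_id=series.child_id,
        date=series.date,
        is_weekend=series.date.weekday() >= 5,
        mvpa=float(minutes[Label.MVPA]),
        lpa=float(minutes[Label.LPA]),
        inactivity=float(minutes[Label.INACTIVITY]),
        sleep=float(minutes[Label.SLEEP] + minutes[Label.NAP]),
        nap_minutes=float(minutes[Label.NAP]),
        recorded_hours=float(recorded_hours),
        valid=bool(recorded_hours >= 16.0),
    )


@dataclass
class WeeklySummary:
    child_id: str
    n_valid_weekdays: int
    n_valid_weekend_days: int
    composition: Composition4


def weekly_average(days: Sequence[DayComposition]) -> WeeklySummary:
    """Weekend-weighted weekly composition from one child's valid days.

    Per behaviour: (5 * weekday mean + 2 * weekend mean) / 7, then closed to
    1440 min.  Raises :class:`InclusionError` when the >= 2 weekday /
    >= 1 weekend-day rule is unmet.
    """
    if not days:
        raise InclusionError("no days supplied")
    child_ids = {d.child_id for d in days}
    if len(child_ids) != 1:
        raise ValueError(f"days span multiple children: {sorted(child_ids)}")
    valid = [d for d in days if d.valid]
    weekdays = [d for d in valid if not d.is_weekend]
    weekends = [d for d in valid if d.is_weekend]
    if len(weekdays) < 2 or len(weekends) < 1:
        raise InclusionError(
            f"child {days[0].child_id}: {len(weekdays)} valid weekdays and "
            f"{len(weekends)} valid weekend days (need >=2 and >=1)"
        )
    wd_mean = np.mean([d.parts() for d in weekdays], axis=0)
    we_mean = np.mean([d.parts() for d in weekends], axis=0)
    weighted = (5.0 * wd_mean + 2.0 * we_mean) / 7.0
    return WeeklySummary(
        child_id=days[0].child_id,
        n_valid_weekdays=len(weekdays),
        n_valid_weekend_days=len(weekends),
        composition=close(weighted),
    )


# ---------------------------------------------------------------------------
# tabular IO


def read_epoch_csv(epoch_csv, night_json=None) -> list[EpochSeries]:
    """Read long-format epoch data into per-child-day series.

    CSV columns: child_id, timestamp (ISO-8601), enmo_mg, recorded.  The
    JSON sidecar maps "child_id/YYYY-MM-DD" to lists of [start_min, end_min]
    night windows.
    """
    df = pd.read_csv(epoch_csv, parse_dates=["timestamp"])
    windows: dict[str, list] = {}
    if night_json is not None:
        with open(night_json) as fh:
            windows = json.load(fh)
    out: list[EpochSeries] = []
    for (child, date), grp in df.groupby(
        [df["child_id"], df["timestamp"].dt.date], sort=True
    ):
        grp = grp.sort_values("timestamp")
        seconds = (
            grp["timestamp"] - pd.Timestamp(date)
        ).dt.total_seconds().to_numpy()
        step = int(np.diff(seconds)[0]) if len(seconds) > 1 else 60
        key = f"{child}/{date.isoformat()}"
        out.append(
            EpochSeries(
                child_id=str(child),
                date=date,
                epoch_length=step,
                enmo=grp["enmo_mg"].to_numpy(),
                night_windows=[tuple(w) for w in windows.get(key, [])],
                recorded_mask=grp["recorded"].to_numpy(dtype=bool)
                if "recorded" in grp
                else None,
            )
        )
    return out


def day_summaries_frame(days: Sequence[DayComposition]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "child_id": [d.child_id for d in days],
            "date": [d.date.isoformat() for d in days],
            "is_weekend": [d.is_weekend for d in days],
            "mvpa_min": [d.mvpa for d in days],
            "lpa_min": [d.lpa for d in days],
            "inactivity_min": [d.inactivity for d in days],
            "sleep_min": [d.sleep for d in days],
            "nap_min": [d.nap_minutes for d in days],
            "recorded_hours": [d.recorded_hours for d in days],
            "valid": [d.valid for d in days],
        }
    )


def weekly_summaries_frame(summaries: Sequence[WeeklySummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "child_id": [s.child_id for s in summaries],
            "n_valid_weekdays": [s.n_valid_weekdays for s in summaries],
            "n_valid_weekend_days": [s.n_valid_weekend_days for s in summaries],
            "mvpa_min": [s.composition.mvpa for s in summaries],
            "lpa_min": [s.composition.lpa for s in summaries],
            "inactivity_min": [s.composition.inactivity for s in summaries],
            "sleep_min": [s.composition.sleep for s in summaries],
        }
    )
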