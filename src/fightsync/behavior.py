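"""Summaries and synchrony metrics for dyadic fighting-behavior logs.

Fights are described by three behaviors: point events (bite/strike,
surface-breath; duration 0) and dyadic mouth-lock episodes with duration.
The quantitative summaries are first occurrences, mouth-lock structure
(episode count, mean duration, fraction of the observation), sliding-window
frequency/duration series (2-minute windows advancing by 1 minute, the
convention used for fight time-series), and opponent-vs-opponent Pearson
correlations of the windowed frequencies.

All intervals are half-open, ``[start, start + duration)``: an event at the
exact end of a mouth-lock episode is outside it, and an event is counted in
every window containing its start.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .behavior_sim import BEHAVIORS, EventLog

__all__ = ["WindowSeries", "interval_check", "first_occurrences",
           "mouthlock_summary", "window_series", "behavior_synchrony"]

POINT_BEHAVIORS = ("bite_strike", "surface_breath")


@dataclass
class WindowSeries:
    """Windowed event counts and durations for one fish and behavior."""

    starts: np.ndarray      # window start times (min)
    counts: np.ndarray      # events starting in each window
    durations: np.ndarray   # overlap duration within each window (min)
    width: float
    step: float

    def __post_init__(self) -> None:
        if not (len(self.starts) == len(self.counts) == len(self.durations)):
            raise ValueError("misaligned window series arrays")


def _validate_events(log: EventLog) -> pd.DataFrame:
    ev = log.events
    for col in ("pair_id", "fish_id", "behavior", "start_min", "duration_min"):
        if col not in ev.columns:
            raise ValueError(f"event log lacks column {col!r}")
    bad_behavior = set(ev["behavior"]) - set(BEHAVIORS)
    if bad_behavior:
        raise ValueError(f"unknown behaviors: {sorted(bad_behavior)}")
    for i, row in enumerate(ev.itertuples(index=False)):
        if not (0 <= row.start_min <= row.start_min + row.duration_min
                <= log.duration + 1e-9):
            raise ValueError(f"event outside observation at record {i}: {row}")
    return ev


def interval_check(log: EventLog) -> pd.DataFrame:
    """Bite/breath events that fall inside a mouth-lock episode.

    Returns the offending records (empty frame = valid log). Episode
    intervals are half-open, so an event at the exact episode end is fine.
    """
    ev = _validate_events(log)
    violations = []
    for pair_id, sub in ev.groupby("pair_id"):
        ml = sub[sub["behavior"] == "mouth_lock"].drop_duplicates(
            subset=["start_min", "duration_min"])
        if ml.empty:
            continue
        starts = ml["start_min"].to_numpy()
        ends = starts + ml["duration_min"].to_numpy()
        pts = sub[sub["behavior"].isin(POINT_BEHAVIORS)]
        t = pts["start_min"].to_numpy()
        inside = ((t[:, None] >= starts[None, :]) &
                  (t[:, None] < ends[None, :])).any(axis=1)
        violations.append(pts[inside])
    if violations:
        out = pd.concat(violations)
        return out
    return ev.iloc[0:0]


def first_occurrences(log: EventLog) -> pd.DataFrame:
    """Earliest start time per pair and behavior (NaN where absent)."""
    ev = _validate_events(log)
    if ev.empty:
        raise ValueError("empty event log")
    first = (ev.groupby(["pair_id", "behavior"], observed=True)["start_min"]
             .min().unstack("behavior"))
    return first.reindex(columns=list(BEHAVIORS))


def mouthlock_summary(log: EventLog) -> pd.DataFrame:
    """Per pair: episode count, mean episode duration, time fraction.

    Mouth-lock rows are dyadic (present once per fish); episodes are
    deduplicated on (start, duration) before counting. Pairs without
    episodes get count 0, missing mean and fraction 0.
    """
    ev = _validate_events(log)
    rows = []
    for pair_id, sub in ev.groupby("pair_id"):
        ml = sub[sub["behavior"] == "mouth_lock"].drop_duplicates(
            subset=["start_min", "duration_min"])
        if ml.empty:
            rows.append((pair_id, 0, np.nan, 0.0))
        else:
            dur = ml["duration_min"]
            rows.append((pair_id, len(ml), dur.mean(),
                         dur.sum() / log.duration))
    return pd.DataFrame(rows, columns=["pair_id", "count", "mean_duration",
                                       "time_fraction"]).set_index("pair_id")


def window_series(log: EventLog, fish: str, behavior: str,
                  width: float = 2.0, step: float = 1.0) -> WindowSeries:
    """Sliding-window frequency/duration series for one fish and behavior.

    Windows are ``[k*step, k*step + width)`` for k = 0..floor((T-width)/step);
    an event contributes its count to every window containing its start and
    its duration clipped to each overlapping window.
    """
    if width <= 0 or step <= 0:
        raise ValueError("width and step must be positive")
    if step > width:
        import warnings
        warnings.warn("step larger than width leaves gaps between windows")
    ev = _validate_events(log)
    sel = ev[(ev["fish_id"] == fish) & (ev["behavior"] == behavior)]
    T = log.duration
    n_win = int(math.floor((T - width) / step)) + 1
    if n_win < 1:
        raise ValueError("observation shorter than one window")
    starts = np.arange(n_win) * step
    counts = np.zeros(n_win)
    durations = np.zeros(n_win)
    t0 = sel["start_min"].to_numpy()
    t1 = t0 + sel["duration_min"].to_numpy()
    for k in range(n_win):
        w0, w1 = starts[k], starts[k] + width
        counts[k] = np.sum((t0 >= w0) & (t0 < w1))
        durations[k] = np.clip(np.minimum(t1, w1) - np.maximum(t0, w0),
                               0.0, None).sum()
    return WindowSeries(starts, counts, durations, width, step)


def behavior_synchrony(series_a: WindowSeries, series_b: WindowSeries) -> float:
    """Pearson r of two fishes' windowed frequency series."""
    if (len(series_a.starts) != len(series_b.starts)
            or series_a.width != series_b.width
            or series_a.step != series_b.step):
        raise ValueError("window grids differ")
    if len(series_a.starts) < 3:
        raise ValueError("need at least three windows")
    a, b = series_a.counts, series_b.counts
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance window series; correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])
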