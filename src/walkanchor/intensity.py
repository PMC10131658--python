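"""Wrist-derived activity intensity: epoch classification, LONG-walk
epoch labelling, sleep accounting and daily summaries.

Intensity is assigned per 15-s epoch from the wrist AVM using two cut
points: below the light threshold is sedentary, at or above the moderate
threshold is MVPA (moderate and vigorous merged — the cut-point family has
no vigorous boundary), light in between.  Boundaries are lower-inclusive
for the upper class.

Within LONG walks only whole epochs count: an epoch belongs to a walk iff
it starts at or after the walk start and ends at or before the walk end.
The epoch grid is global — anchored at the recording start, not per walk —
so a walk starting mid-epoch contributes its first whole on-grid epoch.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, datetime, time, timedelta

import numpy as np

from .config import IntensityCutPoints, PipelineConfig
from .errors import UsageError
from .gait import WalkingBout
from .preprocess import AvmEpochSeries, NonwearIntervals

SEDENTARY, LIGHT, MVPA = "sedentary", "light", "MVPA"


@dataclass(frozen=True)
class LabeledEpoch:
    epoch_start_s: float
    avm_mg: float
    label: str
    in_long_walk: bool = False
    bout_id: int | None = None


@dataclass(frozen=True)
class DailySummary:
    calendar_date: date
    wear_h_waking: float
    valid: bool
    sedentary_min: float
    light_min: float
    mvpa_min: float
    pct_sedentary: float
    pct_light: float
    pct_mvpa: float
    step_count: int


def classify_epoch(avm_mg: float, cuts: IntensityCutPoints) -> str:
    """Map one epoch's AVM to sedentary / light / MVPA."""
    if avm_mg < 0:
        raise UsageError(f"AVM must be non-negative, got {avm_mg}")
    if avm_mg < cuts.light_threshold_mg:
        return SEDENTARY
    if avm_mg < cuts.moderate_threshold_mg:
        return LIGHT
    return MVPA


def classify_epochs(avm_mg: np.ndarray, cuts: IntensityCutPoints) -> np.ndarray:
    """Vectorized :func:`classify_epoch`."""
    avm_mg = np.asarray(avm_mg, dtype=float)
    if np.any(avm_mg < 0):
        raise UsageError("AVM must be non-negative")
    out = np.full(avm_mg.shape, LIGHT, dtype=object)
    out[avm_mg < cuts.light_threshold_mg] = SEDENTARY
    out[avm_mg >= cuts.moderate_threshold_mg] = MVPA
    return out


def label_walk_epochs(
    epochs15: AvmEpochSeries,
    long_walks: list[WalkingBout],
    cuts: IntensityCutPoints,
) -> list[LabeledEpoch]:
    """Intensity-labelled epochs wholly contained in LONG walks.

    Epochs straddling a walk's end are excluded (they would mix walking
    with whatever follows); the first candidate epoch is the first grid
    epoch starting at or after the walk start.
    """
    L = epochs15.epoch_length_s
    starts = epochs15.epoch_starts_s()
    labels = classify_epochs(epochs15.values, cuts)
    out: list[LabeledEpoch] = []
    for bout_id, walk in enumerate(long_walks):
        if not walk.is_long:
            continue
        # first grid index with start >= walk.start_s; last with end <= walk.end_s
        i0 = int(np.ceil(walk.start_s / L - 1e-9))
        i1 = int(np.floor(walk.end_s / L + 1e-9))  # one past: epoch i ends at (i+1)L
        for i in range(max(i0, 0), min(i1, len(starts))):
            out.append(
                LabeledEpoch(
                    epoch_start_s=float(starts[i]),
                    avm_mg=float(epochs15.values[i]),
                    label=str(labels[i]),
                    in_long_walk=True,
                    bout_id=bout_id,
                )
            )
    return out


def detect_sleep_windows(
    epochs: AvmEpochSeries,
    annotations: list[tuple[float, float]] | None = None,
    *,
    search_start: time = time(20, 0),
    search_end: time = time(12, 0),
    rolling_min: float = 5.0,
    avm_threshold_mg: float = 5.0,
    min_sleep_h: float = 5.0,
) -> list[tuple[float, float]]:
    """Nightly sleep intervals (s on the recording time base).

    Explicit annotations are passed through unchanged.  Otherwise a
    simple nocturnal-quiescence heuristic is used: within each night's
    20:00-to-noon search window, the longest run of epochs whose 5-minute
    rolling median AVM stays below 5 mg counts as sleep when it lasts at
    least 5 h.  This is deliberately minimal — it exists to partition
    valid-day wear time, not to stage sleep.
    """
    if annotations is not None:
        return list(annotations)
    if epochs.n_epochs * epochs.epoch_length_s < 24 * 3600:
        return []

    L = epochs.epoch_length_s
    k = max(1, int(round(rolling_min * 60 / L)))
    med = _rolling_median(epochs.values, k)
    quiet = med < avm_threshold_mg

    out = []
    t0 = epochs.start_time
    # nights indexed by the date on which the search window opens
    first_night = (t0 - timedelta(hours=4)).date()
    end_time_abs = t0 + timedelta(seconds=epochs.n_epochs * L)
    night = first_night
    while datetime.combine(night, search_start) < end_time_abs:
        w0 = (datetime.combine(night, search_start) - t0).total_seconds()
        w1 = (datetime.combine(night + timedelta(days=1), search_end) - t0).total_seconds()
        i0 = max(0, int(np.ceil(w0 / L)))
        i1 = min(epochs.n_epochs, int(np.floor(w1 / L)))
        if i1 > i0:
            run = _longest_true_run(quiet[i0:i1])
            if run is not None:
                s, e = run
                if (e - s) * L >= min_sleep_h * 3600:
                    out.append(((i0 + s) * L, (i0 + e) * L))
        night += timedelta(days=1)
    return out


def _rolling_median(values: np.ndarray, k: int) -> np.ndarray:
    import pandas as pd

    return (
        pd.Series(values).rolling(k, center=True, min_periods=1).median().to_numpy()
    )


def _longest_true_run(mask: np.ndarray) -> tuple[int, int] | None:
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    if len(edges) == 0:
        return None
    runs = list(zip(edges[::2], edges[1::2]))
    return max(runs, key=lambda r: r[1] - r[0])


def summarize_days(
    epochs15: AvmEpochSeries,
    nonwear: NonwearIntervals,
    sleep: list[tuple[float, float]],
    bouts: list[WalkingBout],
    config: PipelineConfig,
) -> list[DailySummary]:
    """Per-calendar-day waking-wear activity volumes.

    Only full calendar days (midnight-to-midnight entirely inside the
    recording) are summarized.  Waking wear excludes, epoch by epoch,
    sleep (epoch midpoint inside a sleep interval) and nonwear (wear
    fraction <= 0.5).  Each waking-wear epoch carries one intensity label,
    so class minutes sum exactly to waking wear.  A day is valid when
    waking wear reaches the configured minimum (default 10 h).
    """
    L = epochs15.epoch_length_s
    t0 = epochs15.start_time
    starts = epochs15.epoch_starts_s()
    mids = starts + L / 2
    labels = classify_epochs(epochs15.values, config.cut_points)

    in_sleep = np.zeros(len(starts), dtype=bool)
    for s, e in sleep:
        in_sleep |= (mids >= s) & (mids < e)
    worn = epochs15.wear_fraction > 0.5
    waking_wear = worn & ~in_sleep

    day_step_counts = {}
    for b in bouts:
        if b.is_all_walk:
            d = (t0 + timedelta(seconds=b.start_s)).date()
            day_step_counts[d] = day_step_counts.get(d, 0) + b.step_count

    end_abs = t0 + timedelta(seconds=len(starts) * L)
    day = t0.date() + timedelta(days=0 if t0.time() == time(0, 0) else 1)
    out: list[DailySummary] = []
    while datetime.combine(day + timedelta(days=1), time(0, 0)) <= end_abs:
        d0 = (datetime.combine(day, time(0, 0)) - t0).total_seconds()
        sel = (starts >= d0) & (starts + L <= d0 + 86400)
        ww = sel & waking_wear
        wear_h = ww.sum() * L / 3600
        mins = {
            lab: float((labels[ww] == lab).sum()) * L / 60
            for lab in (SEDENTARY, LIGHT, MVPA)
        }
        total_min = wear_h * 60
        pct = {
            lab: (100 * mins[lab] / total_min if total_min > 0 else float("nan"))
            for lab in (SEDENTARY, LIGHT, MVPA)
        }
        out.append(
            DailySummary(
                calendar_date=day,
                wear_h_waking=wear_h,
                valid=wear_h >= config.valid_day_min_wear_h,
                sedentary_min=mins[SEDENTARY],
                light_min=mins[LIGHT],
                mvpa_min=mins[MVPA],
                pct_sedentary=pct[SEDENTARY],
                pct_light=pct[LIGHT],
                pct_mvpa=pct[MVPA],
                step_count=day_step_counts.get(day, 0),
            )
        )
        day += timedelta(days=1)
    return out
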