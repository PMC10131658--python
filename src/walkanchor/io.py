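"""Reading, writing and aligning device recordings.

Two interchange formats are supported: EDF (see :mod:`walkanchor.edf`) and a
minimal CSV dialect — a header row with columns ``x,y,z`` in units of g and
an optional leading ISO-8601 ``timestamp`` column.  Without a timestamp
column the caller must declare the start time and sampling rate.

``synchronize`` puts the wrist and ankle streams on one clock (the wrist's)
and crops both to their common overlap.  Devices may drift relative to each
other by seconds per day; given one or two manually logged synchronization
events seen by both devices, the ankle clock is corrected by an offset (one
anchor) or a linear offset+rate map (two anchors).  Raw samples are never
resampled — only the ankle's start time and nominal rate metadata change.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .edf import read_edf, write_edf
from .errors import DataError, FormatError, UsageError
from .recording import TriaxialRecording

__all__ = [
    "read_recording",
    "write_recording",
    "synchronize",
    "AlignedPair",
    "read_edf",
    "write_edf",
]


def read_recording(
    path: str | Path,
    format: str,
    site: str,
    *,
    sample_rate_hz: float | None = None,
    start_time: datetime | None = None,
    body_side: str = "unspecified",
    device_id: str = "",
) -> TriaxialRecording:
    """Read one device stream from ``path``.

    For CSV without a timestamp column, ``sample_rate_hz`` and
    ``start_time`` are required.  A CSV timestamp column, when present,
    must be strictly increasing and uniform within 1% of the declared
    (or, failing that, its own median) rate.
    """
    path = Path(path)
    if not path.exists():
        raise UsageError(f"input file does not exist: {path}")
    if format == "edf":
        return read_edf(path, site, body_side=body_side, device_id=device_id)
    if format == "csv":
        return _read_csv(
            path,
            site,
            sample_rate_hz=sample_rate_hz,
            start_time=start_time,
            body_side=body_side,
            device_id=device_id,
        )
    raise UsageError(f"unsupported format {format!r}; expected 'edf' or 'csv'")


def _read_csv(path, site, *, sample_rate_hz, start_time, body_side, device_id):
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = {"x", "y", "z"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing axis column(s) {sorted(missing)}")
    samples = df[["x", "y", "z"]].to_numpy(dtype=float)

    if "timestamp" in df.columns:
        ts = pd.to_datetime(df["timestamp"])
        dt = ts.diff().dt.total_seconds().to_numpy()[1:]
        if np.any(dt <= 0):
            raise DataError(f"{path}: timestamps are not strictly increasing")
        declared = sample_rate_hz
        if declared is None:
            declared = 1.0 / np.median(dt)
        expected_dt = 1.0 / declared
        if np.any(np.abs(dt - expected_dt) > 0.01 * expected_dt):
            worst = float(np.max(np.abs(dt - expected_dt) / expected_dt))
            raise DataError(
                f"{path}: timestamp spacing deviates from {declared:g} Hz by up to "
                f"{100 * worst:.1f}% (limit 1%)"
            )
        sample_rate_hz = declared
        start_time = ts.iloc[0].to_pydatetime()
    elif sample_rate_hz is None or start_time is None:
        raise UsageError(
            f"{path}: CSV without a timestamp column requires declared "
            "sample_rate_hz and start_time"
        )

    return TriaxialRecording(
        site=site,
        sample_rate_hz=float(sample_rate_hz),
        start_time=start_time,
        samples=samples,
        body_side=body_side,
        device_id=device_id,
    )


def write_recording(
    rec: TriaxialRecording,
    path: str | Path,
    format: str = "csv",
    *,
    timestamps: bool = True,
) -> None:
    """Write a recording as CSV (default, with ISO timestamps) or EDF."""
    path = Path(path)
    if format == "edf":
        write_edf(rec, path)
        return
    if format != "csv":
        raise UsageError(f"unsupported format {format!r}; expected 'edf' or 'csv'")
    df = pd.DataFrame(rec.samples, columns=["x", "y", "z"])
    if timestamps:
        times = pd.Timestamp(rec.start_time) + pd.to_timedelta(
            np.arange(rec.n_samples) / rec.sample_rate_hz, unit="s"
        )
        df.insert(0, "timestamp", times.strftime("%Y-%m-%dT%H:%M:%S.%f"))
    df.to_csv(path, index=False, float_format="%.6f")


@dataclass(frozen=True)
class AlignedPair:
    """Wrist and ankle streams cropped to their overlap on the wrist clock.

    The common time base is seconds since ``t0`` (= the overlap start on
    the wrist clock); all downstream epoch and bout times use it.
    """

    wrist: TriaxialRecording
    ankle: TriaxialRecording
    t0: datetime


def synchronize(
    wrist: TriaxialRecording,
    ankle: TriaxialRecording,
    anchors: list[tuple[float, float]] | None = None,
) -> AlignedPair:
    """Align the ankle stream to the wrist clock and crop to the overlap.

    ``anchors`` are up to two ``(event_time_wrist_s, event_time_ankle_s)``
    pairs, each giving the elapsed time at which one physical event was
    seen on each device's own clock.  One anchor corrects a constant
    offset; two correct a linear drift.  Without anchors the device
    clocks are taken as drift-free and aligned by their start stamps.
    """
    ankle = _apply_anchor_map(wrist, ankle, anchors)

    start = max(wrist.start_time, ankle.start_time)
    end = min(wrist.end_time, ankle.end_time)
    if end <= start:
        raise DataError(
            f"recordings do not overlap (wrist {wrist.start_time}..{wrist.end_time}, "
            f"ankle {ankle.start_time}..{ankle.end_time})"
        )

    def crop_to(rec: TriaxialRecording) -> TriaxialRecording:
        s = (start - rec.start_time).total_seconds()
        e = (end - rec.start_time).total_seconds()
        if s == 0 and abs(e - rec.duration_s) < 0.5 / rec.sample_rate_hz:
            return rec
        return rec.crop(s, e)

    return AlignedPair(wrist=crop_to(wrist), ankle=crop_to(ankle), t0=start)


def _apply_anchor_map(wrist, ankle, anchors):
    if not anchors:
        return ankle
    if len(anchors) > 2:
        raise UsageError("at most two anchor pairs are supported")
    from dataclasses import replace

    if len(anchors) == 1:
        (tw, ta), = anchors
        scale = 1.0
        offset = tw - ta
    else:
        (tw1, ta1), (tw2, ta2) = anchors
        if ta2 == ta1:
            raise UsageError("anchor pairs must have distinct ankle times")
        scale = (tw2 - tw1) / (ta2 - ta1)
        if scale <= 0:
            raise DataError("anchor pairs imply a non-causal clock map")
        offset = tw1 - scale * ta1
    # ankle sample i maps to wrist-elapsed offset + scale * i/rate:
    # equivalent to shifting the start stamp and rescaling the nominal rate
    return replace(
        ankle,
        start_time=wrist.start_time + timedelta(seconds=offset),
        sample_rate_hz=ankle.sample_rate_hz / scale,
    )
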