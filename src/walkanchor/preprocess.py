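"""Gravity autocalibration, nonwear detection and AVM epoching.

The activity metric throughout is the average vector magnitude (AVM): the
per-epoch mean of the low-pass-filtered, calibrated acceleration vector
norm minus 1 g, truncated at zero (ENMO-style), reported in milli-g.  It is
independent of sampling rate, which lets 50 Hz and 75 Hz devices share one
set of intensity cut points.

Autocalibration exploits the fact that during stationary periods the
acceleration vector is gravity alone, so its magnitude must be 1 g
regardless of orientation.  Per-axis offsets and gains are fitted so that
stationary-window means lie on the unit sphere; the fit needs windows in
several distinct orientations, otherwise it is under-determined and the
identity calibration is returned flagged as such.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .errors import UsageError
from .recording import TriaxialRecording

# bounds beyond which a fitted calibration is implausible and rejected
GAIN_BOUNDS = (0.8, 1.2)
OFFSET_BOUND_G = 0.25


@dataclass(frozen=True)
class CalibrationParams:
    """Per-axis linear correction: calibrated = offset + gain * raw."""

    offset: np.ndarray = field(default_factory=lambda: np.zeros(3))
    gain: np.ndarray = field(default_factory=lambda: np.ones(3))
    calibrated: bool = False
    n_stationary_windows: int = 0

    def apply(self, rec: TriaxialRecording) -> TriaxialRecording:
        return replace(rec, samples=self.offset + self.gain * rec.samples)


@dataclass(frozen=True)
class NonwearIntervals:
    """Sorted, non-overlapping half-open (start_s, end_s) intervals."""

    intervals: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        prev_end = -np.inf
        for s, e in self.intervals:
            if e <= s or s < prev_end:
                raise UsageError(f"invalid/overlapping nonwear intervals: {self.intervals}")
            prev_end = e

    def total_s(self) -> float:
        return sum(e - s for s, e in self.intervals)

    def overlap_s(self, start_s: float, end_s: float) -> float:
        """Seconds of [start_s, end_s) covered by nonwear."""
        return sum(
            max(0.0, min(e, end_s) - max(s, start_s)) for s, e in self.intervals
        )


@dataclass
class AvmEpochSeries:
    """Per-epoch AVM (milli-g) with per-epoch wear fraction.

    Epoch i covers [i, i+1) * epoch_length_s on the recording's time base;
    ``start_time`` anchors epoch 0 in absolute time.
    """

    epoch_length_s: float
    start_time: datetime
    values: np.ndarray
    wear_fraction: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.wear_fraction = np.asarray(self.wear_fraction, dtype=float)
        if self.values.shape != self.wear_fraction.shape:
            raise UsageError("values and wear_fraction must have equal length")
        if np.any(self.values < 0):
            raise UsageError("AVM values must be non-negative")

    @property
    def n_epochs(self) -> int:
        return len(self.values)

    def epoch_starts_s(self) -> np.ndarray:
        return np.arange(self.n_epochs) * self.epoch_length_s


# ---------------------------------------------------------------------------
# stationary windows + autocalibration


def find_stationary_windows(
    rec: TriaxialRecording,
    window_s: float = 10.0,
    sd_threshold_g: float = 0.013,
) -> list[tuple[float, np.ndarray]]:
    """Non-overlapping windows where all three axes are near-constant.

    Returns ``(window_start_s, mean_xyz)`` for each window whose per-axis
    standard deviation is below ``sd_threshold_g`` on every axis.
    """
    if window_s < 1:
        raise UsageError("window_s must be >= 1 s")
    n_win = int(window_s * rec.sample_rate_hz)
    n = rec.n_samples // n_win
    if n == 0:
        return []
    blocks = rec.samples[: n * n_win].reshape(n, n_win, 3)
    sds = blocks.std(axis=1)
    means = blocks.mean(axis=1)
    keep = np.all(sds < sd_threshold_g, axis=1)
    return [(i * window_s, means[i]) for i in np.flatnonzero(keep)]


def autocalibrate(
    rec: TriaxialRecording,
    windows: list[tuple[float, np.ndarray]] | None = None,
    *,
    min_windows: int = 5,
    min_spread_deg: float = 30.0,
    max_iter: int = 1000,
    tol: float = 1e-16,
    **window_kwargs,
) -> CalibrationParams:
    """Fit per-axis offset/gain so stationary windows sit on the unit sphere.

    Iteratively re-weighted axis-wise linear fit: each iteration projects
    the current calibrated window means onto the unit sphere and regresses
    each axis of the raw means against its projection.  With fewer than
    ``min_windows`` windows, or with all window orientations within
    ``min_spread_deg`` of each other, the problem is under-determined and
    the identity calibration is returned with ``calibrated=False``.  A fit
    wandering outside plausible bounds (gain outside [0.8, 1.2], offset
    beyond 0.25 g) is likewise rejected — a degraded result is flagged,
    never fatal.
    """
    if windows is None:
        windows = find_stationary_windows(rec, **window_kwargs)
    raw = np.array([m for _, m in windows], dtype=float)
    n = len(raw)
    if n < min_windows:
        return CalibrationParams(n_stationary_windows=n)

    units = raw / np.linalg.norm(raw, axis=1, keepdims=True)
    cosines = np.clip(units @ units.T, -1.0, 1.0)
    max_angle = np.degrees(np.arccos(cosines.min()))
    if max_angle <= min_spread_deg:
        return CalibrationParams(n_stationary_windows=n)

    offset = np.zeros(3)
    gain = np.ones(3)
    prev_err = np.inf
    for _ in range(max_iter):
        cal = offset + gain * raw
        norms = np.linalg.norm(cal, axis=1, keepdims=True)
        target = cal / norms
        for ax in range(3):
            A = np.column_stack([np.ones(n), raw[:, ax]])
            coef, *_ = np.linalg.lstsq(A, target[:, ax], rcond=None)
            offset[ax], gain[ax] = coef
        err = float(np.mean((np.linalg.norm(offset + gain * raw, axis=1) - 1.0) ** 2))
        if abs(prev_err - err) < tol:
            break
        prev_err = err

    lo, hi = GAIN_BOUNDS
    if np.any(gain < lo) or np.any(gain > hi) or np.any(np.abs(offset) > OFFSET_BOUND_G):
        return CalibrationParams(n_stationary_windows=n)
    return CalibrationParams(
        offset=offset, gain=gain, calibrated=True, n_stationary_windows=n
    )


# ---------------------------------------------------------------------------
# nonwear


def detect_nonwear(
    rec: TriaxialRecording,
    window_s: float = 60.0,
    sd_threshold_g: float = 0.013,
    range_threshold_g: float = 0.05,
    min_duration_min: float = 60.0,
    merge_gap_min: float = 5.0,
) -> NonwearIntervals:
    """Detect prolonged near-constant signal typical of an unworn device.

    A 60-s window counts as still when at least 2 of 3 axes have both
    standard deviation below ``sd_threshold_g`` and peak-to-peak range
    below ``range_threshold_g``.  Maximal runs of still windows are merged
    across gaps shorter than ``merge_gap_min`` and kept when the merged
    run lasts at least ``min_duration_min``.
    """
    n_win = int(window_s * rec.sample_rate_hz)
    n = rec.n_samples // n_win
    if n == 0 or rec.duration_s < min_duration_min * 60:
        return NonwearIntervals()
    blocks = rec.samples[: n * n_win].reshape(n, n_win, 3)
    sds = blocks.std(axis=1)
    rngs = blocks.max(axis=1) - blocks.min(axis=1)
    axis_still = (sds < sd_threshold_g) & (rngs < range_threshold_g)
    still = axis_still.sum(axis=1) >= 2

    runs = _runs_of_true(still)
    intervals = [(s * window_s, e * window_s) for s, e in runs]
    merged: list[list[float]] = []
    for s, e in intervals:
        if merged and s - merged[-1][1] < merge_gap_min * 60:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    kept = [(s, e) for s, e in merged if e - s >= min_duration_min * 60]
    return NonwearIntervals(tuple(kept))


def _runs_of_true(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open index runs of consecutive True values."""
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    return list(zip(edges[::2], edges[1::2]))


# ---------------------------------------------------------------------------
# AVM epochs


def compute_avm(
    rec: TriaxialRecording,
    calibration: CalibrationParams | None = None,
    epoch_length_s: float = 1.0,
    *,
    lowpass_hz: float = 20.0,
    filter_order: int = 4,
    nonwear: NonwearIntervals | None = None,
) -> AvmEpochSeries:
    """Epoch-average ENMO of the calibrated, low-pass-filtered signal.

    Each axis is zero-phase Butterworth low-pass filtered (skipped when the
    Nyquist frequency does not exceed the cutoff), the vector magnitude is
    taken per sample, 1 g is subtracted and negatives floored to zero, and
    the per-epoch mean is scaled to milli-g.  The trailing partial epoch is
    dropped.  ``nonwear`` intervals, when given, populate the per-epoch
    wear fraction (they do not zero the AVM values).
    """
    if calibration is not None:
        rec = calibration.apply(rec)
    n_ep_samples = int(round(epoch_length_s * rec.sample_rate_hz))
    n_epochs = rec.n_samples // n_ep_samples
    if n_epochs < 1:
        raise UsageError(
            f"epoch of {epoch_length_s} s exceeds recording of {rec.duration_s:.2f} s"
        )

    x = rec.samples
    if rec.sample_rate_hz / 2 > lowpass_hz:
        sos = butter(filter_order, lowpass_hz, btype="low", fs=rec.sample_rate_hz,
                     output="sos")
        x = sosfiltfilt(sos, x, axis=0)
    enmo = np.maximum(np.linalg.norm(x, axis=1) - 1.0, 0.0)
    avm = enmo[: n_epochs * n_ep_samples].reshape(n_epochs, n_ep_samples).mean(axis=1)

    wear = np.ones(n_epochs)
    if nonwear is not None:
        starts = np.arange(n_epochs) * epoch_length_s
        wear = np.array(
            [1.0 - nonwear.overlap_s(s, s + epoch_length_s) / epoch_length_s
             for s in starts]
        )
    return AvmEpochSeries(
        epoch_length_s=epoch_length_s,
        start_time=rec.start_time,
        values=avm * 1000.0,
        wear_fraction=wear,
    )


def reepoch(series: AvmEpochSeries, target_length_s: float = 15.0) -> AvmEpochSeries:
    """Reaverage epochs into longer ones (e.g. 1 s -> 15 s).

    The target must be an integer multiple of the source epoch length; the
    trailing incomplete block is dropped.  Values and wear fractions are
    arithmetic means of their constituents, so the sum of value x length
    over the retained span is conserved exactly.
    """
    ratio = target_length_s / series.epoch_length_s
    if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
        raise UsageError(
            f"target epoch {target_length_s} s is not an integer multiple of "
            f"source epoch {series.epoch_length_s} s"
        )
    k = int(round(ratio))
    n_out = series.n_epochs // k
    vals = series.values[: n_out * k].reshape(n_out, k).mean(axis=1)
    wear = series.wear_fraction[: n_out * k].reshape(n_out, k).mean(axis=1)
    return AvmEpochSeries(
        epoch_length_s=target_length_s,
        start_time=series.start_time,
        values=vals,
        wear_fraction=wear,
    )
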