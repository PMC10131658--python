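"""Raw triaxial acceleration streams.

A :class:`TriaxialRecording` holds one device's uniformly sampled x/y/z
acceleration in units of g (1 g = 9.81 m/s^2), together with the wear site
(wrist or ankle), body side, sampling rate, and absolute start time.  Sample
timestamps are implicit: sample ``i`` occurs ``i / sample_rate_hz`` seconds
after ``start_time``.  Free-living wrist/ankle devices record at 50 or 75 Hz;
any rate in [10, 1000] Hz is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta

import numpy as np

from .errors import DataError, UsageError

VALID_SITES = ("wrist", "ankle")
VALID_SIDES = ("dominant", "nondominant", "unspecified")


@dataclass
class TriaxialRecording:
    site: str
    sample_rate_hz: float
    start_time: datetime
    samples: np.ndarray  # (n, 3) float array, units of g
    body_side: str = "unspecified"
    device_id: str = ""

    def __post_init__(self) -> None:
        if self.site not in VALID_SITES:
            raise UsageError(f"site must be one of {VALID_SITES}, got {self.site!r}")
        if self.body_side not in VALID_SIDES:
            raise UsageError(
                f"body_side must be one of {VALID_SIDES}, got {self.body_side!r}"
            )
        if not (10 <= self.sample_rate_hz <= 1000):
            raise DataError(
                f"sample_rate_hz must lie in [10, 1000], got {self.sample_rate_hz}"
            )
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise DataError(f"samples must have shape (n, 3), got {arr.shape}")
        if arr.shape[0] < 1:
            raise DataError("recording must contain at least one sample")
        if not np.all(np.isfinite(arr)):
            raise DataError("samples contain NaN or infinite values")
        self.samples = arr

    # -- derived quantities -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        """Recording span in seconds (n / rate; the sample at t=0 counts)."""
        return self.n_samples / self.sample_rate_hz

    @property
    def end_time(self) -> datetime:
        return self.start_time + timedelta(seconds=self.duration_s)

    def time_s(self) -> np.ndarray:
        """Per-sample time in seconds since ``start_time``."""
        return np.arange(self.n_samples) / self.sample_rate_hz

    def vector_magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.samples, axis=1)

    def crop(self, start_s: float, end_s: float) -> "TriaxialRecording":
        """Return the sub-recording covering [start_s, end_s) on this
        recording's own time base."""
        if end_s <= start_s:
            raise UsageError("crop requires end_s > start_s")
        i0 = max(0, int(np.ceil(start_s * self.sample_rate_hz - 1e-9)))
        i1 = min(self.n_samples, int(np.floor(end_s * self.sample_rate_hz - 1e-9)) + 1)
        if i1 <= i0:
            raise DataError("crop window contains no samples")
        return replace(
            self,
            samples=self.samples[i0:i1].copy(),
            start_time=self.start_time + timedelta(seconds=i0 / self.sample_rate_hz),
        )
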