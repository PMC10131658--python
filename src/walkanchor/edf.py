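"""Minimal European Data Format (EDF) codec for triaxial acceleration.

EDF stores an ASCII header (256 bytes global + 256 per signal) followed by
fixed-duration data records of little-endian 16-bit integers, mapped
linearly between a digital and a physical range.  This codec writes the
three acceleration axes as three signals with a physical range of ±8 g
(the range of the wrist/ankle devices this pipeline targets) and reads any
EDF whose first three signals share one sampling rate.

Sub-second start times are not representable in the EDF header and are
truncated to the whole second on write.
"""

from __future__ import annotations

from datetime import datetime
from pathlib import Path

import numpy as np

from .errors import FormatError
from .recording import TriaxialRecording

PHYS_MIN = -8.0
PHYS_MAX = 8.0
DIG_MIN = -32768
DIG_MAX = 32767
_AXIS_LABELS = ("Accel X", "Accel Y", "Accel Z")


def _ascii(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(rec: TriaxialRecording, path: str | Path) -> None:
    """Write a recording as a 3-signal EDF file.

    Record layout: 1-second records when the sample count divides evenly
    at an integer rate, otherwise a single record holding the whole stream
    (EDF permits fractional record durations), so the sample count is
    always preserved exactly.
    """
    n = rec.n_samples
    rate = rec.sample_rate_hz
    if float(rate).is_integer() and n % int(rate) == 0:
        spr = int(rate)  # samples per record, per signal
        n_records = n // spr
        record_dur = 1.0
    else:
        spr = n
        n_records = 1
        record_dur = n / rate

    t = rec.start_time
    header = b"".join(
        [
            _ascii("0", 8),
            _ascii(f"X X X {rec.device_id or 'X'}", 80),
            _ascii(
                f"Startdate {t.strftime('%d-%b-%Y').upper()} site={rec.site} "
                f"side={rec.body_side}",
                80,
            ),
            _ascii(t.strftime("%d.%m.%y"), 8),
            _ascii(t.strftime("%H.%M.%S"), 8),
            _ascii(256 * 4, 8),
            _ascii("", 44),
            _ascii(n_records, 8),
            _ascii(f"{record_dur:.6g}", 8),
            _ascii(3, 4),
        ]
    )
    per_signal = b"".join(
        [
            b"".join(_ascii(lbl, 16) for lbl in _AXIS_LABELS),
            b"".join(_ascii("accelerometer", 80) for _ in range(3)),
            b"".join(_ascii("g", 8) for _ in range(3)),
            b"".join(_ascii(PHYS_MIN, 8) for _ in range(3)),
            b"".join(_ascii(PHYS_MAX, 8) for _ in range(3)),
            b"".join(_ascii(DIG_MIN, 8) for _ in range(3)),
            b"".join(_ascii(DIG_MAX, 8) for _ in range(3)),
            b"".join(_ascii("LP:none", 80) for _ in range(3)),
            b"".join(_ascii(spr, 8) for _ in range(3)),
            b"".join(_ascii("", 32) for _ in range(3)),
        ]
    )

    scale = (DIG_MAX - DIG_MIN) / (PHYS_MAX - PHYS_MIN)
    dig = np.round((np.clip(rec.samples, PHYS_MIN, PHYS_MAX) - PHYS_MIN) * scale
                   + DIG_MIN).astype("<i2")
    # records are signal-major within each record: x block, y block, z block
    blocks = dig.reshape(n_records, spr, 3).transpose(0, 2, 1)

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(per_signal)
        fh.write(blocks.tobytes())


def read_edf(path: str | Path, site: str, **meta) -> TriaxialRecording:
    """Read the first three signals of an EDF file as a triaxial recording.

    All three signals must share one samples-per-record value; extra
    signals (if any) are ignored.  ``meta`` forwards ``body_side`` /
    ``device_id`` overrides to :class:`TriaxialRecording`.
    """
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise FormatError(f"{path}: truncated EDF header")
        try:
            n_records = int(head[236:244].decode("ascii").strip())
            record_dur = float(head[244:252].decode("ascii").strip())
            ns = int(head[252:256].decode("ascii").strip())
        except (UnicodeDecodeError, ValueError) as exc:
            raise FormatError(f"{path}: malformed EDF header: {exc}") from exc
        if ns < 3:
            raise FormatError(
                f"{path}: expected 3 acceleration signals, found {ns}"
            )
        start_str = head[168:184].decode("ascii", errors="replace")
        try:
            start_time = datetime.strptime(start_str, "%d.%m.%y%H.%M.%S")
        except ValueError as exc:
            raise FormatError(f"{path}: malformed EDF start stamp") from exc

        sig = fh.read(256 * ns)
        if len(sig) < 256 * ns:
            raise FormatError(f"{path}: truncated EDF signal headers")

        def field(offset: int, width: int, i: int) -> str:
            base = offset * ns + width * i
            return sig[base:base + width].decode("ascii").strip()

        phys_min = [float(field(16 + 80 + 8, 8, i)) for i in range(3)]
        phys_max = [float(field(16 + 80 + 8 + 8, 8, i)) for i in range(3)]
        dig_min = [float(field(16 + 80 + 8 + 16, 8, i)) for i in range(3)]
        dig_max = [float(field(16 + 80 + 8 + 24, 8, i)) for i in range(3)]
        spr = [int(field(16 + 80 + 8 + 32 + 80, 8, i)) for i in range(ns)]
        if len(set(spr[:3])) != 1:
            raise FormatError(
                f"{path}: acceleration signals have unequal sampling rates {spr[:3]}"
            )
        raw = np.frombuffer(fh.read(), dtype="<i2")

    rec_len = sum(spr)
    if raw.size < n_records * rec_len:
        raise FormatError(f"{path}: data section shorter than header promises")
    raw = raw[: n_records * rec_len].reshape(n_records, rec_len)

    offsets = np.concatenate([[0], np.cumsum(spr)])
    axes = []
    for i in range(3):
        dig = raw[:, offsets[i]:offsets[i + 1]].astype(float).ravel()
        gain = (phys_max[i] - phys_min[i]) / (dig_max[i] - dig_min[i])
        axes.append((dig - dig_min[i]) * gain + phys_min[i])

    rate = spr[0] / record_dur
    return TriaxialRecording(
        site=site,
        sample_rate_hz=rate,
        start_time=start_time,
        samples=np.column_stack(axes),
        **meta,
    )
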