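"""Minimal EDF writer for interoperability with standard EEG tooling.

Writes plain EDF (ASCII header, 16-bit little-endian samples, 1-second
data records). Covers the subset needed to export simulated or
preprocessed recordings; per-channel physical scaling is symmetric
around zero. Readable by MNE and other EDF consumers.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from cogload.containers import EEGRecording
from cogload.errors import InvalidArgumentError

_DIG_MIN, _DIG_MAX = -32768, 32767


def _ascii(value: str, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise InvalidArgumentError(f"EDF field {s!r} exceeds {width} chars")
    return s.ljust(width).encode("ascii")


def _num(value: float, width: int) -> bytes:
    for fmt in (f"{value:.6g}", f"{value:.4g}", f"{value:.1e}"):
        if len(fmt) <= width:
            return fmt.ljust(width).encode("ascii")
    raise InvalidArgumentError(f"cannot format {value} in {width} chars")


def write_edf(path: str | Path, recording: EEGRecording) -> None:
    """Write an EEGRecording (microvolts) as an EDF file.

    The sampling rate must be a positive integer and the signal length
    a whole number of seconds (EDF stores fixed 1-second records).
    """
    fs = recording.fs
    if fs <= 0 or fs != int(fs):
        raise InvalidArgumentError("EDF export requires an integer sampling rate")
    fs = int(fs)
    n_ch, n_samp = recording.data.shape
    if n_samp == 0 or n_samp % fs != 0:
        raise InvalidArgumentError(
            "EDF export requires a whole number of seconds of signal"
        )
    n_records = n_samp // fs

    # symmetric physical range per channel, padded so zero maps exactly
    phys_max = np.abs(recording.data).max(axis=1)
    phys_max = np.where(phys_max > 0, phys_max, 1.0)

    header = bytearray()
    header += _ascii("0", 8)                        # version
    header += _ascii("simulated subject", 80)       # patient id
    header += _ascii("cogload export", 80)          # recording id
    header += _ascii("01.01.00", 8)                 # start date
    header += _ascii("00.00.00", 8)                 # start time
    header += _ascii(str(256 * (n_ch + 1)), 8)      # header length
    header += _ascii("", 44)                        # reserved
    header += _ascii(str(n_records), 8)
    header += _ascii("1", 8)                        # record duration (s)
    header += _ascii(str(n_ch), 4)

    def field(values, width):
        out = bytearray()
        for v in values:
            out += v if isinstance(v, bytes) else _ascii(v, width)
        return out

    header += field([ch[:16] for ch in recording.channel_names], 16)
    header += field(["" for _ in range(n_ch)], 80)            # transducer
    header += field(["uV" for _ in range(n_ch)], 8)           # dimension
    header += field([_num(-m, 8) for m in phys_max], 8)       # physical min
    header += field([_num(m, 8) for m in phys_max], 8)        # physical max
    header += field([str(_DIG_MIN) for _ in range(n_ch)], 8)
    header += field([str(_DIG_MAX) for _ in range(n_ch)], 8)
    header += field(["" for _ in range(n_ch)], 80)            # prefiltering
    header += field([str(fs) for _ in range(n_ch)], 8)        # samples/record
    header += field(["" for _ in range(n_ch)], 32)            # reserved

    scale = (_DIG_MAX - _DIG_MIN) / (2 * phys_max)
    digital = np.round((recording.data + phys_max[:, None]) * scale[:, None]) + _DIG_MIN
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        for r in range(n_records):
            block = digital[:, r * fs : (r + 1) * fs]
            fh.write(block.tobytes())  # channel-major within each record
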