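"""EEG cleaning chain and electrode selection.

Fixed stage order: DC removal -> zero-phase band-pass (0.1-45 Hz
default) -> anti-aliased downsampling (to 256 Hz default) -> selection
of the 16 Brodmann-mapped electrodes -> segmentation into labeled
session epochs. Band-pass uses a 4th-order Butterworth applied
forward-backward (no phase distortion, which matters because the
downstream PLV/PTE metrics are phase-based).
"""

from __future__ import annotations

from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy import signal

from cogload.containers import EEGRecording, SessionEpoch
from cogload.errors import InvalidArgumentError, MissingChannelsError

#: Electrodes retained for connectivity, in canonical order.
CANONICAL_CHANNELS = [
    "Fp1", "Fp2", "F7", "F3", "F4", "F8", "T7", "C3",
    "C4", "T8", "P7", "P3", "P4", "P8", "O1", "O2",
]

#: Closest Brodmann area for each canonical electrode.
BRODMANN_AREAS = dict(zip(
    CANONICAL_CHANNELS,
    [10, 10, 47, 8, 8, 45, 42, 2, 1, 21, 37, 39, 39, 37, 18, 18],
))

DEFAULT_BAND = (0.1, 45.0)
DEFAULT_TARGET_FS = 256.0


def remove_dc(recording: EEGRecording) -> EEGRecording:
    """Subtract each channel's mean (DC offset removal)."""
    if recording.n_samples < 1:
        raise InvalidArgumentError("recording has no samples")
    data = recording.data - recording.data.mean(axis=1, keepdims=True)
    return EEGRecording(data, recording.fs, list(recording.channel_names))


def bandpass(
    recording: EEGRecording, low_hz: float = DEFAULT_BAND[0],
    high_hz: float = DEFAULT_BAND[1],
) -> EEGRecording:
    """Zero-phase 4th-order Butterworth band-pass (forward-backward)."""
    nyq = recording.fs / 2.0
    if not 0 < low_hz < high_hz:
        raise InvalidArgumentError("need 0 < low_hz < high_hz")
    if high_hz >= nyq:
        raise InvalidArgumentError(
            f"high_hz={high_hz} must be below Nyquist ({nyq} Hz)"
        )
    sos = signal.butter(4, (low_hz, high_hz), btype="bandpass",
                        fs=recording.fs, output="sos")
    data = signal.sosfiltfilt(sos, recording.data, axis=1)
    return EEGRecording(data, recording.fs, list(recording.channel_names))


def downsample(recording: EEGRecording, target_fs: float = DEFAULT_TARGET_FS) -> EEGRecording:
    """Anti-aliased resampling to target_fs (polyphase FIR).

    Output length is floor(n_samples * target_fs / fs).
    """
    if target_fs <= 0:
        raise InvalidArgumentError("target_fs must be positive")
    if target_fs > recording.fs:
        raise InvalidArgumentError("target_fs must not exceed the current rate")
    if target_fs == recording.fs:
        return EEGRecording(recording.data.copy(), recording.fs,
                            list(recording.channel_names))
    ratio = Fraction(target_fs / recording.fs).limit_denominator(10000)
    data = signal.resample_poly(recording.data, ratio.numerator,
                                ratio.denominator, axis=1)
    n_out = int(np.floor(recording.n_samples * target_fs / recording.fs))
    data = data[:, :n_out]
    return EEGRecording(data, target_fs, list(recording.channel_names))


def select_channels(
    recording: EEGRecording,
) -> tuple[EEGRecording, dict[str, int]]:
    """Project onto the 16 canonical electrodes (case-insensitive match).

    Returns the 16-channel recording in canonical order together with
    the electrode -> Brodmann-area map. Raises MissingChannelsError
    naming any absent electrode.
    """
    lookup = {name.lower(): i for i, name in enumerate(recording.channel_names)}
    missing = [ch for ch in CANONICAL_CHANNELS if ch.lower() not in lookup]
    if missing:
        raise MissingChannelsError(missing)
    rows = [lookup[ch.lower()] for ch in CANONICAL_CHANNELS]
    out = EEGRecording(recording.data[rows], recording.fs, list(CANONICAL_CHANNELS))
    return out, dict(BRODMANN_AREAS)


def segment_sessions(
    recording: EEGRecording,
    boundaries: list[tuple[int, int, str]],
) -> list[SessionEpoch]:
    """Cut half-open [start, end) sample windows into labeled epochs.

    Boundaries must be in-range and non-overlapping (any order).
    """
    n = recording.n_samples
    for start, end, _label in boundaries:
        if not (0 <= start < end <= n):
            raise InvalidArgumentError(
                f"boundary [{start}, {end}) outside signal of {n} samples"
            )
    spans = sorted((s, e) for s, e, _ in boundaries)
    for (s1, e1), (s2, _e2) in zip(spans, spans[1:]):
        if s2 < e1:
            raise InvalidArgumentError("boundaries overlap")
    return [
        SessionEpoch(
            data=recording.data[:, start:end],
            fs=recording.fs,
            label=label,
            channel_names=list(recording.channel_names),
        )
        for start, end, label in boundaries
    ]


def preprocess(
    recording: EEGRecording,
    low_hz: float = DEFAULT_BAND[0],
    high_hz: float = DEFAULT_BAND[1],
    target_fs: float = DEFAULT_TARGET_FS,
) -> EEGRecording:
    """Full cleaning chain: DC removal -> band-pass -> downsample -> select."""
    rec = remove_dc(recording)
    rec = bandpass(rec, low_hz, high_hz)
    rec = downsample(rec, target_fs)
    rec, _areas = select_channels(rec)
    return rec


def read_edf(path: str | Path) -> EEGRecording:
    """Read an EDF recording (via MNE) into an EEGRecording in microvolts."""
    import mne  # optional dependency, only needed for EDF input

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return EEGRecording(
        data=raw.get_data() * 1e6,
        fs=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
    )
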