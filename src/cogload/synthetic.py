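"""Coupled-oscillator EEG simulator.

Each channel carries a noisy sinusoidal source: a fixed-frequency
oscillation with a random initial phase and a random-walk phase jitter
(phase diffusion), plus additive noise. Coupling between channels is
linear mixing of source components:

* undirected coupling (lag 0) with strength c mixes source i into
  channel j with weight c, so the two channels share a phase component
  and PLV/MI between them grows with c;
* directed coupling (lag L > 0 samples) mixes a *delayed* copy of
  source i into channel j, so information flows i -> j and dPTE in
  that direction exceeds 0.5.

The generator also produces whole study-shaped datasets: 3 workload
classes x n sessions per class, in seeded randomized order, matching
an n-back protocol of 339 sessions (113 per class) of ~18 s at 256 Hz.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from cogload.containers import CLASS_LABELS, EEGRecording, SessionEpoch
from cogload.errors import InvalidArgumentError

#: The 16 scalp electrodes used downstream, in canonical order.
CANONICAL_16 = [
    "Fp1", "Fp2", "F7", "F3", "F4", "F8", "T7", "C3",
    "C4", "T8", "P7", "P3", "P4", "P8", "O1", "O2",
]


def _default_channel_names(n: int) -> list[str]:
    if n == len(CANONICAL_16):
        return list(CANONICAL_16)
    return [f"CH{i + 1:02d}" for i in range(n)]


@dataclass
class CouplingSpec:
    """Ground-truth coupling structure for one workload class.

    pair_strengths[i, j] in [0, 1] is the mixing weight of source i
    into channel j (row = source, column = target); directed_lags[i, j]
    is the delay in samples applied to that component (0 = undirected).
    noise_sd is the additive-noise amplitude relative to unit-amplitude
    oscillators; phase_jitter_sd is the per-sample phase-diffusion step
    in radians.
    """

    n_channels: int
    pair_strengths: np.ndarray | None = None
    directed_lags: np.ndarray | None = None
    noise_sd: float = 1.0
    base_freqs: np.ndarray | None = None
    phase_jitter_sd: float = 0.05
    noise_color: str = "white"
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = self.n_channels
        if n < 1:
            raise InvalidArgumentError("n_channels must be >= 1")
        if self.pair_strengths is None:
            self.pair_strengths = np.zeros((n, n))
        self.pair_strengths = np.asarray(self.pair_strengths, dtype=float)
        if self.directed_lags is None:
            self.directed_lags = np.zeros((n, n), dtype=int)
        self.directed_lags = np.asarray(self.directed_lags)
        if self.base_freqs is None:
            # spread through the alpha band so channels are distinguishable
            self.base_freqs = np.linspace(8.0, 12.0, n)
        self.base_freqs = np.asarray(self.base_freqs, dtype=float)

        if self.pair_strengths.shape != (n, n) or self.directed_lags.shape != (n, n):
            raise InvalidArgumentError("coupling matrices must be n_channels square")
        if self.base_freqs.shape != (n,):
            raise InvalidArgumentError("base_freqs must have one entry per channel")
        if np.any(self.pair_strengths < 0) or np.any(self.pair_strengths > 1):
            raise InvalidArgumentError("pair_strengths entries must lie in [0, 1]")
        if np.any(np.diag(self.pair_strengths) != 0):
            raise InvalidArgumentError("pair_strengths diagonal must be 0")
        if np.any(self.directed_lags < 0) or np.any(self.directed_lags % 1 != 0):
            raise InvalidArgumentError("directed_lags must be non-negative integers")
        if np.any(np.diag(self.directed_lags) != 0):
            raise InvalidArgumentError("directed_lags diagonal must be 0")
        self.directed_lags = self.directed_lags.astype(int)
        if self.noise_color not in ("white", "pink"):
            raise InvalidArgumentError("noise_color must be 'white' or 'pink'")
        if not self.channel_names:
            self.channel_names = _default_channel_names(n)


@dataclass
class StudySchedule:
    """Session layout of the n-back study: 3 classes x n sessions each."""

    n_sessions_per_class: int = 113
    classes: tuple[str, ...] = CLASS_LABELS
    session_duration_s: float = 18.0
    fs: float = 256.0

    def __post_init__(self) -> None:
        if self.n_sessions_per_class < 1:
            raise InvalidArgumentError("n_sessions_per_class must be >= 1")
        if tuple(self.classes) != CLASS_LABELS:
            raise InvalidArgumentError(f"classes must be {CLASS_LABELS}")

    @property
    def n_sessions(self) -> int:
        return len(self.classes) * self.n_sessions_per_class


def _pink_noise(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """1/f-amplitude Gaussian noise, unit variance per channel."""
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(shape[-1])
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(freqs[nz])
    scale[0] = 0.0
    out = np.fft.irfft(spec * scale, n=shape[-1], axis=-1)
    sd = out.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd


def simulate_session(
    spec: CouplingSpec, duration_s: float, fs: float, seed: int
) -> EEGRecording:
    """Simulate one session of coupled-oscillator EEG.

    Deterministic given (spec, duration_s, fs, seed). Raises
    InvalidArgumentError for non-positive duration/fs, fewer than 256
    samples, or a lag that reaches the signal length.
    """
    if duration_s <= 0 or fs <= 0:
        raise InvalidArgumentError("duration_s and fs must be positive")
    n_samples = int(round(duration_s * fs))
    if n_samples < 256:
        raise InvalidArgumentError("session must be at least 256 samples long")
    if np.any(spec.directed_lags >= n_samples):
        raise InvalidArgumentError("directed lag must be smaller than signal length")

    n = spec.n_channels
    rng = np.random.default_rng(seed)
    max_lag = int(spec.directed_lags.max()) if n > 1 else 0
    total = n_samples + max_lag

    # per-channel sources: sinusoid with random initial phase + phase diffusion
    t = np.arange(total) / fs
    phase0 = rng.uniform(-np.pi, np.pi, size=n)
    jitter = np.cumsum(
        rng.standard_normal((n, total)) * spec.phase_jitter_sd, axis=-1
    )
    sources = np.sin(
        2 * np.pi * spec.base_freqs[:, None] * t[None, :]
        + phase0[:, None]
        + jitter
    )

    # linear mixing: channel j = own source (down-weighted) + coupled
    # components. An undirected (lag 0) coupling of strength c mixes source i
    # in with weight c, so full coupling means a fully shared phase. A
    # directed (lagged) coupling of strength c uses weight c/2: transfer-
    # entropy detectability of a replaced component peaks at half mixing and
    # collapses at full replacement (the pair simply synchronizes), so
    # mapping strength onto [0, 1/2] keeps planted direction monotonically
    # recoverable over the whole strength range.
    data = np.empty((n, n_samples))
    mix = np.where(spec.directed_lags > 0,
                   spec.pair_strengths / 2.0, spec.pair_strengths)
    incoming = mix.sum(axis=0)
    for j in range(n):
        own = max(0.0, 1.0 - incoming[j])
        sig = own * sources[j, max_lag:]
        for i in range(n):
            w = mix[i, j]
            if i == j or w == 0.0:
                continue
            lag = int(spec.directed_lags[i, j])
            start = max_lag - lag
            sig = sig + w * sources[i, start : start + n_samples]
        data[j] = sig

    if spec.noise_sd > 0:
        if spec.noise_color == "pink":
            noise = _pink_noise(rng, (n, n_samples))
        else:
            noise = rng.standard_normal((n, n_samples))
        data = data + spec.noise_sd * noise

    return EEGRecording(data=data, fs=fs, channel_names=list(spec.channel_names))


def generate_study(
    schedule: StudySchedule,
    class_specs: dict[str, CouplingSpec],
    seed: int,
    drop_first_k: int = 0,
) -> list[SessionEpoch]:
    """Generate a full labeled study in seeded randomized session order.

    Each class's sessions are drawn from its CouplingSpec with distinct
    per-session seeds. drop_first_k removes the first k sessions of each
    class before shuffling (mirrors protocols that discard warm-up
    blocks); the default keeps all sessions.
    """
    missing = [c for c in schedule.classes if c not in class_specs]
    if missing:
        raise InvalidArgumentError(
            f"missing CouplingSpec for classes: {', '.join(missing)}"
        )
    if not 0 <= drop_first_k < schedule.n_sessions_per_class:
        raise InvalidArgumentError("drop_first_k must be in [0, n_sessions_per_class)")

    ss = np.random.SeedSequence(seed)
    order_rng = np.random.default_rng(ss.spawn(1)[0])
    epochs: list[SessionEpoch] = []
    for label in schedule.classes:
        spec = class_specs[label]
        child_seeds = ss.spawn(schedule.n_sessions_per_class)
        for k in range(drop_first_k, schedule.n_sessions_per_class):
            rec = simulate_session(
                spec, schedule.session_duration_s, schedule.fs, child_seeds[k]
            )
            epochs.append(
                SessionEpoch(
                    data=rec.data,
                    fs=rec.fs,
                    label=label,
                    channel_names=rec.channel_names,
                )
            )
    perm = order_rng.permutation(len(epochs))
    return [epochs[i] for i in perm]


def default_class_specs(
    n_channels: int = 16,
    strength: float = 0.9,
    noise_sd: float = 0.5,
    directed_lag: int = 0,
) -> dict[str, CouplingSpec]:
    """Three CouplingSpecs with distinct coupling topologies per workload class.

    Workload classes differ by *which* channel pairs are coupled (disjoint
    pair sets roughly over frontal, central and posterior electrodes), the
    simplest ground truth a connectivity-based classifier should separate.
    With directed_lag > 0 the same pairs become lagged (directed) couplings.
    """
    if n_channels < 12:
        raise InvalidArgumentError("class topologies need at least 12 channels")
    topologies = {
        "low": [(0, 1), (2, 3), (4, 5), (0, 3)],
        "medium": [(6, 7), (8, 9), (6, 9), (7, 8)],
        "high": [(10, 11), (n_channels - 2, n_channels - 1),
                 (10, n_channels - 1), (11, n_channels - 2)],
    }
    specs = {}
    for label, pairs in topologies.items():
        strengths = np.zeros((n_channels, n_channels))
        lags = np.zeros((n_channels, n_channels), dtype=int)
        for i, j in pairs:
            strengths[i, j] = strength
            lags[i, j] = directed_lag
        specs[label] = CouplingSpec(
            n_channels=n_channels,
            pair_strengths=strengths,
            directed_lags=lags,
            noise_sd=noise_sd,
        )
    return specs


# ---------------------------------------------------------------------------
# plain epoch format: one .npz per subject + JSON sidecar with the metadata
# ---------------------------------------------------------------------------

def save_study(path: str | Path, epochs: list[SessionEpoch]) -> None:
    """Write a study as <path>.npz (sessions x channels x samples) + <path>.json."""
    if not epochs:
        raise InvalidArgumentError("cannot save an empty study")
    path = Path(path)
    lengths = {e.n_samples for e in epochs}
    if len(lengths) != 1 or len({e.n_channels for e in epochs}) != 1:
        raise InvalidArgumentError("all epochs must share channel count and length")
    data = np.stack([e.data for e in epochs]).astype(np.float32)
    np.savez_compressed(path.with_suffix(".npz"), data=data)
    meta = {
        "fs": epochs[0].fs,
        "channel_names": epochs[0].channel_names,
        "labels": [e.label for e in epochs],
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_study(path: str | Path) -> list[SessionEpoch]:
    """Read a study saved by :func:`save_study`."""
    path = Path(path)
    npz = path.with_suffix(".npz")
    meta_path = path.with_suffix(".json")
    if not npz.exists() or not meta_path.exists():
        raise FileNotFoundError(f"expected {npz} and {meta_path}")
    data = np.load(npz)["data"].astype(float)
    meta = json.loads(meta_path.read_text())
    return [
        SessionEpoch(
            data=data[i],
            fs=meta["fs"],
            label=meta["labels"][i],
            channel_names=meta["channel_names"],
        )
        for i in range(data.shape[0])
    ]
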