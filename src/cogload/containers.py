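"""Core data containers passed between pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from cogload.errors import InvalidArgumentError

#: Workload class labels in canonical order (1-back, 2-back, 3-back).
CLASS_LABELS = ("low", "medium", "high")


@dataclass
class EEGRecording:
    """Raw or preprocessed multichannel EEG.

    data is channels x samples in microvolts (arbitrary units for
    simulated signals); channel_names is one label per row.
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise InvalidArgumentError("data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise InvalidArgumentError(f"fs must be positive, got {self.fs}")
        if len(self.channel_names) != self.data.shape[0]:
            raise InvalidArgumentError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} signal rows"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class SessionEpoch:
    """One n-back session: a channel x sample segment plus its workload label."""

    data: np.ndarray
    fs: float
    label: str
    channel_names: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise InvalidArgumentError("epoch data must be 2-D (channels x samples)")
        if self.label not in CLASS_LABELS:
            raise InvalidArgumentError(
                f"label must be one of {CLASS_LABELS}, got {self.label!r}"
            )
        if len(self.channel_names) != self.data.shape[0]:
            raise InvalidArgumentError("channel_names length mismatch")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class PhaseSeries:
    """Instantaneous phase and amplitude from the analytic (Hilbert) signal.

    phase is wrapped to (-pi, pi]; amplitude is the non-negative envelope.
    Both are channels x samples.
    """

    phase: np.ndarray
    amplitude: np.ndarray

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.phase.shape != self.amplitude.shape:
            raise InvalidArgumentError("phase and amplitude shapes differ")

    @property
    def n_channels(self) -> int:
        return self.phase.shape[0]

    @property
    def n_samples(self) -> int:
        return self.phase.shape[-1]


@dataclass
class ConnectivityMatrix:
    """A 16x16 functional-connectivity matrix for one session epoch.

    metric is one of {"MI", "PLV", "dPTE"}; directed is True only for dPTE.
    """

    values: np.ndarray
    metric: str
    directed: bool
    channel_names: list[str]
    label: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise InvalidArgumentError("connectivity matrix must be square")
        if self.metric not in ("MI", "PLV", "dPTE"):
            raise InvalidArgumentError(f"unknown metric {self.metric!r}")


@dataclass
class EvalReport:
    """Test-set evaluation: accuracy, per-class P/R/F1 (percent), confusion, ROC AUC."""

    accuracy: float
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    confusion: np.ndarray
    roc_auc: dict[str, float]
    n_test: int
    class_names: tuple[str, ...] = CLASS_LABELS
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.confusion = np.asarray(self.confusion, dtype=int)
        n = int(self.confusion.sum())
        if n != self.n_test:
            raise InvalidArgumentError("confusion entries must sum to n_test")

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "confusion": self.confusion.tolist(),
            "roc_auc": self.roc_auc,
            "n_test": self.n_test,
            "class_names": list(self.class_names),
            **({"extra": self.extra} if self.extra else {}),
        }
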