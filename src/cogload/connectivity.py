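"""Model-free functional connectivity: MI, PLV and PTE/dPTE.

All three metrics are computed per session epoch and assembled into a
16x16 matrix:

* Mutual information (MI) between two channels' raw amplitude series,
  from a joint histogram with uniform-width bins over each series'
  observed range; natural logarithm (nats); empty cells contribute 0.
* Phase locking value (PLV): the modulus of the time-averaged unit
  phasor of the instantaneous phase difference,
  PLV = | mean_t exp(j (phi_x(t) - phi_y(t))) |, in [0, 1].
* Phase transfer entropy (PTE): a directed, phase-specific transfer
  entropy estimated from histograms of current and lagged phases,
  PTE_{x->y} = H(y_t, y_t') + H(y_t', x_t') - H(y_t') - H(y_t, y_t', x_t')
  with past states at lag theta (y_t' = y_{t-theta}); normalized to
  dPTE = PTE_xy / (PTE_xy + PTE_yx), where 0.5 means no preferential
  information flow and dPTE > 0.5 means net flow x -> y.

Instantaneous phase/amplitude come from the analytic signal (Hilbert
transform). The PTE analysis lag and histogram bin count follow the
data-driven rules theta = round(L*CH / Nsc) and
bins = round(exp(0.626 + 0.4 * ln(L - theta - 1))), where L is the
epoch length in samples, CH the channel count and Nsc the number of
sign changes of the wrapped phase across time and channels.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.signal import hilbert

from cogload.containers import ConnectivityMatrix, PhaseSeries, SessionEpoch
from cogload.errors import DegenerateSignalError, InvalidArgumentError

logger = logging.getLogger(__name__)

N_MATRIX_CHANNELS = 16


@dataclass
class PTEParams:
    """Histogram parameters for phase transfer entropy."""

    delay_theta: int
    n_bins: int
    L: int
    CH: int
    n_sign_changes: int

    def __post_init__(self) -> None:
        if self.delay_theta < 1:
            raise InvalidArgumentError("delay_theta must be >= 1")
        if self.n_bins < 2:
            raise InvalidArgumentError("n_bins must be >= 2")
        if self.delay_theta >= self.L:
            raise InvalidArgumentError("delay_theta must be < epoch length")


def analytic_phase(epoch: SessionEpoch | np.ndarray) -> PhaseSeries:
    """Instantaneous phase and amplitude via the Hilbert transform.

    Phase is wrapped to (-pi, pi]; amplitude is the analytic-signal
    modulus. Raises DegenerateSignalError for a constant channel.
    """
    data = epoch.data if isinstance(epoch, SessionEpoch) else np.asarray(epoch, float)
    if data.ndim == 1:
        data = data[None, :]
    if np.any(np.ptp(data, axis=1) == 0):
        raise DegenerateSignalError("constant channel has no instantaneous phase")
    analytic = hilbert(data, axis=1)
    return PhaseSeries(phase=np.angle(analytic), amplitude=np.abs(analytic))


def default_mi_bins(n_samples: int) -> int:
    """Default histogram resolution: ceil(sqrt(N / 5)), at least 2 bins."""
    return max(2, math.ceil(math.sqrt(n_samples / 5)))


def compute_mi(x: np.ndarray, y: np.ndarray, n_bins: int | None = None) -> float:
    """Mutual information (nats) between two series from a joint histogram.

    Uniform-width bins span each series' observed range; empty cells
    contribute zero. Symmetric in its arguments by construction.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise InvalidArgumentError("series lengths differ")
    if n_bins is None:
        n_bins = default_mi_bins(x.size)
    if n_bins < 2:
        raise InvalidArgumentError("n_bins must be >= 2")
    if x.size < n_bins:
        raise InvalidArgumentError("need at least n_bins samples")
    joint, _, _ = np.histogram2d(x, y, bins=n_bins)
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    mask = p > 0
    mi = float(np.sum(p[mask] * np.log(p[mask] / (px @ py)[mask])))
    return max(mi, 0.0)


def compute_plv(phase_x: np.ndarray, phase_y: np.ndarray) -> float:
    """Phase locking value: |mean exp(j(phi_x - phi_y))| in [0, 1]."""
    phase_x = np.asarray(phase_x, dtype=float).ravel()
    phase_y = np.asarray(phase_y, dtype=float).ravel()
    if phase_x.shape != phase_y.shape:
        raise InvalidArgumentError("phase series lengths differ")
    if phase_x.size < 1:
        raise InvalidArgumentError("need at least one sample")
    plv = float(np.abs(np.mean(np.exp(1j * (phase_x - phase_y)))))
    return min(plv, 1.0)


def _wrapped_signs(phase: np.ndarray) -> np.ndarray:
    """Signs of wrapped phases; zeros take the following sample's sign."""
    s = np.sign(phase)
    # backward-fill zeros from the next sample (trailing zeros stay 0:
    # they can never produce a sign change)
    for ch in range(s.shape[0]):
        row = s[ch]
        zeros = np.flatnonzero(row == 0)
        for idx in zeros[::-1]:
            row[idx] = row[idx + 1] if idx + 1 < row.size else 0.0
    return s


def derive_pte_params(phases: PhaseSeries) -> PTEParams:
    """Data-driven PTE analysis lag and histogram bin count.

    theta = round(L*CH / Nsc) (floored at 1); bins =
    round(exp(0.626 + 0.4 ln(L - theta - 1))) (floored at 2); Nsc counts
    consecutive-sample pairs with opposite wrapped-phase signs, summed
    over channels.
    """
    phase = np.atleast_2d(phases.phase)
    CH, L = phase.shape
    if L <= 4:
        raise InvalidArgumentError("epoch too short to derive PTE parameters")
    if CH < 1:
        raise InvalidArgumentError("need at least one channel")
    s = _wrapped_signs(phase.copy())
    n_sc = int(np.sum(s[:, 1:] * s[:, :-1] < 0))
    if n_sc == 0:
        raise DegenerateSignalError("phase never changes sign; cannot set PTE lag")
    theta = max(1, int(round(L * CH / n_sc)))
    if L - theta - 1 < 1:
        raise InvalidArgumentError("derived lag leaves no usable samples")
    n_bins = max(2, int(round(math.exp(0.626 + 0.4 * math.log(L - theta - 1)))))
    return PTEParams(delay_theta=theta, n_bins=n_bins, L=L, CH=CH,
                     n_sign_changes=n_sc)


def _bin_phase(phase: np.ndarray, n_bins: int) -> np.ndarray:
    """Uniform-width binning of wrapped phases over (-pi, pi]."""
    idx = np.floor((phase + np.pi) / (2 * np.pi) * n_bins).astype(np.int64)
    return np.clip(idx, 0, n_bins - 1)


def _entropy_from_codes(codes: np.ndarray) -> float:
    """Entropy (nats) of a discrete sample given integer codes."""
    counts = np.bincount(codes)
    p = counts[counts > 0] / codes.size
    return float(-np.sum(p * np.log(p)))


def compute_pte(
    phase_x: np.ndarray, phase_y: np.ndarray, params: PTEParams
) -> tuple[float, float]:
    """Phase transfer entropy in both directions: (PTE_xy, PTE_yx).

    PTE_xy quantifies information flow x -> y. Entropies are estimated
    from uniform-width histograms of current and theta-lagged phases;
    tiny negative estimates are clamped to 0.
    """
    phase_x = np.asarray(phase_x, dtype=float).ravel()
    phase_y = np.asarray(phase_y, dtype=float).ravel()
    if phase_x.shape != phase_y.shape:
        raise InvalidArgumentError("phase series lengths differ")
    theta, b = params.delay_theta, params.n_bins
    if phase_x.size < theta + 2:
        raise InvalidArgumentError("series shorter than delay_theta + 2")

    bx = _bin_phase(phase_x, b)
    by = _bin_phase(phase_y, b)

    def pte_one_way(src_past, tgt_now, tgt_past):
        # H(y_t, y_t') + H(y_t', x_t') - H(y_t') - H(y_t, y_t', x_t')
        h_tt = _entropy_from_codes(tgt_now * b + tgt_past)
        h_tp_sp = _entropy_from_codes(tgt_past * b + src_past)
        h_tp = _entropy_from_codes(tgt_past)
        h_triplet = _entropy_from_codes((tgt_now * b + tgt_past) * b + src_past)
        return max(0.0, h_tt + h_tp_sp - h_tp - h_triplet)

    x_now, x_past = bx[theta:], bx[:-theta]
    y_now, y_past = by[theta:], by[:-theta]
    pte_xy = pte_one_way(x_past, y_now, y_past)
    pte_yx = pte_one_way(y_past, x_now, x_past)
    return pte_xy, pte_yx


def normalize_dpte(pte_xy: float, pte_yx: float) -> float:
    """Directionality index dPTE = PTE_xy / (PTE_xy + PTE_yx) in [0, 1].

    0.5 means no preferential flow; > 0.5 means net flow x -> y. If both
    inputs are zero the pair carries no directional evidence and 0.5 is
    returned with a warning.
    """
    if pte_xy < 0 or pte_yx < 0:
        raise InvalidArgumentError("PTE values must be non-negative")
    total = pte_xy + pte_yx
    if total == 0:
        logger.warning("both PTE values are zero; returning dPTE = 0.5")
        return 0.5
    return pte_xy / total


def connectivity_matrix(
    epoch: SessionEpoch,
    metric: str,
    mi_bins: int | None = None,
    pte_params: PTEParams | None = None,
) -> ConnectivityMatrix:
    """Assemble the 16x16 connectivity matrix for one session epoch.

    MI is computed on the raw (cleaned) signal; PLV and dPTE on the
    instantaneous phase. Diagonal convention: 0 for MI and dPTE, 1 for
    PLV. For dPTE the analysis lag/bins default to the data-driven rule
    on this epoch's phases.
    """
    metric = {"mi": "MI", "plv": "PLV", "dpte": "dPTE"}.get(metric.lower())
    if metric is None:
        raise InvalidArgumentError("metric must be one of MI, PLV, dPTE")
    n = epoch.n_channels
    if n != N_MATRIX_CHANNELS:
        raise InvalidArgumentError(
            f"expected {N_MATRIX_CHANNELS} channels, got {n}"
        )

    values = np.zeros((n, n))
    if metric == "MI":
        bins = mi_bins if mi_bins is not None else default_mi_bins(epoch.n_samples)
        for i in range(n):
            for j in range(i + 1, n):
                mi = compute_mi(epoch.data[i], epoch.data[j], bins)
                values[i, j] = values[j, i] = mi
    else:
        phases = analytic_phase(epoch)
        if metric == "PLV":
            np.fill_diagonal(values, 1.0)
            for i in range(n):
                for j in range(i + 1, n):
                    plv = compute_plv(phases.phase[i], phases.phase[j])
                    values[i, j] = values[j, i] = plv
        else:  # dPTE
            params = pte_params if pte_params is not None else derive_pte_params(phases)
            for i in range(n):
                for j in range(i + 1, n):
                    pte_ij, pte_ji = compute_pte(phases.phase[i], phases.phase[j],
                                                 params)
                    d = normalize_dpte(pte_ij, pte_ji)
                    values[i, j] = d
                    values[j, i] = 1.0 - d

    return ConnectivityMatrix(
        values=values,
        metric=metric,
        directed=(metric == "dPTE"),
        channel_names=list(epoch.channel_names),
        label=epoch.label,
    )


# ---------------------------------------------------------------------------
# batch container: one subject's per-session matrices + JSON sidecar
# ---------------------------------------------------------------------------

def save_matrices(path: str | Path, matrices: list[ConnectivityMatrix]) -> None:
    """Write a subject's matrices as <path>.npz + <path>.json sidecar."""
    if not matrices:
        raise InvalidArgumentError("cannot save an empty matrix batch")
    metrics = {m.metric for m in matrices}
    if len(metrics) != 1:
        raise InvalidArgumentError("a batch must hold a single metric")
    path = Path(path)
    values = np.stack([m.values for m in matrices])
    np.savez_compressed(path.with_suffix(".npz"), values=values)
    meta = {
        "metric": matrices[0].metric,
        "directed": matrices[0].directed,
        "channel_names": matrices[0].channel_names,
        "labels": [m.label for m in matrices],
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_matrices(path: str | Path) -> list[ConnectivityMatrix]:
    """Read a matrix batch written by :func:`save_matrices`."""
    path = Path(path)
    npz, meta_path = path.with_suffix(".npz"), path.with_suffix(".json")
    if not npz.exists() or not meta_path.exists():
        raise FileNotFoundError(f"expected {npz} and {meta_path}")
    values = np.load(npz)["values"]
    meta = json.loads(meta_path.read_text())
    return [
        ConnectivityMatrix(
            values=values[i],
            metric=meta["metric"],
            directed=meta["directed"],
            channel_names=meta["channel_names"],
            label=meta["labels"][i],
        )
        for i in range(values.shape[0])
    ]
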