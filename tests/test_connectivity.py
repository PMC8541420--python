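"""Connectivity metrics vs closed forms and brute-force oracles."""

import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr

from cogload.connectivity import (
    PTEParams,
    analytic_phase,
    compute_mi,
    compute_plv,
    compute_pte,
    connectivity_matrix,
    derive_pte_params,
    load_matrices,
    normalize_dpte,
    save_matrices,
)
from cogload.containers import SessionEpoch
from cogload.errors import DegenerateSignalError, InvalidArgumentError
from cogload.preprocess import CANONICAL_CHANNELS
from cogload.synthetic import CouplingSpec, simulate_session

from conftest import directed_pair_spec


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def hilbert_oracle(x):
    """Frequency-domain analytic signal, coded independently: zero the
    negative frequencies, double the positive ones, keep DC/Nyquist."""
    n = len(x)
    spectrum = np.fft.fft(x)
    gain = np.zeros(n)
    gain[0] = 1.0
    if n % 2 == 0:
        gain[n // 2] = 1.0
        gain[1 : n // 2] = 2.0
    else:
        gain[1 : (n + 1) // 2] = 2.0
    return np.fft.ifft(spectrum * gain)


def mi_oracle(x_codes, y_codes):
    """MI in nats by explicit enumeration of the joint distribution."""
    n = len(x_codes)
    joint = Counter(zip(x_codes, y_codes))
    px = Counter(x_codes)
    py = Counter(y_codes)
    mi = 0.0
    for (a, b), c in joint.items():
        p_ab = c / n
        mi += p_ab * math.log(p_ab / ((px[a] / n) * (py[b] / n)))
    return mi


def entropy_oracle(*code_seqs):
    """Joint entropy (nats) of tuples, by explicit counting."""
    n = len(code_seqs[0])
    counts = Counter(zip(*code_seqs))
    return -sum((c / n) * math.log(c / n) for c in counts.values())


def pte_oracle(x_codes, y_codes, theta):
    """PTE x->y from enumerated entropies of binned phase codes."""
    y_now, y_past, x_past = y_codes[theta:], y_codes[:-theta], x_codes[:-theta]
    return (
        entropy_oracle(y_now, y_past)
        + entropy_oracle(y_past, x_past)
        - entropy_oracle(y_past)
        - entropy_oracle(y_now, y_past, x_past)
    )


def bin_centers(codes, n_bins):
    """Phase values at bin centers, so binning recovers the codes exactly."""
    codes = np.asarray(codes)
    return -np.pi + (codes + 0.5) * 2 * np.pi / n_bins


# ---------------------------------------------------------------------------
# analytic phase
# ---------------------------------------------------------------------------

class TestAnalyticPhase:
    def test_cosine_phase_slope(self):
        fs, f = 256.0, 10.0
        t = np.arange(1024) / fs
        ph = analytic_phase(np.cos(2 * np.pi * f * t))
        unwrapped = np.unwrap(ph.phase[0])[100:-100]
        slope = np.polyfit(np.arange(unwrapped.size), unwrapped, 1)[0]
        assert slope == pytest.approx(2 * np.pi * f / fs, abs=1e-3)

    def test_unit_cosine_amplitude(self):
        t = np.arange(1024) / 256.0
        ph = analytic_phase(np.cos(2 * np.pi * 10 * t))
        assert np.allclose(ph.amplitude[0][100:-100], 1.0, atol=0.01)

    def test_matches_independent_hilbert_oracle(self, rng):
        t = np.arange(512) / 256.0
        x = (np.sin(2 * np.pi * 7 * t) + 0.5 * np.sin(2 * np.pi * 19 * t + 1.1)
             + 0.1 * rng.standard_normal(512))
        ph = analytic_phase(x)
        oracle = hilbert_oracle(x)
        np.testing.assert_allclose(ph.phase[0], np.angle(oracle), atol=1e-9)
        np.testing.assert_allclose(ph.amplitude[0], np.abs(oracle), atol=1e-9)

    def test_phase_wrapped_range(self, rng):
        ph = analytic_phase(rng.standard_normal((3, 512)))
        assert np.all(ph.phase > -np.pi) and np.all(ph.phase <= np.pi)
        assert np.all(ph.amplitude >= 0)

    def test_constant_channel_rejected(self):
        with pytest.raises(DegenerateSignalError):
            analytic_phase(np.ones((1, 100)))


# ---------------------------------------------------------------------------
# mutual information
# ---------------------------------------------------------------------------

class TestMutualInformation:
    def test_perfect_two_bin_dependence_is_ln2(self):
        # joint counts [[5,0],[0,5]]: uniform marginals, perfect coupling
        x = np.array([0.0] * 5 + [1.0] * 5)
        assert compute_mi(x, x, n_bins=2) == pytest.approx(math.log(2), abs=1e-12)

    def test_identity_equals_marginal_entropy(self, rng):
        x = rng.normal(size=200)
        bins = 4
        codes = np.clip(
            np.floor((x - x.min()) / (x.max() - x.min()) * bins), 0, bins - 1
        ).astype(int)
        h_x = entropy_oracle(codes)
        assert compute_mi(x, x, n_bins=bins) == pytest.approx(h_x, abs=1e-12)

    def test_independent_series_small_bias(self):
        # bias bound frozen after a 50-seed pilot on N=10000, 16 bins
        vals = []
        for seed in range(50):
            r = np.random.default_rng(seed)
            vals.append(compute_mi(r.random(10000), r.random(10000), n_bins=16))
        assert max(vals) < 0.03

    def test_matches_enumeration_oracle(self, rng):
        # length <= 20, <= 4 bins, exact agreement with brute-force counting
        for _ in range(20):
            n = rng.integers(8, 21)
            bins = rng.integers(2, 5)
            x_codes = rng.integers(0, bins, n)
            y_codes = rng.integers(0, bins, n)
            # values at bin centres of a unit range so binning is exact
            x = (x_codes + 0.5) / bins
            y = (y_codes + 0.5) / bins
            x[0], x[-1] = 0.0, 1.0  # pin the observed range
            y[0], y[-1] = 0.0, 1.0
            x_codes[0], x_codes[-1] = 0, bins - 1
            y_codes[0], y_codes[-1] = 0, bins - 1
            expected = mi_oracle(tuple(x_codes), tuple(y_codes))
            assert compute_mi(x, y, n_bins=int(bins)) == pytest.approx(
                expected, abs=1e-12
            )

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidArgumentError):
            compute_mi(np.arange(10), np.arange(9), n_bins=2)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_symmetric_and_nonnegative(self, seed):
        r = np.random.default_rng(seed)
        x, y = r.normal(size=64), r.normal(size=64)
        mi_xy = compute_mi(x, y, n_bins=4)
        mi_yx = compute_mi(y, x, n_bins=4)
        assert mi_xy >= 0
        assert mi_xy == pytest.approx(mi_yx, abs=1e-12)


# ---------------------------------------------------------------------------
# phase locking value
# ---------------------------------------------------------------------------

class TestPLV:
    def test_constant_phase_difference_is_one(self, rng):
        base = rng.uniform(-np.pi, np.pi, 256)
        for delta in (0.0, 1.234, -2.5):
            x = base
            y = np.angle(np.exp(1j * (base - delta)))
            assert compute_plv(x, y) == pytest.approx(1.0, abs=1e-12)

    def test_antiphase_alternation_cancels(self):
        x = np.zeros(100)
        y = np.tile([0.0, np.pi], 50)
        assert compute_plv(x, y) == pytest.approx(0.0, abs=1e-12)

    def test_two_sample_quarter_turn(self):
        # phasors 1 and e^{j pi/2}: |(1+j)/2| = sqrt(2)/2
        x = np.array([0.0, 0.0])
        y = np.array([0.0, -np.pi / 2])
        assert compute_plv(x, y) == pytest.approx(np.sqrt(2) / 2, abs=1e-12)

    @given(st.integers(0, 2**31 - 1), st.floats(-3.0, 3.0))
    @settings(max_examples=25, deadline=None)
    def test_range_and_common_shift_invariance(self, seed, shift):
        r = np.random.default_rng(seed)
        x, y = r.uniform(-np.pi, np.pi, 128), r.uniform(-np.pi, np.pi, 128)
        plv = compute_plv(x, y)
        assert 0.0 <= plv <= 1.0
        assert compute_plv(x + shift, y + shift) == pytest.approx(plv, abs=1e-9)


# ---------------------------------------------------------------------------
# phase transfer entropy
# ---------------------------------------------------------------------------

class TestPTEParams:
    def test_unit_ratio_gives_theta_one(self):
        # L=512, CH=16, Nsc=8192 -> theta = round(8192/8192) = 1: phases that
        # change sign every sample give exactly one change per sample pair
        phase = np.tile([0.5, -0.5], (16, 256))
        params = derive_pte_params(_phases(phase))
        assert params.n_sign_changes == 16 * 511
        assert params.delay_theta == 1

    def test_bin_formula_at_theta_11(self):
        # round(exp(0.626 + 0.4 ln(512 - 11 - 1))) = round(22.46) = 22
        expected = round(math.exp(0.626 + 0.4 * math.log(500)))
        assert expected == 22
        params = PTEParams(delay_theta=11, n_bins=expected, L=512, CH=2,
                           n_sign_changes=100)
        assert params.n_bins == 22

    def test_constant_phase_rejected(self):
        with pytest.raises(DegenerateSignalError):
            derive_pte_params(_phases(np.full((2, 64), 0.3)))


def _phases(phase):
    from cogload.containers import PhaseSeries

    return PhaseSeries(phase=phase, amplitude=np.ones_like(phase))


class TestPTE:
    def test_matches_enumeration_oracle(self, rng):
        # toy sequences: length <= 20, <= 4 bins, theta = 1
        for _ in range(20):
            n = int(rng.integers(10, 21))
            bins = int(rng.integers(2, 5))
            x_codes = rng.integers(0, bins, n)
            y_codes = rng.integers(0, bins, n)
            params = PTEParams(delay_theta=1, n_bins=bins, L=n, CH=2,
                               n_sign_changes=1)
            pte_xy, pte_yx = compute_pte(
                bin_centers(x_codes, bins), bin_centers(y_codes, bins), params
            )
            assert pte_xy == pytest.approx(
                pte_oracle(tuple(x_codes), tuple(y_codes), 1), abs=1e-12
            )
            assert pte_yx == pytest.approx(
                pte_oracle(tuple(y_codes), tuple(x_codes), 1), abs=1e-12
            )

    def test_directed_coupling_detected(self):
        # planted 0 -> 1 coupling: dPTE in the true direction exceeds 0.5
        # in at least 95% of seeded runs (pilot: 100% over 60 seeds)
        spec = directed_pair_spec(0.9, lag=5)
        hits = 0
        n_runs = 50
        for seed in range(n_runs):
            rec = simulate_session(spec, 18.0, 256.0, seed=seed)
            ph = analytic_phase(rec.data)
            params = derive_pte_params(ph)
            pte_xy, pte_yx = compute_pte(ph.phase[0], ph.phase[1], params)
            hits += normalize_dpte(pte_xy, pte_yx) > 0.5
        assert hits >= 0.95 * n_runs

    def test_direction_monotone_in_strength(self):
        strengths = [0.2, 0.4, 0.6, 0.8, 1.0]
        means = []
        for c in strengths:
            spec = directed_pair_spec(c, lag=5)
            vals = []
            for seed in range(25):
                rec = simulate_session(spec, 18.0, 256.0, seed=seed)
                ph = analytic_phase(rec.data)
                params = derive_pte_params(ph)
                vals.append(normalize_dpte(*compute_pte(ph.phase[0], ph.phase[1],
                                                        params)))
            means.append(np.mean(vals))
        rho = spearmanr(strengths, means).statistic
        assert rho > 0.9

    def test_independent_phases_near_half(self):
        # Monte-Carlo null: band frozen after a 60-seed pilot ([0.494, 0.506])
        vals = []
        for seed in range(50):
            r = np.random.default_rng(seed)
            x = r.uniform(-np.pi, np.pi, 5000)
            y = r.uniform(-np.pi, np.pi, 5000)
            params = PTEParams(delay_theta=3, n_bins=16, L=5000, CH=2,
                               n_sign_changes=1)
            pte_xy, pte_yx = compute_pte(x, y, params)
            assert abs(pte_xy - pte_yx) < 0.05
            vals.append(normalize_dpte(pte_xy, pte_yx))
        assert all(abs(v - 0.5) < 0.05 for v in vals)

    def test_short_series_rejected(self):
        params = PTEParams(delay_theta=5, n_bins=3, L=100, CH=2, n_sign_changes=1)
        with pytest.raises(InvalidArgumentError):
            compute_pte(np.zeros(6), np.zeros(6), params)


class TestNormalizeDPTE:
    @pytest.mark.parametrize(
        "pte_xy,pte_yx,expected",
        [(0.7, 0.7, 0.5), (3.0, 1.0, 0.75), (0.0, 5.0, 0.0), (5.0, 0.0, 1.0)],
    )
    def test_closed_forms(self, pte_xy, pte_yx, expected):
        assert normalize_dpte(pte_xy, pte_yx) == pytest.approx(expected, abs=1e-12)

    def test_double_zero_returns_half_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            assert normalize_dpte(0.0, 0.0) == 0.5
        assert any("0.5" in r.message for r in caplog.records)


# ---------------------------------------------------------------------------
# matrix assembly
# ---------------------------------------------------------------------------

def _noise_epoch(seed, n_samples=2560):
    r = np.random.default_rng(seed)
    return SessionEpoch(
        data=r.standard_normal((16, n_samples)),
        fs=256.0,
        label="low",
        channel_names=list(CANONICAL_CHANNELS),
    )


class TestConnectivityMatrix:
    def test_plv_matrix_conventions(self):
        mat = connectivity_matrix(_noise_epoch(0), "PLV")
        assert mat.values.shape == (16, 16)
        assert np.allclose(np.diag(mat.values), 1.0)
        assert np.allclose(mat.values, mat.values.T, atol=1e-9)
        assert not mat.directed

    def test_mi_matrix_conventions(self):
        mat = connectivity_matrix(_noise_epoch(1), "MI")
        assert np.allclose(np.diag(mat.values), 0.0)
        assert np.allclose(mat.values, mat.values.T, atol=1e-9)
        assert np.all(mat.values >= 0)

    def test_dpte_complementarity(self):
        mat = connectivity_matrix(_noise_epoch(2), "dPTE")
        off = ~np.eye(16, dtype=bool)
        assert np.allclose((mat.values + mat.values.T)[off], 1.0, atol=1e-9)
        assert np.allclose(np.diag(mat.values), 0.0)
        assert mat.directed

    def test_dpte_null_near_half(self):
        # 20-seed Monte-Carlo null on independent channels
        for seed in range(20):
            mat = connectivity_matrix(_noise_epoch(100 + seed), "dPTE")
            off = mat.values[~np.eye(16, dtype=bool)]
            assert np.all(np.abs(off - 0.5) < 0.1)

    def test_wrong_channel_count_rejected(self, rng):
        epoch = SessionEpoch(
            data=rng.standard_normal((4, 512)), fs=256.0, label="low",
            channel_names=["a", "b", "c", "d"],
        )
        with pytest.raises(InvalidArgumentError):
            connectivity_matrix(epoch, "MI")

    def test_batch_roundtrip(self, tmp_path):
        mats = [connectivity_matrix(_noise_epoch(s, 512), "PLV") for s in range(3)]
        save_matrices(tmp_path / "batch", mats)
        loaded = load_matrices(tmp_path / "batch")
        assert len(loaded) == 3
        for a, b in zip(mats, loaded):
            np.testing.assert_allclose(a.values, b.values)
            assert b.metric == "PLV" and b.label == "low"
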