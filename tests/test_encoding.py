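"""Baseline reconstruction, spike sets, desired potentials, normalisation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mrisnn as m
from mrisnn import encoding
from mrisnn.errors import DegenerateStateError, ValidationError


def baseline_oracle(s, alpha):
    """Independent scalar transcription of the baseline recursion."""
    s = list(s)
    mth = min(range(len(s)), key=lambda i: s[i])
    b = [None] * len(s)
    for i in range(mth + 1):
        b[i] = s[i]
    for i in range(mth, len(s) - 1):
        if s[i + 1] > b[i]:
            b[i + 1] = alpha * s[i + 1] + (1 - alpha) * b[i]
        else:
            b[i + 1] = s[i + 1]
    return np.array(b)


def desired_oracle(s, spike_idx, sigma, ts):
    rho, t_s, started = 0.0, None, False
    out = np.zeros(len(s))
    for i in range(len(s)):
        if i in spike_idx:
            rho, t_s, started = s[i], i * ts, True
        if started:
            out[i] = rho * np.exp(-(i * ts - t_s) / sigma)
    return out


class TestBaseline:
    def test_hand_stepped_example(self):
        sig = m.ContinuousSignal(np.array([3.0, 1.0, 2.0, 4.0]), 8.0)
        b = m.baseline_reconstruct(sig, m.BaselineParams(0.5))
        np.testing.assert_allclose(b.values[:, 0], [3.0, 1.0, 1.5, 2.75])

    def test_monotone_decreasing_tracks_signal(self):
        s = np.linspace(5.0, 1.0, 20)
        b = m.baseline_reconstruct(m.ContinuousSignal(s, 8.0))
        np.testing.assert_allclose(b.values[:, 0], s)

    def test_constant_signal_tracks_equality_branch(self):
        s = np.full(15, 2.5)
        b = m.baseline_reconstruct(m.ContinuousSignal(s, 8.0))
        np.testing.assert_allclose(b.values[:, 0], s)

    @given(st.integers(min_value=0, max_value=2 ** 31 - 1),
           st.floats(min_value=0.0, max_value=1.0))
    @settings(max_examples=50, deadline=None)
    def test_matches_scalar_oracle(self, seed, alpha):
        rng = np.random.default_rng(seed)
        s = rng.normal(size=40)
        b = m.baseline_reconstruct(m.ContinuousSignal(s, 8.0),
                                   m.BaselineParams(alpha))
        np.testing.assert_allclose(b.values[:, 0], baseline_oracle(s, alpha),
                                   rtol=1e-12, atol=1e-12)


class TestSpikeSet:
    def test_equal_signal_and_baseline_gives_empty(self):
        s = np.full(10, 1.0)
        sig = m.ContinuousSignal(s, 8.0)
        spikes = m.spike_set_from_signal(sig, sig)
        assert spikes.spike_times["ch0"].size == 0

    def test_signal_above_baseline_everywhere(self):
        sig = m.ContinuousSignal(np.arange(10.0), 8.0)
        base = m.ContinuousSignal(np.arange(10.0) - 1.0, 8.0)
        spikes = m.spike_set_from_signal(sig, base)
        np.testing.assert_allclose(spikes.spike_times["ch0"],
                                   np.arange(10) * 8.0)

    def test_matches_bruteforce_scan(self):
        rng = np.random.default_rng(11)
        s = rng.normal(size=60)
        sig = m.ContinuousSignal(s, 8.0)
        b = m.baseline_reconstruct(sig, m.BaselineParams(0.3))
        spikes = m.spike_set_from_signal(sig, b)
        expect = [i * 8.0 for i in range(60) if s[i] > b.values[i, 0]]
        np.testing.assert_allclose(spikes.spike_times["ch0"], expect)

    def test_pipeline_is_idempotent_for_fixed_alpha(self):
        rng = np.random.default_rng(4)
        sig = m.ContinuousSignal(rng.normal(size=50), 8.0)
        p = m.BaselineParams(0.4)
        x1 = m.spike_set_from_signal(sig, m.baseline_reconstruct(sig, p))
        x2 = m.spike_set_from_signal(sig, m.baseline_reconstruct(sig, p))
        np.testing.assert_array_equal(x1.spike_times["ch0"],
                                      x2.spike_times["ch0"])


class TestDesiredPotential:
    def test_value_at_spike_equals_eeg(self):
        s = np.array([0.5, -0.2, 0.8, 0.1])
        sig = m.ContinuousSignal(s, 8.0)
        spikes = m.SpikeTrain({"ch0": np.array([0.0, 16.0])})
        vd = m.desired_potential(sig, spikes, sigma_ms=8.0)
        assert vd.values[0, 0] == pytest.approx(0.5)
        assert vd.values[2, 0] == pytest.approx(0.8)

    def test_single_spike_exponential_decay(self):
        sig = m.ContinuousSignal(np.array([1.0, 0.0, 0.0]), 8.0)
        spikes = m.SpikeTrain({"ch0": np.array([0.0])})
        vd = m.desired_potential(sig, spikes, sigma_ms=8.0)
        assert vd.values[1, 0] == pytest.approx(np.exp(-1.0))
        assert vd.values[2, 0] == pytest.approx(np.exp(-2.0))

    def test_zero_before_first_spike(self):
        sig = m.ContinuousSignal(np.ones(6), 8.0)
        spikes = m.SpikeTrain({"ch0": np.array([24.0])})
        vd = m.desired_potential(sig, spikes, sigma_ms=8.0)
        np.testing.assert_array_equal(vd.values[:3, 0], 0.0)
        assert vd.first_spike_index[0] == 3

    def test_exact_decay_ratio_between_spikes(self):
        rng = np.random.default_rng(2)
        sig = m.ContinuousSignal(rng.uniform(0.5, 1.0, size=30), 8.0)
        spikes = m.SpikeTrain({"ch0": np.array([0.0])})
        sigma = 20.0
        vd = m.desired_potential(sig, spikes, sigma_ms=sigma)
        ratios = vd.values[1:, 0] / vd.values[:-1, 0]
        np.testing.assert_allclose(ratios, np.exp(-8.0 / sigma), rtol=1e-12)

    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_matches_scalar_oracle(self, seed):
        rng = np.random.default_rng(seed)
        s = rng.normal(size=40)
        sig = m.ContinuousSignal(s, 8.0)
        idx = np.sort(rng.choice(40, size=rng.integers(0, 10), replace=False))
        spikes = m.SpikeTrain({"ch0": idx * 8.0})
        vd = m.desired_potential(sig, spikes, sigma_ms=16.0)
        np.testing.assert_allclose(vd.values[:, 0],
                                   desired_oracle(s, set(idx), 16.0, 8.0),
                                   rtol=1e-12, atol=1e-12)

    def test_from_spike_trains_unit_amplitude(self):
        spikes = m.SpikeTrain({"a": np.array([0.0, 40.0])})
        vd = encoding.desired_potential_from_spikes(spikes, ["a"], 10, 8.0,
                                                    sigma_ms=8.0)
        assert vd.values[0, 0] == pytest.approx(1.0)
        assert vd.values[5, 0] == pytest.approx(1.0)
        assert vd.values[1, 0] == pytest.approx(np.exp(-1.0))


class TestNormalizeObserved:
    def test_three_four_five(self):
        np.testing.assert_allclose(m.normalize_observed([3.0, 4.0]),
                                   [0.6, 0.8])

    def test_unit_norm_and_scale_invariance(self):
        rng = np.random.default_rng(8)
        v = rng.normal(size=12)
        out = m.normalize_observed(v)
        assert np.linalg.norm(out) == pytest.approx(1.0)
        for k in (1e-3, 7.0, 2e4):
            np.testing.assert_allclose(m.normalize_observed(k * v), out,
                                       rtol=1e-12)

    def test_zero_vector_raises(self):
        with pytest.raises(DegenerateStateError):
            m.normalize_observed(np.zeros(5))


class TestSignalValidation:
    def test_spike_train_must_increase(self):
        with pytest.raises(ValidationError):
            m.SpikeTrain({"a": np.array([3.0, 2.0])})

    def test_alpha_range_enforced(self):
        with pytest.raises(ValidationError):
            m.BaselineParams(1.5)

    def test_nonfinite_signal_rejected(self):
        with pytest.raises(ValidationError):
            m.ContinuousSignal(np.array([1.0, np.nan]), 8.0)
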