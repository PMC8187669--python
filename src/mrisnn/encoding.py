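"""Conversions between continuous signals and spike sets.

The reservoir is supervised by a *desired potential* built from the EEG.
Each channel is scanned against an adaptive baseline B(t): starting from the
global minimum, B follows the signal exactly when the signal does not exceed
it and otherwise relaxes upward with smoothing factor alpha.  Sample times
where the signal strictly exceeds its baseline form the spike set X.  The
desired potential holds the EEG amplitude sampled at the latest spike time
and decays exponentially with constant sigma between spikes; before the
first spike it is zero (there is no target yet).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ContractError, DegenerateStateError, ValidationError


@dataclass
class ContinuousSignal:
    """A samples x channels numeric matrix with a sample period (ms)."""

    values: np.ndarray
    ts_ms: float = 8.0
    channel_names: list = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if self.ts_ms <= 0:
            raise ValidationError("sample period must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("signal contains non-finite values")
        if self.channel_names is None:
            self.channel_names = [f"ch{k}" for k in range(self.values.shape[1])]
        self.channel_names = list(self.channel_names)
        if len(self.channel_names) != self.values.shape[1]:
            raise ContractError("channel name count does not match columns")

    @property
    def n_samples(self):
        return self.values.shape[0]

    @property
    def n_channels(self):
        return self.values.shape[1]

    @property
    def times_ms(self):
        return np.arange(self.n_samples) * self.ts_ms

    @property
    def sample_rate_hz(self):
        return 1000.0 / self.ts_ms


@dataclass
class SpikeTrain:
    """Per-channel strictly increasing spike times (ms)."""

    spike_times: dict  # channel name -> 1d float array

    def __post_init__(self):
        clean = {}
        for name, t in self.spike_times.items():
            t = np.asarray(t, dtype=float)
            if t.size and (np.any(np.diff(t) <= 0) or np.any(t < 0)):
                raise ValidationError(
                    f"spike times of {name} must be non-negative, strictly increasing"
                )
            clean[name] = t
        self.spike_times = clean

    @property
    def channel_names(self):
        return list(self.spike_times.keys())


@dataclass
class BaselineParams:
    alpha: float = 0.5

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValidationError("alpha must lie in [0, 1]")


@dataclass
class DesiredPotential:
    """Target traces for the observed neurons plus bookkeeping.

    ``first_spike_index`` marks, per channel, the first sample with a
    defined target; errors are masked to zero before it.
    """

    values: np.ndarray  # samples x channels
    sigma_ms: float
    first_spike_index: np.ndarray = field(default=None)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.sigma_ms <= 0:
            raise ValidationError("sigma must be positive")
        if self.first_spike_index is None:
            self.first_spike_index = np.zeros(self.values.shape[1], dtype=int)


def _baseline_1d(s, alpha):
    s = np.asarray(s, dtype=float)
    b = np.empty_like(s)
    m = int(np.argmin(s))
    b[: m + 1] = s[: m + 1]  # before the global minimum B simply tracks S
    for i in range(m, s.size - 1):
        if s[i + 1] > b[i]:
            b[i + 1] = alpha * s[i + 1] + (1.0 - alpha) * b[i]
        else:  # includes equality: B keeps tracking S
            b[i + 1] = s[i + 1]
    return b


def baseline_reconstruct(signal, params=None):
    """Adaptive baseline B(t) per channel (same shape as the signal)."""
    if params is None:
        params = BaselineParams()
    if signal.n_samples < 1:
        raise ValidationError("signal is empty")
    b = np.column_stack(
        [_baseline_1d(signal.values[:, k], params.alpha)
         for k in range(signal.n_channels)]
    )
    return ContinuousSignal(b, signal.ts_ms, list(signal.channel_names))


def spike_set_from_signal(signal, baseline):
    """X = sample times where the signal strictly exceeds its baseline."""
    if signal.values.shape != baseline.values.shape:
        raise ContractError("signal and baseline are not aligned")
    t = signal.times_ms
    trains = {}
    for k, name in enumerate(signal.channel_names):
        exceed = signal.values[:, k] > baseline.values[:, k]
        trains[name] = t[exceed]
    return SpikeTrain(trains)


def desired_potential(v_eeg, spikes, sigma_ms=None):
    """Exponentially decaying hold of the EEG amplitude at spike times.

    rho(t_i) = V_EEG(t_i) when t_i is a spike time, held otherwise;
    V_d(t_i) = rho(t_i) exp(-(t_i - t_s)/sigma) with t_s the latest spike
    at or before t_i, and 0 before the first spike.  Default sigma is the
    sample period.
    """
    if sigma_ms is None:
        sigma_ms = v_eeg.ts_ms
    if sigma_ms <= 0:
        raise ValidationError("sigma must be positive")
    t = v_eeg.times_ms
    n_t, n_ch = v_eeg.values.shape
    out = np.zeros((n_t, n_ch))
    first_idx = np.full(n_ch, n_t, dtype=int)
    for k, name in enumerate(v_eeg.channel_names):
        st = np.asarray(spikes.spike_times.get(name, ()), dtype=float)
        spike_mask = np.isin(t, st)
        rho = 0.0
        t_s = -np.inf
        started = False
        for i in range(n_t):
            if spike_mask[i]:
                rho = v_eeg.values[i, k]
                t_s = t[i]
                if not started:
                    first_idx[k] = i
                    started = True
            if started:
                out[i, k] = rho * np.exp(-(t[i] - t_s) / sigma_ms)
    return DesiredPotential(out, sigma_ms, first_idx)


def desired_potential_from_spikes(spikes, channel_order, n_samples, ts_ms,
                                  sigma_ms=None, amplitude=1.0):
    """Desired potential for the spike-input realisation.

    With only spike trains available there is no amplitude to sample, so the
    held value is a constant ``amplitude``.  Spike times are snapped to the
    sample grid.
    """
    if sigma_ms is None:
        sigma_ms = ts_ms
    t = np.arange(n_samples) * ts_ms
    out = np.zeros((n_samples, len(channel_order)))
    first_idx = np.full(len(channel_order), n_samples, dtype=int)
    for k, name in enumerate(channel_order):
        st = np.asarray(spikes.spike_times.get(name, ()), dtype=float)
        idx = np.unique(np.clip(np.round(st / ts_ms).astype(int), 0, n_samples - 1)) \
            if st.size else np.array([], dtype=int)
        t_s = -np.inf
        started = False
        ptr = 0
        for i in range(n_samples):
            if ptr < idx.size and idx[ptr] == i:
                t_s = t[i]
                ptr += 1
                if not started:
                    first_idx[k] = i
                    started = True
            if started:
                out[i, k] = amplitude * np.exp(-(t[i] - t_s) / sigma_ms)
    return DesiredPotential(out, sigma_ms, first_idx)


def normalize_observed(v_ob):
    """v / ||v||_2; raises on a zero vector."""
    v_ob = np.asarray(v_ob, dtype=float)
    norm = float(np.linalg.norm(v_ob))
    if norm == 0.0 or not np.isfinite(norm):
        raise DegenerateStateError("observed potential vector has zero norm")
    return v_ob / norm
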