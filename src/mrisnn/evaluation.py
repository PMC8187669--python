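"""Output filtering and error metrics.

Model outputs and reference signals are compared only after passing through
the *same* linear-phase FIR lowpass (0-70 Hz requested, 80 dB stopband),
applied forward-backward so the operands stay time-aligned.  When the
requested passband is infeasible at the data's sampling rate the edges are
clamped below Nyquist with a warning.  Errors follow the normalised
one-step-ahead definition: MSE is the time average of E'E.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

from .encoding import ContinuousSignal
from .errors import ContractError, FilterDesignError, ValidationError

CLAMP_FRACTION = 0.88  # of Nyquist, when requested edges are infeasible


@dataclass
class FilterSpec:
    """Linear-phase FIR lowpass specification."""

    kind: str = "equiripple"          # equiripple | kaiser
    passband_hz: float = 70.0
    stopband_edge_hz: float = None    # default: passband + 8% of Nyquist
    attenuation_db: float = 80.0
    sample_rate_hz: float = 125.0
    passband_ripple_db: float = 0.01

    def __post_init__(self):
        if self.kind not in ("equiripple", "kaiser"):
            raise ValidationError("kind must be 'equiripple' or 'kaiser'")
        if self.attenuation_db <= 0:
            raise ValidationError("attenuation must be positive")
        if self.sample_rate_hz <= 0:
            raise ValidationError("sample rate must be positive")

    @property
    def nyquist_hz(self):
        return self.sample_rate_hz / 2.0

    def resolved(self):
        """Feasible band edges, clamped below Nyquist if necessary."""
        nyq = self.nyquist_hz
        pb, sb = self.passband_hz, self.stopband_edge_hz
        if sb is None:
            sb = pb + 0.08 * nyq
        if sb >= nyq or pb >= nyq:
            pb_new = min(pb, CLAMP_FRACTION * nyq)
            sb_new = min(max(sb, pb_new + 0.08 * nyq), 0.96 * nyq)
            if pb_new >= sb_new:
                pb_new = sb_new - 0.08 * nyq
            warnings.warn(
                f"requested band ({pb}-{sb} Hz) infeasible at fs="
                f"{self.sample_rate_hz} Hz; clamped to {pb_new:.3g}-{sb_new:.3g} Hz",
                stacklevel=3,
            )
            pb, sb = pb_new, sb_new
        if not 0 < pb < sb < nyq:
            raise FilterDesignError(f"invalid band edges {pb}, {sb} at fs={self.sample_rate_hz}")
        return replace(self, passband_hz=pb, stopband_edge_hz=sb)


def _measure(taps, spec, n_grid=4096):
    w, h = sps.freqz(taps, worN=n_grid, fs=spec.sample_rate_hz)
    mag = np.abs(h)
    stop = w >= spec.stopband_edge_hz
    pb = w <= spec.passband_hz
    atten_db = -20.0 * np.log10(max(mag[stop].max(), 1e-300)) if stop.any() else np.inf
    with np.errstate(divide="ignore"):
        ripple_db = np.max(np.abs(20.0 * np.log10(np.maximum(mag[pb], 1e-300))))
    return atten_db, ripple_db


def design_filter(spec):
    """FIR taps meeting the (resolved) spec; measured on a 4096-point grid.

    Equiripple uses Parks-McClellan at the estimated minimum order, bumped
    upward until the measured stopband attenuation and passband ripple meet
    the spec; Kaiser uses the kaiserord/firwin pair.
    """
    r = spec.resolved()
    delta_f = r.stopband_edge_hz - r.passband_hz
    if r.kind == "kaiser":
        numtaps, beta = sps.kaiserord(r.attenuation_db, delta_f / r.nyquist_hz)
        numtaps |= 1  # odd length: type-I linear phase
        for extra in range(0, 80, 2):  # the order estimate can fall short
            taps = sps.firwin(numtaps + extra,
                              (r.passband_hz + r.stopband_edge_hz) / 2.0,
                              window=("kaiser", beta), fs=r.sample_rate_hz)
            atten, _ = _measure(taps, r)
            if atten >= r.attenuation_db - 1.0:
                return taps
        raise FilterDesignError("kaiser search failed to meet the spec")

    delta_p = 10.0 ** (r.passband_ripple_db / 20.0) - 1.0
    delta_s = 10.0 ** (-r.attenuation_db / 20.0)
    # Bellanger's order estimate, then search upward
    dfn = delta_f / r.sample_rate_hz
    n_est = int(np.ceil(2.0 / 3.0 * np.log10(1.0 / (10.0 * delta_p * delta_s)) / dfn))
    weight = [delta_s / delta_p, 1.0]
    for numtaps in range(max(n_est - 10, 9) | 1, (n_est + 200) | 1, 2):
        try:
            taps = sps.remez(
                numtaps,
                [0, r.passband_hz, r.stopband_edge_hz, r.nyquist_hz],
                [1.0, 0.0], weight=weight, fs=r.sample_rate_hz,
            )
        except Exception:
            continue
        atten, ripple = _measure(taps, r)
        if atten >= r.attenuation_db - 1.0 and ripple <= r.passband_ripple_db:
            return taps
    raise FilterDesignError("equiripple search failed to meet the spec")


def apply_filter(signal_or_values, taps, ts_ms=None):
    """Zero-phase (forward-backward) FIR application along time.

    Accepts a :class:`ContinuousSignal` or a plain array; the signal must be
    longer than three filter lengths so the reflected padding is valid.
    """
    if isinstance(signal_or_values, ContinuousSignal):
        x = signal_or_values.values
    else:
        x = np.atleast_2d(np.asarray(signal_or_values, dtype=float))
        if x.shape[0] == 1 and x.size > 1:
            x = x.T
    if x.shape[0] <= 3 * len(taps):
        raise ValidationError(
            f"signal of {x.shape[0]} samples too short for a {len(taps)}-tap "
            "zero-phase filter (needs > 3x filter length)"
        )
    y = sps.filtfilt(taps, [1.0], x, axis=0)
    if isinstance(signal_or_values, ContinuousSignal):
        return ContinuousSignal(y, signal_or_values.ts_ms,
                                list(signal_or_values.channel_names))
    return y


@dataclass
class MetricsReport:
    """MSE (time average of E'E), per-channel error SD, and p-values."""

    mse: float
    max_sd: float
    per_channel: pd.DataFrame
    p_value: float = None
    filter_spec: FilterSpec = None

    def to_json_dict(self):
        return {
            "mse": self.mse,
            "max_sd": self.max_sd,
            "p_value": self.p_value,
            "channels": self.per_channel.to_dict(orient="records"),
        }


def compute_errors(predicted, truth, filter_spec=None, channel_names=None):
    """Error metrics between aligned (already identically filtered) operands.

    ``MSE = mean_t  E(t)' E(t)`` with E the per-channel error vector, plus
    the per-channel standard deviation of the error and its maximum.
    """
    p = predicted.values if isinstance(predicted, ContinuousSignal) else np.atleast_2d(np.asarray(predicted, float))
    y = truth.values if isinstance(truth, ContinuousSignal) else np.atleast_2d(np.asarray(truth, float))
    if p.ndim == 1:
        p = p[:, None]
    if y.ndim == 1:
        y = y[:, None]
    if p.shape != y.shape:
        raise ContractError(f"operand shapes differ: {p.shape} vs {y.shape}")
    if channel_names is None:
        channel_names = (predicted.channel_names
                         if isinstance(predicted, ContinuousSignal)
                         else [f"ch{k}" for k in range(p.shape[1])])
    err = y - p
    mse = float(np.mean(np.sum(err ** 2, axis=1)))
    sd = err.std(axis=0, ddof=0)
    per_channel = pd.DataFrame({
        "channel": channel_names,
        "mse": np.mean(err ** 2, axis=0),
        "sd": sd,
    })
    return MetricsReport(mse=mse, max_sd=float(sd.max()),
                         per_channel=per_channel, filter_spec=filter_spec)


def compare_distributions(predicted, truth, alpha=0.05, test="ks"):
    """Two-sample distribution comparison per channel.

    Kolmogorov-Smirnov by default (Welch's t-test via ``test='welch'``);
    returns (combined p = max over channels, per-channel p array).  Constant
    (degenerate) channels yield NaN and are flagged.
    """
    p = predicted.values if isinstance(predicted, ContinuousSignal) else np.atleast_2d(np.asarray(predicted, float))
    y = truth.values if isinstance(truth, ContinuousSignal) else np.atleast_2d(np.asarray(truth, float))
    if p.shape != y.shape:
        raise ContractError("operands must be aligned")
    pvals = np.empty(p.shape[1])
    for k in range(p.shape[1]):
        if np.ptp(p[:, k]) == 0 and np.ptp(y[:, k]) == 0:
            pvals[k] = np.nan
            continue
        if test == "ks":
            pvals[k] = stats.ks_2samp(p[:, k], y[:, k]).pvalue
        elif test == "welch":
            pvals[k] = stats.ttest_ind(p[:, k], y[:, k], equal_var=False).pvalue
        else:
            raise ValidationError("test must be 'ks' or 'welch'")
    finite = pvals[np.isfinite(pvals)]
    combined = float(finite.max()) if finite.size else np.nan
    return combined, pvals


def power_spectrum(signal, nperseg=None):
    """Welch-averaged periodogram per channel: (freqs_hz, psd)."""
    x = signal.values if isinstance(signal, ContinuousSignal) else np.atleast_2d(np.asarray(signal, float))
    if x.ndim == 1:
        x = x[:, None]
    if x.shape[0] < 64:
        raise ValidationError("need at least 64 samples for a spectrum")
    fs = signal.sample_rate_hz if isinstance(signal, ContinuousSignal) else 125.0
    if nperseg is None:
        nperseg = min(256, x.shape[0])
    freqs, psd = sps.welch(x, fs=fs, axis=0, nperseg=nperseg)
    return freqs, psd
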