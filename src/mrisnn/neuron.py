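"""Izhikevich membrane dynamics.

The two-variable Izhikevich model

    dv/dt = 0.04 v^2 + 5 v + 140 - u + I
    du/dt = a (b v - u)
    if v >= v_peak (30 mV): v <- c, u <- u + d

is integrated with forward Euler at a sub-step of ``dt / n_substeps``
(default 0.5 ms for the 8 ms EEG sampling period); 8 ms Euler steps are
unstable near the quadratic spike upstroke.  Within one sample step a neuron
spikes at most once: on the first crossing it is reset and held at ``(c,
u+d)`` for the remaining sub-steps, so the post-step state of a spiking
neuron is exactly the reset state.  The input current ``I`` is held constant
across the sub-steps of a sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import NumericalOverflowError, ValidationError

V_PEAK_MV = 30.0


@dataclass
class IzhikevichParams:
    """Per-neuron (a, b, c, d) constants and the spike threshold."""

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    d: np.ndarray
    v_peak: float = V_PEAK_MV

    def __post_init__(self):
        self.a = np.atleast_1d(np.asarray(self.a, dtype=float))
        self.b = np.atleast_1d(np.asarray(self.b, dtype=float))
        self.c = np.atleast_1d(np.asarray(self.c, dtype=float))
        self.d = np.atleast_1d(np.asarray(self.d, dtype=float))
        if not (self.a.shape == self.b.shape == self.c.shape == self.d.shape):
            raise ValidationError("parameter arrays must share a shape")
        if np.any(self.a <= 0):
            raise ValidationError("recovery rate a must be positive")
        if not np.isfinite(self.v_peak):
            raise ValidationError("v_peak must be finite")
        if np.any(self.c >= self.v_peak):
            raise ValidationError("reset potential c must lie below v_peak")

    @property
    def n(self):
        return self.a.shape[0]


@dataclass
class NeuronState:
    """Membrane potential v (mV), recovery u, and this-step spike flags."""

    v: np.ndarray
    u: np.ndarray
    spiked: np.ndarray = field(default=None)
    spike_time: np.ndarray = field(default=None)  # ms, NaN if silent this step

    def __post_init__(self):
        self.v = np.atleast_1d(np.asarray(self.v, dtype=float))
        self.u = np.atleast_1d(np.asarray(self.u, dtype=float))
        n = self.v.shape[0]
        if self.spiked is None:
            self.spiked = np.zeros(n, dtype=bool)
        if self.spike_time is None:
            self.spike_time = np.full(n, np.nan)

    @property
    def n(self):
        return self.v.shape[0]


def initial_state(params):
    """Resting start: v = -65 mV, u = b*v (the conventional initial point)."""
    v = np.full(params.n, -65.0)
    return NeuronState(v=v, u=params.b * v)


def sample_params(n, is_inhibitory, seed=0, param_table="canonical",
                  v_peak=V_PEAK_MV):
    """Draw heterogeneous (a, b, c, d) for excitatory/inhibitory populations.

    Inhibitory neurons (both tables): a = 0.02 + 0.08 r, b = 0.25 - 0.05 r,
    c ~ U(-70, -60), d = 2.  Excitatory neurons: a = 0.02, b = 0.2 and

    - ``param_table='canonical'`` (default): c = -65 + 15 r^2, d = 8 - 6 r^2,
      the standard regular-to-chattering heterogeneity;
    - ``param_table='paper'``: c = -5 + 25 r, d = 8 - 6 r, the published
      parameter table evaluated literally (its c row places the reset at or
      above the firing range; kept selectable for auditing).
    """
    if param_table not in ("canonical", "paper"):
        raise ValidationError("param_table must be 'canonical' or 'paper'")
    is_inhibitory = np.asarray(is_inhibitory, dtype=bool)
    if is_inhibitory.shape != (n,):
        raise ValidationError("is_inhibitory must have length n")
    rng = np.random.default_rng(seed)
    r = rng.uniform(0.0, 1.0, size=n)

    a = np.where(is_inhibitory, 0.02 + 0.08 * r, 0.02)
    b = np.where(is_inhibitory, 0.25 - 0.05 * r, 0.2)
    if param_table == "canonical":
        c_exc = -65.0 + 15.0 * r ** 2
        d_exc = 8.0 - 6.0 * r ** 2
    else:
        c_exc = -5.0 + 25.0 * r
        d_exc = 8.0 - 6.0 * r
    c_inh = rng.uniform(-70.0, -60.0, size=n)
    c = np.where(is_inhibitory, c_inh, c_exc)
    d = np.where(is_inhibitory, 2.0, d_exc)
    if param_table == "paper":
        # the literal table allows c >= v_peak; clip just below to keep the
        # reset admissible while preserving the printed distribution shape
        c = np.minimum(c, v_peak - 1e-9)
    return IzhikevichParams(a=a, b=b, c=c, d=d, v_peak=v_peak)


def step(state, params, I, dt, n_substeps=16, t0=0.0):
    """Advance all neurons one sample step of length ``dt`` (ms).

    Returns a new :class:`NeuronState`; ``spiked`` marks neurons that crossed
    ``v_peak`` during this step and ``spike_time`` holds the sub-step-resolved
    crossing time (ms, absolute given ``t0``).
    """
    if dt <= 0:
        raise ValidationError("dt must be positive")
    if n_substeps < 1:
        raise ValidationError("n_substeps must be >= 1")
    I = np.broadcast_to(np.asarray(I, dtype=float), state.v.shape)
    if not np.all(np.isfinite(I)):
        raise ValidationError("input current contains non-finite values")

    v = state.v.copy()
    u = state.u.copy()
    n = v.shape[0]
    spiked = np.zeros(n, dtype=bool)
    spike_time = np.full(n, np.nan)
    h = dt / n_substeps
    # a neuron entering the step at or above threshold resets before any
    # integration, so its recovery variable increases by exactly d
    entry = v >= params.v_peak
    if np.any(entry):
        v[entry] = params.c[entry]
        u[entry] = u[entry] + params.d[entry]
        spiked |= entry
        spike_time[entry] = t0
    for k in range(n_substeps):
        live = ~spiked
        dv = 0.04 * v[live] ** 2 + 5.0 * v[live] + 140.0 - u[live] + I[live]
        du = params.a[live] * (params.b[live] * v[live] - u[live])
        v[live] = v[live] + h * dv
        u[live] = u[live] + h * du
        crossing = live & (v >= params.v_peak)
        if np.any(crossing):
            v[crossing] = params.c[crossing]
            u[crossing] = u[crossing] + params.d[crossing]
            spiked |= crossing
            spike_time[crossing] = t0 + (k + 1) * h
    bad = ~(np.isfinite(v) & np.isfinite(u))
    if np.any(bad):
        raise NumericalOverflowError(np.flatnonzero(bad))
    return NeuronState(v=v, u=u, spiked=spiked, spike_time=spike_time)


def params_to_table(params, is_inhibitory):
    """Tabular dump (id, a, b, c, d, inhibitory) for reproducibility."""
    import pandas as pd

    return pd.DataFrame(
        {
            "id": np.arange(params.n),
            "a": params.a,
            "b": params.b,
            "c": params.c,
            "d": params.d,
            "inhibitory": np.asarray(is_inhibitory, dtype=bool),
        }
    )


def params_from_table(df, v_peak=V_PEAK_MV):
    df = df.sort_values("id")
    p = IzhikevichParams(
        a=df["a"].to_numpy(),
        b=df["b"].to_numpy(),
        c=df["c"].to_numpy(),
        d=df["d"].to_numpy(),
        v_peak=v_peak,
    )
    return p, df["inhibitory"].to_numpy(dtype=bool)
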