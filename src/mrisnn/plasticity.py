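"""Weight dynamics of the reservoir.

Two learning rules coexist on the same neighbourhood graph:

* **STDP** for rows of hidden neurons: a presynaptic spike preceding a
  postsynaptic spike by ``dt`` potentiates the edge by ``A+ exp(-dt/tau+)``;
  the reverse order depresses it by ``A- exp(-|dt|/tau-)`` (``stdp_sign=
  'standard'``).  The published rule prints growing exponentials; that
  literal form is kept behind ``stdp_sign='paper'``, and the
  potentiation-only variant with a unit step behind ``variant='paper16'``.

* **GDR** (gradient descent rule) for rows of observed neurons: the cost
  J = 1/2 E'E with e_i = v_d_i - v_i/||V_ob||_2 is descended through the
  surrogate output model F = tanh(W V) + theta.  The default ``rederived``
  mode uses the direct gradient

      dw_ij = eta * (1 - tanh(W_i V)^2) * e_i * v_j / ||V||_2,

  while ``paper`` mode evaluates the published W-transposed expression
  per edge (which leaves an all-zero row exactly unchanged).  The leakage
  term integrates dtheta/dt = E / ||V||_2.

Weights are structural: entries exist only for j in N_i; querying a
non-edge raises, distinct from a zero weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    ContractError,
    DegenerateStateError,
    NoConnectionError,
    ValidationError,
)

STDP_A_DEFAULT = 2e-3     # max synaptic modification, both directions
STDP_TAU_DEFAULT = 5000.0  # time constant of permissible change


class WeightMatrix:
    """Directed weights on the neighbourhood graph, self-loops included.

    Stored dense with a boolean structural mask; values off the mask are
    identically zero and are not part of the model.
    """

    def __init__(self, values, mask):
        values = np.asarray(values, dtype=float)
        mask = np.asarray(mask, dtype=bool)
        if values.shape != mask.shape or values.ndim != 2:
            raise ContractError("values and mask must be equal square shapes")
        if values.shape[0] != values.shape[1]:
            raise ContractError("weight matrix must be square")
        if not np.all(np.isfinite(values[mask])):
            raise ValidationError("weights contain non-finite entries")
        self.values = np.where(mask, values, 0.0)
        self.mask = mask

    @property
    def n(self):
        return self.values.shape[0]

    def has_connection(self, i, j):
        return bool(self.mask[i, j])

    def get(self, i, j):
        if not self.mask[i, j]:
            raise NoConnectionError(f"no connection {i} -> {j}")
        return float(self.values[i, j])

    def copy(self):
        return WeightMatrix(self.values.copy(), self.mask.copy())

    def row(self, i):
        """(neighbor ids, weights) for row i."""
        nbr = np.flatnonzero(self.mask[i])
        return nbr, self.values[i, nbr]

    def __eq__(self, other):
        return (
            isinstance(other, WeightMatrix)
            and np.array_equal(self.mask, other.mask)
            and np.array_equal(self.values, other.values)
        )


@dataclass
class STDPParams:
    """Magnitudes, time constants and variant switches of the STDP rule."""

    a_plus: float = STDP_A_DEFAULT
    a_minus: float = STDP_A_DEFAULT
    tau_plus: float = STDP_TAU_DEFAULT
    tau_minus: float = STDP_TAU_DEFAULT  # not published; taken equal to tau+
    window: float = 100.0  # ms, |dt| beyond which a pair contributes nothing
    variant: str = "classic"  # classic | paper16
    sign: str = "standard"  # standard (decaying) | paper (as printed)

    def __post_init__(self):
        if self.a_plus < 0 or self.a_minus < 0:
            raise ValidationError("STDP magnitudes must be non-negative")
        if self.tau_plus <= 0 or self.tau_minus <= 0:
            raise ValidationError("STDP time constants must be positive")
        if self.variant not in ("classic", "paper16"):
            raise ValidationError("variant must be 'classic' or 'paper16'")
        if self.sign not in ("standard", "paper"):
            raise ValidationError("sign must be 'standard' or 'paper'")


@dataclass
class LeakageState:
    """Per-observed-neuron leakage term theta and its current derivative."""

    theta: np.ndarray
    dtheta_dt: np.ndarray = field(default=None)

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=float)
        if self.dtheta_dt is None:
            self.dtheta_dt = np.zeros_like(self.theta)


@dataclass
class TrainingState:
    """Per-step quantities the updates consume."""

    e: np.ndarray          # error vector over observed neurons
    v_norm: float          # ||V_ob(t)||_2
    ts: float              # sample period, ms
    v_d: np.ndarray = None
    v_ob: np.ndarray = None

    def __post_init__(self):
        self.e = np.asarray(self.e, dtype=float)

    @property
    def cost(self):
        """J = 1/2 E'E."""
        return 0.5 * float(self.e @ self.e)


def stdp_delta(delta_t, p):
    """Weight change of one spike pair at timing difference ``delta_t`` (ms).

    ``delta_t = t_post - t_pre``; positive means pre-before-post.
    """
    dt = np.asarray(delta_t, dtype=float)
    out = np.zeros_like(dt)
    inside = np.abs(dt) <= p.window
    pos = inside & (dt >= 0)
    neg = inside & (dt < 0)
    if p.variant == "paper16":
        # potentiation-only branch gated by the unit step u_s(-dt)
        gate = inside & (dt <= 0)
        mag = np.abs(dt) if p.sign == "standard" else -dt  # -dt >= 0 on gate
        arg = -mag / p.tau_plus if p.sign == "standard" else mag / p.tau_plus
        out[gate] = p.a_plus * np.exp(arg[gate])
        return out if out.ndim else float(out)
    if p.sign == "standard":
        out[pos] = p.a_plus * np.exp(-dt[pos] / p.tau_plus)
        out[neg] = -p.a_minus * np.exp(dt[neg] / p.tau_minus)
    else:  # literal published exponents (growing with |dt|)
        out[pos] = p.a_plus * np.exp(dt[pos] / p.tau_plus)
        out[neg] = -p.a_minus * np.exp(-dt[neg] / p.tau_minus)
    return out if out.ndim else float(out)


def observed_input_current(w_obs, v, dv_dt, dw_dt, dtheta_dt):
    """Input-current law for observed neurons.

    I_i = (sum_j w_ij dv_j/dt + dw_ij/dt v_j) (1 - tanh(sum_j w_ij v_j)^2)
          + dtheta_i/dt,

    with all sums restricted by the structural mask (off-mask entries are
    zero).  ``w_obs`` and ``dw_dt`` are (n_ob, n); ``v`` and ``dv_dt`` are
    full potential vectors (n,).
    """
    w_obs = np.asarray(w_obs, dtype=float)
    dw_dt = np.asarray(dw_dt, dtype=float)
    v = np.asarray(v, dtype=float)
    dv_dt = np.asarray(dv_dt, dtype=float)
    dtheta_dt = np.asarray(dtheta_dt, dtype=float)
    if w_obs.shape != dw_dt.shape:
        raise ContractError("w_obs and dw_dt shapes differ")
    if v.shape != dv_dt.shape or w_obs.shape[1] != v.shape[0]:
        raise ContractError("potential vectors do not match weight columns")
    if dtheta_dt.shape[0] != w_obs.shape[0]:
        raise ContractError("dtheta_dt length does not match observed rows")
    drive = w_obs @ dv_dt + dw_dt @ v
    gain = 1.0 - np.tanh(w_obs @ v) ** 2
    return drive * gain + dtheta_dt


def gdr_weight_update(w_obs, v, st, mask_obs=None, mode="rederived", eta=None):
    """Observed-row weight deltas for one sample step.

    ``eta`` is the gradient step; by default the sample period expressed in
    seconds (``st.ts / 1000``), which keeps single-step updates O(1e-3) at
    EEG potential scales.  Returns an (n_ob, n) delta, zero off the mask.
    """
    w_obs = np.asarray(w_obs, dtype=float)
    v = np.asarray(v, dtype=float)
    if st.v_norm <= 0 or not np.isfinite(st.v_norm):
        raise DegenerateStateError("||V||_2 is not positive")
    if mode not in ("rederived", "paper"):
        raise ValidationError("gradient mode must be 'rederived' or 'paper'")
    if w_obs.shape[1] != v.shape[0]:
        raise ContractError("weight columns do not match potential length")
    if st.e.shape[0] != w_obs.shape[0]:
        raise ContractError("error length does not match observed rows")
    if eta is None:
        eta = st.ts / 1000.0

    if mode == "rederived":
        gain = 1.0 - np.tanh(w_obs @ v) ** 2  # (n_ob,)
        delta = (eta / st.v_norm) * gain[:, None] * np.outer(st.e, v)
    else:
        # literal per-edge transcription: left-multiplied by the weight itself
        gain = 1.0 - np.tanh(w_obs * v[None, :]) ** 2
        delta = w_obs * gain * (eta / st.v_norm) * np.outer(st.e, v)
    if mask_obs is not None:
        delta = np.where(mask_obs, delta, 0.0)
    return delta


def leakage_update(st, leak, decay=0.0, scale=1.0):
    """dtheta/dt = E / ||V||_2; integrates theta by one sample period.

    With the defaults this is the pure accumulator
    ``theta <- theta + (E/||V||) Ts``.  A nonzero ``decay`` turns theta into
    a leaky integrator (bounded bias memory) and ``scale`` rescales the
    integration step (e.g. to express Ts in seconds).
    """
    if st.v_norm <= 0 or not np.isfinite(st.v_norm):
        raise DegenerateStateError("||V||_2 is not positive")
    if leak.theta.shape != st.e.shape:
        raise ContractError("theta length does not match error length")
    dtheta_dt = st.e / st.v_norm
    leak.dtheta_dt = dtheta_dt
    leak.theta = (1.0 - decay) * leak.theta + dtheta_dt * st.ts * scale
    return dtheta_dt


def stdp_step(W, hidden_mask, new_spike_time, last_spike_time, p):
    """Apply STDP to hidden rows for the spikes of one sample step.

    ``new_spike_time`` holds this step's spike times (NaN = silent);
    ``last_spike_time`` the most recent spike time per neuron *before* this
    step.  Pairing is nearest-spike: each new spike pairs once as post
    (against the latest presynaptic spike, including simultaneous ones) and
    once as pre (against earlier postsynaptic spikes of neurons that stayed
    silent this step).  Self-loops are excluded.
    """
    spikers = np.flatnonzero(np.isfinite(new_spike_time))
    if spikers.size == 0:
        return
    latest = np.where(np.isfinite(new_spike_time), new_spike_time, last_spike_time)
    n = W.n
    for j in spikers:
        t_j = new_spike_time[j]
        if hidden_mask[j]:
            # j as post: row j against every presynaptic neighbour's latest spike
            nbr = W.mask[j].copy()
            nbr[j] = False
            pre_t = latest.copy()
            pre_t[j] = np.nan
            valid = nbr & np.isfinite(pre_t)
            if np.any(valid):
                dt = t_j - pre_t[valid]
                W.values[j, valid] += stdp_delta(dt, p)
        # j as pre: hidden posts that did NOT spike this step, earlier spikes
        posts = W.mask[:, j] & hidden_mask & np.isfinite(last_spike_time)
        posts &= ~np.isfinite(new_spike_time)
        posts[j] = False
        if np.any(posts):
            dt = last_spike_time[posts] - t_j
            W.values[posts, j] += stdp_delta(dt, p)


def clamp_inhibitory(W, is_inhibitory):
    """Outgoing weights of inhibitory neurons act non-positively."""
    cols = np.flatnonzero(is_inhibitory)
    W.values[:, cols] = np.minimum(W.values[:, cols], 0.0)
    W.values[~W.mask] = 0.0


def combined_update(W, layout, st, leak, p, v, new_spike_time, last_spike_time,
                    mode="rederived", eta=None, theta_decay=0.0,
                    theta_scale=1.0):
    """One training-step update of the full weight matrix.

    Observed rows move by the GDR, hidden rows by STDP over this step's
    spike pairs, leakage integrates, and inhibitory columns are clamped
    non-positive afterwards.  Returns the observed-row delta (for the
    dW/dt term of the current law).
    """
    obs_ids = layout.observed_ids
    mask_obs = W.mask[obs_ids]
    delta_obs = gdr_weight_update(
        W.values[obs_ids], v, st, mask_obs=mask_obs, mode=mode, eta=eta
    )
    W.values[obs_ids] += delta_obs
    hidden_mask = ~layout.observed_mask
    stdp_step(W, hidden_mask, new_spike_time, last_spike_time, p)
    leakage_update(st, leak, decay=theta_decay, scale=theta_scale)
    clamp_inhibitory(W, layout.is_inhibitory)
    return delta_obs


def prune_strongest(W):
    """Keep, for each unordered pair, only the direction with larger |w|.

    Ties keep the (i < j) direction; self-loops are untouched.  Returns a
    new matrix; idempotent.
    """
    out = W.copy()
    v = out.values
    upper = np.triu(np.ones_like(v, dtype=bool), k=1) & W.mask & W.mask.T
    i_idx, j_idx = np.nonzero(upper)
    wij = v[i_idx, j_idx]
    wji = v[j_idx, i_idx]
    keep_ij = np.abs(wij) >= np.abs(wji)  # tie keeps i<j
    v[i_idx[~keep_ij], j_idx[~keep_ij]] = 0.0
    v[j_idx[keep_ij], i_idx[keep_ij]] = 0.0
    # one-directional structural edges (mask asymmetry cannot arise from the
    # symmetric neighbourhood rule, but guard anyway)
    return out
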