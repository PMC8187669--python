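"""End-to-end training and prediction protocol.

The public surface is :class:`ReservoirForecaster`, an sklearn-style
estimator.  ``fit`` builds the spatial reservoir (geometry + Izhikevich
parameters + zero/near-zero weights), converts the EEG into desired
potentials, and runs incremental one-step-ahead training: per sample the
observed neurons receive the proposed input-current law, the network is
advanced one 8 ms step, the normalised observed output is compared with the
next desired sample, and the combined GDR + STDP update is applied.  States
and weights carry across epochs.

``predict`` free-runs the trained network (observed weights and leakage
frozen, hidden STDP still active) with no external data.
``reconstruct`` reads out hidden neurons nearest to electrode positions
that were never recorded — the unmonitored-channel prediction.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml
from sklearn.base import BaseEstimator

from . import encoding, geometry, neuron, plasticity
from .encoding import ContinuousSignal, SpikeTrain
from .errors import ContractError, ValidationError

TS_MS_DEFAULT = 8.0


@dataclass
class SplitSpec:
    """Temporal 70/30 split: the earliest samples train, the rest test."""

    train_fraction: float = 0.7

    def counts(self, n_samples):
        n_train = int(np.floor(self.train_fraction * n_samples))
        return n_train, n_samples - n_train


def split_series(n_samples, spec=None):
    """Contiguous (train_indices, test_indices); train precedes test."""
    if spec is None:
        spec = SplitSpec()
    if n_samples < 10:
        raise ValidationError("series too short to split (need >= 10 samples)")
    n_train, n_test = spec.counts(n_samples)
    idx = np.arange(n_samples)
    return idx[:n_train], idx[n_train:]


@dataclass
class PredictionResult:
    """Aligned predicted traces (+truth where available) per location."""

    predicted: np.ndarray            # samples x locations
    location_names: list
    targets: np.ndarray = None
    unmonitored: np.ndarray = None   # bool per location

    def __post_init__(self):
        self.predicted = np.asarray(self.predicted, dtype=float)
        if self.unmonitored is None:
            self.unmonitored = np.zeros(self.predicted.shape[1], dtype=bool)


@dataclass
class ModelConfig:
    """Serialisable mirror of the estimator parameters."""

    n_neurons: int = 300
    frac_inhibitory: float = 0.2
    neighborhood_mm: float = 70.0
    ts_ms: float = TS_MS_DEFAULT
    epochs: int = 50
    train_fraction: float = 0.7
    observed_init: str = "uniform"
    observed_init_scale: float = 1e-3
    hidden_init: str = "smallworld"
    hidden_init_scale: float = 0.5
    gradient: str = "rederived"
    gdr_eta: float = None
    gdr_eta_halflife: float = 10.0
    stdp_sign: str = "standard"
    stdp_variant: str = "classic"
    stdp_window_ms: float = 100.0
    tau_plus: float = 5000.0
    tau_minus: float = 5000.0
    a_plus: float = 2e-3
    a_minus: float = 2e-3
    param_table: str = "canonical"
    potential_scale: str = "normalized"
    current_gain: float = 20.0
    theta_feedback: float = 0.01
    theta_decay: float = 1e-3
    output_scale: float = None
    hidden_coupling: str = "graded"
    hidden_coupling_gain: float = 0.25
    syn_tau_ms: float = 0.0
    inhibitory_scope: str = "hidden"
    norm_scope: str = "all"
    n_substeps: int = 16
    sigma_ms: float = None
    baseline_alpha: float = 0.5
    hidden_noise_sd: float = 0.0
    readout_k: int = 5
    seed: int = 0

    def to_yaml(self, path=None):
        text = yaml.safe_dump(asdict(self), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source):
        if hasattr(source, "read"):
            data = yaml.safe_load(source)
        else:
            try:
                with open(source) as fh:
                    data = yaml.safe_load(fh)
            except (OSError, ValueError):
                data = yaml.safe_load(source)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


class ReservoirForecaster(BaseEstimator):
    """3D spiking reservoir forecaster of multichannel EEG.

    Parameters mirror :class:`ModelConfig`; ``cloud`` and ``montage``
    default to a synthetic spherical head and the first study montage.
    Fitted attributes carry a trailing underscore.
    """

    def __init__(self, cloud=None, montage=None, n_neurons=300,
                 frac_inhibitory=0.2, neighborhood_mm=70.0, ts_ms=TS_MS_DEFAULT,
                 epochs=50, train_fraction=0.7, observed_init="uniform",
                 observed_init_scale=1e-3, hidden_init="smallworld",
                 hidden_init_scale=0.5, gradient="rederived", gdr_eta=None,
                 gdr_eta_halflife=10.0, stdp_sign="standard", stdp_variant="classic",
                 stdp_window_ms=100.0, tau_plus=5000.0, tau_minus=5000.0,
                 a_plus=2e-3, a_minus=2e-3, param_table="canonical",
                 potential_scale="normalized", current_gain=20.0,
                 theta_feedback=0.01, theta_decay=1e-3, output_scale=None,
                 hidden_coupling="graded", hidden_coupling_gain=0.25,
                 syn_tau_ms=0.0, inhibitory_scope="hidden", norm_scope="all",
                 n_substeps=16, sigma_ms=None, baseline_alpha=0.5,
                 hidden_noise_sd=0.0, readout_k=5, snapshot_epochs=(),
                 random_state=0):
        self.cloud = cloud
        self.montage = montage
        self.n_neurons = n_neurons
        self.frac_inhibitory = frac_inhibitory
        self.neighborhood_mm = neighborhood_mm
        self.ts_ms = ts_ms
        self.epochs = epochs
        self.train_fraction = train_fraction
        self.observed_init = observed_init
        self.observed_init_scale = observed_init_scale
        self.hidden_init = hidden_init
        self.hidden_init_scale = hidden_init_scale
        self.gradient = gradient
        self.gdr_eta = gdr_eta
        self.gdr_eta_halflife = gdr_eta_halflife
        self.stdp_sign = stdp_sign
        self.stdp_variant = stdp_variant
        self.stdp_window_ms = stdp_window_ms
        self.tau_plus = tau_plus
        self.tau_minus = tau_minus
        self.a_plus = a_plus
        self.a_minus = a_minus
        self.param_table = param_table
        self.potential_scale = potential_scale
        self.current_gain = current_gain
        self.theta_feedback = theta_feedback
        self.theta_decay = theta_decay
        self.output_scale = output_scale
        self.hidden_coupling = hidden_coupling
        self.hidden_coupling_gain = hidden_coupling_gain
        self.syn_tau_ms = syn_tau_ms
        self.inhibitory_scope = inhibitory_scope
        self.norm_scope = norm_scope
        self.n_substeps = n_substeps
        self.sigma_ms = sigma_ms
        self.baseline_alpha = baseline_alpha
        self.hidden_noise_sd = hidden_noise_sd
        self.readout_k = readout_k
        self.snapshot_epochs = snapshot_epochs
        self.random_state = random_state

    @classmethod
    def from_config(cls, cfg, cloud=None, montage=None):
        kw = asdict(cfg)
        kw["random_state"] = kw.pop("seed")
        return cls(cloud=cloud, montage=montage, **kw)

    # ------------------------------------------------------------------ build
    def _resolve_geometry(self, channel_names, seeds):
        from . import synthetic

        cloud = self.cloud
        if cloud is None:
            cloud = synthetic.gen_head_cloud(max(1000, self.n_neurons), seed=0)
        montage = self.montage
        if montage is None:
            montage = synthetic.gen_montage_1020("case1")
        if channel_names is not None:
            missing = [c for c in channel_names if c not in montage.names]
            if missing:
                raise ValidationError(f"channels missing from montage: {missing}")
            montage = montage.subset(channel_names)
        layout = geometry.place_neurons(
            cloud, montage, self.n_neurons, self.frac_inhibitory,
            seed=seeds[0], inhibitory_scope=self.inhibitory_scope,
        )
        graph = geometry.build_neighborhoods(layout, self.neighborhood_mm)
        W = geometry.init_weights(
            graph, layout, self.observed_init_scale, seed=seeds[1],
            observed_init=self.observed_init, hidden_init=self.hidden_init,
            hidden_init_scale=self.hidden_init_scale,
        )
        return cloud, montage, layout, graph, W

    def _build_targets(self, X, channel_names):
        """Desired potentials + training length from either input realisation.

        Targets (baseline, spike set, desired potential) are derived from
        the *training window only*, so no test sample can influence any
        weight — the baseline's global minimum in particular must not see
        the future.
        """
        if isinstance(X, SpikeTrain):
            if channel_names is None:
                channel_names = X.channel_names
            horizon = max((t[-1] for t in X.spike_times.values() if t.size),
                          default=0.0)
            n_samples = int(np.floor(horizon / self.ts_ms)) + 1
            if n_samples < 10:
                raise ValidationError("spike input too short")
            n_train, _ = SplitSpec(self.train_fraction).counts(n_samples)
            vd = encoding.desired_potential_from_spikes(
                X, channel_names, n_train, self.ts_ms, self.sigma_ms
            )
            sig = None
        else:
            if isinstance(X, ContinuousSignal):
                sig = X
            else:
                sig = ContinuousSignal(np.asarray(X, dtype=float), self.ts_ms,
                                       channel_names)
            channel_names = sig.channel_names
            n_samples = sig.n_samples
            n_train, _ = SplitSpec(self.train_fraction).counts(n_samples)
            train_sig = ContinuousSignal(sig.values[:n_train], sig.ts_ms,
                                         list(sig.channel_names))
            baseline = encoding.baseline_reconstruct(
                train_sig, encoding.BaselineParams(self.baseline_alpha)
            )
            spikes = encoding.spike_set_from_signal(train_sig, baseline)
            vd = encoding.desired_potential(train_sig, spikes, self.sigma_ms)
        return sig, vd, n_samples, channel_names

    # ------------------------------------------------------------------- fit
    def fit(self, X, y=None, channel_names=None):
        """Train on a samples x channels EEG matrix (or SpikeTrain)."""
        ss = np.random.SeedSequence(self.random_state)
        seeds = ss.spawn(4)
        sig, vd, n_samples, channel_names = self._build_targets(X, channel_names)
        cloud, montage, layout, graph, W = self._resolve_geometry(channel_names, seeds)

        params = neuron.sample_params(
            layout.n_neurons, layout.is_inhibitory, seed=seeds[2],
            param_table=self.param_table,
        )
        self.stdp_params_ = plasticity.STDPParams(
            a_plus=self.a_plus, a_minus=self.a_minus, tau_plus=self.tau_plus,
            tau_minus=self.tau_minus, window=self.stdp_window_ms,
            variant=self.stdp_variant, sign=self.stdp_sign,
        )
        n_train, _ = SplitSpec(self.train_fraction).counts(n_samples)
        if n_train < 2:
            raise ValidationError("training window too short")

        obs = layout.observed_ids
        hidden_mask = ~layout.observed_mask
        n = layout.n_neurons
        rng = np.random.default_rng(seeds[3])

        if self.potential_scale not in ("normalized", "raw"):
            raise ValidationError("potential_scale must be 'normalized' or 'raw'")
        if self.norm_scope not in ("observed", "all"):
            raise ValidationError("norm_scope must be 'observed' or 'all'")
        normalized = self.potential_scale == "normalized"
        norm_ids = obs if self.norm_scope == "observed" else slice(None)

        def vnorm_of(v_full):
            return float(np.linalg.norm(v_full[norm_ids]))

        def scaled(v_full):
            # potentials as seen by the learning rules and the current law:
            # either raw millivolts or the unit-observed-norm scale, under
            # which ||V_ob|| = 1 identically and the printed formulas apply
            # to the normalised output directly
            if not normalized:
                return v_full
            return v_full / vnorm_of(v_full)

        state = neuron.initial_state(params)
        leak = plasticity.LeakageState(np.zeros(len(obs)))
        last_delta_obs = np.zeros((len(obs), n))
        sv = scaled(state.v)
        dv_dt = np.zeros(n)
        last_spike_time = np.full(n, np.nan)
        spike_indicator = np.zeros(n)
        syn_trace = np.zeros(n)
        syn_decay = (np.exp(-self.ts_ms / self.syn_tau_ms)
                     if self.syn_tau_ms > 0 else 0.0)
        t_abs = 0.0

        if self.hidden_coupling not in ("spike", "graded"):
            raise ValidationError("hidden_coupling must be 'spike' or 'graded'")
        # desired potentials mapped affinely into the operating band of the
        # unit-norm output: rest maps to the resting direction -1/sqrt(n_ob)
        n_norm = len(obs) if self.norm_scope == "observed" else n
        rest_base = -1.0 / np.sqrt(n_norm)
        if self.output_scale is None:
            targets = vd.values[:n_train]
        else:
            targets = rest_base + self.output_scale * vd.values[:n_train]
        target_defined = (np.arange(n_train)[:, None]
                          >= vd.first_spike_index[None, :])
        self.rest_base_ = rest_base

        cost_trace = []
        snapshots = {}
        v_hist = np.empty((n_train, n))
        vnorm_hist = np.empty(n_train)
        spike_counts_epoch = np.zeros(n)

        eta0 = self.gdr_eta if self.gdr_eta is not None else self.ts_ms / 1000.0
        for epoch in range(self.epochs):
            # harmonically decaying gradient step stabilises the weight
            # structure once the early adaptation has been absorbed
            if self.gdr_eta_halflife and self.gdr_eta_halflife > 0:
                eta_epoch = eta0 / (1.0 + epoch / self.gdr_eta_halflife)
            else:
                eta_epoch = eta0
            costs = np.empty(n_train - 1)
            spike_counts_epoch[:] = 0.0
            v_hist[0] = state.v
            vnorm_hist[0] = vnorm_of(state.v)
            for t in range(n_train - 1):
                I = np.zeros(n)
                I[obs] = self.current_gain * plasticity.observed_input_current(
                    W.values[obs], sv, dv_dt, last_delta_obs / self.ts_ms,
                    leak.dtheta_dt + self.theta_feedback * leak.theta,
                )
                syn_trace = syn_trace * syn_decay + spike_indicator
                drive = syn_trace.copy()
                if self.hidden_coupling == "graded":
                    drive[obs] += self.hidden_coupling_gain * (state.v[obs] + 65.0) / 10.0
                I[hidden_mask] = W.values[hidden_mask] @ drive
                if self.hidden_noise_sd > 0:
                    I[hidden_mask] += rng.normal(
                        0.0, self.hidden_noise_sd, size=int(hidden_mask.sum())
                    )
                new_state = neuron.step(state, params, I, self.ts_ms,
                                        self.n_substeps, t0=t_abs)
                v_norm = vnorm_of(new_state.v)
                sv_new = scaled(new_state.v)
                e = targets[t + 1] - new_state.v[obs] / v_norm
                e = np.where(target_defined[t + 1], e, 0.0)
                st = plasticity.TrainingState(
                    e=e, v_norm=1.0 if normalized else v_norm, ts=self.ts_ms
                )
                last_delta_obs = plasticity.combined_update(
                    W, layout, st, leak, self.stdp_params_, sv_new,
                    new_state.spike_time, last_spike_time, mode=self.gradient,
                    eta=eta_epoch, theta_decay=self.theta_decay,
                    theta_scale=1e-3,
                )
                costs[t] = st.cost
                fired = np.isfinite(new_state.spike_time)
                last_spike_time = np.where(fired, new_state.spike_time,
                                           last_spike_time)
                spike_indicator = fired.astype(float)
                spike_counts_epoch += spike_indicator
                dv_dt = (sv_new - sv) / self.ts_ms
                sv = sv_new
                state = new_state
                t_abs += self.ts_ms
                v_hist[t + 1] = state.v
                vnorm_hist[t + 1] = v_norm
            cost_trace.append(float(np.mean(costs)))
            if epoch in set(self.snapshot_epochs):
                snapshots[epoch] = {
                    "v": state.v.copy(),
                    "spike_counts": spike_counts_epoch.copy(),
                    "weights": W.copy(),
                }

        self.cloud_, self.montage_ = cloud, montage
        self.layout_, self.graph_, self.weights_ = layout, graph, W
        self.params_ = params
        self.leak_ = leak
        self.state_ = state
        self.cost_trace_ = np.asarray(cost_trace)
        self.v_history_ = v_hist
        self.vnorm_history_ = vnorm_hist
        self.spike_counts_ = spike_counts_epoch.copy()
        self.snapshots_ = snapshots
        self.n_train_ = n_train
        self.n_samples_in_ = n_samples
        self.channel_names_ = channel_names
        self.desired_ = vd
        self.signal_ = sig
        self._dv_dt = dv_dt
        self._sv = sv
        self._last_spike_time = last_spike_time
        self._spike_indicator = spike_indicator
        self._syn_trace = syn_trace
        self._t_abs = t_abs
        self.n_features_in_ = len(channel_names)
        return self

    # ---------------------------------------------------------------- predict
    def predict(self, horizon):
        """Free-running forecast of ``horizon`` samples.

        No data enter; observed weights and leakage are frozen, hidden STDP
        stays active.  Returns normalised observed-neuron outputs
        (samples x channels).
        """
        self._check_fitted()
        if horizon is None or horizon <= 0:
            raise ValidationError("horizon must be a positive sample count")
        layout = self.layout_
        obs = layout.observed_ids
        hidden_mask = ~layout.observed_mask
        n = layout.n_neurons
        W = self.weights_
        state = self.state_
        dv_dt = self._dv_dt
        sv = self._sv
        normalized = self.potential_scale == "normalized"
        norm_ids = (obs if self.norm_scope == "observed" else slice(None))
        spike_indicator = self._spike_indicator
        syn_trace = self._syn_trace.copy()
        syn_decay = (np.exp(-self.ts_ms / self.syn_tau_ms)
                     if self.syn_tau_ms > 0 else 0.0)
        last_spike_time = self._last_spike_time
        t_abs = self._t_abs
        zeros_dw = np.zeros((len(obs), n))
        theta_term = self.theta_feedback * self.leak_.theta

        out = np.empty((horizon, len(obs)))
        v_hist = np.empty((horizon, n))
        vnorm_hist = np.empty(horizon)
        for t in range(horizon):
            I = np.zeros(n)
            I[obs] = self.current_gain * plasticity.observed_input_current(
                W.values[obs], sv, dv_dt, zeros_dw, theta_term
            )
            syn_trace = syn_trace * syn_decay + spike_indicator
            drive = syn_trace.copy()
            if self.hidden_coupling == "graded":
                drive[obs] += self.hidden_coupling_gain * (state.v[obs] + 65.0) / 10.0
            I[hidden_mask] = W.values[hidden_mask] @ drive
            new_state = neuron.step(state, self.params_, I, self.ts_ms,
                                    self.n_substeps, t0=t_abs)
            plasticity.stdp_step(W, hidden_mask, new_state.spike_time,
                                 last_spike_time, self.stdp_params_)
            plasticity.clamp_inhibitory(W, layout.is_inhibitory)
            v_norm = float(np.linalg.norm(new_state.v[norm_ids]))
            out[t] = new_state.v[obs] / v_norm
            v_hist[t] = new_state.v
            vnorm_hist[t] = v_norm
            fired = np.isfinite(new_state.spike_time)
            last_spike_time = np.where(fired, new_state.spike_time,
                                       last_spike_time)
            spike_indicator = fired.astype(float)
            sv_new = (new_state.v / v_norm) if normalized else new_state.v
            dv_dt = (sv_new - sv) / self.ts_ms
            sv = sv_new
            state = new_state
            t_abs += self.ts_ms

        self.state_ = state
        self._dv_dt = dv_dt
        self._sv = sv
        self._spike_indicator = spike_indicator
        self._last_spike_time = last_spike_time
        self._t_abs = t_abs
        self.freerun_v_history_ = v_hist
        self.freerun_vnorm_history_ = vnorm_hist
        return PredictionResult(out, list(self.channel_names_))

    # ------------------------------------------------------------ reconstruct
    def reconstruct(self, virtual_montage, window="train"):
        """Read out signals at unmonitored electrode positions.

        For each virtual channel the nearest hidden neuron (or the
        inverse-distance average of the ``readout_k`` nearest hidden
        neurons) provides its normalised potential trace over the requested
        window (``train``, ``freerun`` or ``all``).  A virtual channel at an
        observed neuron's exact position reads out that neuron itself.
        """
        self._check_fitted()
        v_hist, vnorm = self._window_history(window)
        norm_const = float(np.mean(vnorm))  # constant normaliser: the
        # time-varying norm would imprint global activity on silent neurons
        layout = self.layout_
        hidden_ids = np.flatnonzero(~layout.observed_mask)
        traces = []
        for k, name in enumerate(virtual_montage.names):
            p = virtual_montage.positions[k]
            d_all = np.linalg.norm(layout.positions - p, axis=1)
            nearest = int(np.argmin(d_all))
            if d_all.min() > self.neighborhood_mm:
                warnings.warn(
                    f"virtual channel {name} is {d_all.min():.1f} mm from the "
                    "nearest neuron, beyond the neighbourhood radius",
                    stacklevel=2,
                )
            if layout.observed_mask[nearest] and d_all[nearest] == 0.0:
                trace = v_hist[:, nearest] / vnorm
            else:
                d_h = d_all[hidden_ids]
                k_eff = min(max(1, self.readout_k), hidden_ids.size)
                sel = np.argsort(d_h)[:k_eff]
                w = 1.0 / np.maximum(d_h[sel], 1e-9)
                w /= w.sum()
                trace = (v_hist[:, hidden_ids[sel]] @ w) / norm_const
            traces.append(trace)
        out = np.column_stack(traces)
        return PredictionResult(out, list(virtual_montage.names),
                                unmonitored=np.ones(out.shape[1], dtype=bool))

    def _window_history(self, window):
        if window == "train":
            return self.v_history_, self.vnorm_history_
        if window == "freerun":
            if not hasattr(self, "freerun_v_history_"):
                raise ValidationError("no free-run has been performed")
            return self.freerun_v_history_, self.freerun_vnorm_history_
        if window == "all":
            if not hasattr(self, "freerun_v_history_"):
                return self.v_history_, self.vnorm_history_
            return (np.vstack([self.v_history_, self.freerun_v_history_]),
                    np.concatenate([self.vnorm_history_,
                                    self.freerun_vnorm_history_]))
        raise ValidationError("window must be 'train', 'freerun' or 'all'")

    def observed_outputs(self, window="train"):
        """Normalised observed-neuron traces over a recorded window."""
        self._check_fitted()
        v_hist, vnorm = self._window_history(window)
        return v_hist[:, self.layout_.observed_ids] / vnorm[:, None]

    def _check_fitted(self):
        if not hasattr(self, "weights_"):
            raise ValidationError("model is not fitted")


# ----------------------------------------------------------------- wrappers

def train(eeg, config=None, cloud=None, montage=None, **overrides):
    """Build and fit a :class:`ReservoirForecaster`; returns the model."""
    cfg = config or ModelConfig()
    model = ReservoirForecaster.from_config(cfg, cloud=cloud, montage=montage)
    if overrides:
        model.set_params(**overrides)
    return model.fit(eeg)


def predict_free_run(model, horizon):
    return model.predict(horizon)


def predict_unmonitored(model, virtual_montage, window="train"):
    return model.reconstruct(virtual_montage, window=window)


def random_walk_baseline(signal):
    """Univariate persistence baseline: prediction(t) = value(t-1)."""
    values = signal.values if isinstance(signal, ContinuousSignal) else np.asarray(signal, float)
    if values.ndim == 1:
        values = values[:, None]
    if values.shape[0] < 2:
        raise ValidationError("need at least two samples")
    names = (signal.channel_names if isinstance(signal, ContinuousSignal)
             else [f"ch{k}" for k in range(values.shape[1])])
    return PredictionResult(values[:-1], list(names), targets=values[1:])
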