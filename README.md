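# mrisnn — personalized 3D spiking reservoirs for EEG modelling

`mrisnn` builds a three-dimensional reservoir of Izhikevich spiking neurons
inside a personal head geometry and trains it to model, forecast, and
spatially extrapolate multichannel EEG.  It is aimed at computational
neuroscientists and EEG methodologists who want a structurally personalized
alternative to template-based spiking reservoirs: the neuron positions come
from the subject's own head volume (a point cloud extracted from an MRI
volume mesh, or a synthetic stand-in), electrodes of the 10–20 system anchor
*observed* neurons, and the remaining *hidden* neurons fill the volume.
Because the model is spatial, it can read out predicted signals at electrode
positions that were **never recorded** — reconstruction of unmonitored brain
locations.

## The model

Every neuron follows the Izhikevich dynamics

```
dv/dt = 0.04 v² + 5v + 140 − u + I        du/dt = a(bv − u)
if v ≥ 30 mV:  v ← c,  u ← u + d
```

integrated with sub-millisecond forward Euler inside each 8 ms EEG sample.
Neurons i, j are synaptically connected iff their distance satisfies
D_ij ≤ T (default T = 70 mm), with a self-feedback loop for every neuron.

Learning is hybrid:

* **Observed neurons** (one per EEG channel) are trained supervised by a
  gradient-descent rule (GDR).  Each channel's EEG is converted into a
  *desired potential* V_d — the signal amplitude sampled at adaptive
  threshold crossings and decayed exponentially between them — and the
  normalised membrane output v_n = v/‖V(t)‖₂ is driven toward it by
  descending J(t) = ½‖V_d − V_n‖² through the surrogate output model
  F = tanh(WV) + θ:

  ```
  Δw_ij = η (1 − tanh²(W_i V)) e_i v_j / ‖V‖₂ ,   dθ/dt = E / ‖V‖₂
  ```

  The observed neurons receive the input-current law

  ```
  I_i = (Σ_j w_ij dv_j/dt + dw_ij/dt v_j)(1 − tanh²(Σ_j w_ij v_j)) + dθ_i/dt
  ```

* **Hidden neurons** learn unsupervised by spike-time-dependent plasticity:
  a presynaptic spike Δt before a postsynaptic one changes the synapse by
  A₊e^(−Δt/τ₊) (depression −A₋e^(−|Δt|/τ₋) for the reverse order), with
  A₊ = A₋ = 2·10⁻³ and τ₊ = τ₋ = 5000.

The training protocol is a temporal 70/30 split with one-step-ahead (8 ms)
supervision over 50 incremental epochs; testing is free-running (no input,
observed weights frozen, STDP still active).  Outputs and reference signals
are compared only after passing through the same zero-phase minimum-order
equiripple (or Kaiser) FIR lowpass, 0–70 Hz requested with 80 dB stopband
(band edges are clamped below Nyquist at low sampling rates).

## Worked example

Train on 15 synthetic EEG channels (two shared oscillatory sources mixed
across the scalp with distance-decaying gains) and reconstruct a 16th
channel, C3, that the model never saw:

```python
import numpy as np
import mrisnn as m
from mrisnn import evaluation

montage = m.gen_montage_1020(m.CASE1_CHANNELS + ["C3"])
sources = np.array([[-50.0, 30.0, 40.0], [45.0, -40.0, 45.0]])
spec = m.SyntheticEEGSpec(n_channels=16, n_samples=500, seed=7,
                          mixing=m.spatial_mixing(montage, sources),
                          channel_names=montage.names)
eeg, _, _ = m.gen_synthetic_eeg(spec)

train = m.ContinuousSignal(eeg.values[:, :15], ts_ms=8.0,
                           channel_names=m.CASE1_CHANNELS)
model = m.ReservoirForecaster(epochs=50, random_state=3).fit(train)
print(f"reservoir: {model.layout_.n_observed} observed + "
      f"{model.layout_.n_hidden} hidden neurons")
print(f"epoch cost: {model.cost_trace_[0]:.5f} -> {model.cost_trace_[-1]:.5f}")

forecast = model.predict(150)                       # free-run, 1.2 s ahead
print(f"free-run forecast: {forecast.predicted.shape}")

rec = model.reconstruct(montage.subset(["C3"]))     # unmonitored channel
taps = evaluation.design_filter(m.FilterSpec(sample_rate_hz=125.0))
rec_f = evaluation.apply_filter(rec.predicted, taps)[:, 0]
truth = evaluation.apply_filter(eeg.values[:model.n_train_, 15:16], taps)[:, 0]
r = np.corrcoef(rec_f[20:], truth[20:])[0, 1]
print(f"held-out C3 correlation after matched 0-55 Hz filtering: r = {r:.3f}")
```

Output:

```
reservoir: 15 observed + 285 hidden neurons
epoch cost: 1.11517 -> 1.11485
free-run forecast: (150, 15)
held-out C3 correlation after matched 0-55 Hz filtering: r = 0.503
```

The epoch cost is the mean of J(t) = ½‖E(t)‖² over the 350-sample training
window; it decreases across the 50 incremental epochs as the leakage bias
and the weight structure adapt.  The held-out correlation shows that hidden
neurons near the C3 position, driven only through learned spatial
connectivity from the 15 recorded channels, carry a signal that matches the
true (never-seen) C3 trace after identical filtering of both traces.

A thin CLI wraps the same pipeline:

```bash
mrisnn build   --cloud head.txt --montage montage.sfp --config cfg.yaml
mrisnn train   --eeg eeg.csv --out run/
mrisnn predict --run run/ --horizon 150 --virtual-channels O1,O2,F3
mrisnn baseline --eeg eeg.csv
```

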