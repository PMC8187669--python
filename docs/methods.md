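# Methods

This note documents the model implemented in `mrisnn`, the choices that were
genuinely open, and what the synthetic fixtures do and do not establish.

## Reservoir construction

A reservoir of `n_neurons` (default 300) Izhikevich neurons is embedded in a
head-shaped 3D point cloud (millimetres).  Each 10–20 montage channel, in
montage order, greedily claims the nearest unused cloud point; these become
*observed* neurons (simultaneously input and output).  The remaining
*hidden* neurons are drawn uniformly without replacement from the unused
points — the subsampling rule from a dense volume mesh is our choice, not a
given.  Neurons i, j are connected iff D_ij ≤ T (default **T = 70 mm**,
boundary inclusive), and every neuron carries a self-feedback edge.  Weights
exist only on these edges; querying a non-edge is an error, distinct from a
zero weight.

20 % of neurons (`frac_inhibitory`, floor-rounded) are inhibitory, acting
through non-positive outgoing weights (clamped after every update).  By
default inhibitory labels are drawn **among hidden neurons only**
(`inhibitory_scope="hidden"`): observed neurons are measurement ports, and
letting a port draw an inhibitory label sign-inverts its injected signal
downstream, making unmonitored-channel read-outs depend on the label
lottery rather than on geometry.  `inhibitory_scope="all"` restores the
uniform draw over everyone.

### Initial weights

The published initialisation (all weights exactly zero) is a provable fixed
point of the W-transposed form of the supervised update, and it leaves
hidden neurons with identically zero input forever.  Defaults therefore
deviate in two audited ways:

* observed rows start uniform in (−`observed_init_scale`,
  +`observed_init_scale`), default 10⁻³, never exactly zero
  (`observed_init="zero"` restores the literal behaviour);
* hidden rows get a small-world-style coupling of ±0.5
  (`hidden_init="smallworld"`, `hidden_init_scale`) **on their observed
  columns only** — excitatory positive, inhibitory negative — so spikes and
  graded activity can propagate from the measured channels into the volume
  from step one.  Hidden-to-hidden edges keep the zero initialisation and
  are grown by STDP alone; seeding them too was tried and produces runaway
  recurrent excitation.  `hidden_init="zero"` restores the literal rule.

## Neuron model

Forward Euler with `n_substeps` = 16 per 8 ms sample (0.5 ms internal step);
the quadratic upstroke is unstable at 8 ms Euler steps.  Within a sample a
neuron spikes at most once: at the first crossing of v_peak = 30 mV it is
reset to (c, u + d) and held for the remainder of the sample, so the
post-step state of a spiking neuron is exactly the reset state, and a
neuron already at/above threshold on entry resets before any integration.
Spike times are resolved at the sub-step.

Parameter heterogeneity (`sample_params`): inhibitory neurons use
a = 0.02 + 0.08r, b = 0.25 − 0.05r, c ~ U(−70, −60), d = 2.  For excitatory
neurons two tables ship: `param_table="canonical"` (default) uses the
standard regular-spiking-to-chattering form c = −65 + 15r², d = 8 − 6r²;
`param_table="paper"` evaluates the published row literally
(c = −5 + 25r, d = 8 − 6r), whose reset then sits at or above the firing
range — kept selectable for auditing, clipped just below v_peak to remain
admissible.

## Supervision signal (desired potential)

Per channel, an adaptive baseline B(t) starts at the signal's global
minimum and relaxes upward with factor α (default 0.5) whenever the signal
exceeds it, otherwise tracking the signal exactly (the unspecified equality
case takes the tracking branch; samples before the global minimum take
B = S).  Sample times with S > B form the spike set X.  The desired
potential holds the signal amplitude sampled at the latest spike time and
decays as e^(−(t−t_s)/σ) between spikes, σ defaulting to the sample period
(8 ms).  Before a channel's first threshold crossing there is no target;
the error is masked to zero there (this also makes "zero input ⇒ zero
cost" exact).  **Targets are computed from the training window only** — in
particular the baseline's global minimum must not see test samples.

For spike-train input (the spike-based realisation), the desired potential
uses a unit held amplitude, since no analog amplitude exists to sample.

## Learning dynamics and scales

The learning rules and the input-current law are evaluated, by default, on
potentials divided by ‖V(t)‖₂ (`potential_scale="normalized"`); on that
scale ‖V‖ = 1 identically and the printed formulas apply directly to the
normalised output the cost is defined on.  Evaluated instead at raw
millivolt scale (`potential_scale="raw"`), the first gradient step
saturates the tanh nonlinearity permanently and the current law emits
currents two orders below the neuron's working range — both measured during
development, which motivated the default.

* **Gradient step**: Δw = η(1 − tanh²(W_i V))e_i v_j/‖V‖ with η the sample
  period expressed in seconds (0.008), decayed harmonically per epoch with
  a 10-epoch half-life (`gdr_eta_halflife`); a constant step keeps the
  weight structure drifting after its useful adaptation is absorbed and
  the epoch cost creeps back up.  The published W-transposed form is kept
  under `gradient="paper"`.
* **Current gain**: the observed input current is multiplied by
  `current_gain` (default 20), mapping the dimensionless current law into
  the Izhikevich input range (the model expects I ≈ 5–10 to leave rest).
* **Leakage**: dθ/dt = E/‖V‖ as printed; θ itself is additionally realised
  as a slow leaky integrator (integration step in seconds, per-step decay
  `theta_decay` = 10⁻³) feeding back into the current with gain
  `theta_feedback` = 0.01.  The output model F = tanh(WV) + θ is additive
  in θ, so θ must influence the membrane and not only through its
  derivative; the leak bounds windup.  At the plasticity-function level the
  pure accumulator (decay 0) remains the default contract.
* **Normaliser scope**: ‖V(t)‖₂ is taken over **all** neurons by default
  (`norm_scope="all"`).  With the observed-only norm, one spiking channel
  moves every normalised output simultaneously; that common-mode term is
  quadratic in the cost and dominates the learnable part.  The
  observed-only norm of the printed cost remains available
  (`norm_scope="observed"`).
* **STDP**: nearest-spike pairing; each spike pair potentiates the forward
  synapse and depresses the reverse one; self-loops are not plastic (a
  self-pair always has Δt = 0 and would potentiate without bound).
  τ₋ = τ₊ = 5000 (τ₋ is unpublished), window 100 ms, A₊ = A₋ = 2·10⁻³.
  The published growing-exponential variant lives behind
  `stdp_sign="paper"`, and the potentiation-only unit-step variant behind
  `stdp_variant="paper16"`.
* **Hidden drive**: hidden neuron h receives Σ_j w_hj s_j(t) (s = spike
  indicator of the previous sample; optionally an exponential synaptic
  trace via `syn_tau_ms`, default 0 because its lag degrades correlation at
  alpha/beta frequencies) plus a graded term
  `hidden_coupling_gain`·(v_j + 65)/10 for observed neighbours
  (`hidden_coupling="graded"`), realising continuous-value transmission
  from the measured channels; plus optional Gaussian background current
  (`hidden_noise_sd`, default 0).

## Protocol

Temporal 70/30 split (earliest samples train).  Training iterates
`epochs` = 50 passes over the training window with membrane states, spike
history, θ and weights carried across epochs (incremental training); per
step the network advances one sample under the current law, the error
against the *next* desired sample is formed, and observed rows (GDR),
hidden rows (STDP) and θ update together.  Free-running prediction freezes
observed weights and leakage (E is undefined), keeps STDP active, and emits
normalised observed potentials.  Unmonitored-channel read-out takes, per
virtual electrode position, the inverse-distance-weighted mean of the
`readout_k` = 5 nearest hidden neurons' potentials over the recorded
window, divided by the time-averaged normaliser (a time-varying normaliser
imprints global activity onto silent neurons); a virtual channel exactly at
an observed neuron's position reads out that neuron.  After training,
`prune_strongest` optionally keeps, per unordered pair, only the direction
with the larger |w| (ties keep i < j; self-loops untouched).

## Evaluation

Both comparison operands pass the identical linear-phase FIR lowpass,
applied forward-backward (zero phase).  The requested 0–70 Hz band is
infeasible at the 125 Hz sampling rate of 8 ms data; edges are then clamped
(passband to 0.88× Nyquist = 55 Hz, stopband inside Nyquist) with a
warning.  Equiripple designs iterate Parks–McClellan upward from a
Bellanger order estimate until the measured response (4096-point grid)
meets the stopband attenuation (80 dB) and passband ripple (0.01 dB);
Kaiser designs bump the kaiserord estimate the same way.  MSE is the time
average of EᵀE on the normalised scale; per-channel error SDs and a
two-sample Kolmogorov–Smirnov comparison per channel (max p reported;
Welch's t-test selectable) complete the metrics.  Spectra are Welch
periodograms.

## Synthetic fixtures

`gen_head_cloud` builds concentric Fibonacci-sphere shells with counts
proportional to shell surface (near-constant nearest-neighbour spacing) —
a stand-in for a BEM-derived volume mesh, deterministic by construction.
`gen_montage_1020` implements the idealised spherical 10–20/10–10
construction: midline electrodes on the nasion–inion arc at 18° steps, the
outer ring at 72° inclination, interior electrodes as great-circle
midpoints, P9/P10 one step below the ring, idealised earlobe/mastoid
positions; left/right homologues mirror exactly in x.  `gen_synthetic_eeg`
mixes `n_sources` = 2 latent sources (sums of 10 Hz and 20 Hz sinusoids
with random phases, amplitudes 1.0/0.5) into channels, by default through
distance-decaying spatial gains (`spatial_mixing`, length scale 80 mm),
plus white noise of SD 0.1 at 125 Hz sampling.  `gen_spike_fixture` draws
homogeneous Poisson trains.

What passing on these fixtures shows: the learning loop extracts shared
low-rank structure across channels well enough that a held-out channel's
trace can be reconstructed from hidden neurons near its position
(correlation ≈ 0.5 after matched filtering, across seeds), and the
training cost decreases over incremental epochs.  What it does **not**
show: performance on real EEG (no 1/f background, no artifacts, no
nonstationarity, no volume-conduction forward model), nor the absolute
error levels reported for clinical recordings, which depend on data that
is not distributed with the package.

## Problem sizes

The shipped tests and the acceptance script use the full 300-neuron,
500-sample, 50-epoch configuration for the end-to-end run (≈1 minute on one
CPU) and reduced sizes (40–80 neurons, 100–150 samples, 2–5 epochs) for
unit-level checks; determinism is audited at 5 epochs.  These sizes are the
package's own test configuration choices.

## Known limitations

* The supervision signal encodes each channel only at threshold-crossing
  times; between crossings the target is an extrapolation, which bounds
  achievable per-channel fidelity on fast signals.
* Accurate amplitude tracking of unit-scale targets by a unit-norm output
  vector is geometrically impossible when ‖V_d(t)‖ ≠ 1; the achievable
  part is the direction, and the residual norm mismatch is an irreducible
  floor of the printed cost.
* The free-running network is autonomous; without input its trajectory
  reflects the learned attractor, not a forecast conditioned on recent
  samples beyond the carried state.
* Epoch-cost decrease margins are small relative to the cost's absolute
  value: most of the cost is the irreducible floor above.
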