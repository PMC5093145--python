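# Methods

This note records the modeling choices behind `snn-spikesort`: what is
simulated, which constants matter, why their defaults are what they are,
and what the synthetic benchmark does and does not establish.

## Signal model and encoder

The input is a single-channel, uniformly sampled extracellular voltage
trace (default 20 kHz). It is max-abs normalized to [−1, 1] — offline over
the whole trace by default, or causally with a trailing running maximum
(`mode="running"`) for online use; the two agree once the running maximum
has seen the largest excursion.

The encoder is a bank of 32 Butterworth band-pass filters of order 2
(4 poles as realized), centers linearly spaced 100–2000 Hz, passband
`center ± 30 Hz`. Filtering is causal (single-pass `sosfilt`), not
zero-phase: the system targets real-time operation, and acausal filtering
would fake negative latency. Outputs are full-wave rectified.

Two physical facts shape everything downstream:

* **Low-frequency rejection.** Content below 100 Hz (field potentials,
  drift, mains-adjacent interference) passes the bank at < 1 % of the
  band energy of a single spike — spike detection is therefore implicit
  and no amplitude threshold exists anywhere in the pipeline.
* **Ringing.** A 60 Hz-wide band-pass cannot respond faster than the
  time–bandwidth limit allows: the impulse response decays to 1 % of peak
  only after ~41–44 ms (measured; the test suite pins < 50 ms). Claims of
  "few-ms" responses at this bandwidth are not physical. The ringing sets
  the duration of the input-layer burst an event evokes, which in turn
  dictates the lateral-inhibition duration (below).

## Neurons

Both layers use the simplest LIF consistent with three parameters:
exponential leak (`v ← v·exp(−dt/τ) + drive`), hard reset to 0 at
threshold, absolute refractory period during which the state is frozen
and inputs are discarded. Reset-to-zero and exponential leak are
assumptions; the reference tables specify only (threshold, τ_leak,
t_refractory) = (0.1 a.u., 0.2 ms, 4 ms) for layer 1 and (0.58 a.u.,
5.1 ms, 46.1 ms) for layer 2, which are the package defaults.

The simulation is clock-driven at the sampling rate (dt = 50 µs, finer
than every time constant). Layer 1 runs through a compiled kernel whose
semantics are step-for-step identical to the reference `lif_step` (tested
to exact equality, and against analytic exponential bookkeeping at 1e-9
relative). Layer 2 is advanced only at steps that carry input spikes,
using the exact analytic leak between them — bit-identical to the naive
loop because output integrators receive drive only from input spikes and
cannot cross threshold while decaying.

A refractory-boundary convention matters at exact multiples of dt: a step
landing exactly at the end of the refractory window is still refractory
(1 ns grace against float rounding), so a neuron driven at threshold every
step fires with inter-spike interval `t_refractory + dt`.

**Input drive.** Input neuron k receives
`drive = input_gain · amplitude_k · dt` — an amplitude–time integral,
invariant to the clock rate, making `input_gain` a rate constant in
1/s. With the layer-1 threshold fixed at 0.1 a.u. the gain *must* be of
order 10³–10⁴: the quasi-steady integration under constant amplitude `a`
is `gain·a·dt/(1−exp(−dt/τ₁)) ≈ 4.5·gain·a·dt`, and in-band spike
transients reach a ≈ 0.05–0.09 after normalization. The default
`input_gain = 16000` was tuned once — the same role the manually tuned
front end plays in the reference system — so that each event drives 1–3
spikes per in-band channel (layer-1 activity mirrors band energy) while
band-passed background noise (≈ 0.004 amplitude) stays an order of
magnitude below threshold. A unit gain with this drive definition would
leave layer 1 permanently silent.

**Synaptic drive.** An input spike delivers `weight · synaptic_gain` to
every eligible output integrator. `synaptic_gain = 0.15` makes an
*untrained* network (mean weight ≈ 0.5) marginally excitable by a full
burst (~15–30 weighted spikes against the 0.58 threshold) — necessary for
the initial random firing that bootstraps learning — while a trained
pattern (weights → 1) crosses threshold within ~4 ms of event onset.
Raising it to 0.2 was observed to let partially potentiated neurons fire
on burst residuals and split classes; lowering it stalls learning of the
weaker unit.

## Synapses

A weight is n = 10 binary devices in parallel. State resistances are
log-normal: median 25 kΩ (LRS) and 250 kΩ (HRS) — a one-decade window —
with log-spreads 0.3 and 0.5 (variability grows with resistance). These
four numbers are calibration constants standing in for measured
distributions that exist only as figure panels in the literature; they are
configurable in the `synapse.distribution` section. Every programming
pulse re-samples the target-state resistance (cycle-to-cycle variability)
and is charged to the ledger even if the device was already in the target
state — a physical pulse is a physical pulse. Devices start LRS with
probability 0.5, giving initial weights ≈ 0.5 and random initial output.

The normalized weight is `(G_total − G_min)/(G_max − G_min)` with
G_min/G_max the all-HRS/all-LRS sums at the distribution medians, clipped
to [0, 1]. With zero spread the weight takes exactly the n+1 values k/n;
with spread it is only approximately discrete.

Energetics: set 75 pJ (2.5 V × 30 µA × 1 µs), reset 45 pJ (1.5 V
magnitude), read `V²·G·t` at 0.1 V / 1 µs — 0.39 pJ at 25.64 kΩ, so read
energy is dominated by devices in LRS. Reads are booked per device of
every synapse a pre-spike touches (the weight must be sensed to deliver
current), i.e. `n_output × n_devices` read events per input spike,
independent of learning.

## Plasticity and winner-take-all

On each post-synaptic spike, for every input i with pre-post delay
Δt = t_post − t_pre(i): if Δt < t_LTP each HRS device of synapse i→winner
is set with probability p_set, otherwise (including inputs that never
spiked, Δt = ∞) each LRS device is reset with probability p_reset. The
per-device Bernoulli choice — rather than one coin for the whole synapse —
is what produces gradual multi-level LTP/LTD from abrupt binary devices;
the expected LRS fraction after k potentiation events from all-HRS is
`1 − (1 − p_set)^k` (verified by Monte-Carlo within 3 SE).

Lateral inhibition is realized as deterministic winner-take-all: within a
time step, among eligible outputs at or above threshold the one with the
largest integration fires (ties to the lowest id); every other output is
reset to zero and inhibited for `inhibition_s`. At most one output spike
can occur per step.

* `t_LTP = 10 ms` spans a 1–2 ms spike plus the leading filter transients.
* `inhibition_s = 35 ms` must cover the *whole* input burst an event
  evokes (set by the ~40 ms filter ringing, not by the spike itself).
  With short inhibition (e.g. 5 ms) a second neuron reliably fires on the
  burst residual, potentiates on the same pattern and becomes a duplicate
  class — observed as a near-1:1 shadow of the true responder. The cost
  of long inhibition is that a different unit's event landing inside the
  window is missed (~10 % of events at 3 Hz rates), which bounds attainable
  recognition below 1.
* `p_set = 0.3, p_reset = 0.05`. The reference constants were optimized by
  a genetic algorithm and never published. The package targets the
  desk-scale benchmark (0.1× time), where a unit contributes only ~70–200
  events in total; p_set = 0.3 lets a selective neuron saturate within
  roughly ten of its events — the same *fraction* of a unit's presence as
  the slow-learning regime occupies at full scale. At p_set ≥ 0.5
  single-event potentiation becomes strong enough for class splitting;
  at 0.1 the learning transient consumes most of the scaled recording.
  Both probabilities (and t_LTP, and the output-layer LIF triple) are
  exposed to the GA module, which reproduces the original tuning
  procedure: ≤ 20 % multiplicative mutation, four winners per generation,
  variation halved when the best fitness improves by < 1 %.

## Synthetic benchmark

The generator emulates paired extra-/intracellular validation recordings:
the trace is a linear superposition of per-unit templates at Poisson event
times (thinned by a per-unit refractory dead time), white Gaussian noise
(σ = 0.05 against unit-normalized template peaks), and a 0.1-amplitude
20 Hz interference sinusoid; a 1/f ("pink") noise option emulates noisier
in-vivo recordings. Event times are returned exactly — the synthetic
intracellular ground truth.

Default world: two units at 3 Hz each (tens of events per 10 s);
template A a 2.2 ms Gabor packet at 1.5 kHz carrier, template B a 2.4 ms
Ricker wavelet (spectral peak ~0.64 kHz, relative amplitude 0.8); band
fingerprints nearly disjoint (cosine similarity ≈ 0.1). An early design
used a 1 ms biphasic pulse for A, but so short a transient spreads its
energy almost uniformly across all 32 bands and has no usable fingerprint;
the Gabor packet is an equally realistic extracellular waveform with a
concentrated one. The per-unit refractory period is 50 ms: tonically
firing units at ~3 Hz rarely produce shorter intervals, and the output
layer's fixed 46.1 ms refractory presupposes such statistics (a same-unit
interval shorter than it is unrecognizable by construction).

The staged protocol mirrors the three-phase structure of the reference
experiment at 0.1× scale: 68.1 s total, unit B present throughout, unit A
only in [28.5 s, 54.5 s]. The sorter must latch onto B unsupervised,
discover A mid-run, and leave A's neuron silent afterwards.

**What a green benchmark establishes — and what it does not.** Passing
shows the closed loop works: implicit detection, fingerprint encoding,
unsupervised class formation, stable binding, and energy accounting, under
noise and event collisions. It does not establish performance on real
tissue: the synthetic world has stationary templates (no electrode drift
or bursting amplitude modulation), only two units, Poisson timing, and a
known noise law. Recognition rates on it (~0.88–0.97) are not comparable
to figures reported for any real recording.

## Evaluation definitions

A ground-truth event at t is *recognized* if the assigned neuron spikes in
the half-open causal window (t, t + 20 ms] — a spike exactly at t does not
count. Rates are computed per 10 s bin as recognized/total events in the
bin; bins without events are excluded, so the mean starts at the unit's
first occurrence. Unit→neuron assignment is greedy and injective by
matched-event count (ties to the lower neuron id), emulating post-hoc
identification against an intracellular reference. Precision/false-positive
measures are deliberately not part of the headline surface (recognition is
the reference metric); the raw trains are returned for any further
analysis. The system report divides total synaptic energy by the signal
duration for power; per-device endurance is the mean set/reset count per
device scaled linearly to a 10-year horizon (3.1536e8 s).

## Numerical and degenerate-case choices

* Zero leak time constants are rejected at construction rather than
  special-cased.
* Filter passbands falling at or below 0 Hz or at or above Nyquist are
  clipped into range with a warning; a configuration whose band centers
  reach Nyquist is an error.
* An all-zero trace normalizes to itself; a silent network yields an
  empty assignment with a warning and an unbounded data-reduction ratio,
  reported as infinity.
* All randomness flows from one master seed through named substreams
  (synapse initialization, STDP coins, synthetic data), so reruns are
  bit-identical; the GA discards non-finite fitness values with a warning
  instead of crashing.

## Known limitations

* Single-channel input only; no tetrode/array encoding.
* Two network layers; no synaptic or axonal delays, no inhibitory
  plasticity, no adaptive thresholds.
* The OxRAM model is behavioral (binary states + sampled variability +
  pulse energies); it does not model forming, IV characteristics, current
  compliance dependence, or gradual single-device switching.
* The recognition metric is recall-like by design; a neuron could in
  principle inflate it by firing densely (the winner-take-all refractory
  and the reported activity counts are the practical guard).
* At 0.1× scale the learning transient and event-collision losses weigh
  ~10× more heavily in the per-bin mean than they would at full scale;
  desk-scale recognition figures are therefore conservative in structure
  but not comparable across scales.
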