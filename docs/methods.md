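# Methods

## The model family

`thetaflex` simulates six single-compartment Hodgkin–Huxley oscillator
models of cortical theta (~7 Hz) rhythm generators, named **M, I, MI, MS,
IS, MIS** for the hyperpolarizing ("inhibitory") currents each contains:

* **M** — the m-current `I_m = g_m n (V − E_K)`, a slow non-inactivating
  potassium current whose activation time constant peaks at ~43 ms near
  −26 mV.  Together with the persistent sodium current `I_NaP` it produces
  theta-frequency subthreshold oscillations (~7.5 Hz in the spike-free
  reduced model).
* **I** — feedback synaptic inhibition from a somatostatin-like (SOM)
  interneuron: rise 0.25 ms, decay 50 ms, reversal −95 mV.  The SOM cell is
  held just below threshold by a constant −0.95 holding current and spikes
  one-to-one with the RS (regular-spiking pyramidal) cell through a fast
  excitatory synapse.
* **S** — a "super-slow" calcium-activated potassium current
  `I_KSS = g_KSS q (V − E_K)`.  Its gate `q` opens at rate
  `α_q = min(0.1 Ca, 1)` and closes at `β_q = 0.002 /ms` (500 ms decay).
  Calcium enters through a high-threshold Ca current during spikes and
  burst plateaus, so `q` builds up over ~150 ms of strong driving and
  introduces a delta-timescale pause into the dynamics.

All cells share the same spiking backbone (fast Na, delayed-rectifier K,
leak); only the leak conductance and the tonic drive differ between models.
Voltages are in mV, time in ms, conductances/currents in the consistent
per-area units conventional for such models.

### Calibration

Two quantities are not fully determined by the model equations and are set
by calibration, once, as part of the model definition:

* **Tonic drive.**  The defining property of the family is that every
  variant fires tonically at 7 Hz, so the models can be compared at matched
  intrinsic frequency.  Each model's drive magnitude was set by bisection
  on its F-I curve (rate over the final 5 s of 6 s noisy simulations,
  averaged over seeds) and frozen in the model table: M 7.382, MI 7.182,
  I 8.173, IS 10.011, MIS 9.091, MS 8.670.  The drive ramps up linearly
  over the first 500 ms and carries a white-noise component of proportion
  0.25 (increments N(0,1)/√dt — unit-spectral-density convention).
* **Calcium buffer.**  `dCa/dt = −φ·I_Ca − Ca/τ_Ca` with φ = 0.001 and
  τ_Ca = 160 ms.  This pair was chosen (scanning φ × τ_Ca with the drive
  re-calibrated at each candidate) so that in model MS the `q` gate rises
  by ~0.3 in ~150 ms during a strong input pulse and relaxes over a few
  hundred ms, while tonic spiking leaves it oscillating mid-range
  (~0.33–0.47) with headroom to build up.  Larger φ·τ_Ca saturates `q` at
  rest and removes the buildup that drives flexible phase-locking.

### Numerics

Fixed-step explicit Euler (Euler–Maruyama for the additive noise) at
dt = 0.01 ms.  Rate-form gates are converted to steady-state/time-constant
form; removable singularities in the rate functions are evaluated by their
limits; gates are clipped to [0, 1] against stochastic Euler overshoot.
Spikes are upward 0 mV crossings with a 2 ms refractory period and
linearly interpolated times.  Halving dt moves noise-free spike times by
< 0.5 ms over 3 s (regression-tested).  A blow-up guard (|V| > 200 mV)
raises `IntegrationError` naming the step.

## Stimuli

Periodic pulse trains are smoothed square waves: an indicator of width
`w(s−1)/s` convolved with a Gaussian `exp(−(st/w)²)`, width
`w = 1000·d/ω` ms, duty cycle d = 1/4, squareness s = 25.  Quasi-rhythmic
trains draw each pulse's frequency, duty cycle, shape, and onset offset
uniformly from intervals that widen along a 20-row "bandwidth" ladder
(1 Hz → 13.35 Hz, centered on 7 Hz); the printed rows are interpolated
linearly, with integer rounding of the shape bounds.  Every train is
normalized so that its **mean injected current equals the gain** — the
total integrated input is the same at every frequency, and a gain of g
delivers g/f charge units per cycle.  Pulse supports (onset/offset at 1%
of peak) are recorded for the piecewise-linear phase construction.

## Phase and phase-locking

* Periodic inputs: phase = angle of a complex Morlet convolution (7 cycles)
  at the input frequency; half a wavelet is discarded at each edge.
* Quasi-rhythmic inputs: piecewise-linear phase advancing π/2 across each
  pulse support and 3π/2 across each gap (one cycle per pulse).
* Envelope inputs: the three most powerful multitaper spectral peaks
  (Thomson method, NW = 4, 7 tapers, peaks ≥ 2 Hz apart) inside the theta
  band (3–13 Hz) define the oscillatory modes; the envelope is convolved
  with Morlet wavelets at those frequencies and the phase is the angle of
  the summed complex series.  (Restricting to the theta band implements
  the intent of skipping the dominant delta-band bulk peak of natural
  speech envelopes, and behaves identically when such a peak is present.)

Entrainment is the spike-rate-adjusted PLV,
`PLV = (n|MRV|² − 1)/(n − 1)` with `MRV = mean(exp(−iφ(t_spike)))`, whose
expectation is ~0 under uniform phases at any spike count.  "Appreciable
locking" means PLV ≥ 0.5 with ≥ 0.9 spikes per input cycle (the
spikes-per-cycle clause is dropped above the intrinsic frequency, where
locking legitimately occurs with fewer spikes than cycles).  Sweeps use
30 s simulations, 3 seeds per cell, and majority vote.

## Delay probe and mechanism analyses

A single pulse (one summand of the periodic train, integral gain×4×width)
is triggered by the first spike after a 2 s transient; the matched
no-pulse run shares the noise path.  The delay D from pulse onset to the
first post-pulse spike predicts locking at frequency f iff 1/f ≤ D; a
pulse of width w stands in for the f = 1/(4w) periodic train.  For the
synaptic-inhibition model the prediction has the closed form
D = (1/4f) + 1/7, binding at f* = 5.25 Hz.

The prediction is exact for cycle-skipping but conservative near the
boundary: under sustained rhythmic forcing the super-slow current
accumulates across cycles (so a lone pulse underestimates MS's
flexibility at low gain), and conversely a model can hold PLV ≥ 0.5
slightly below the predicted limit by emitting its clock-reset spike at a
consistent phase each cycle (model I at strong gain).  Agreement between
the predicted and directly measured lower locking limits is within one
0.5 Hz grid step for models M and MS; for model I the direct criterion
admits such a stable two-phase pattern half a step below the analytic
bound, and the residual discrepancy is one additional grid step.

Pre-spike analyses sample the full state one integration step before each
detected spike (with first and second backward differences).  The
negative linear relation between pre-spike synaptic-inhibition and
super-slow activations in model IS — slope ≈ −g_SOM→RS/g_KSS ≈ −1 — is
exposed by pooling single-pulse probe trials across gains 1–4 (150 ms
pulses, forced spikes excluded, inhibition gate ≤ 0.1, gross outliers
trimmed at median ± 5 MAD); purely tonic runs instead show a weak
positive co-decay correlation and do not span enough of the (s, q) plane.
Model MS shows no comparable linear relation (R² near 0 versus ~0.2).

## Synthetic speech

The generator emulates the output of a subcortical auditory model applied
to read speech: 16 channels (0.1–3.29 kHz labels) of non-negative
amplitude envelopes with 1 s of pre-speech silence.  Each syllable is a
consonant interval (35% of its duration) followed by a vowel; the vocalic
nucleus is a Gaussian bump centered exactly at the syllable midpoint,
with cross-channel amplitude unimodal around the designated mid-vocalic
channel; consonants add weaker, higher-channel transients.  Syllable
durations are lognormal (median 1000/rate ms, σ = 0.3 by default).  The
envelope set is normalized like the pulse trains: the peak channel
carries unit mean input over the speech period before the gain is
applied.  What this surrogate does **not** model: formant structure,
coarticulation, channel-specific temporal fine structure, pauses, or any
corpus statistics — passing tests show the pipeline recovers structure
the generator planted, not performance on real speech.

## Segmentation

16 parameter-identical, unconnected copies of a model are driven by the
16 channel envelopes.  Their spike trains are convolved with a causal
exponential (decay w_s/5), summed, and smoothed with a unit-area Gaussian
(σ = 25/4 ms); boundaries are upward crossings of
`p* = r_thresh · max P` over the pre-speech second, pruned by a 25 ms
refractory rule.  Boundaries are scored against transcription syllable
midpoints with the Victor–Purpura distance (shift cost |Δ|/τ, insert and
delete cost 1, τ = 50 ms), normalized as `D = log(d / #matches)` where
matches are sub-unit-cost shifts on an optimal path (ties broken toward
more matches; d = 0 and zero-match cases are flagged ±∞ and excluded
from means with a count).  `(w_s, r_thresh)` is optimized by exhaustive
search over {25, 30, …, 75} × {1/3, .4, .45, .5, .55, .6, 2/3} of the
minimum-over-gains mean D.

The end-to-end recovery experiment drives model MS with noise-free 5 Hz
sentences configured as a mid-vocalic **sub-band**: all 16 channels carry
substantial vocalic energy (profile width 6 channels), narrow nuclei
(σ = 10% of syllable duration), weak consonant transients (0.2), duration
jitter σ = 0.15, gains {0.6, 0.8, 1.0, 1.2}.  At the optimum the mean
D_VP,50 is ≈ −0.34: every derived boundary matches a distinct syllable
midpoint within 50 ms, and the boundary phoneme distribution is
vowel-dominated.

## Problem sizes

Defaults used by the test suite and the reproduction script: 30 s sweeps
with 3 seeds per cell on reduced grids ({1, 1.5, …, 7} Hz and 3–4 gains);
6 s runs for rate calibration; 5 probe seeds per delay cell; 3 sentences
of 10 syllables for segmentation.  These sizes give stable majority votes
and sub-0.1 Hz rate estimates; larger grids (the full 0.25–23 Hz × 41-gain
sweep) are available through the CLI.

## Known limitations

* Printed-table drives reproduce 7 Hz only approximately in this
  implementation (each model sits on the steep part of its F-I curve), so
  drives are re-calibrated; all conductances and kinetics are as printed.
* The input gain scale is defined by the mean-current normalization; at
  gain 4 the forcing is strong relative to the tonic drive, and locking
  regions extend ~0.5 Hz below their weak-forcing boundaries.
* The quasi-rhythmic phase is extrapolated at the mean cycle rate beyond
  the last pulse; spikes there contribute slightly noisier phases.
* Segmentation quality degrades gracefully with envelope noise and
  duration jitter; the recovery guarantee (D < 0) holds for the noise-free
  sub-band protocol above, not for arbitrary generator settings.
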