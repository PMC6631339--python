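# Methods

## Signal model and processing chain

The pipeline treats the EEG as a sum of band-limited rhythm oscillations
plus broadband background activity, observed through a 10-bit ADC at a
nominal 100 Hz.  All analysis is time-domain: the state discriminator is
the vector of per-band mean absolute amplitudes, not a spectrum.

A rolling buffer holds the most recent 1000 samples (10 s).  At each
logging tick (10 Hz) the buffer window is mean-subtracted and passed
through a band-pass filter bank; the five feature amplitudes (alpha,
beta0, beta1, beta2, delta) feed the classifier.  Gamma as usually quoted
(32–100 Hz) exceeds the 50 Hz Nyquist limit of the stream, so the band
table clips it to 32–45 Hz and the feature vector excludes it.

## Filter bank

Default mode is a linear-phase windowed-sinc FIR (Hamming window, 401
taps at 100 Hz) per band.  Linear phase keeps the band traces mutually
time-aligned and makes the delay through the filter exactly
(taps − 1)/2 = 200 samples = 2 s.  An alternative 4th-order Butterworth
IIR mode (second-order sections) is provided; both modes satisfy the same
response contract, checked against a direct-DFT oracle in the tests:
gain within ±1 dB at the band centre, at least 20 dB attenuation at DC
and Nyquist, and no sidelobe above −15 dB outside a 2 Hz transition
region.  (The Butterworth response is monotone and therefore has no
sidelobes; near the transition edge its *rolloff* has not yet reached
−15 dB, which the contract deliberately permits.)

The beta sub-band edges are a repository convention: beta0 = 13–16 Hz
(low-beta gap filler), beta1 = 16–23 Hz, beta2 = 23–31 Hz, a contiguous
partition of the conventional 16–31 Hz beta range.  All edges are
config-overridable.

## Amplitude estimation and feature latency

"Average amplitude" is the mean absolute value of the DC-removed filtered
trace.  Two windowing choices matter:

* the first (taps − 1) output samples of each windowed filtering are a
  startup transient and are discarded;
* the amplitude is averaged over the **trailing 2 s** (200 samples) of
  the remaining steady-state output, not the whole buffer.

The second choice is deliberate: the pipeline is an online detector.  The
causal filter output lags the input by the 2 s group delay, and every
extra second of averaging adds half a second of effective latency.
Averaging the full window would give the feature an effective lag of
about 5 s — half a 10 s marker interval — which demonstrably destroys the
state information (the whole pipeline drops to chance).  With the 2 s
trailing span the feature reflects the input interval [t − 4 s, t − 2 s],
an effective latency of 3 s.

That latency is accounted for during training: warm-up feature vectors
are labelled with the marker state at `t − 3 s` (filter group delay plus
half the amplitude span; `SessionConfig.label_latency_s`, computed from
the bank by default, 0 to disable).  Without compensation roughly half
the warm-up labels contradict what the features encode, and high-capacity
trainers memorize the contradiction instead of learning the amplitude
rule.  Predictions are still logged and scored against the *current*
marker, so the latency bounds attainable accuracy at roughly
1 − 3 s/10 s ≈ 0.70 on well-separated synthetic data; reported
accuracies close to 0.70 mean the classifier is at that protocol ceiling.

## Networks and trainers

Logistic-sigmoid units throughout; output thresholded at 0.5, ties
mapped to state 0.  Weights and biases initialize uniformly in
[−0.5, 0.5] from a seeded generator; the seed is a required session
parameter.  The single-layer 5-1 structure is used by the
error-correction rule, 5-6-6-1 by the gradient-based trainers.  Loss is
the mean squared error on the sigmoid output, matching the classical
formulations of the four algorithms.

Defaults (all config-overridable): 50 epochs per training call with early
stop at MSE < 0.01; learning rate 0.5 for backprop and the perceptron
rule; Rprop⁻ constants η⁺ = 1.2, η⁻ = 0.5, Δ₀ = 0.1, Δ ∈ [10⁻⁶, 50] (the
canonical published values), with the update skipped on a gradient sign
flip; Levenberg–Marquardt damping λ₀ = 10⁻³, ×10 on a rejected
(SSE-increasing) step, ×0.1 on an accepted one, at most 5 escalations per
epoch before the run is declared stalled.  A singular damped normal
matrix escalates λ rather than raising.  Gradients and the residual
Jacobian are verified against central-difference oracles in the tests;
the λ = 0 LM step on a linear network is verified against the closed-form
least-squares solution.

Backprop at these defaults underfits the 500-pair warm-up set (it
typically leaves the output near-constant, scoring exactly 0.5 on the
balanced marker track).  This is the honest behaviour of plain batch
gradient descent at a 50-epoch budget, not a defect; the trainers are
deliberately left as their classical formulations (no momentum,
regularization or validation machinery).

## Session protocol

Markers alternate states every `interval_s` (default 10 s), state 0
first: `state(t) = ⌊t/interval⌋ mod 2`.  Tone frequencies (1500 Hz ↔
state 0, 1000 Hz ↔ state 1) are metadata carried in log headers; no audio
is synthesized.  Feature sampling starts once the buffer first fills
(10 s) and runs at the logging cadence.  Training happens once, at the
60 s mark, on the z-scored warm-up features (normalization statistics are
frozen thereafter); continued online retraining is available behind
`continue_training` but off by default, matching a train-once protocol.
Evaluation drops rows before 60 s and within 10 s of the end and scores
the centred 400 rows (an odd surplus drops the extra row at the head).

## Synthetic EEG generator

Each band contributes a sinusoid whose frequency is drawn uniformly
inside the band, re-drawn at every marker interval with phase continuity;
the amplitude switches with the marker state.  Pink (1/f) noise — closer
to EEG background than white noise — is generated by spectral shaping of
seeded white noise and scaled to a standard deviation in ADC counts
(default 10).  The sum rides on a baseline of 512 counts and is rounded
and clipped to [0, 1023]; a configuration whose clipping rate would
exceed 0.1% is rejected.

Preset effect sizes are repository choices — no quantitative effect
magnitudes exist for the original subjects: `eo_ec_alpha` doubles alpha
(30 → 60 counts) in state 1; `task_beta` multiplies the beta sub-bands by
1.5 and alpha by 0.7; `null` is state-independent.  Baseline amplitudes
(delta 20, alpha 30, beta ~10, gamma 5 counts) are set so the band
structure is visible above the noise floor without clipping.

What the generator does *not* emulate: eye blinks, EMG bursts, sleep
spindles, slow nonstationarity, electrode drift, mains hum, or any
subject-to-subject variability.  Passing tests on this generator
demonstrate that the pipeline recovers known, stationary band-amplitude
effects through its own acquisition, filtering, training and scoring
machinery — not that it would reach the same accuracy on live recordings,
where reported accuracies for this class of hardware sit near 0.5–0.66.

Because the per-interval frequency draw interacts with the band-edge
rolloff of the filters (a draw near an edge is attenuated up to ~50%),
effect-size checks in the tests compare amplitude-swapped models under
the same seed, which equalizes the drawn frequencies and isolates the
amplitude effect.

## Numerical and degenerate-input conventions

* FIR filtering is evaluated by FFT convolution (identical to direct
  convolution within ~10⁻¹⁰ absolute) and requires the window to be at
  least as long as the filter.
* A zero-variance window yields all-zero amplitudes; the alpha/raw ratio
  (×1000) returns NaN rather than raising when the raw amplitude is 0.
* Flat features (zero warm-up variance) get a normalization SD of 1, so
  a constant source degrades gracefully to a constant predictor.
* Log files store times with shortest-round-trip float repr, making
  write→read an exact identity.
* Session runs are bit-identical given (source, config): the only
  randomness is the seeded network initialization and the seeded
  generator.

## Problem sizes

The standard battery used by the tests and the acceptance script is ten
sessions per condition, each 110 s at 100 Hz (11000 samples, 500 warm-up
pairs, 400 scored rows), chosen to match the session protocol while
keeping a full four-algorithm comparison battery comfortably fast on one
CPU core (~1 s per session).

## Known limitations

* The serial frame dialect is this repository's convention; original
  hardware used an undocumented framing, so only the replay and synthetic
  paths are faithful end-to-end.
* The ~0.70 protocol ceiling means algorithm comparisons on
  well-separated synthetic data compress: every competent trainer
  saturates, and mean differences between Levenberg–Marquardt, Rprop and
  the perceptron rule are at the level of seed noise.  On `task_beta` the
  state effect is linear in the five features, so even the single-layer
  perceptron separates it well above chance.
* The IIR mode's group delay is approximated as zero for latency
  compensation; at the default bands the passband delay is a few tens of
  milliseconds, negligible against the 10 s intervals.
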