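# Methods

`smrbci` implements a four-class mental-imagery BCI pipeline of the kind
used in cue-based sensorimotor-rhythm (SMR) decoding: band-limited EEG
oscillations over motor and parietal cortex drop in power (event-related
desynchronization, ERD) while the user performs a mental task, and a
decoder turns those power changes into discrete commands for a pad-race
game.  Because no subject recordings ship with the package, a synthetic
EEG generator provides ground-truth data with the statistical structure
the pipeline assumes, so every stage — and the closed loop as a whole —
can be tested quantitatively.

## Synthetic EEG model

Each channel is a linear mixture of band-limited oscillatory sources plus
independent 1/f-shaped background noise:

    x_c(t) = sum_s M[s, c] * g_s(t) * u_s(t) + n_c(t)

* `u_s` — unit-variance band-limited noise (4th-order Butterworth-filtered
  white noise) representing an idling rhythm; default sources are mu
  (8–16 Hz) and beta (16–30 Hz) pairs centred on C3, Cz and Pz.
* `M` — the sources × channels mixing matrix (default: weight 1 at the
  centre electrode, 0.5 at its four 2.5 cm neighbours).  No volume-conductor
  forward model is computed; the mixing is a free parameter.
* `g_s(t)` — a power envelope.  ERD of fractional depth `d` (> −1, negative
  = desynchronization) multiplies source power by `1 + d` during the
  imagery window, i.e. amplitude by `sqrt(1 + d)`, with 250 ms
  raised-cosine ramps so the modulation itself creates no broadband
  transients that would trip the artifact gates.
* `n_c` — Gaussian noise with power spectral density ∝ 1/f^slope
  (default slope 1, total SD 10 µV), synthesized by FFT shaping.

Default conditions: 512 Hz sampling, a 32-channel montage containing
C3/Cz/C4 with four close orthogonal neighbours each (for 5-point Laplacian
derivations), AFz, and frontal/parietal coverage; classes HAND, FEET, SUB
(mental subtraction) and REST; ERD depth −0.5 in both bands for each
non-rest class over its own topography.  Source amplitudes (mu 10 µV RMS,
beta 6 µV RMS) are set so that the idling rhythms dominate the in-band
background (roughly 9:1 in band power at the centre electrode) while peak
amplitudes of clean EEG stay well below the ±100 µV rejection threshold —
both properties of real SMR recordings.  The pilot studies this design
emulates did not publish effect sizes, so the depth −0.5 is a plausible,
deliberately strong modulation; results on synthetic data bound what the
pipeline can do when its assumptions hold exactly and say nothing about
any particular subject.

Calibration sessions follow the cue-based timing: fixation at −3 s, cue at
0, 5 s imagery, 2–3 s inter-trial break drawn uniformly (the protocol
states the range but no distribution), classes pseudorandomized with exact
per-class counts, and a 30 s resting baseline opening each session.  Race
training streams alternate 5 s task / 5 s rest per 10 s pad; rest pads are
unmodulated.  Artifacts are injected with ground truth: blinks as 0.4 s
raised-cosine transients, frontal-dominant and maximal at AFz; steps as
sustained baseline shifts.  What the generator does *not* emulate: EMG/ECG
contamination, electrode drift and popping, inter-subject topography
variability, and non-stationary feature drift between sessions — the
failure mode that most affects real online use.

## Preprocessing

Butterworth IIR filters (SOS form), causal or zero-phase (forward-backward,
effective order doubled); the online pipeline is strictly causal so
training and feedback share filter characteristics.  The notch is a
2nd-order IIR at 50 Hz, Q = 35.  Trial rejection applies three criteria in
a single pass over the original set: amplitude beyond ±100 µV (applied to
the filtered data, since unfiltered drift would dominate), per-channel
Gaussian joint log-probability, and mean kurtosis, the latter two z-scored
across trials with a two-sided 4 SD threshold.  Variance normalization
divides each channel by its SD over the session's resting segment,
reducing the influence of high-variance channels before pooling trials
across sessions.

## ERD/ERS maps

Graz-style bandpass–square–average estimator: per 2 Hz-wide bin (stepped
1 Hz over 2–40 Hz), causal 6th-order bandpass, squaring, trial averaging
and a 250 ms moving average; values are percent change against the mean
power in the −2…−1 s pre-cue reference.  Trials are reflect-padded by 2 s
before filtering so narrow-band filters are settled by the reference
interval (without padding the reference power is biased low and the whole
map biased positive).  Significance: percentile-t bootstrap over trial
resamples in which *both* the activity and the reference power are
recomputed per resample; per bin the studentized statistic
`(v* − v)/se*` inverts to a CI, masked where the CI excludes zero.  No
multiple-comparison correction is applied beyond the per-bin test; on null
data the significant-bin fraction sits at the nominal level (checked by
simulation).

## Features: shrinkage CSP + log band power

One-vs-one CSP per frequency band.  Class covariances are averages of
per-trial covariances (trace-normalized by default, making trial weights
robust to amplitude fluctuations; exact invariance of eigenvalues under
invertible channel mixing holds with `trace_norm=False`), shrunk toward
scaled identity `Σ̂ = (1−γ)Σ + γ(trΣ/C)I`, with γ either fixed or
Ledoit–Wolf ("auto").  Filters solve `eigh(Σ̂_A, Σ̂_A + Σ̂_B)`; eigenvalues
are class-A variance ratios in [0, 1]; the two largest and two smallest
eigenvalues' filters are retained, so the feature dimension is
`pairs(k) × 4 × bands` — 48 for four classes and two bands (8–16, 16–30 Hz),
24 for one band, 12 for three classes and one band.  Sign convention: each
filter's largest-magnitude coefficient is positive.  Features are natural
logs of the squared projections averaged causally over the trailing 1 s
window at every sample, floored at 1e−12; the first second uses a growing
window and is flagged as burn-in.  The online processing order is
band-filter → resting-variance normalize → CSP project.

## Classification and evaluation

Shrinkage LDA: pooled within-class covariance shrunk toward scaled
identity (γ fixed or Ledoit–Wolf), equal priors (designs are balanced),
probabilities via softmax over the linear discriminant scores.  At γ = 0
decisions coincide with classic LDA; at γ = 1 with nearest class mean —
both used as test oracles.

Evaluation is repeated stratified k-fold CV (default 10×5) with *all*
label-dependent fitting (CSP, sLDA) inside training folds; band filtering
is label-independent and precomputed.  Accuracy is traced at every sample
of the trial; the peak and its latency are reported with SD across folds.
Trial-level accuracy uses majority voting over the 1–4 s feedback window,
with strict majority required — an exact tie, or a plurality short of half
the window, counts as incorrect, which places the null trial accuracy for
four classes *below* 1/4 (the per-timepoint accuracy curve is the 1/4
quantity).  Confusion matrices are row-normalized percentages.  The
above-chance threshold is the upper bound of the adjusted Wald
(Agresti–Coull) binomial CI at p = 1/k, alpha = 0.05; it is calibrated for
a single accuracy number (the permutation test exceeds it in ≤ alpha of
runs), not for the maximum of an accuracy curve over thousands of
correlated time points, which needs larger trial counts before the same
bound applies.  Task-combination ranking runs the CV for every k-subset of
a task pool (C(8,4) = 70) and sorts by peak accuracy, with the median of
the curve over 1–4 s as a secondary statistic.

## Online decisions and artifact gating

Class probabilities are averaged over a trailing 1 s window; at each
decision tick (16 Hz = every 32 samples at 512 Hz; the source protocol
does not state a rate) the highest averaged probability among classes
exceeding their class-specific thresholds is emitted; exact ties emit
nothing, and an emitted REST maps to "no command" in the game.  Thresholds
are suggested from a 5×5 CV bias estimate — per class, the mean
probability it receives on other classes' trials plus 2 SD — as a
reproducible stand-in for manual per-class tuning; they remain overridable
in configuration.

Two detectors gate the output (commands forced to none while active):

* Blink gate — 1–10 Hz band power at AFz over a 250 ms window, blocked
  above mean + 3 SD of the same statistic on the session's resting EEG.
  That power is approximately chi-squared with ~4.5 dof (2 × bandwidth ×
  window), so the false-block rate on clean data is ~1–2%, not the 0.13%
  a Gaussian 3 SD tail would give.
* AR gate — per channel, an order-10 autoregressive model fitted on
  resting EEG by Yule–Walker; blocked when the one-step prediction error
  exceeds 3 × its resting SD on any channel (union over channels bounds
  the clean-data block rate at ~32 × 0.27%).  Adaptation, unspecified in
  the source protocol, is implemented as exponentially forgotten
  autocorrelation and error-variance estimates (default 30 s memory)
  updated from unblocked samples only, with the coefficients re-solved per
  250 ms processing block; this keeps slow amplitude drifts from inflating
  the block rate.

The streaming decoder keeps all filter, window and gate state across
blocks, so block-wise processing is sample-exact equal to batch processing
(verified by truncation tests).

## Race simulator

Tracks are pseudorandom pad sequences with exact per-class counts (16 pads
at 4 trials per class, 20 at 5).  Per tick the avatar moves at base speed,
× boost for a correct command on an action pad, × slow for a wrong command
or any command on a rest pad; a command lasts one tick.  No official speed
constants exist for the game this emulates; defaults (base 1 unit/s, pad
11.25 units, boost 2.0, slow 0.5) make a fully passive 16-pad run 180 s
and a perfect run 90 s, bracketing the scale of competitive runtimes —
runtimes are therefore comparable only within this simulator.  The
significance baseline is the median runtime under uniformly random
commands (one of the four classes per tick; REST acts as no command).
Closed-loop simulation co-evolves EEG generation and decoding: at each
tick the stream renders EEG with the modulation of the pad the avatar
currently occupies, the decoder emits a command, and the command drives
the avatar.

## Problem sizes and numerical choices

Tests and the acceptance script run the repeated-experiment studies on a
reduced 16-channel, 128 Hz montage (the generators default to the full
32-channel, 512 Hz setup, which the closed-loop race study uses): the
permutation study uses 100 seeds of a 1×5 CV on 32 trials; the
ERDS-null study 4 sessions × 40 trials with 400 bootstrap resamples; the
race study one decoder calibrated on 20 trials per class, 100 seeded races
against a 500-run random baseline.  Shrinkage "auto" subsamples long
windows to ≤ 20 000 observations for the Ledoit–Wolf estimate.  Degenerate
inputs fail loudly: zero resting variance names the channel, bands at or
above Nyquist are rejected at configuration load, sub-5-trial rejection
and singular unshrunk covariances return warnings/errors rather than
silent results.

## Known limitations

Synthetic linear mixing with stationary sources cannot exhibit the
feature-distribution drift that degrades real sessions; passing the
closed-loop study shows the machinery is correct, not that a given subject
would achieve control.  The EDF writer emits plain 16-bit EDF with 1 s
records (final record zero-padded); reading uses mne.  The AR gate's
block-wise adaptation is one instantiation of an underspecified protocol
step.  The race physics are deliberately minimal (no bot opponents, no
command queuing).
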