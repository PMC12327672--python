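# Methods

This note documents the models, numerical choices, and limitations behind
`eegflow`, in the order data flows through a pipeline.

## Conventions

Amplitudes are microvolts throughout; readers convert on load.  Sample
indexing is 0-based; epoch windows are half-open `[start, end)` in time and
samples.  Onset-to-sample conversion uses `floor`, window length uses
`round` — a documented deterministic tie-break for windows that are not an
integer number of samples.  Acquisition latency is modeled as a single
scalar offset added to every event onset (a constant network/driver delay
between stimulus timestamps and the recording clock); per-event jitter and
clock drift are out of scope.

## Stimulus schedules

An ERP session is cue → buffer repeated `trial_count` times after one
fixation lead-in, so the total duration is exactly
`(cue_time + buffer_time) · trials + fixation_time`.  Whether the buffer
precedes or follows the cue is not observable from the schedule contract;
cue-then-buffer is fixed here.  Class labels are apportioned from
non-negative weights by the largest-remainder method (quota = normalized
weight × trials; floor; leftover seats to the largest fractional
remainders, ties to the lower class index).  This makes counts a pure
function of the weights — a 0.1 : 0.1 : 0.8 three-oddball design over 10
trials always yields 1/1/8 — while the seeded shuffle randomizes order
only.  SSVEP schedules put every flickering stimulus at onset 0 with its
frequency in event metadata; calibration schedules are evenly spaced
"blink" prompts used to record EOG calibration data.

## Synthetic EEG

The generator produces the statistical structure the pipeline stages
assume, not a biophysical forward model (no head geometry, no dipoles):

- **Background**: per-channel white Gaussian noise shaped in the frequency
  domain by f^(−β/2) (DC removed), rescaled to sample SD `sigma_uv`.
  Defaults β = 1, σ = 10 µV — typical resting-EEG spectral slope and
  amplitude scale.
- **SSVEP**: Σ_h a_h sin(2π h f t + φ_h) with seeded phases, rejected if
  any harmonic reaches Nyquist.
- **ERP**: a Gaussian bump (peak latency, width, amplitude) added after
  each event onset.
- **Blinks**: a fixed 0.3 s half-sine bump scaled per channel by a known
  mixing vector; the EOG reference channel carries the unscaled bump plus
  1 µV sensor noise.  Real blinks vary in shape and duration; the fixed
  waveform is deliberate so that regression/ICA cleaning can be scored
  against exact ground truth.
- **Class effects** for classification fixtures are variance modulations
  (extra Gaussian noise of chosen SD on chosen channels during the cue
  window) rather than waveform differences, because CSP, covariance and
  RMDM methods operate on second-order statistics; a 15 µV boost over the
  10 µV background gives a log-variance effect size d ≈ 1.2–1.5 per
  epoch.

All injections are additive and every stage is seeded, so output minus
background equals the analytic injected signal and runs are reproducible
bit-for-bit.  Passing tests on these fixtures demonstrates correct
*mechanics* (epoch alignment, unmixing, eigenstructure), not robustness to
real-EEG nonstationarity, electrode drift, or muscle artifacts.

## Channel selection

The relevance criteria need a per-channel scalar per epoch; textbook
definitions leave it open for continuous multichannel data.  We use the log
of the epoch sample variance — the same quantity CSP exploits — which keeps
the four criteria comparable.  Constant channels are floored at 1e−12
before the log and flagged.

- **Correlation**: |R| with integer-coded labels (codes 0..K−1 in sorted
  label order).  Multi-class coding imposes an arbitrary ordering; this is
  a documented limitation, not a recommendation.
- **Mutual information**: plug-in H(Y) − H(Y|X) in bits after
  equal-frequency (quantile) discretization, default 4 bins.  Quantile
  binning is monotone-invariant and robust to heavy tails.
- **Chi-squared**: Σ(O−E)²/E on the binned-scalar × class table; empty
  rows/columns are merged (dropped) with a warning so E > 0.
- **CSP patterns**: the spatial patterns (columns of W⁻¹) are
  source-distribution vectors; each of the m = 4 most discriminative
  patterns (2 per eigenvalue tail) is normalized to unit max-abs and
  weighted by 2|λ − 0.5| before taking the per-channel maximum.  The
  weighting matters: with a single informative source, only one pattern is
  discriminative, and unweighted normalized noise patterns (λ ≈ 0.5) would
  give their randomly-peaked channels the same top score.

Top-n selection sorts descending with ties to the lower channel index.

## Preprocessing

Butterworth filters are designed as second-order sections; offline mode
defaults to zero-phase forward–backward application (squares the magnitude
response — |H| = 1/2 at cutoff instead of 1/√2 — and cancels group delay),
causal mode applies the same design once for streaming use.  The
transition bandwidth is fully determined by order and cutoff, hence exposed
read-only.  Kaiser windowing defaults to β = 8.6 (≈ Blackman sidelobes).
Common-average referencing subtracts the instantaneous channel mean and is
undefined for one channel.  Amplitude rejection drops an epoch when any
sample of any channel exceeds the threshold in absolute value — cheap
enough for online use, effective because ocular artifacts sit far above
background EEG.

EOG regression fits per-channel OLS slopes of mean-centered calibration EEG
on the mean-centered reference, then subtracts b·ref **uncentered**: the
contamination model is additive, and a one-sided artifact (blink bumps)
has a non-zero mean that would otherwise leak back in as a DC shift.

ICA uses seeded FastICA with unit-variance whitening (tolerance 1e−4,
≤ 500 iterations, up to 3 deterministic re-initializations before a
diagnostic error — fixed-point ICA is sensitive to its random start, and a
mixture whose channels are mostly Gaussian leaves the Gaussian subspace
rotation unidentifiable, so non-convergence there is expected rather than a
bug), components ordered by explained sensor variance.  Artifact components are flagged by |Pearson r| ≥ 0.8
against the EOG reference, with an excess-kurtosis > 5 fallback when no
reference exists (blink activations are strongly super-Gaussian); this
correlation rule is a deliberate replacement for trained component
classifiers, which cannot be reproduced from first principles.
Reconstruction attributes the channel-mean vector to components through the
unmixing matrix, so a dropped artifact takes its DC contribution with it;
dropping nothing round-trips the input to 1e−6 and dropping everything
yields zero.  When ICA is used inside a pipeline, the model must be fitted
on data that has passed the same upstream stages (CAR re-mixes channels and
drops rank by one).

## Features

Defaults, all configurable: k_max = 10 (Higuchi), m = 2 and r = 0.2·SD
(approximate/sample entropy; ApEn includes self-matches, SampEn excludes
them), 16 equal-width bins (Shannon), DFA scales log-spaced 4..n/4 with
per-window linear detrending, Hann windows with 50 % overlap (Welch,
coherence, STFT), db4 wavelet in periodization mode (energy-conserving),
canonical band edges delta 1–4 / theta 4–8 / alpha 8–13 / beta 13–30 /
gamma 30–45 Hz.  Kurtosis is excess kurtosis (Gaussian → 0).  Relative
band powers are normalized over the chosen partition and form a simplex by
construction.

CSP solves C_A w = λ (C_A + C_B) w on class-mean covariances built from
trace-normalized per-epoch covariances with shrinkage γ = 0.05 toward the
scaled identity (rank deficiency after channel subsetting or CAR would
otherwise break the eigenproblem).  Filters come from both spectral
extremes; the transform emits log-variances of the filtered epochs.

The phase slope index is Im Σ_f C*(f)C(f+δf) over a band, with coherency
phase defined so that **positive PSI means the first argument leads**; the
sign convention is asserted by a delayed-copy test.

## Riemannian classification

Epoch covariances are shrunk toward (trace/d)·I with γ = 0.05, which
guarantees SPD even for short epochs.  The affine-invariant metric is
computed from generalized eigenvalues; the log-Euclidean metric is offered
as a cheaper configuration alternative.  The Fréchet mean uses the
standard fixed-point iteration (average the logs in the tangent space at
the current estimate, exponentiate back), tolerance 1e−8, max 50
iterations, initialized at the arithmetic mean; commuting inputs converge
to the elementwise geometric mean.  RMDM stores one mean per class and
predicts by nearest mean, ties to the lexicographically smaller label.
Tangent projection vectorizes log(G^−1/2 C G^−1/2) with √2-scaled
off-diagonals, so the Euclidean norm at the base point equals the AIRM
distance — the isometry the tests assert.

The classifier registry wraps seeded scikit-learn estimators (decision
tree, random forest with 100 trees, RBF-SVM with C = 1, Gaussian naive
Bayes) behind one fit/predict call; external models (including deep
networks trained elsewhere) can be registered with a single factory call.
Evaluation uses seeded stratified k-fold (default k = 5) with per-fold
accuracy and the generalized (Gorodkin) multi-class Matthews correlation
coefficient computed from the fold confusion matrix.

## Flowgraph runtime

Pipelines are DAGs of registry nodes with typed ports drawn from a closed
seven-kind algebra (recording, epochs, scores, features, covs, labels,
report), validated structurally before execution: cycles, dangling or
multiply-driven inputs, kind mismatches, and unknown operations are all
reported, and a failing node halts with its id and upstream trace.  Graphs
serialize to versioned JSON and round-trip losslessly.  Offline mode
passes whole datasets in topological order; online mode pulls single
epochs from a stream source (the file-replay adapter emits each epoch as
soon as its window is buffered — timestamps honored, wall clock ignored)
and pushes them through the chain, concatenating at the sinks.  Stateless
chains produce identical per-epoch results in both modes; stateful nodes
(ICA model, CSP, RMDM) must be fitted offline and supplied frozen,
mirroring the calibrate-offline / classify-online workflow.  Buffering is
non-overlapping fixed-length epochs; overlap and backpressure policies are
left to the adapter.

## Problem sizes

Test fixtures use 4–8 channels at 250 Hz: a 60 s blink recording, 200-epoch
channel-selection datasets, 40 trials/class classification sessions (10
seeded replicates), 1000-trial random-SPD property checks, and 200–500
sample entropy oracles — sizes chosen so the full suite and the acceptance
script each run in seconds on one CPU while keeping every statistical
margin wide.

## Known limitations

Synthetic data only validates mechanics (see above).  EDF reading requires
the optional `mne` dependency.  Correlation/MI/chi-squared treat epochs as
exchangeable and ignore temporal dependence between adjacent epochs of 1/f
background.  The regression cleaner subtracts the *measured* reference, so
its residual floor is b·(reference sensor noise).  Wrapper/embedded channel
selection, adaptive artifact filters, and training of deep EEG models are
explicitly out of scope.
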