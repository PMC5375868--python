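# Methods

This note documents the models, numerical choices and known limitations of
`limbeval`. Everything stated here is computed by the test suite or the
acceptance script; nothing is quoted from external runs.

## Signal model and preprocessing

Recordings carry 10 surface-EMG channels at 1000 Hz (channels 1–8 a forearm
ring, 9 biceps, 10 triceps; millivolts) and two 6-axis IMUs at 100 Hz
(IMU1 forearm, IMU2 upper arm; accelerometer in g, gyroscope in deg/s).
The 10:1 rate ratio is a hard invariant: all channels share one time origin
and segment boundaries map between clocks by the integer ratio.

EMG is band-pass filtered with a 2nd-order Butterworth at 20–495 Hz. The
nominal 500 Hz upper edge equals the Nyquist frequency and cannot be
realized; 495 Hz preserves the intent, and a pure 20 Hz high-pass is
available in the config. IMU axes get a 2nd-order 20 Hz low-pass. Both are
applied forward–backward (zero phase, reflective edge padding) so EMG and
IMU streams stay aligned at segment boundaries; whether the original
analysis filtered causally is unknowable from the outside, but at envelope
scale the difference is negligible and the choice is recorded in the config.

## Segmentation

The activity series S(t) = ‖ω₁(t)‖₂ + ‖ω₂(t)‖₂ (deg/s) is computed from the
*filtered* gyroscopes. Onset is the first sample strictly above
T_R = 3 deg/s; offset is the end of the above-threshold run after which
S(t) stays below T_R for a full 2 s hold; sub-threshold dips shorter than
the hold do not interrupt a repetition. Segments are half-open index
intervals. Additional rules: segments shorter than 0.3 s are discarded as
twitches; if the record ends before the hold can be verified the segment is
closed at the last above-threshold sample and flagged `truncated`. The hold
check uses the same filtered S(t) as the onset detection.

## Features

* **Motion data profile (MDP, 22 × 256).** EMG envelopes are means of the
  rectified signal over 256 ms windows stepped by 8 ms, windows fully inside
  the segment. Every row (10 envelopes + 12 IMU axes) is linearly resampled
  to 256 points, then normalized per sensor group: the EMG rows jointly by
  their maximum, the 6 accelerometer rows jointly and the 6 gyroscope rows
  jointly by the maximal absolute value (sign-preserving). Normalizing after
  resampling guarantees the documented extrema (a joint maximum of exactly 1
  per group) on the output grid. All-zero groups are left as zeros.
  Polyphase resampling is a config option.
* **Duration** in seconds; **extremum count** as strict sign changes of the
  first difference on the 12 filtered (pre-normalization) IMU axes, with
  plateaus counting once — deterministic on quantized data.
* **Power distributions** (per-channel EMG RMS fractions; per-axis RMS
  fractions per device), **intensity ratios** (RMS of the IMU1 magnitude
  series over IMU2's, for accelerometer and gyroscope; a zero denominator
  reports a configurable cap), and **magnitude means/maxima** are computed
  on filtered, *unnormalized* signals so they retain the intensity
  information the MDP removes.

## Preliminary indicators and the reference bank

The per-task bank holds every healthy subject's repetitions (48 entries for
16 healthy × 3). A repetition is scored by (1) the maximal Pearson
correlation between its MDP and any bank MDP, both flattened to
5632-vectors (a per-row-averaged variant is a config option); (2) the
minimal DTW distance, treating the MDP as 256 frames of dimension 22, with
the classic boundary-anchored dynamic program, step set
{(1,0),(0,1),(1,1)}, Euclidean local cost, no warping window and no
path-length normalization (both configurable); and (3) minimal Euclidean
distances for the five power-distribution vectors. Averaging over a
subject's repetitions gives the per-task indicator; summing one component
over tasks gives the global preliminary indicator. A healthy test subject
is always excluded from its own bank (enforced and tested via a leakage
canary: with the subject left in, PCC is exactly 1).

Implementation note: the indicator of any row under any bank exclusion is a
masked maximum/minimum over a row × bank-entry matrix, so these matrices
are computed once per cohort and shared by all leave-one-subject-out folds.
This is an exact restatement, not an approximation, and is what keeps the
34-fold × 6-method evaluation at desk scale (the DTW inner loop is also
JIT-compiled).

## Evaluation-indicator models

Per task, feature rows (7 indicators + duration, extremum count, 2
intensity ratios, 4 magnitude means, 4 maxima; n = 19, fixed order) are
reduced to a scalar by a rank-1 factorization V = W H:

* **PCA** — features z-scored on training statistics; leading eigenvector
  of the covariance; deterministic.
* **Sammon MDS** — 1-D embedding minimizing Sammon's stress
  (1/Σd*) Σ (d* − d)²/d* by gradient descent with backtracking and
  keep-best iterates, initialized from both the PCA projection (with seeded
  jitter) and a seeded random start, keeping the better optimum
  (tol 1e-8 relative stress change, max 500 iterations). Duplicate rows are
  perturbed by a seeded 1e-9 jitter to avoid zero reference distances.
  Because an embedding has no native out-of-sample map, an ordinary
  least-squares linear map from standardized features to the embedded
  coordinate serves as the transform applied to test rows.
* **NMF** — features min-max scaled to [0,1] on training statistics
  (nonnegativity), then rank-1 multiplicative updates
  W ← W·(VHᵀ)/(WHHᵀ), H ← H·(WᵀV)/(WᵀWH) with the W column renormalized to
  unit norm each sweep and the inverse scale absorbed into H, so the
  product — and the monotonically non-increasing Frobenius error — is
  unchanged; 200 sweeps, seeded init, 1e-12 denominator guards. The
  out-of-sample weight for a scaled row x is max(0, xHᵀ/HHᵀ), the
  pseudo-inverse of H.
* **LASSO** — min ‖Vz − y‖² + λ‖z‖₁ with y the per-task clinical item
  scores, solved by coordinate descent (the penalty is solver-independent at
  the optimum); λ = 0 falls back to an exact least-squares solve. λ is
  chosen by an inner seeded 5-fold cross-validation over a logarithmic grid
  inside each training fold; the selected λ is recorded in the diagnostics.

**Orientation.** A 1-D unsupervised component has an arbitrary sign; it is
oriented so its correlation with the PCC feature column (a known
healthy-high feature) is positive. NMF weights cannot be negated, so for
NMF the *columns* are oriented instead: features whose training correlation
with the PCC column is negative are reflected (x → 1 − x after scaling),
making every column healthy-high before the factorization. Both rules are
deterministic and label-free.

**Calibration to the clinical scale.** Raw scores are mapped to the task's
full score by the affine calibration
EI = full · (raw − floor)/(anchor − floor), clipped to [0, full], with
floor = the training minimum and anchor = the healthy-training maximum by
default (`task_norm: healthy_max`; `healthy_mean` and `global_max` are
options). Two considerations drove this: dividing by a bare healthy mean is
ill-conditioned when raw scores are centered (PCA/MDS), so the floor pins
the denominator to the observed score spread; and anchoring the *mean* at
the full score saturates roughly half of the healthy rows at the clip
ceiling, collapsing the healthy variance the normal range is built from —
anchoring the healthy *maximum* leaves healthy scores scattered on both
sides of the scale, as clinical scatter plots show. Under
`task_norm: healthy_mean`, a row whose raw score equals the healthy
training mean maps exactly to the full score (tested).

## Protocol and metrics

Leave-one-subject-out: for each held-out subject the bank, the feature
standardization, the factor model and the calibration are fitted on the
remaining subjects only (healthy training rows are additionally scored
against banks purged of themselves). Component EIs (mean over the held-out
subject's repetitions, on the task scale) sum to the global EI; the healthy
mean of the global EI is expanded to 66 and the same factor applied to
everyone — so the healthy mean of the scaled global EI is 66 by protocol,
an identity the acceptance script recomputes end to end. Per-fold seeds for
MDS/NMF/LASSO derive deterministically from the master seed, fold index and
task id.

NDVR = 100 · 1.96 · SD/mean and the normal range mean ± 1.96 SD use the
sample SD (n−1); a population-SD option exists. DC is the R² of the simple
linear regression between global EIs and clinical totals; a zero-variance
predictor yields DC = 0 with a warning.

## Synthetic cohort

The generator emulates the statistical structure the pipeline assumes, not
biomechanics. Each task has a deterministic template: 2–6 raised-cosine
angular-velocity pulses (alternating sign) along fixed per-task directions,
amplitudes 60–150 deg/s, nominal durations 2.2–4 s; accelerometer profiles
(0.3–0.8 g) along their own directions; EMG activation envelopes time-locked
to the movement on 3 forearm channels plus biceps or triceps. EMG is the
activation envelope times a unit-RMS 20–450 Hz Gaussian carrier (0.4 mV
gain, 0.01 mV baseline noise); gyro noise is 0.3 deg/s, accelerometer noise
0.01 g. Trials hold three repetitions separated by 3 s rest (1.5 s lead-in,
2.5 s tail), and carry their constructed repetition boundaries (first/last
clean crossing of the 3 deg/s threshold) as ground truth.

Impairment level L ∈ [0,1] drives four mechanisms: duration × (1 + 0.75 L),
amplitude × (1 − 0.5 L), 5 Hz tremor of 20 L deg/s added to the gyros during
movement (within the 20 Hz passband, so it survives filtering and inflates
extremum counts), and a 0.6 L fraction of each agonist envelope mixed into
its antagonist channel. Healthy subjects draw a ±10% time warp and ±10%
amplitude jitter (plus ±3% per repetition), making the normal range
nontrivial and bank leakage detectable. Clinical item scores are
full · (1 − L) plus rounding noise, clipped per task; the 24 points of the
0–66 scale not covered by the 11 tasks are filled by an equally scaled
residual. Healthy subjects carry full scores by definition. The default
cohort is 16 healthy + 18 impaired with impairment levels spread evenly
over [0, 0.8].

What passing tests show — and do not show: the pipeline separates the
generator's impairment mechanisms (slowing, weakness, tremor,
co-contraction) monotonically and recovers constructed segment boundaries
within ±1 IMU sample. Real hemiparetic data add phenomena the generator
omits (motion artifacts, electrode shift, spasticity-dependent waveform
changes, compensatory movement strategies), so synthetic performance bounds
nothing clinically; it validates the machinery, not the instrument.

## Problem sizes and runtime choices

The default test and acceptance workloads use the full 34-subject cohort
(374 trials, 1122 repetitions); pairwise indicator caching and the
JIT-compiled DTW keep a complete 6-method leave-one-subject-out run in the
low minutes on one CPU. Unit tests use smaller cohorts (3–6 healthy
subjects) where the protocol, not the scale, is under test.

## Known limitations

* The DTW operates on time-normalized 256-frame MDPs, so its warping mostly
  absorbs residual shape misalignment, not gross duration differences
  (duration is a separate feature).
* The MDS out-of-sample linear map is an approximation; a genuinely
  nonlinear embedding has no exact inverse transform.
* With 16 healthy subjects the 1.96·SD normal range is an estimate from 16
  values; single-subject in/out-of-range flags near the boundary are not
  statistically stable, and the supervised (LASSO) indicator concentrates
  healthy scores so tightly that ±0.1-point effects decide flags.
* EMG envelope stretch-invariance of the MDP holds only up to the fixed
  256 ms window width relative to segment duration.
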