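# Methods

This note documents the models, procedures, numerical choices, and known
limitations behind `cuffbp`, in the order data flows through the pipeline.

## Signal model and working grid

All processing happens at 125 Hz, the native rate of the bedside-monitor
waveforms the pipeline targets. Records arriving at other rates are brought
onto that grid in one of two ways: *decimation* selects existing samples at
the nearest source index (samples are skipped, never invented — appropriate
when downsampling, e.g. 300 → 125 Hz), while *linear interpolation* fills
the uniform 125 Hz grid (appropriate when upsampling, e.g. 100 → 125 Hz).
Output length is `round(n · 125 / fs_in)` in both cases; decimation output
values are always a subset of the input values, and both methods are exact
identities at 125 Hz.

Records are partitioned into 10-minute segments. Quality control operates
per segment; a record shorter than one segment forms a single short segment
flagged in its metadata.

WFDB support is a minimal native reader/writer restricted to format 16 (one
interleaved 16-bit little-endian `.dat` plus a text `.hea` header). Each
channel is digitized at a per-channel gain capped at 1000 (resolution no
finer than 0.001 units), so write-then-read round-trips are exact to the
declared quantization step. CSV (one header row, one column per channel,
optional ignored `time` column) is the fixture format.

## Quality control

Each 10-minute segment passes through, in order:

1. **NaN fill** — missing values are replaced by the nearest available
   sample (ties to the earlier index). Long gaps thereby become flat lines,
   which the next rule rejects: missing data is made explicit, never
   reconstructed.
2. **Flat lines** — any run of ≥ 125 identical consecutive samples (1 s) in
   ABP or PPG rejects the segment. The threshold is a package choice; the
   failure mode is a disconnected or saturated sensor.
3. **Flat peaks** — a peak whose tip is a plateau of ≥ 3 identical samples
   counts as flat; the segment is rejected when the flat fraction strictly
   exceeds 5% in ABP or PPG. Candidate peaks come from a prominence-gated
   local-maximum search at a 0.3-s minimum spacing.
4. **Pressure plausibility and monotonicity** — ABP must stay within
   [15, 300] mmHg (bounds inclusive-pass, reading "range between"
   inclusively); and neither ABP nor PPG may have a first derivative of
   constant sign for more than 170 samples — strictly more, so a run of
   exactly 170 passes. At 125 Hz, 170 samples is 1.36 s, i.e. a "pulse"
   with no cardiac activity for over a second.
5. **Filtering** — PPG: zero-phase 4th-order Butterworth band-pass,
   0.5–8 Hz (below lies baseline wander, above lies high-frequency noise).
   ECG: zero-phase 8th-order Chebyshev-I band-pass, 2–59 Hz, implemented in
   second-order sections for numerical stability at order 8, with 0.5 dB
   design ripple (the ripple is a free design parameter; 0.5 dB keeps the
   forward–backward response within 1 dB in-band). Zero-phase
   (forward–backward) filtering is used so fiducial points are not shifted
   against the ABP targets; the effective magnitude response is the square
   of the design response.
6. **Hampel outlier removal** (PPG and ABP) — a sample deviating from its
   11-sample window median by more than 3 × 1.4826 × MAD is replaced by
   that median; everything else passes untouched. The MAD is computed
   per window against that window's own median (a two-pass rolling-median
   shortcut is *not* equivalent: in monotone stretches every sample equals
   its own window median, the shortcut's MAD collapses to zero, and smooth
   peaks get clipped into plateaus).
7. **Duration rule** (per patient) — patients with under 190 min of clean
   signal are dropped; longer recordings are truncated to the first
   190 min. Kept segments are concatenated without gaps and re-segmented.

A rejected segment is attributed to the *first* failing rule in scheme
order, so every rejection has exactly one named cause; the report also
retains every rule's pass/fail and detail per segment. Filtering steps are
recorded in the record's metadata and skipped on re-entry, which makes the
whole scheme idempotent: QC applied to its own output returns an identical
record and an all-pass report.

Standardization/normalization is deliberately *outside* QC because its
statistics must come from training data only (see Datasets).

ECG is band-pass filtered but not Hampel-filtered (the outlier filter is
specified for the pressure-coupled channels); the ECG filter can be
disabled via `QCRuleConfig.standardize_ecg`.

## Beat extraction

Systolic peaks are found with a two-event-moving-average detector: band-pass
the pressure wave (0.5–8 Hz, 2nd-order Butterworth, zero-phase), clip
negatives, square, and compare a peak-scale moving average (111 ms) against
a beat-scale moving average (667 ms) plus an offset β·mean(squared signal)
with β = 0.02. Contiguous regions where the peak-scale average wins, at
least one peak-window wide, are blocks of interest; the raw-signal maximum
inside each block is a systolic peak. The diastolic valley of beat *i* is
the signal minimum between peaks *i* and *i+1*; the final beat keeps its
tail valley only when the tail spans at least half a median beat interval,
otherwise the beat is dropped so the per-beat arrays stay aligned. All
three detector parameters are exposed as keyword arguments.

Window targets for the direct setup are the arithmetic means of the
per-beat SBP and DBP whose systolic index falls inside the (half-open)
window; beatless windows are skipped rather than imputed.

## Datasets and normalization

PPG and ECG are standardized (zero mean, unit variance); ABP and the scalar
pressure targets are min–max normalized to [0, 1]. Statistics are fitted on
training records only, attached to the normalized record, and serialized
with every dataset, so predictions can always be mapped back to mmHg;
normalizing an already-normalized record is detected and refused.

Direct windows are 625 samples (5 s) and non-overlapping; sequence windows
are 250 samples (2 s) with input `[t−250, t)` and target `ABP[t]`, stride 1
for evaluation and a configurable larger stride for training (the package
default is 5) to bound dataset size. Windows never cross a segment or
patient boundary. The within-subject split is temporal: the final 20% of
each patient's windows form the validation set.

## Architectures

Seven families share one declarative spec:

* **fc** — flatten, dense stack (default 240–180–120), linear head.
* **lstm_stack** — three stacked LSTM layers of 128 cells, the first
  bidirectional, with a per-timestep linear head.
* **wavenet** — two blocks of four dilated causal convolutions (dilations
  1, 2, 4, 8 per block, kernel 3, 32 filters, ReLU), 1×1 linear head.
  Plain convolutions are used, not the gated activations of the original
  audio model. Receptive field: `1 + Σ (k−1)·d = 61` samples.
* **wavenet_lstm** — the wavenet trunk feeding the LSTM stack.
* **resnet** (direct) — four residual blocks, kernel 3, first-conv
  stride 2, filters doubling 64 → 512, then max-pool, global average
  pooling, linear head.
* **resnet_lstm_direct** — the four stride-2 residual blocks (625 → 40
  timesteps) feeding the LSTM stack; the final hidden state drives a
  two-unit linear head. The convolutions act as learned downsampling so
  the recurrent layers see short sequences.
* **resnet_lstm_seq** — the same residual trunk at stride 1 with causal
  padding and no pooling, so the output grid matches the input grid;
  LSTM stack and per-timestep head.

Residual blocks are Conv–BN–ReLU–Conv–BN plus a skip connection (identity
when shapes match, 1×1 conv + BN otherwise), added with **no activation
after the sum**: zeroing the branch weights makes the block exactly the
(shape-matched) identity, which is the property that makes deep stacks
trainable from near-identity initializations. Convolutions feeding batch
norm carry no bias (the BN shift makes a conv bias a null direction).
Weights use seeded Glorot-uniform initialization; LSTM forget-gate biases
start at 1. Output heads are single linear units with no activation.

Direct models map `(625, C)` to two scalars; sequence models map `(250, C)`
to one output per timestep, of which the final sample is the prediction for
the instant the window ends at. Causality therefore holds at the window
level for every sequence model — the prediction for *t* can never see
samples after *t* because the window ends there — and additionally per
timestep inside the window for the purely convolutional family (the
bidirectional recurrent layer reads the whole window, which is legitimate
precisely because the whole window is in the past).

The layer stack (dense, strided/dilated/causal 1-D convolution, batch
normalization, max/global-average pooling, LSTM with reversal and
concatenation wrappers, residual blocks) is implemented in numpy with
explicit forward/backward passes; every layer's gradients are verified
against central finite differences in the test suite.

## Training and evaluation

Adam (learning rate 0.001 by default), Huber loss with δ = 1 on normalized
targets (δ is a tunable hyperparameter; at normalized scale 1 covers the
full pressure range, so the quadratic branch dominates and the linear tails
only damp outliers), mini-batches of 32 by default with **drop-last**
batching, making the update count exactly `epochs · ⌊n/batch⌋` — the
invariant that makes runs with different batch sizes comparable at equal
weight-update counts. Training is deterministic given the config seed; a
NaN loss aborts with a diagnostic.

Direct evaluation de-normalizes predictions and reports MAE/RMSE per target
in mmHg, with a per-patient breakdown. Sequence evaluation reconstructs the
predicted pressure stream (stride-1 windows) and reports both the
sample-by-sample stream errors and beat-level SBP/DBP errors obtained by
running the beat detector *on the predicted stream* and matching each
reference beat to the nearest predicted beat within half a median beat
interval — two views, because peak re-extraction adds error of its own.

Leave-one-patient-out cross-validation builds each fold's normalization
statistics and training windows from the N−1 training patients only; the
overall error is the unweighted mean of per-fold MAEs. A `model_factory`
hook lets protocol tests substitute oracle or biased-oracle stubs.

The ANSI/AAMI-style device bound is |mean difference| ≤ 5 mmHg with sample
standard deviation (ddof = 1) ≤ 8 mmHg, both inclusive.

The complexity estimator implements the order formula
`length × (vector dimension)²` for dense/recurrent families and
`length × (vector dimension)² × kernel` for convolutional families. For the
fully connected model on a 625-sample window this gives 625 (one channel)
and 2500 (two channels). Note that published cost tables for comparable
convolutional models sometimes print values (e.g. ~1850, ~4375 for
single-channel input) that do not follow from this formula with kernel 3,
which yields 1875; the estimator implements the formula as printed and
makes no attempt to reproduce those rounded figures.

## Synthetic data generator

The generator produces physiologically *shaped*, not physiologically
validated, waveforms with exact ground truth:

* **ABP** — per beat, two half-Gaussian lobes around the systolic peak: a
  fast rise (σ = 80 ms) and a slow decay (σ = 0.3 × beat period),
  interpolating between a diastolic and a systolic trajectory. Both
  trajectories drift sinusoidally (defaults: SBP 120 ± 15 mmHg over 300 s,
  DBP 80 ± 8 mmHg over 240 s) and SBP additionally carries a heart-rate
  coupled component (2 mmHg per bpm of HR deviation; HR itself is 72 ± 4
  bpm over a 60-s cycle with 1% beat-to-beat jitter). The arterial line is
  modeled noise-free, so the returned per-beat annotations are read off the
  constructed signal exactly.
* **PPG** — ABP delayed by 200 ms (a pulse-transit surrogate), smoothed by
  a first-order filter (40 ms time constant), scaled by a patient-specific
  affine coupling, then corrupted the way finger photoplethysmography
  actually degrades: slow multiplicative gain drift (±35%, 137-s period,
  vasomotor tone / contact pressure), slow additive baseline drift
  (±0.3 a.u., 89-s period), and white noise (σ = 0.25 a.u. against an O(1)
  pulse amplitude). These drifts matter: they remove the unrealistic
  shortcut in which the optical channel is a calibrated pressure gauge, so
  a model must use waveform shape and timing, and the clean ECG channel
  carries non-redundant information about the HR-coupled pressure
  component — mirroring the empirical finding that adding ECG improves
  cuffless estimates.
* **ECG** — Gaussian R-spikes (10 ms width) at beat onsets plus white noise
  (σ = 0.02).

Cohorts (`generate_patients`) vary baseline pressures, heart rate, and the
PPG coupling per patient, with the SBP/DBP baselines kept a safe margin
apart so the trajectories never cross. Because the coupling is
patient-specific, within-patient validation is much easier than
leave-one-patient-out — the generator reproduces the "personalization"
gap, and LOO errors on small synthetic cohorts are accordingly large.

Artifact injection reproduces each QC failure mode (NaN gaps, flat lines,
clipped "flat peak" tips, negative pressures, strictly monotone ramps),
refuses overlapping spans, and records every span as ground truth, so QC
recall (every artifact trips its rule) and precision (clean output trips
nothing) are directly testable.

**What passing tests do and do not show.** The generator's BP–PPG coupling
is monotone, stationary per patient, and low-dimensional; real ICU data has
pathology-driven waveform morphology changes, sensor repositioning,
drug-induced hemodynamic shifts, and inter-device calibration differences,
none of which are modeled. Success on the synthetic conditions demonstrates
that the pipeline is correctly plumbed (no leakage, correct targets,
trainable models, honest metrics), not that any architecture reaches
clinical accuracy on real patients.

## Desk-scale training conditions

The parameter-recovery checks train a reduced-width
`resnet_lstm_direct` (filters 16–32–64–64, LSTM width 32) on 30 minutes of
synthetic two-channel data for 10 epochs, batch size 8, learning rate 0.01.
Problem sizes and widths are package choices made to keep single-CPU runs
in the tens of seconds; the raised learning rate and smaller batch follow
from the update-count arithmetic — 10 epochs over 288 windows yield only
360 Adam updates, and with per-update displacement ≈ lr, a 0.001 rate
cannot even traverse the distance from a near-zero initialization to the
normalized target mean (≈ 0.7) in that budget. Thresholds for these checks
(SBP MAE < 8 mmHg, DBP MAE < 5 mmHg held-out) are deliberately loose
screening bounds for a correctly plumbed pipeline at this scale.

## Numerical choices and degenerate inputs

* Ties in the NaN nearest-neighbour fill go to the earlier index.
* All-missing segments are rejected (attributed to the flat-line rule, the
  rule that owns sensor dropouts); an all-missing channel cannot be filled.
* `flat_peak_fraction` on an empty peak list raises ("insufficient beats")
  rather than returning 0, so beatless segments cannot silently pass.
* The monotonicity rule counts first-difference samples; "more than 170" is
  strict, so exactly 170 passes.
* Filters raise on inputs shorter than their warm-up length instead of
  padding blindly.
* Constant-PPG or constant-ECG training sets are rejected at
  statistics-fitting time (zero standard deviation).
* Batch sizes larger than the dataset raise rather than silently training
  zero steps.
* Sequence-window counts follow the window semantics exactly: for segment
  length L and stride s, instants run over `range(250, L, s)` (the target
  index must exist), e.g. 598 windows for a 10-minute segment at stride 125
  — verified against brute-force enumeration.

## Known limitations

* The WFDB reader supports only format 16 single-file records — sufficient
  for round-tripping this package's own output, not for arbitrary archive
  records (format 212, multi-file, annotation files).
* The numpy layer stack is single-threaded BLAS-bound; paper-scale widths
  (filters to 512, LSTM width 128) build and run forward passes fine but
  are not practical to train here.
* Beat matching in sequence evaluation uses nearest-index pairing with a
  half-beat tolerance; pathological predicted streams with spurious peaks
  inflate beat-level errors, which is intended (the stream-level metrics
  are the robust view).
* The ECG lead is treated as an opaque channel label; no lead-identity
  validation is attempted.
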