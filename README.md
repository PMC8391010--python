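# cuffbp

Cuffless arterial blood-pressure estimation from photoplethysmogram (PPG)
and electrocardiogram (ECG) signals, as a tested, end-to-end pipeline:

* **Signal I/O** — multichannel physiological records (WFDB or CSV), with
  resampling of foreign rates onto the 125 Hz working grid by sample
  skipping or linear interpolation.
* **Quality control** — a per-segment rejection scheme for the artifact
  classes that plague bedside-monitor waveforms (NaN gaps, flat lines, flat
  peaks, negative pressures, long monotone ramps), plus zero-phase
  band-pass filtering (4th-order Butterworth 0.5–8 Hz for PPG, 8th-order
  Chebyshev-I 2–59 Hz for ECG) and Hampel outlier removal.
* **Beat extraction** — systolic peaks via a two-moving-average event
  detector on the squared band-passed pressure wave; diastolic valleys as
  inter-peak minima.
* **Datasets** — two regression setups: *direct* (5-s windows → mean SBP
  and DBP of the beats inside) and *sequence* (2-s windows → the pressure
  sample at the window's right edge), with train-set-only normalization
  statistics that travel with every dataset.
* **Model zoo** — 1-D architectures built on an in-package trainable layer
  stack (gradient-checked numpy): fully connected, stacked LSTM (first
  layer bidirectional), WaveNet-style dilated causal convolutions, 4-block
  residual networks, and conv+LSTM hybrids for both setups.
* **Training & validation** — Huber loss (δ on normalized targets), Adam,
  drop-last mini-batching so weight-update counts satisfy
  `steps = epochs · ⌊n/batch⌋`, MAE/RMSE in mmHg, leave-one-patient-out
  cross-validation, the ANSI/AAMI 5 ± 8 mmHg device bound, and the
  `length × dim² (× kernel)` complexity estimator.
* **Synthetic generator** — coupled ABP/PPG/ECG records with exact per-beat
  SBP/DBP ground truth and scripted artifact injection, so the entire
  pipeline is exercisable and testable without clinical databases.

It is aimed at researchers prototyping regression models for continuous,
cuff-free blood-pressure monitoring who need the unglamorous parts — signal
QC, target extraction, leakage-free normalization, per-patient validation —
to be correct and testable.

## The regression problem

Given a window of PPG (and optionally ECG) samples at 125 Hz, estimate
arterial pressure. In the **direct** setup the model maps a 625-sample
window to the two scalars (SBP, DBP), the mean systolic and diastolic
pressures of the 4–6 beats inside. In the **sequence** setup a causal model
maps the 250 samples before instant *t* to the pressure at *t*, so a full
pressure wave can be reconstructed in real time. Models are trained with
the Huber loss

    L_δ(r) = r²/2            if |r| ≤ δ
             δ|r| − δ²/2     otherwise,      r = y − f(x)

and scored with MAE and RMSE in mmHg after de-normalization; sequence
models are additionally scored beat-by-beat after re-extracting systolic
peaks and diastolic valleys from the predicted stream.

## Worked example

`examples/03_direct_sbp_dbp_training.py` generates 30 minutes of synthetic
two-channel data, runs QC, builds 5-s windows, and trains a reduced-width
residual-conv + LSTM model for 10 epochs:

```
288 training / 72 validation windows of shape (625, 2)
360 weight updates; Huber loss 0.1671 -> 0.0044
held-out SBP: MAE 5.78  RMSE 7.03 mmHg
held-out DBP: MAE 3.67  RMSE 4.49 mmHg
device-validation bound (|mean|<=5, sd<=8 mmHg): mean +0.85, sd 5.86 -> compliant
```

The model recovers the patient-specific PPG/ECG-to-pressure coupling built
into the generator: held-out errors of a few mmHg on the same synthetic
patient, within the ANSI/AAMI device-validation bound. The other examples
cover beat detection against ground truth (`01`), QC artifact attribution
(`02`), whole-signal sequence prediction (`04`), and leave-one-out
validation plus complexity accounting (`05`).

A thin CLI covers the shell-friendly steps:

```sh
cuffbp synth --minutes 10 --seed 1 --out rec.csv
cuffbp preprocess --in rec.csv --report qc_report.csv --out clean.csv
cuffbp extract-beats --in rec.csv --out beats.csv
```

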