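"""Train the conv-recurrent direct model to predict (SBP, DBP) from 5-s
PPG + ECG windows, at desk scale.

A reduced-width variant of the residual-conv + LSTM architecture is trained
for a few minutes of synthetic data; errors are reported in mmHg on a
held-out temporal split and checked against the device-validation bound
(mean error within 5 mmHg, SD within 8 mmHg).
"""

import numpy as np

from cuffbp import (
    ModelSpec,
    QCRuleConfig,
    SynthConfig,
    TrainConfig,
    ansi_compliant,
    apply_qc,
    build_model,
    detect_beats,
    evaluate_direct,
    fit_norm_stats,
    generate_record,
    make_direct_windows,
    normalize,
    train,
)
from cuffbp.windows import denormalize_abp

record, _ = generate_record(SynthConfig(duration_minutes=30, seed=11))
clean, _ = apply_qc(record, QCRuleConfig(min_total_minutes=10, truncate_minutes=30))
ann = detect_beats(clean.channels["ABP"], clean.fs)
norm = normalize(clean, fit_norm_stats([clean]))

dataset = make_direct_windows(norm, ann, channels=("PPG", "ECG"))
train_ds, val_ds = dataset.time_split(0.2)
print(f"{len(train_ds)} training / {len(val_ds)} validation windows "
      f"of shape {dataset.inputs.shape[1:]}")

spec = ModelSpec(family="resnet_lstm_direct", channels=2,
                 resnet_filters=(16, 32, 64, 64), lstm_width=32)
model = build_model(spec, seed=1)
history = train(model, train_ds,
                TrainConfig(learning_rate=0.01, batch_size=8, epochs=10, seed=1))
print(f"{history['steps']} weight updates; Huber loss "
      f"{history['loss'][0]:.4f} -> {history['loss'][-1]:.4f}")

result = evaluate_direct(model, val_ds)
print(f"held-out SBP: MAE {result.mae_sbp:.2f}  RMSE {result.rmse_sbp:.2f} mmHg")
print(f"held-out DBP: MAE {result.mae_dbp:.2f}  RMSE {result.rmse_dbp:.2f} mmHg")

pred = denormalize_abp(model.predict(val_ds.inputs), val_ds.stats)
targ = denormalize_abp(val_ds.targets, val_ds.stats)
ok, (mean_err, sd_err) = ansi_compliant((pred - targ).ravel())
print(f"device-validation bound (|mean|<=5, sd<=8 mmHg): "
      f"mean {mean_err:+.2f}, sd {sd_err:.2f} -> {'compliant' if ok else 'NOT compliant'}")
# Within-subject errors of a few mmHg are expected: the model recovers the
# patient-specific PPG/ECG-to-pressure coupling built into the generator.
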