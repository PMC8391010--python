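"""Predict the continuous pressure wave: each 2-s PPG window predicts the
ABP sample at its right edge.

A small dilated-causal-convolution network (WaveNet-style) is trained on
sequence windows; evaluation reconstructs the predicted pressure stream and
scores it both sample-by-sample and beat-by-beat (systolic peaks and
diastolic valleys re-extracted from the predicted stream).
"""

from cuffbp import (
    ModelSpec,
    SynthConfig,
    TrainConfig,
    build_model,
    evaluate_sequence,
    fit_norm_stats,
    generate_record,
    make_sequence_windows,
    normalize,
    train,
)
from cuffbp.models import receptive_field

record, _ = generate_record(SynthConfig(duration_minutes=3.0, seed=5))
norm = normalize(record, fit_norm_stats([record]))

train_ds = make_sequence_windows(norm, channels=("PPG",), stride=25)
eval_ds = make_sequence_windows(norm, channels=("PPG",), stride=5)
print(f"{len(train_ds)} training windows of {train_ds.inputs.shape[1]} samples")

spec = ModelSpec(family="wavenet", setup="sequence", input_length=250,
                 channels=1, wavenet_filters=16)
print(f"receptive field: {receptive_field(spec)} samples "
      f"({receptive_field(spec) / 125:.2f} s)")

model = build_model(spec, seed=0)
train(model, train_ds, TrainConfig(learning_rate=0.005, batch_size=32,
                                   epochs=6, seed=0))

result = evaluate_sequence(model, eval_ds)
print(f"whole-signal: MAE {result.signal_mae:.2f}  RMSE {result.signal_rmse:.2f} mmHg")
print(f"beat-level  : SBP MAE {result.mae_sbp:.2f}  DBP MAE {result.mae_dbp:.2f} mmHg")
# The beat-level errors can exceed the whole-signal error because peak and
# valley extraction on the predicted stream adds error of its own.
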