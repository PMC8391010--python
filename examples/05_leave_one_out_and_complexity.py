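"""Leave-one-patient-out validation and architecture complexity accounting.

Each of N folds trains on N-1 synthetic patients (normalization statistics
fitted on those patients only) and evaluates on the held-out patient; the
overall error is the unweighted mean of the per-fold MAEs.  Cross-patient
errors exceed within-patient errors because each synthetic patient has its
own PPG coupling — the personalization effect.
"""

from cuffbp import ModelSpec, SynthConfig, TrainConfig, detect_beats, loo_cv
from cuffbp.synth import generate_patients
from cuffbp.train import flops_estimate

cohort = generate_patients(4, SynthConfig(duration_minutes=5.0), seed=3)
patients = [(rec, detect_beats(rec.channels["ABP"], rec.fs)) for rec, _ in cohort]

spec = ModelSpec(family="fc", setup="direct", channels=1, fc_layers=(64, 32))
cfg = TrainConfig(learning_rate=0.005, batch_size=16, epochs=6, seed=0)
folds, overall = loo_cv(patients, spec, cfg)

for i, fold in enumerate(folds):
    held_out = list(fold.per_patient)[0]
    print(f"fold {i} (held out {held_out}): "
          f"SBP MAE {fold.mae_sbp:6.2f}  DBP MAE {fold.mae_dbp:6.2f} mmHg")
print(f"overall (mean of fold MAEs): SBP {overall['mae_sbp']:.2f}  "
      f"DBP {overall['mae_dbp']:.2f} mmHg")

print("\ncost estimates, 5-s window (length 625), formula length x dim^2 [x kernel]:")
for family in ("fc", "lstm", "wavenet", "resnet_lstm"):
    one = flops_estimate(family, 625, 1)
    two = flops_estimate(family, 625, 2)
    print(f"  {family:12s}  PPG ~{one:>6}  PPG+ECG ~{two:>6}")
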