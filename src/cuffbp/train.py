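"""Training loop, evaluation metrics, leave-one-out protocol, and
complexity accounting for the blood-pressure regression models.

Metrics are always reported in mmHg after de-normalization.  Training uses
the Huber loss on normalized targets with Adam and drop-last mini-batching,
so the number of weight updates is exactly
``epochs * floor(n_samples / batch_size)`` — architectures compared at equal
batch counts see their weights updated the same number of times.

Leave-one-out cross-validation holds out one patient per fold; the held-out
patient contributes neither to that fold's normalization statistics nor to
its training windows, and the overall error is the unweighted mean of the
per-fold MAEs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .beats import BeatAnnotations, NoBeatsError, detect_beats
from .models import Model, ModelSpec, build_model
from .nn import Adam, huber_grad, huber_loss
from .signal_io import Record
from .windows import (
    NormStats,
    WindowedDataset,
    denormalize_abp,
    fit_norm_stats,
    make_direct_windows,
    make_sequence_windows,
    normalize,
)

__all__ = [
    "TrainConfig",
    "EvalResult",
    "mae",
    "rmse",
    "training_steps",
    "train",
    "evaluate_direct",
    "evaluate_sequence",
    "loo_cv",
    "ansi_compliant",
    "flops_estimate",
    "concat_datasets",
]


@dataclass
class TrainConfig:
    """Optimization settings: Adam with learning rate 0.001, Huber loss with
    threshold ``delta`` (on normalized targets), mini-batches of 32."""

    learning_rate: float = 0.001
    batch_size: int = 32
    epochs: int = 10
    delta: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.learning_rate <= 0 or self.epochs < 1:
            raise ValueError("batch_size, learning_rate, epochs must be positive")


@dataclass
class EvalResult:
    """Errors in mmHg.  ``signal_*`` entries are filled only for the
    sequence setup, where the whole reconstructed pressure stream is also
    compared sample-by-sample with the target stream."""

    mae_sbp: float
    mae_dbp: float
    rmse_sbp: float
    rmse_dbp: float
    signal_mae: float | None = None
    signal_rmse: float | None = None
    per_patient: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for m, r in ((self.mae_sbp, self.rmse_sbp), (self.mae_dbp, self.rmse_dbp)):
            if m < 0 or r < 0 or m > r + 1e-9:
                raise ValueError(f"invalid metric pair mae={m}, rmse={r}")


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def mae(pred: np.ndarray, target: np.ndarray) -> float:
    """Mean absolute error (L1 distance / m)."""
    pred, target = np.asarray(pred, float), np.asarray(target, float)
    if pred.shape != target.shape or pred.size == 0:
        raise ValueError("pred and target must be non-empty and equal-shaped")
    return float(np.mean(np.abs(pred - target)))


def rmse(pred: np.ndarray, target: np.ndarray) -> float:
    """Root-mean-squared error (L2 norm / sqrt(m))."""
    pred, target = np.asarray(pred, float), np.asarray(target, float)
    if pred.shape != target.shape or pred.size == 0:
        raise ValueError("pred and target must be non-empty and equal-shaped")
    return float(np.sqrt(np.mean((pred - target) ** 2)))


def training_steps(epochs: int, n_samples: int, batch_size: int) -> int:
    """Weight updates performed: epochs x floor(n / batch) (drop-last)."""
    if epochs < 1 or n_samples < 1 or batch_size < 1:
        raise ValueError("all arguments must be positive")
    if batch_size > n_samples:
        raise ValueError("batch_size exceeds the number of samples")
    return epochs * (n_samples // batch_size)


def ansi_compliant(errors: np.ndarray) -> tuple[bool, tuple[float, float]]:
    """Device-validation bound: mean difference within +/-5 mmHg and standard
    deviation at most 8 mmHg (both inclusive)."""
    errors = np.asarray(errors, dtype=float)
    if errors.size < 2:
        raise ValueError("need at least 2 measurements")
    mean = float(np.mean(errors))
    sd = float(np.std(errors, ddof=1))
    return (abs(mean) <= 5.0) and (sd <= 8.0), (mean, sd)


_CONV_FAMILIES = ("wavenet", "wavenet_lstm", "resnet", "resnet_lstm_direct",
                  "resnet_lstm_seq", "resnet_lstm")
_DENSE_FAMILIES = ("fc", "lstm", "lstm_stack")


def flops_estimate(family: str, length: int, channels: int, kernel: int = 3) -> int:
    """Order-of-magnitude cost: ``length x channels^2`` for dense/recurrent
    families, times ``kernel`` for convolutional families."""
    if family in _DENSE_FAMILIES:
        return length * channels**2
    if family in _CONV_FAMILIES:
        return length * channels**2 * kernel
    raise ValueError(f"unknown family {family!r}")


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _point_predictions(model: Model, out: np.ndarray) -> np.ndarray:
    if model.output_kind == "sequence":
        return out[:, -1]
    return out[:, 0] if out.ndim == 2 and out.shape[1] == 1 else out


def train(
    model: Model,
    dataset: WindowedDataset,
    cfg: TrainConfig,
    val_dataset: WindowedDataset | None = None,
) -> dict:
    """Mini-batch Huber/Adam training; deterministic given ``cfg.seed``.

    Returns a history dict with per-step training loss and, if a validation
    set is supplied, per-epoch validation MAE (mmHg, averaged over targets).
    """
    if dataset.setup != model.spec.setup:
        raise ValueError(
            f"dataset setup {dataset.setup!r} does not match model setup "
            f"{model.spec.setup!r}"
        )
    n = len(dataset)
    steps_per_epoch = n // cfg.batch_size
    if steps_per_epoch == 0:
        raise ValueError("batch_size exceeds the dataset size")
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    history: dict = {"loss": [], "val_mae": []}

    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        for s in range(steps_per_epoch):
            idx = order[s * cfg.batch_size : (s + 1) * cfg.batch_size]
            xb = dataset.inputs[idx]
            yb = dataset.targets[idx]
            out = model.forward(xb, training=True)
            if model.spec.setup == "direct":
                loss = huber_loss(yb, out, cfg.delta)
                gout = huber_grad(yb, out, cfg.delta)
            else:
                pred = _point_predictions(model, out)
                loss = huber_loss(yb, pred, cfg.delta)
                gpred = huber_grad(yb, pred, cfg.delta)
                gout = np.zeros_like(out)
                if model.output_kind == "sequence":
                    gout[:, -1] = gpred
                else:
                    gout[:, 0] = gpred
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"NaN/inf loss at step {len(history['loss'])}; "
                    "reduce the learning rate or inspect the inputs"
                )
            history["loss"].append(loss)
            model.zero_grad()
            model.backward(gout)
            opt.step()
        if val_dataset is not None:
            res = (
                evaluate_direct(model, val_dataset)
                if model.spec.setup == "direct"
                else None
            )
            if res is not None:
                history["val_mae"].append(0.5 * (res.mae_sbp + res.mae_dbp))
    history["steps"] = len(history["loss"])
    return history


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def _per_patient(pids: np.ndarray, fn) -> dict:
    return {pid: fn(np.flatnonzero(pids == pid)) for pid in np.unique(pids)}


def evaluate_direct(model: Model, dataset: WindowedDataset) -> EvalResult:
    """De-normalize the (SBP, DBP) predictions and compare with targets."""
    if dataset.stats is None:
        raise ValueError("dataset lacks normalization statistics")
    preds = model.predict(dataset.inputs)
    pred_mmhg = denormalize_abp(preds, dataset.stats)
    targ_mmhg = denormalize_abp(dataset.targets, dataset.stats)

    def metrics(idx):
        return {
            "mae_sbp": mae(pred_mmhg[idx, 0], targ_mmhg[idx, 0]),
            "mae_dbp": mae(pred_mmhg[idx, 1], targ_mmhg[idx, 1]),
            "rmse_sbp": rmse(pred_mmhg[idx, 0], targ_mmhg[idx, 0]),
            "rmse_dbp": rmse(pred_mmhg[idx, 1], targ_mmhg[idx, 1]),
        }

    overall = metrics(np.arange(len(dataset)))
    return EvalResult(
        **overall, per_patient=_per_patient(dataset.patient_ids, metrics)
    )


def evaluate_sequence(
    model: Model, dataset: WindowedDataset, fs: float = 125.0
) -> EvalResult:
    """Reconstruct the predicted pressure stream and score it twice:
    sample-by-sample against the target stream, and beat-by-beat after
    extracting systolic peaks and diastolic valleys from the *predicted*
    stream (the extraction itself may add error, which is why both views
    are reported)."""
    if dataset.stats is None:
        raise ValueError("dataset lacks normalization statistics")
    preds = model.predict_point(dataset.inputs)
    pred_mmhg = denormalize_abp(preds, dataset.stats)
    targ_mmhg = denormalize_abp(dataset.targets, dataset.stats)

    sig_mae = mae(pred_mmhg, targ_mmhg)
    sig_rmse = rmse(pred_mmhg, targ_mmhg)

    sbp_err, dbp_err = [], []
    per_patient: dict = {}
    for pid in np.unique(dataset.patient_ids):
        idx = np.flatnonzero(dataset.patient_ids == pid)
        order = idx[np.argsort(dataset.t_indices[idx])]
        p_stream, t_stream = pred_mmhg[order], targ_mmhg[order]
        try:
            se, de = _beat_errors(p_stream, t_stream, fs)
        except (NoBeatsError, ValueError):
            continue
        sbp_err.extend(se)
        dbp_err.extend(de)
        per_patient[pid] = {
            "signal_mae": mae(p_stream, t_stream),
            "signal_rmse": rmse(p_stream, t_stream),
            "mae_sbp": float(np.mean(np.abs(se))) if len(se) else np.nan,
            "mae_dbp": float(np.mean(np.abs(de))) if len(de) else np.nan,
        }
    if not sbp_err:
        raise NoBeatsError("no beats could be extracted from the predicted stream")
    sbp_err = np.asarray(sbp_err)
    dbp_err = np.asarray(dbp_err)
    return EvalResult(
        mae_sbp=float(np.mean(np.abs(sbp_err))),
        mae_dbp=float(np.mean(np.abs(dbp_err))),
        rmse_sbp=float(np.sqrt(np.mean(sbp_err**2))),
        rmse_dbp=float(np.sqrt(np.mean(dbp_err**2))),
        signal_mae=sig_mae,
        signal_rmse=sig_rmse,
        per_patient=per_patient,
    )


def _beat_errors(pred_stream, targ_stream, fs) -> tuple[list, list]:
    """Signed per-beat SBP/DBP differences, matching each target beat to the
    nearest predicted beat within half a median beat interval."""
    ann_t = detect_beats(targ_stream, fs)
    ann_p = detect_beats(pred_stream, fs)
    if len(ann_p) == 0 or len(ann_t) == 0:
        return [], []
    tol = 0.5 * float(np.median(np.diff(ann_t.systolic_indices))) if len(ann_t) > 1 else fs
    sbp_err, dbp_err = [], []
    for i, s_idx in enumerate(ann_t.systolic_indices):
        j = int(np.argmin(np.abs(ann_p.systolic_indices - s_idx)))
        if abs(ann_p.systolic_indices[j] - s_idx) <= tol:
            sbp_err.append(ann_p.sbp_values[j] - ann_t.sbp_values[i])
            dbp_err.append(ann_p.dbp_values[j] - ann_t.dbp_values[i])
    return sbp_err, dbp_err


# ---------------------------------------------------------------------------
# Leave-one-out cross-validation
# ---------------------------------------------------------------------------

def loo_cv(
    patients: list[tuple[Record, BeatAnnotations]],
    spec: ModelSpec,
    cfg: TrainConfig,
    channels: tuple[str, ...] = ("PPG",),
    stride: int = 5,
    model_factory=None,
) -> tuple[list[EvalResult], dict]:
    """Leave-one-patient-out cross-validation.

    For each of the N folds, normalization statistics are fitted on the N-1
    training patients only; the held-out patient is windowed with those
    statistics and never contributes to training.  The overall errors are
    the unweighted means of the per-fold MAEs.

    ``model_factory(train_ds, heldout_ds) -> Model`` overrides the default
    build-and-train path; it is the hook for oracle/stub models in protocol
    tests.
    """
    if len(patients) < 2:
        raise ValueError("leave-one-out needs at least 2 patients")
    folds: list[EvalResult] = []
    for i in range(len(patients)):
        train_recs = [r for j, (r, _) in enumerate(patients) if j != i]
        stats = fit_norm_stats(train_recs)

        def build_ds(rec: Record, ann: BeatAnnotations) -> WindowedDataset:
            norm = normalize(rec, stats)
            if spec.setup == "direct":
                return make_direct_windows(norm, ann, channels=channels)
            return make_sequence_windows(norm, channels=channels, stride=stride)

        train_ds = concat_datasets(
            [build_ds(r, a) for j, (r, a) in enumerate(patients) if j != i]
        )
        heldout_ds = build_ds(*patients[i])
        if model_factory is not None:
            model = model_factory(train_ds, heldout_ds)
        else:
            model = build_model(spec, seed=cfg.seed)
            train(model, train_ds, cfg)
        folds.append(
            evaluate_direct(model, heldout_ds)
            if spec.setup == "direct"
            else evaluate_sequence(model, heldout_ds)
        )
    overall = {
        "mae_sbp": float(np.mean([f.mae_sbp for f in folds])),
        "mae_dbp": float(np.mean([f.mae_dbp for f in folds])),
    }
    if spec.setup == "sequence":
        overall["signal_mae"] = float(np.mean([f.signal_mae for f in folds]))
    return folds, overall


def concat_datasets(datasets: list[WindowedDataset]) -> WindowedDataset:
    """Concatenate window datasets sharing setup, channels, and statistics."""
    first = datasets[0]
    for d in datasets[1:]:
        if d.setup != first.setup or d.channel_names != first.channel_names:
            raise ValueError("datasets are not compatible")
    return WindowedDataset(
        inputs=np.concatenate([d.inputs for d in datasets]),
        targets=np.concatenate([d.targets for d in datasets]),
        patient_ids=np.concatenate([d.patient_ids for d in datasets]),
        setup=first.setup,
        stats=first.stats,
        channel_names=first.channel_names,
        t_indices=np.concatenate([d.t_indices for d in datasets]),
    )
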