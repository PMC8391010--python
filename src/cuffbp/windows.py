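"""Windowed dataset construction with train-set normalization statistics.

Two regression setups are supported:

* **direct** — non-overlapping 5-s windows (625 samples at 125 Hz); the
  target is the pair (mean SBP, mean DBP) over the beats inside the window,
  min-max normalized to the training ABP range.
* **sequence** — sliding 2-s windows (250 samples); the window ending just
  before instant ``t`` predicts the (normalized) ABP value at ``t``.

PPG and ECG are standardized (zero mean, unit variance); ABP and the scalar
pressure targets are min-max normalized, and predictions must be
de-normalized back to mmHg through the same statistics.  Statistics are
fitted on training records only, and travel with every dataset so that
de-normalization is always possible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .beats import BeatAnnotations, WindowSkipped, window_targets
from .signal_io import Record

__all__ = [
    "NormStats",
    "WindowedDataset",
    "fit_norm_stats",
    "normalize",
    "denormalize_abp",
    "make_direct_windows",
    "make_sequence_windows",
    "save_dataset",
    "load_dataset",
    "DIRECT_WINDOW",
    "SEQUENCE_WINDOW",
]

DIRECT_WINDOW = 625  # 5 s x 125 Hz
SEQUENCE_WINDOW = 250  # 2 s x 125 Hz


@dataclass
class NormStats:
    """Channel normalization statistics, in source units."""

    ppg_mean: float
    ppg_std: float
    abp_min: float
    abp_max: float
    ecg_mean: float = 0.0
    ecg_std: float = 1.0

    def __post_init__(self) -> None:
        if self.ppg_std <= 0 or self.ecg_std <= 0:
            raise ValueError("standardization requires positive std")
        if self.abp_max <= self.abp_min:
            raise ValueError("abp_max must exceed abp_min")

    def to_json(self) -> str:
        return json.dumps(self.__dict__)

    @classmethod
    def from_json(cls, s: str) -> "NormStats":
        return cls(**json.loads(s))


def fit_norm_stats(records: list[Record]) -> NormStats:
    """Pooled PPG/ECG mean and std, ABP min and max over training records."""
    if not records:
        raise ValueError("empty training set")
    ppg = np.concatenate([r.channels["PPG"] for r in records if "PPG" in r.channels])
    abp = np.concatenate([r.channels["ABP"] for r in records if "ABP" in r.channels])
    if ppg.size == 0 or abp.size == 0:
        raise ValueError("training records must contain PPG and ABP")
    ppg_std = float(np.std(ppg))
    if ppg_std == 0:
        raise ValueError("constant PPG: cannot standardize")
    ecgs = [r.channels["ECG"] for r in records if "ECG" in r.channels]
    if ecgs:
        ecg = np.concatenate(ecgs)
        ecg_mean, ecg_std = float(np.mean(ecg)), float(np.std(ecg))
        if ecg_std == 0:
            raise ValueError("constant ECG: cannot standardize")
    else:
        ecg_mean, ecg_std = 0.0, 1.0
    return NormStats(
        ppg_mean=float(np.mean(ppg)),
        ppg_std=ppg_std,
        abp_min=float(np.min(abp)),
        abp_max=float(np.max(abp)),
        ecg_mean=ecg_mean,
        ecg_std=ecg_std,
    )


def normalize(record: Record, stats: NormStats) -> Record:
    """Standardize PPG/ECG and min-max normalize ABP.

    Applying a dataset's statistics to an already-normalized record is
    detected (via a metadata flag) and refused.
    """
    if record.metadata.get("normalized"):
        raise ValueError("record is already normalized; refusing to normalize twice")
    out = record.copy()
    if "PPG" in out.channels:
        out.channels["PPG"] = (out.channels["PPG"] - stats.ppg_mean) / stats.ppg_std
    if "ECG" in out.channels:
        out.channels["ECG"] = (out.channels["ECG"] - stats.ecg_mean) / stats.ecg_std
    if "ABP" in out.channels:
        out.channels["ABP"] = (out.channels["ABP"] - stats.abp_min) / (
            stats.abp_max - stats.abp_min
        )
    out.metadata["normalized"] = True
    out.metadata["norm_stats"] = stats
    return out


def denormalize_abp(values: np.ndarray, stats: NormStats) -> np.ndarray:
    """Map normalized pressure predictions back to mmHg (exact inverse)."""
    return np.asarray(values) * (stats.abp_max - stats.abp_min) + stats.abp_min


def normalize_abp(values: np.ndarray, stats: NormStats) -> np.ndarray:
    return (np.asarray(values) - stats.abp_min) / (stats.abp_max - stats.abp_min)


@dataclass
class WindowedDataset:
    """Fixed-length input windows with aligned targets.

    ``inputs`` has shape ``(n_windows, length, channels)`` with channels
    ordered as ``channel_names``.  For the direct setup ``targets`` has shape
    ``(n, 2)`` holding normalized (SBP, DBP); for the sequence setup shape
    ``(n,)`` holding the normalized ABP value at the prediction instant.
    ``t_indices`` records, per window, the window start (direct) or the
    prediction instant ``t`` (sequence) in the source record.
    """

    inputs: np.ndarray
    targets: np.ndarray
    patient_ids: np.ndarray
    setup: str  # "direct" | "sequence"
    stats: NormStats
    channel_names: tuple[str, ...] = ("PPG",)
    t_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        if self.setup not in ("direct", "sequence"):
            raise ValueError(f"unknown setup {self.setup!r}")
        expected = DIRECT_WINDOW if self.setup == "direct" else SEQUENCE_WINDOW
        if self.inputs.ndim != 3 or self.inputs.shape[1] != expected:
            raise ValueError(
                f"{self.setup} windows must have shape (n, {expected}, C), "
                f"got {self.inputs.shape}"
            )
        if len(self.inputs) != len(self.targets) or len(self.inputs) != len(
            self.patient_ids
        ):
            raise ValueError("inputs, targets, patient_ids must be aligned")

    def __len__(self) -> int:
        return len(self.inputs)

    @property
    def n_channels(self) -> int:
        return self.inputs.shape[2]

    def subset(self, idx: np.ndarray) -> "WindowedDataset":
        return WindowedDataset(
            inputs=self.inputs[idx],
            targets=self.targets[idx],
            patient_ids=self.patient_ids[idx],
            setup=self.setup,
            stats=self.stats,
            channel_names=self.channel_names,
            t_indices=self.t_indices[idx] if len(self.t_indices) else self.t_indices,
        )

    def time_split(self, val_fraction: float = 0.2) -> tuple["WindowedDataset", "WindowedDataset"]:
        """Within-patient temporal split: the final ``val_fraction`` of each
        patient's windows (in time order) form the validation set."""
        train_idx, val_idx = [], []
        for pid in np.unique(self.patient_ids):
            where = np.flatnonzero(self.patient_ids == pid)
            n_val = max(1, int(round(val_fraction * len(where))))
            train_idx.extend(where[: len(where) - n_val])
            val_idx.extend(where[len(where) - n_val :])
        return self.subset(np.array(train_idx)), self.subset(np.array(val_idx))


def _stack_channels(record: Record, channels: tuple[str, ...]) -> np.ndarray:
    missing = [c for c in channels if c not in record.channels]
    if missing:
        raise KeyError(f"record lacks channels {missing}")
    return np.stack([record.channels[c] for c in channels], axis=-1)


def _require_normalized(record: Record) -> NormStats:
    stats = record.metadata.get("norm_stats")
    if not record.metadata.get("normalized") or stats is None:
        raise ValueError("record must be normalized first (see normalize())")
    return stats


def make_direct_windows(
    record: Record,
    ann: BeatAnnotations,
    channels: tuple[str, ...] = ("PPG",),
) -> WindowedDataset:
    """Non-overlapping 5-s windows with (mean SBP, mean DBP) targets.

    ``ann`` carries per-beat pressures in mmHg (from the pre-normalization
    ABP); targets are min-max normalized with the record's attached
    statistics.  Windows containing no systolic peak are skipped.  Windows
    never cross a segment boundary.
    """
    stats = _require_normalized(record)
    data = _stack_channels(record, channels)
    if record.n_samples < DIRECT_WINDOW:
        raise ValueError(
            f"record has {record.n_samples} samples, shorter than one "
            f"{DIRECT_WINDOW}-sample window"
        )
    inputs, targets, starts = [], [], []
    for seg_start, seg_end in record.segment_boundaries:
        start = seg_start
        while start + DIRECT_WINDOW <= seg_end:
            window = (start, start + DIRECT_WINDOW)
            try:
                sbp, dbp = window_targets(ann, window)
            except WindowSkipped:
                start += DIRECT_WINDOW
                continue
            inputs.append(data[start : start + DIRECT_WINDOW])
            targets.append(
                [
                    float(normalize_abp(sbp, stats)),
                    float(normalize_abp(dbp, stats)),
                ]
            )
            starts.append(start)
            start += DIRECT_WINDOW
    return WindowedDataset(
        inputs=np.asarray(inputs, dtype=float),
        targets=np.asarray(targets, dtype=float),
        patient_ids=np.full(len(inputs), record.patient_id, dtype=object),
        setup="direct",
        stats=stats,
        channel_names=channels,
        t_indices=np.asarray(starts, dtype=int),
    )


def count_direct_windows(record: Record) -> int:
    """Number of non-overlapping 5-s windows before beat-based skipping."""
    return sum(
        (end - start) // DIRECT_WINDOW for start, end in record.segment_boundaries
    )


def make_sequence_windows(
    record: Record,
    channels: tuple[str, ...] = ("PPG",),
    stride: int = 1,
) -> WindowedDataset:
    """Sliding 2-s windows predicting the next ABP sample.

    For each valid instant ``t >= 250`` (within a segment), the input is the
    normalized channel data over ``[t-250, t)`` and the target is the
    normalized ABP at ``t``.  ``stride`` subsamples the instants (use 1 for
    evaluation; larger strides bound training-set size).  Windows never
    cross a segment boundary.
    """
    stats = _require_normalized(record)
    if "ABP" not in record.channels:
        raise KeyError("sequence targets require the ABP channel")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    data = _stack_channels(record, channels)
    abp = record.channels["ABP"]
    if record.n_samples < SEQUENCE_WINDOW + 1:
        raise ValueError(
            f"record has {record.n_samples} samples, needs more than "
            f"{SEQUENCE_WINDOW} for one window plus target"
        )
    inputs, targets, instants = [], [], []
    for seg_start, seg_end in record.segment_boundaries:
        for t in range(seg_start + SEQUENCE_WINDOW, seg_end, stride):
            inputs.append(data[t - SEQUENCE_WINDOW : t])
            targets.append(abp[t])
            instants.append(t)
    return WindowedDataset(
        inputs=np.asarray(inputs, dtype=float),
        targets=np.asarray(targets, dtype=float),
        patient_ids=np.full(len(inputs), record.patient_id, dtype=object),
        setup="sequence",
        stats=stats,
        channel_names=channels,
        t_indices=np.asarray(instants, dtype=int),
    )


def save_dataset(ds: WindowedDataset, path: str | Path) -> None:
    """Store windows as ``.npz`` with a JSON sidecar for stats and setup."""
    path = Path(path)
    np.savez_compressed(
        path.with_suffix(".npz"),
        inputs=ds.inputs,
        targets=ds.targets,
        patient_ids=ds.patient_ids.astype(str),
        t_indices=ds.t_indices,
    )
    sidecar = {
        "setup": ds.setup,
        "channel_names": list(ds.channel_names),
        "stats": json.loads(ds.stats.to_json()),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_dataset(path: str | Path) -> WindowedDataset:
    path = Path(path)
    arrays = np.load(path.with_suffix(".npz"), allow_pickle=False)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return WindowedDataset(
        inputs=arrays["inputs"],
        targets=arrays["targets"],
        patient_ids=arrays["patient_ids"].astype(object),
        setup=sidecar["setup"],
        stats=NormStats(**sidecar["stats"]),
        channel_names=tuple(sidecar["channel_names"]),
        t_indices=arrays["t_indices"],
    )
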