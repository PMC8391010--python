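"""Systolic peak / diastolic valley detection and per-window scalar targets.

Systolic peaks are located with the two-event-moving-average scheme of
Elgendi's beat detector: the signal is band-passed (0.5-8 Hz), negative
values are clipped, the result is squared, and two moving averages — one at
the scale of a systolic peak (~111 ms) and one at the scale of a full beat
(~667 ms) — delimit "blocks of interest" wherever the peak-scale average
exceeds the beat-scale average plus an offset proportional to the signal
energy.  The maximum of the raw signal inside each sufficiently wide block
is a systolic peak.  Diastolic valleys are the minima between consecutive
systolic peaks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

__all__ = ["BeatAnnotations", "detect_beats", "window_targets", "NoBeatsError"]


class NoBeatsError(ValueError):
    """Raised when no heartbeats can be located in a signal."""


@dataclass
class BeatAnnotations:
    """Per-beat fiducial points and pressures.

    ``sbp_values[i] == signal[systolic_indices[i]]`` and each
    ``diastolic_indices[i]`` lies between systolic peaks ``i`` and ``i+1``
    (or in the tail after the final peak).  Arrays are index-aligned: one
    entry per retained beat.
    """

    systolic_indices: np.ndarray
    diastolic_indices: np.ndarray
    sbp_values: np.ndarray
    dbp_values: np.ndarray

    def __post_init__(self) -> None:
        self.systolic_indices = np.asarray(self.systolic_indices, dtype=int)
        self.diastolic_indices = np.asarray(self.diastolic_indices, dtype=int)
        self.sbp_values = np.asarray(self.sbp_values, dtype=float)
        self.dbp_values = np.asarray(self.dbp_values, dtype=float)
        if len(self.systolic_indices) > 1 and np.any(np.diff(self.systolic_indices) <= 0):
            raise ValueError("systolic indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.systolic_indices)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "systolic_index": self.systolic_indices,
                "diastolic_index": self.diastolic_indices,
                "sbp": self.sbp_values,
                "dbp": self.dbp_values,
            }
        )


def detect_beats(
    abp: np.ndarray,
    fs: float = 125.0,
    peak_window_ms: float = 111.0,
    beat_window_ms: float = 667.0,
    beta: float = 0.02,
) -> BeatAnnotations:
    """Detect systolic peaks and diastolic valleys in an ABP signal.

    Parameters follow the two-moving-average event detector: ``peak_window_ms``
    and ``beat_window_ms`` are the short/long moving-average widths and
    ``beta`` scales the energy-dependent threshold offset.

    Raises
    ------
    NoBeatsError
        If no block of interest wide enough for a systolic peak is found
        (e.g. on a constant signal).
    """
    abp = np.asarray(abp, dtype=float)
    if len(abp) < 2 * fs:
        raise ValueError("need at least 2 s of signal to detect beats")
    if np.ptp(abp) == 0:
        raise NoBeatsError("constant signal contains no beats")

    nyq = fs / 2.0
    b, a = butter(2, [0.5 / nyq, 8.0 / nyq], btype="band")
    filtered = filtfilt(b, a, abp)
    clipped = np.clip(filtered, 0.0, None)
    squared = clipped**2

    w1 = max(1, int(round(peak_window_ms / 1000.0 * fs)))  # peak-scale MA
    w2 = max(w1 + 1, int(round(beat_window_ms / 1000.0 * fs)))  # beat-scale MA
    ma_peak = _moving_average(squared, w1)
    ma_beat = _moving_average(squared, w2)
    alpha = beta * float(np.mean(squared))
    thr1 = ma_beat + alpha

    blocks = ma_peak > thr1
    idx = np.flatnonzero(blocks)
    if idx.size == 0:
        raise NoBeatsError("no blocks of interest found")
    gaps = np.flatnonzero(np.diff(idx) > 1)
    block_starts = np.concatenate([[idx[0]], idx[gaps + 1]])
    block_ends = np.concatenate([idx[gaps], [idx[-1]]])

    sys_idx = []
    for s, e in zip(block_starts, block_ends):
        if e - s + 1 >= w1:
            sys_idx.append(s + int(np.argmax(abp[s : e + 1])))
    if not sys_idx:
        raise NoBeatsError("no beats found")
    sys_idx = np.asarray(sys_idx, dtype=int)

    # diastole: minimum between consecutive systolic peaks; final beat keeps
    # its tail valley only if the tail spans at least half a median beat
    dia_idx, keep = [], []
    intervals = np.diff(sys_idx)
    median_iv = float(np.median(intervals)) if len(intervals) else fs
    for i, s in enumerate(sys_idx):
        if i + 1 < len(sys_idx):
            lo, hi = s, sys_idx[i + 1]
        else:
            lo, hi = s, len(abp)
            if hi - lo < 0.5 * median_iv:
                continue
        dia_idx.append(lo + int(np.argmin(abp[lo:hi])))
        keep.append(i)
    sys_kept = sys_idx[keep]
    dia_arr = np.asarray(dia_idx, dtype=int)
    return BeatAnnotations(
        systolic_indices=sys_kept,
        diastolic_indices=dia_arr,
        sbp_values=abp[sys_kept],
        dbp_values=abp[dia_arr],
    )


def _moving_average(x: np.ndarray, w: int) -> np.ndarray:
    """Centered moving average with edge truncation (same length as input)."""
    kernel = np.ones(w) / w
    out = np.convolve(x, kernel, mode="same")
    return out


class WindowSkipped(ValueError):
    """Raised when a window contains no complete beat."""


def window_targets(
    ann: BeatAnnotations, window: tuple[int, int]
) -> tuple[float, float]:
    """Mean SBP and DBP of the beats whose systolic index falls in ``window``.

    A 5-s window typically holds 4-6 cardiac cycles; the arithmetic mean of
    their systolic and diastolic pressures is the regression target.

    Raises
    ------
    WindowSkipped
        If no systolic index falls inside the half-open window.
    """
    lo, hi = window
    mask = (ann.systolic_indices >= lo) & (ann.systolic_indices < hi)
    if not np.any(mask):
        raise WindowSkipped(f"no beats in window [{lo}, {hi})")
    return float(np.mean(ann.sbp_values[mask])), float(np.mean(ann.dbp_values[mask]))
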