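"""Per-segment quality control and pre-processing for PPG/ECG/ABP records.

Bedside-monitor waveforms fail in characteristic ways: the stream drops to
NaN, a disconnected sensor produces long constant runs ("flat lines"),
saturated transducers clip beat tips ("flat peaks"), pressure lines read
negative or implausibly high values, and drifting baselines produce long
strictly-monotone ramps with no cardiac activity.  Each 10-minute segment is
screened with one rule per failure mode; segments failing any rule are
dropped, and patients left with too little clean signal are discarded.

The full per-segment scheme, in order:

1. replace NaNs with the nearest available sample;
2. reject segments with flat lines in ABP or PPG;
3. reject segments where more than 5% of ABP or PPG peaks are flat peaks;
4. reject segments with ABP outside [15, 300] mmHg, or with ABP/PPG first
   derivative of constant sign for more than 170 samples (1.36 s at 125 Hz);
5. band-pass the PPG (4th-order Butterworth, 0.5-8 Hz) — and, when an ECG
   channel is present, band-pass it too (8th-order Chebyshev I, 2-59 Hz);
6. remove PPG and ABP outliers with a Hampel filter;
7. drop patients with under 190 min of clean signal; truncate the rest to
   the first 190 min.

Standardization/normalization is deliberately *not* part of QC: those
statistics must be fitted on training data only (see
:mod:`cuffbp.windows`).

All filtering is zero-phase (forward-backward), so systolic peaks are not
shifted relative to the ABP targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import butter, cheby1, filtfilt, find_peaks, sosfiltfilt

from .signal_io import Record, TARGET_FS

__all__ = [
    "QCRuleConfig",
    "QCReport",
    "fill_missing",
    "detect_flat_lines",
    "flat_peak_fraction",
    "abp_plausible",
    "monotone_run_exceeds",
    "filter_ppg",
    "filter_ecg",
    "hampel_filter",
    "apply_qc",
]

MAD_SCALE = 1.4826  # consistent-estimator scaling of MAD to Gaussian sigma


@dataclass
class QCRuleConfig:
    """Thresholds of the rejection rules.

    ``monotone_max_run`` is expressed in samples of the first derivative:
    170 samples at 125 Hz is 1.36 s of strictly monotone signal.  Runs of
    identical values of at least ``flat_line_min_run`` samples (default 1 s)
    count as flat lines.  A peak counts as flat when its tip is a plateau of
    at least ``flat_peak_plateau_min`` identical samples; a segment fails
    when the flat fraction strictly exceeds ``flat_peak_max_fraction``.
    """

    flat_line_min_run: int = 125
    flat_peak_max_fraction: float = 0.05
    flat_peak_plateau_min: int = 3
    abp_min: float = 15.0
    abp_max: float = 300.0
    monotone_max_run: int = 170
    hampel_window: int = 11
    hampel_nsigma: float = 3.0
    min_total_minutes: float = 190.0
    truncate_minutes: float = 190.0
    standardize_ecg: bool = True  # ECG gets the Chebyshev filter; Hampel is PPG/ABP only

    def __post_init__(self) -> None:
        if self.abp_min >= self.abp_max:
            raise ValueError("abp_min must be below abp_max")
        if self.flat_line_min_run < 1 or self.monotone_max_run < 1:
            raise ValueError("run lengths must be >= 1")
        if not 0.0 < self.flat_peak_max_fraction < 1.0:
            raise ValueError("flat_peak_max_fraction must lie in (0, 1)")
        if self.hampel_window < 3 or self.hampel_window % 2 == 0:
            raise ValueError("hampel_window must be odd and >= 3")


RULES = ("flat_line", "flat_peak", "abp_range", "monotone")


@dataclass
class QCReport:
    """Per-segment rule outcomes plus patient-level bookkeeping.

    ``segments[i]`` maps rule name to ``(passed, detail)`` where detail is the
    rule's count or fraction.  ``rejected_by[i]`` is the first failing rule in
    scheme order (``None`` for kept segments), so every rejection is
    attributable to exactly one rule.
    """

    segments: list[dict] = field(default_factory=list)
    rejected_by: list = field(default_factory=list)
    patient_kept: bool = True
    patient_reject_reason: str | None = None

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def kept_indices(self) -> list[int]:
        return [i for i, r in enumerate(self.rejected_by) if r is None]

    @property
    def n_kept(self) -> int:
        return len(self.kept_indices)

    @property
    def n_rejected(self) -> int:
        return self.n_segments - self.n_kept

    def rejections_per_rule(self) -> dict[str, int]:
        out = {rule: 0 for rule in RULES}
        for r in self.rejected_by:
            if r is not None:
                out[r] += 1
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, seg in enumerate(self.segments):
            row = {"segment": i, "rejected_by": self.rejected_by[i]}
            for rule, (passed, detail) in seg.items():
                row[f"{rule}_passed"] = passed
                row[f"{rule}_detail"] = detail
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Individual rules
# ---------------------------------------------------------------------------

def fill_missing(signal: np.ndarray) -> np.ndarray:
    """Replace NaNs with the value at the nearest non-missing index.

    Ties between an earlier and a later neighbour go to the earlier index.
    Long gaps thereby become flat lines, which the flat-line rule then
    rejects — missing data is never invented, only made explicit.
    """
    signal = np.asarray(signal, dtype=float)
    missing = np.isnan(signal)
    if not missing.any():
        return signal.copy()
    if missing.all():
        raise ValueError("all-missing signal cannot be filled")
    valid_idx = np.flatnonzero(~missing)
    target_idx = np.arange(len(signal))
    # for each position, nearest valid index; ties -> earlier
    pos = np.searchsorted(valid_idx, target_idx)
    left = np.clip(pos - 1, 0, len(valid_idx) - 1)
    right = np.clip(pos, 0, len(valid_idx) - 1)
    dist_left = np.abs(target_idx - valid_idx[left])
    dist_right = np.abs(valid_idx[right] - target_idx)
    nearest = np.where(dist_left <= dist_right, valid_idx[left], valid_idx[right])
    out = signal.copy()
    out[missing] = signal[nearest[missing]]
    return out


def _identical_runs(signal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Start indices and lengths of maximal runs of consecutive identical values."""
    n = len(signal)
    if n == 0:
        return np.array([], int), np.array([], int)
    # treat NaN == NaN as identical (a NaN gap is a flat line of missing data)
    same = (signal[1:] == signal[:-1]) | (np.isnan(signal[1:]) & np.isnan(signal[:-1]))
    change = np.flatnonzero(~same)
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change + 1, [n]])
    return starts, ends - starts


def detect_flat_lines(signal: np.ndarray, min_run: int) -> list[tuple[int, int]]:
    """Maximal runs of >= ``min_run`` consecutive identical values, as
    ``(start, end)`` half-open index ranges."""
    if min_run < 2:
        raise ValueError("min_run must be >= 2")
    signal = np.asarray(signal, dtype=float)
    starts, lengths = _identical_runs(signal)
    return [(int(s), int(s + l)) for s, l in zip(starts, lengths) if l >= min_run]


def flat_peak_fraction(
    signal: np.ndarray, peaks: np.ndarray, plateau_min: int = 3
) -> float:
    """Fraction of peaks whose tip is a plateau of >= ``plateau_min`` identical
    samples.  A segment fails QC when this strictly exceeds the 5% threshold."""
    if plateau_min < 2:
        raise ValueError("plateau_min must be >= 2")
    peaks = np.asarray(peaks, dtype=int)
    if peaks.size == 0:
        raise ValueError("insufficient beats: empty peak list")
    signal = np.asarray(signal, dtype=float)
    n = len(signal)
    flat = 0
    for p in peaks:
        tip = signal[p]
        lo = p
        while lo > 0 and signal[lo - 1] == tip:
            lo -= 1
        hi = p
        while hi < n - 1 and signal[hi + 1] == tip:
            hi += 1
        if hi - lo + 1 >= plateau_min:
            flat += 1
    return flat / len(peaks)


def abp_plausible(
    segment: np.ndarray, cfg: QCRuleConfig | None = None
) -> tuple[bool, int]:
    """Check every ABP sample lies in [abp_min, abp_max] mmHg (inclusive).

    Returns ``(passed, n_out_of_range)``.
    """
    cfg = cfg or QCRuleConfig()
    segment = np.asarray(segment, dtype=float)
    bad = int(np.sum((segment < cfg.abp_min) | (segment > cfg.abp_max)))
    return bad == 0, bad


def monotone_run_exceeds(
    signal: np.ndarray, max_run: int = 170
) -> tuple[bool, int]:
    """Longest run of strictly-positive or strictly-negative first differences.

    Returns ``(passed, longest_run)``; fails iff the longest run strictly
    exceeds ``max_run`` differences ("more than 170 samples" is strict).
    """
    signal = np.asarray(signal, dtype=float)
    if len(signal) < 2:
        raise ValueError("need at least 2 samples")
    d = np.diff(signal)
    longest = max(_longest_true_run(d > 0), _longest_true_run(d < 0))
    return longest <= max_run, longest


def _longest_true_run(mask: np.ndarray) -> int:
    if not mask.any():
        return 0
    padded = np.concatenate([[False], mask, [False]]).astype(int)
    change = np.diff(padded)
    starts = np.flatnonzero(change == 1)
    ends = np.flatnonzero(change == -1)
    return int(np.max(ends - starts))


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def filter_ppg(signal: np.ndarray, fs: float = TARGET_FS) -> np.ndarray:
    """Zero-phase band-pass for PPG: 4th-order Butterworth, 0.5-8 Hz.

    Below 0.5 Hz lies baseline wander, above 8 Hz high-frequency noise.
    """
    nyq = fs / 2.0
    b, a = butter(4, [0.5 / nyq, 8.0 / nyq], btype="band")
    if len(signal) <= 3 * max(len(a), len(b)):
        raise ValueError("signal shorter than filter warm-up length")
    return filtfilt(b, a, np.asarray(signal, dtype=float))


def filter_ecg(signal: np.ndarray, fs: float = TARGET_FS, rp: float = 0.5) -> np.ndarray:
    """Zero-phase band-pass for ECG: 8th-order Chebyshev type I, 2-59 Hz.

    Rejects motion artefacts (below 2 Hz) and mains interference (near
    60 Hz).  ``rp`` is the passband ripple in dB (design parameter of the
    Chebyshev prototype).  Implemented in second-order sections for
    numerical stability at order 8.
    """
    nyq = fs / 2.0
    sos = cheby1(8, rp, [2.0 / nyq, 59.0 / nyq], btype="band", output="sos")
    if len(signal) <= 8 * len(sos):
        raise ValueError("signal shorter than filter warm-up length")
    return sosfiltfilt(sos, np.asarray(signal, dtype=float))


def hampel_filter(
    signal: np.ndarray, window: int = 11, nsigma: float = 3.0
) -> np.ndarray:
    """Sliding-window median outlier filter.

    Samples deviating from their window median by more than
    ``nsigma * 1.4826 * MAD`` are replaced by the median; all other samples
    pass through unchanged.  Window edges use reflected padding.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    x = np.asarray(signal, dtype=float)
    half = window // 2
    padded = np.pad(x, half, mode="reflect")
    views = sliding_window_view(padded, window)  # (n, window)
    med = np.median(views, axis=1)
    mad = np.median(np.abs(views - med[:, None]), axis=1)
    thresh = nsigma * MAD_SCALE * mad
    out = x.copy()
    flagged = np.abs(x - med) > thresh
    out[flagged] = med[flagged]
    return out


# ---------------------------------------------------------------------------
# Full scheme
# ---------------------------------------------------------------------------

def _segment_rules(
    channels: dict[str, np.ndarray], cfg: QCRuleConfig, fs: float
) -> dict:
    """Evaluate all rejection rules on one segment; returns rule -> (passed, detail)."""
    abp = channels.get("ABP")
    ppg = channels.get("PPG")
    results: dict[str, tuple[bool, float]] = {}

    # flat lines (ABP or PPG)
    n_flat = 0
    for sig in (abp, ppg):
        if sig is not None:
            n_flat += len(detect_flat_lines(sig, cfg.flat_line_min_run))
    results["flat_line"] = (n_flat == 0, n_flat)

    # flat peaks (ABP or PPG): > threshold fraction fails
    worst_frac = 0.0
    for sig in (abp, ppg):
        if sig is None:
            continue
        peaks, _ = find_peaks(sig, distance=int(0.3 * fs), prominence=np.ptp(sig) * 0.1)
        if peaks.size == 0:
            continue
        worst_frac = max(
            worst_frac, flat_peak_fraction(sig, peaks, cfg.flat_peak_plateau_min)
        )
    results["flat_peak"] = (worst_frac <= cfg.flat_peak_max_fraction, worst_frac)

    # ABP plausibility
    if abp is not None:
        ok, bad = abp_plausible(abp, cfg)
        results["abp_range"] = (ok, bad)
    else:
        results["abp_range"] = (True, 0)

    # monotone runs on ABP and PPG derivatives
    longest = 0
    for sig in (abp, ppg):
        if sig is not None and len(sig) >= 2:
            _, run = monotone_run_exceeds(sig, cfg.monotone_max_run)
            longest = max(longest, run)
    results["monotone"] = (longest <= cfg.monotone_max_run, longest)
    return results


def apply_qc(record: Record, cfg: QCRuleConfig | None = None) -> tuple[Record | None, QCReport]:
    """Run the full pre-processing scheme on a record.

    Per 10-minute segment: fill NaNs, evaluate the rejection rules (flat
    line, flat peak, ABP range, monotonicity), drop failing segments, then
    band-pass the PPG (and ECG, if configured), Hampel-filter PPG and ABP,
    enforce the patient-level duration rule, and truncate.

    Returns ``(cleaned, report)``.  ``cleaned`` is ``None`` when the patient
    is rejected (no clean segments, or under ``min_total_minutes``).  Kept
    segments are concatenated without gaps and re-segmented.

    Filtering steps already recorded in ``record.metadata`` are skipped, so
    the operation is idempotent: re-running on its own output returns an
    identical record and an all-pass report.
    """
    cfg = cfg or QCRuleConfig()
    report = QCReport()
    kept_segments: list[dict[str, np.ndarray]] = []

    for i in range(len(record.segment_boundaries)):
        seg = record.segment(i)
        # step 1: fill missing values (all channels)
        filled = {}
        fillable = True
        for name, sig in seg.items():
            if np.isnan(sig).all():
                fillable = False
                break
            filled[name] = fill_missing(sig)
        if not fillable:
            report.segments.append({r: (r != "flat_line", np.inf) for r in RULES})
            report.rejected_by.append("flat_line")
            continue
        rules = _segment_rules(filled, cfg, record.fs)
        report.segments.append(rules)
        failing = [r for r in RULES if not rules[r][0]]
        report.rejected_by.append(failing[0] if failing else None)
        if not failing:
            kept_segments.append(filled)

    if not kept_segments:
        report.patient_kept = False
        report.patient_reject_reason = "no clean segments"
        return None, report

    channels = {
        name: np.concatenate([seg[name] for seg in kept_segments])
        for name in kept_segments[0]
    }

    # duration rule (per patient) and truncation
    total_min = len(next(iter(channels.values()))) / record.fs / 60.0
    if total_min < cfg.min_total_minutes:
        report.patient_kept = False
        report.patient_reject_reason = (
            f"only {total_min:.1f} min of clean signal (< {cfg.min_total_minutes:g})"
        )
        return None, report
    n_keep = int(round(cfg.truncate_minutes * 60 * record.fs))
    channels = {name: sig[:n_keep] for name, sig in channels.items()}

    metadata = dict(record.metadata)
    # filtering (skipped when already applied, making apply_qc idempotent)
    if "PPG" in channels and not metadata.get("ppg_filtered"):
        channels["PPG"] = filter_ppg(channels["PPG"], record.fs)
        metadata["ppg_filtered"] = True
    if "ECG" in channels and cfg.standardize_ecg and not metadata.get("ecg_filtered"):
        channels["ECG"] = filter_ecg(channels["ECG"], record.fs)
        metadata["ecg_filtered"] = True
    if not metadata.get("hampel_applied"):
        for name in ("PPG", "ABP"):
            if name in channels:
                channels[name] = hampel_filter(
                    channels[name], cfg.hampel_window, cfg.hampel_nsigma
                )
        metadata["hampel_applied"] = True
    metadata["qc_applied"] = True

    cleaned = Record(
        patient_id=record.patient_id,
        fs=record.fs,
        channels=channels,
        metadata=metadata,
    )
    return cleaned, report
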