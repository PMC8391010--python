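"""Synthetic coupled ABP/PPG/ECG generator with artifact injection.

The generator produces physiologically *shaped* — not physiologically
validated — waveforms whose per-beat systolic and diastolic pressures are
known exactly, so that every downstream stage (quality control, beat
detection, windowing, model training) can be tested without access to
clinical waveform databases.

Model
-----
* **ABP** — each beat is built from two half-Gaussian lobes around the
  systolic peak: a fast rise (sigma ~80 ms) and a slow decay (sigma scaled
  to the beat period), interpolating between the diastolic and systolic
  trajectories.  The trajectories drift slowly (sinusoids with distinct
  periods) to emulate baseline blood-pressure variability.
* **PPG** — a delayed (pulse-transit surrogate), first-order-smoothed,
  affinely rescaled transform of ABP plus additive Gaussian noise.  The
  affine coupling coefficients are patient-specific, which preserves the
  monotone BP-PPG relationship within a patient while making cross-patient
  generalization genuinely harder — mirroring the "personalization" effect
  seen on real data.
* **ECG** — a train of Gaussian R-spikes aligned to beat onsets plus noise.

Artifacts
---------
:func:`inject_artifacts` reproduces the sensor-failure classes the QC
scheme screens for: NaN gaps, flat lines, flat (clipped) peaks, negative
pressures, and long strictly-monotone ramps.  Each injected artifact is
recorded in the plan, providing ground truth for QC recall tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks, lfilter

from .beats import BeatAnnotations
from .signal_io import Record, TARGET_FS

__all__ = [
    "SynthConfig",
    "Artifact",
    "ArtifactPlan",
    "generate_record",
    "generate_patients",
    "inject_artifacts",
]

ARTIFACT_TYPES = ("nan_gap", "flat_line", "flat_peak", "negative_bp", "monotone_ramp")


@dataclass
class SynthConfig:
    """Conditions for one synthetic patient.

    Defaults describe a resting adult: 72 bpm with mild sinusoidal heart-rate
    variability, SBP 120 +/- 15 mmHg and DBP 80 +/- 8 mmHg drifting over a few
    minutes, a 200 ms pulse-transit delay, and moderate optical noise on the
    PPG channel (the invasive ABP line is treated as noise-free so per-beat
    ground truth stays exact).
    """

    duration_minutes: float = 10.0
    fs: float = TARGET_FS
    heart_rate: float = 72.0
    hr_variability: float = 4.0          # bpm amplitude of slow HR modulation
    sbp_baseline: float = 120.0
    sbp_swing: float = 15.0              # mmHg amplitude of slow SBP drift
    sbp_period_s: float = 300.0
    dbp_baseline: float = 80.0
    dbp_swing: float = 8.0
    dbp_period_s: float = 240.0
    hr_bp_coupling: float = 2.0          # mmHg of SBP per bpm of HR deviation
    ppg_delay_ms: float = 200.0
    ppg_smooth_ms: float = 40.0          # first-order smoothing time constant
    ppg_noise_sd: float = 0.25           # a.u.; the optical channel is noisy
    ppg_gain_drift: float = 0.35         # slow multiplicative drift (vasomotor tone)
    ppg_baseline_drift: float = 0.3      # a.u., slow additive drift (contact pressure)
    ecg_noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs != TARGET_FS:
            raise ValueError("generator operates at 125 Hz")
        if not (30.0 <= self.heart_rate <= 220.0):
            raise ValueError("heart_rate must lie in [30, 220] bpm")
        if self.dbp_baseline + self.dbp_swing >= self.sbp_baseline - self.sbp_swing:
            raise ValueError("SBP trajectory must stay above DBP trajectory")
        if self.duration_minutes <= 0:
            raise ValueError("duration must be positive")


@dataclass
class Artifact:
    type: str
    channel: str
    start: int
    length: int
    magnitude: float = 0.0

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass
class ArtifactPlan:
    artifacts: list[Artifact] = field(default_factory=list)

    def add(self, type: str, channel: str, start: int, length: int,
            magnitude: float = 0.0) -> "ArtifactPlan":
        self.artifacts.append(Artifact(type, channel, start, length, magnitude))
        return self

    def __iter__(self):
        return iter(self.artifacts)

    def __len__(self) -> int:
        return len(self.artifacts)


def _beat_onsets(cfg: SynthConfig, n_samples: int, rng: np.random.Generator) -> np.ndarray:
    """Beat onset times (s): instantaneous HR = base + slow sinusoid + jitter."""
    duration = n_samples / cfg.fs
    onsets = []
    t = 0.0
    while t < duration:
        onsets.append(t)
        hr = cfg.heart_rate + cfg.hr_variability * np.sin(2 * np.pi * t / 60.0)
        period = 60.0 / hr
        t += period * (1.0 + 0.01 * rng.standard_normal())
    return np.asarray(onsets)


def generate_record(cfg: SynthConfig) -> tuple[Record, BeatAnnotations]:
    """Generate one synthetic patient record plus exact per-beat ground truth.

    Returns
    -------
    record:
        :class:`~cuffbp.signal_io.Record` with PPG, ECG, and ABP channels.
    truth:
        :class:`~cuffbp.beats.BeatAnnotations` whose systolic/diastolic
        indices and values are read off the constructed ABP signal itself,
        so ``sbp_values[i] == ABP[systolic_indices[i]]`` exactly.
    """
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_minutes * 60 * cfg.fs))
    t = np.arange(n) / cfg.fs

    # heart-rate deviation couples into SBP (baroreflex-like interaction);
    # the coupling term follows the same 60-s modulation as the beat onsets
    hr_dev = cfg.hr_variability * np.sin(2 * np.pi * t / 60.0)
    sbp_traj = (
        cfg.sbp_baseline
        + cfg.sbp_swing * np.sin(2 * np.pi * t / cfg.sbp_period_s)
        + cfg.hr_bp_coupling * hr_dev
    )
    dbp_traj = cfg.dbp_baseline + cfg.dbp_swing * np.sin(
        2 * np.pi * t / cfg.dbp_period_s + 1.0
    )

    onsets = _beat_onsets(cfg, n, rng)
    abp = np.array(dbp_traj)  # baseline: diastolic trajectory
    rise_s = 0.08
    sys_idx: list[int] = []
    for k, onset in enumerate(onsets):
        period = (onsets[k + 1] - onset) if k + 1 < len(onsets) else 60.0 / cfg.heart_rate
        peak_t = onset + 1.6 * rise_s
        peak_i = int(round(peak_t * cfg.fs))
        if peak_i >= n:
            break
        decay_s = 0.30 * period
        lo = int(round(onset * cfg.fs))
        hi = min(n, int(round((onset + period) * cfg.fs)))
        tt = t[lo:hi]
        pulse = np.where(
            tt < peak_t,
            np.exp(-0.5 * ((tt - peak_t) / rise_s) ** 2),
            np.exp(-0.5 * ((tt - peak_t) / decay_s) ** 2),
        )
        amp = sbp_traj[peak_i] - dbp_traj[peak_i]
        abp[lo:hi] = dbp_traj[lo:hi] + amp * pulse
        sys_idx.append(lo + int(np.argmax(abp[lo:hi])))

    # exact ground truth from the constructed signal
    sys_idx_arr = np.asarray(sys_idx, dtype=int)
    truth = _annotate_from_signal(abp, sys_idx_arr, cfg.fs)

    # PPG: delay -> first-order smoothing -> patient-specific affine -> noise
    delay = int(round(cfg.ppg_delay_ms / 1000.0 * cfg.fs))
    delayed = np.concatenate([np.full(delay, abp[0]), abp[:-delay] if delay else abp])
    alpha = 1.0 - np.exp(-1.0 / (cfg.ppg_smooth_ms / 1000.0 * cfg.fs))
    # first-order IIR smoothing: y[i] = y[i-1] + alpha * (x[i] - y[i-1])
    smoothed, _ = lfilter(
        [alpha], [1.0, -(1.0 - alpha)], delayed, zi=[(1.0 - alpha) * delayed[0]]
    )
    scale = 1.0 / 60.0 * (1.0 + 0.2 * rng.standard_normal())
    offset = rng.uniform(-0.5, 0.5)
    # slow uncalibrated drifts: the optical amplitude is not a pressure gauge
    gain_t = 1.0 + cfg.ppg_gain_drift * np.sin(2 * np.pi * t / 137.0 + rng.uniform(0, 6.28))
    base_t = cfg.ppg_baseline_drift * np.sin(2 * np.pi * t / 89.0 + rng.uniform(0, 6.28))
    ppg = (
        scale * gain_t * smoothed
        + offset
        + base_t
        + cfg.ppg_noise_sd * rng.standard_normal(n)
    )

    # ECG: R spikes at beat onsets
    ecg = cfg.ecg_noise_sd * rng.standard_normal(n)
    spike_half = int(round(0.02 * cfg.fs)) + 1
    for onset in onsets:
        c = int(round(onset * cfg.fs))
        if c >= n:
            break
        lo, hi = max(0, c - spike_half), min(n, c + spike_half + 1)
        ecg[lo:hi] += np.exp(-0.5 * ((t[lo:hi] - onset) / 0.01) ** 2)

    record = Record(
        patient_id=f"synth-{cfg.seed}",
        fs=cfg.fs,
        channels={"PPG": ppg, "ECG": ecg, "ABP": abp},
    )
    return record, truth


def _annotate_from_signal(
    abp: np.ndarray, sys_idx: np.ndarray, fs: float
) -> BeatAnnotations:
    """Build exact annotations: diastolic valley = minimum between peaks;
    the final beat keeps its tail valley if the tail is at least half a beat."""
    if len(sys_idx) == 0:
        return BeatAnnotations(
            np.array([], int), np.array([], int), np.array([]), np.array([])
        )
    dia_idx = []
    keep = []
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


def generate_patients(
    n_patients: int, base_cfg: SynthConfig | None = None, seed: int = 0
) -> list[tuple[Record, BeatAnnotations]]:
    """Generate a cohort with per-patient variation in baseline BP and HR."""
    base = base_cfg or SynthConfig()
    rng = np.random.default_rng(seed)
    out = []
    for p in range(n_patients):
        sbp_b = base.sbp_baseline + rng.normal(0, 8)
        dbp_b = base.dbp_baseline + rng.normal(0, 5)
        # keep the pulse pressure physiological: trajectories must not cross
        margin = base.sbp_swing + base.dbp_swing + 10.0
        dbp_b = min(dbp_b, sbp_b - margin)
        cfg = SynthConfig(
            duration_minutes=base.duration_minutes,
            heart_rate=float(np.clip(base.heart_rate + rng.normal(0, 6), 45, 110)),
            sbp_baseline=sbp_b,
            dbp_baseline=dbp_b,
            sbp_swing=base.sbp_swing,
            dbp_swing=base.dbp_swing,
            ppg_noise_sd=base.ppg_noise_sd,
            ecg_noise_sd=base.ecg_noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        rec, truth = generate_record(cfg)
        rec.patient_id = f"synth-p{p}"
        out.append((rec, truth))
    return out


# ---------------------------------------------------------------------------
# Artifact injection
# ---------------------------------------------------------------------------

def inject_artifacts(record: Record, plan: ArtifactPlan) -> Record:
    """Return a corrupted copy of ``record`` with every planned artifact applied.

    Raises ``ValueError`` on overlapping artifacts (same channel), unknown
    artifact types, or out-of-bounds spans.
    """
    n = record.n_samples
    by_channel: dict[str, list[Artifact]] = {}
    for art in plan:
        if art.type not in ARTIFACT_TYPES:
            raise ValueError(f"unknown artifact type {art.type!r}")
        if art.channel not in record.channels:
            raise ValueError(f"unknown channel {art.channel!r}")
        if art.start < 0 or art.end > n:
            raise ValueError(f"artifact out of bounds: {art}")
        by_channel.setdefault(art.channel, []).append(art)
    for channel, arts in by_channel.items():
        arts_sorted = sorted(arts, key=lambda a: a.start)
        for a, b in zip(arts_sorted, arts_sorted[1:]):
            if b.start < a.end:
                raise ValueError(f"overlapping artifacts on {channel}: {a} / {b}")

    out = record.copy()
    for art in plan:
        sig = out.channels[art.channel]
        sl = slice(art.start, art.end)
        if art.type == "nan_gap":
            sig[sl] = np.nan
        elif art.type == "flat_line":
            sig[sl] = sig[art.start]
        elif art.type == "negative_bp":
            sig[sl] = art.magnitude if art.magnitude < 0 else -5.0
        elif art.type == "monotone_ramp":
            rise = art.magnitude if art.magnitude > 0 else 30.0
            sig[sl] = np.linspace(sig[art.start], sig[art.start] + rise, art.length)
        elif art.type == "flat_peak":
            _clip_peaks(sig, art.start, art.end, art.magnitude or 2.0)
    return out


def _clip_peaks(sig: np.ndarray, start: int, end: int, depth: float) -> None:
    """Clip every local peak in [start, end) to a plateau ``depth`` below its tip."""
    window = sig[start:end]
    peaks, _ = find_peaks(window, distance=int(0.3 * TARGET_FS))
    for p in peaks:
        thr = window[p] - depth
        lo = p
        while lo > 0 and window[lo - 1] > thr:
            lo -= 1
        hi = p
        while hi < len(window) - 1 and window[hi + 1] > thr:
            hi += 1
        window[lo : hi + 1] = np.minimum(window[lo : hi + 1], thr)
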