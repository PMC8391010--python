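"""Reading, writing, and resampling of multichannel physiological records.

A :class:`Record` holds synchronized PPG/ECG/ABP channels at a common sampling
rate.  All internal processing assumes 125 Hz, the native rate of the bedside
monitors the pipeline targets; :func:`resample_to_125` brings foreign rates
onto that grid either by skipping samples (nearest-source-index decimation)
or by linear interpolation.

Two on-disk formats are supported:

* CSV — one header row with channel names, one column per channel, an
  optional ``time`` column which is ignored.  Used for small fixtures.
* WFDB — a minimal native implementation of the classic ``.hea``/``.dat``
  header-plus-signal layout, restricted to format 16 (interleaved 16-bit
  little-endian two's complement, one ``.dat`` file per record).  Enough to
  round-trip records written by :func:`write_record`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

TARGET_FS = 125.0
SEGMENT_MINUTES = 10

__all__ = [
    "Record",
    "read_record",
    "write_record",
    "resample_to_125",
    "segment_boundaries_for",
    "TARGET_FS",
    "SEGMENT_MINUTES",
]


class ChannelAbsentError(KeyError):
    """A requested channel is not present in the source file."""


@dataclass
class Record:
    """A patient's synchronized multichannel recording.

    Parameters
    ----------
    patient_id:
        Opaque identifier; leave-one-out folds group windows by this key.
    fs:
        Sampling rate in Hz.  After ingestion this is always 125.
    channels:
        Mapping from channel name (``"PPG"``, ``"ECG"``, ``"ABP"``) to a 1-D
        float array.  ABP is in mmHg; PPG/ECG are in arbitrary units.
    segment_boundaries:
        ``(start, end)`` half-open index ranges partitioning the samples into
        10-minute segments.  A record shorter than one segment forms a single
        short segment, flagged in ``metadata["short_final_segment"]``.
    metadata:
        Free-form processing flags (e.g. which filters have been applied).
    """

    patient_id: str
    fs: float
    channels: dict[str, np.ndarray]
    segment_boundaries: list[tuple[int, int]] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        lengths = {name: len(sig) for name, sig in self.channels.items()}
        if len(set(lengths.values())) > 1:
            raise ValueError(f"inconsistent channel lengths: {lengths}")
        self.channels = {
            name: np.asarray(sig, dtype=float) for name, sig in self.channels.items()
        }
        if not self.segment_boundaries:
            self.segment_boundaries = segment_boundaries_for(self.n_samples, self.fs)
            if self.n_samples < SEGMENT_MINUTES * 60 * self.fs:
                self.metadata.setdefault("short_final_segment", True)
        self._check_boundaries()

    def _check_boundaries(self) -> None:
        prev_end = 0
        for start, end in self.segment_boundaries:
            if start != prev_end or end <= start:
                raise ValueError(
                    f"segment boundaries must be ordered, disjoint and covering: "
                    f"{self.segment_boundaries}"
                )
            prev_end = end
        if self.segment_boundaries and prev_end != self.n_samples:
            raise ValueError("segment boundaries do not cover the record")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values()))) if self.channels else 0

    @property
    def duration_minutes(self) -> float:
        return self.n_samples / self.fs / 60.0

    def segment(self, i: int) -> dict[str, np.ndarray]:
        start, end = self.segment_boundaries[i]
        return {name: sig[start:end] for name, sig in self.channels.items()}

    def copy(self) -> "Record":
        return Record(
            patient_id=self.patient_id,
            fs=self.fs,
            channels={k: v.copy() for k, v in self.channels.items()},
            segment_boundaries=list(self.segment_boundaries),
            metadata=dict(self.metadata),
        )


def segment_boundaries_for(
    n_samples: int, fs: float, minutes: int = SEGMENT_MINUTES
) -> list[tuple[int, int]]:
    """Partition ``n_samples`` into full ``minutes``-long segments plus a
    trailing short segment if any samples remain."""
    if n_samples == 0:
        return []
    seg_len = int(round(minutes * 60 * fs))
    bounds = []
    start = 0
    while start + seg_len <= n_samples:
        bounds.append((start, start + seg_len))
        start += seg_len
    if start < n_samples:
        bounds.append((start, n_samples))
    return bounds


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------

def _read_csv(path: Path, fs: float, channels: list[str] | None) -> Record:
    df = pd.read_csv(path)
    df = df.drop(columns=[c for c in df.columns if c.lower() == "time"])
    requested = channels if channels is not None else list(df.columns)
    missing = [c for c in requested if c not in df.columns]
    if missing:
        raise ChannelAbsentError(
            f"channel(s) absent from {path.name}: {missing} (present: {list(df.columns)})"
        )
    data = {c: df[c].to_numpy(dtype=float) for c in requested}
    return Record(patient_id=path.stem, fs=fs, channels=data)


def _write_csv(record: Record, path: Path) -> None:
    pd.DataFrame(record.channels).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Minimal WFDB (format 16)
# ---------------------------------------------------------------------------

def _write_wfdb(record: Record, path: Path) -> None:
    """Write ``path.hea`` and ``path.dat`` (format 16, interleaved int16).

    Each channel is stored digitally as ``round(x * gain) + baseline`` with a
    per-channel gain chosen so the full analog range maps into int16; the
    quantization step is therefore ``1/gain`` per channel.
    """
    names = list(record.channels)
    n_sig = len(names)
    n_samp = record.n_samples
    digital = np.empty((n_samp, n_sig), dtype=np.int16)
    header_lines = [f"{path.stem} {n_sig} {record.fs:g} {n_samp}"]
    for j, name in enumerate(names):
        x = record.channels[name]
        span = float(np.max(np.abs(x))) if n_samp else 0.0
        gain = 30000.0 / span if span > 0 else 1000.0
        gain = min(gain, 1000.0)  # cap resolution at 0.001 units
        d = np.round(x * gain).astype(np.int64)
        if d.min() < -32768 or d.max() > 32767:
            raise ValueError(f"channel {name} overflows int16 at gain {gain}")
        digital[:, j] = d.astype(np.int16)
        checksum = int(np.sum(d, dtype=np.int64) & 0xFFFF)
        if checksum >= 0x8000:
            checksum -= 0x10000
        units = "mmHg" if name.upper() == "ABP" else "au"
        first = int(digital[0, j]) if n_samp else 0
        header_lines.append(
            f"{path.stem}.dat 16 {gain:.6f}(0)/{units} 16 0 {first} {checksum} 0 {name}"
        )
    path.with_suffix(".hea").write_text("\n".join(header_lines) + "\n")
    digital.tofile(path.with_suffix(".dat"))


def _read_wfdb(path: Path, channels: list[str] | None) -> Record:
    hea = path.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(hea)
    lines = [
        ln for ln in hea.read_text().splitlines() if ln.strip() and not ln.startswith("#")
    ]
    rec_fields = lines[0].split()
    n_sig, fs, n_samp = int(rec_fields[1]), float(rec_fields[2]), int(rec_fields[3])
    sig_lines = lines[1 : 1 + n_sig]
    names, gains, baselines = [], [], []
    for ln in sig_lines:
        parts = ln.split()
        fmt = parts[1]
        if fmt != "16":
            raise NotImplementedError(f"only WFDB format 16 is supported, got {fmt}")
        gain_field = parts[2].split("/")[0]
        if "(" in gain_field:
            gain_str, base_str = gain_field[:-1].split("(")
            gains.append(float(gain_str))
            baselines.append(float(base_str))
        else:
            gains.append(float(gain_field))
            baselines.append(0.0)
        names.append(parts[-1])
    raw = np.fromfile(path.with_suffix(".dat"), dtype=np.int16)
    if raw.size != n_samp * n_sig:
        raise ValueError(
            f"{path.name}.dat has {raw.size} samples, expected {n_samp * n_sig}"
        )
    digital = raw.reshape(n_samp, n_sig).astype(float)
    data = {
        name: (digital[:, j] - baselines[j]) / gains[j] for j, name in enumerate(names)
    }
    requested = channels if channels is not None else names
    missing = [c for c in requested if c not in data]
    if missing:
        raise ChannelAbsentError(
            f"channel(s) absent from {path.name}: {missing} (present: {names})"
        )
    return Record(
        patient_id=path.stem, fs=fs, channels={c: data[c] for c in requested}
    )


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def read_record(
    path: str | Path,
    format: str = "csv",
    fs: float = TARGET_FS,
    channels: list[str] | None = None,
) -> Record:
    """Read a multichannel record from disk.

    Parameters
    ----------
    path:
        File path.  For WFDB, the record base name (with or without
        ``.hea``/``.dat`` extension).
    format:
        ``"csv"`` or ``"wfdb"``.
    fs:
        Declared sampling rate for CSV input (WFDB carries its own).
    channels:
        Channel names to load; ``None`` loads all.  Records missing a
        requested channel raise :class:`ChannelAbsentError`, mirroring the
        discard-if-absent ingestion rule.
    """
    path = Path(path)
    if format == "csv":
        if not path.exists():
            raise FileNotFoundError(path)
        return _read_csv(path, fs, channels)
    if format == "wfdb":
        return _read_wfdb(path.with_suffix(""), channels)
    raise ValueError(f"unknown format {format!r}")


def write_record(record: Record, path: str | Path, format: str = "csv") -> None:
    """Write a record to disk in CSV or minimal-WFDB format."""
    path = Path(path)
    if format == "csv":
        _write_csv(record, path)
    elif format == "wfdb":
        _write_wfdb(record, path.with_suffix(""))
    else:
        raise ValueError(f"unknown format {format!r}")


def resample_to_125(
    signal: np.ndarray, fs_in: float, method: str = "linear"
) -> np.ndarray:
    """Bring a signal sampled at ``fs_in`` onto the 125 Hz grid.

    ``method="decimate"`` selects existing samples at the nearest source
    index (samples are skipped, never invented), as appropriate when
    downsampling e.g. a 300 Hz optical channel.  ``method="linear"``
    interpolates on the uniform 125 Hz grid, as appropriate when upsampling
    e.g. a 100 Hz ECG.  Output length is ``round(len(signal) * 125 / fs_in)``.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.size == 0:
        raise ValueError("cannot resample an empty signal")
    if fs_in <= 0:
        raise ValueError(f"fs_in must be positive, got {fs_in}")
    n_out = int(round(len(signal) * TARGET_FS / fs_in))
    if method == "decimate":
        idx = np.round(np.arange(n_out) * fs_in / TARGET_FS).astype(int)
        idx = np.clip(idx, 0, len(signal) - 1)
        return signal[idx]
    if method == "linear":
        t_out = np.arange(n_out) / TARGET_FS
        t_in = np.arange(len(signal)) / fs_in
        return np.interp(t_out, t_in, signal)
    raise ValueError(f"unknown resampling method {method!r}")
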