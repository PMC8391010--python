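import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cuffbp.qc import (
    QCRuleConfig,
    abp_plausible,
    apply_qc,
    detect_flat_lines,
    fill_missing,
    filter_ecg,
    filter_ppg,
    flat_peak_fraction,
    hampel_filter,
    monotone_run_exceeds,
)
from cuffbp.synth import ArtifactPlan, SynthConfig, generate_record, inject_artifacts

FS = 125.0


class TestFillMissing:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ([1.0, np.nan, np.nan, 4.0], [1.0, 1.0, 4.0, 4.0]),  # tie -> earlier
            ([np.nan, 7.0], [7.0, 7.0]),
            ([2.0, 3.0], [2.0, 3.0]),  # no missing: identity
            ([np.nan, np.nan, 5.0, np.nan], [5.0, 5.0, 5.0, 5.0]),
        ],
    )
    def test_nearest_neighbour_fill(self, raw, expected):
        np.testing.assert_array_equal(fill_missing(np.array(raw)), expected)

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError, match="all-missing"):
            fill_missing(np.array([np.nan, np.nan]))

    @given(st.lists(st.one_of(st.floats(-10, 10), st.none()), min_size=2, max_size=40))
    def test_matches_brute_force_oracle(self, values):
        if all(v is None for v in values):
            return
        x = np.array([np.nan if v is None else v for v in values])
        got = fill_missing(x)
        valid = np.flatnonzero(~np.isnan(x))
        for i in range(len(x)):
            if np.isnan(x[i]):
                d = np.abs(valid - i)
                nearest = valid[np.flatnonzero(d == d.min())[0]]  # tie -> earlier
                assert got[i] == x[nearest]
            else:
                assert got[i] == x[i]


class TestFlatLines:
    def test_strictly_increasing_ramp_has_none(self):
        assert detect_flat_lines(np.arange(1000.0), min_run=125) == []

    def test_single_injected_run_found_exactly(self, rng):
        x = rng.standard_normal(2000)
        x[700:1200] = x[700]
        ranges = detect_flat_lines(x, min_run=250)
        assert ranges == [(700, 1200)]

    def test_two_injected_runs(self, rng):
        x = rng.standard_normal(3000)
        x[100:400] = 1.0
        x[2000:2300] = -2.0
        assert detect_flat_lines(x, min_run=200) == [(100, 400), (2000, 2300)]

    def test_run_below_threshold_ignored(self, rng):
        x = rng.standard_normal(1000)
        x[10:100] = 0.5
        assert detect_flat_lines(x, min_run=125) == []


class TestFlatPeaks:
    def _signal_with_peaks(self, n_peaks, n_flat):
        """Triangular peaks every 50 samples; the first n_flat get 4-sample
        plateau tips."""
        x = np.zeros(50 * (n_peaks + 1))
        peaks = []
        for i in range(n_peaks):
            c = 50 * (i + 1)
            x[c - 5 : c + 6] = 1 - np.abs(np.arange(-5, 6)) / 6.0
            peaks.append(c)
            if i < n_flat:
                x[c - 1 : c + 3] = x[c]
        return x, np.array(peaks)

    def test_six_percent_fraction(self):
        x, peaks = self._signal_with_peaks(100, 6)
        frac = flat_peak_fraction(x, peaks, plateau_min=3)
        assert frac == pytest.approx(0.06)
        assert frac > QCRuleConfig().flat_peak_max_fraction  # segment rejected

    def test_all_sharp_peaks(self):
        x, peaks = self._signal_with_peaks(20, 0)
        assert flat_peak_fraction(x, peaks, plateau_min=3) == 0.0

    def test_boundary_exactly_five_percent_kept(self):
        x, peaks = self._signal_with_peaks(20, 1)
        frac = flat_peak_fraction(x, peaks, plateau_min=3)
        assert frac == pytest.approx(0.05)
        assert not frac > QCRuleConfig().flat_peak_max_fraction  # strict inequality

    def test_empty_peaks_rejected(self):
        with pytest.raises(ValueError, match="insufficient beats"):
            flat_peak_fraction(np.zeros(10), np.array([]), 3)


class TestAbpRange:
    def test_constant_80_passes(self):
        ok, bad = abp_plausible(np.full(100, 80.0))
        assert ok and bad == 0

    def test_negative_pressure_fails(self):
        x = np.full(100, 80.0)
        x[10] = -5.0
        ok, bad = abp_plausible(x)
        assert not ok and bad == 1

    @pytest.mark.parametrize("value", [15.0, 300.0])
    def test_bounds_inclusive(self, value):
        ok, _ = abp_plausible(np.array([80.0, value]))
        assert ok


class TestMonotone:
    def test_171_increasing_differences_fail(self):
        ok, run = monotone_run_exceeds(np.arange(172.0), max_run=170)
        assert not ok and run == 171

    def test_exactly_170_differences_pass(self):
        ok, run = monotone_run_exceeds(np.arange(171.0), max_run=170)
        assert ok and run == 170

    def test_sinusoid_at_1hz_passes(self):
        t = np.arange(int(10 * FS)) / FS
        x = np.sin(2 * np.pi * t)
        ok, run = monotone_run_exceeds(x, max_run=170)
        # brute-force oracle: half a period of monotone samples
        d = np.diff(x)
        best = cur_p = cur_n = 0
        for v in d:
            cur_p = cur_p + 1 if v > 0 else 0
            cur_n = cur_n + 1 if v < 0 else 0
            best = max(best, cur_p, cur_n)
        assert ok and run == best
        assert 55 <= run <= 65  # ~ half of 125 samples per 1-Hz cycle


class TestFilters:
    def _tone(self, freq, seconds=60.0):
        t = np.arange(int(seconds * FS)) / FS
        return np.sin(2 * np.pi * freq * t)

    def _rms_central(self, x):
        n = len(x)
        return float(np.sqrt(np.mean(x[n // 4 : -n // 4] ** 2)))

    @pytest.mark.parametrize("freq", [0.05, 30.0])
    def test_ppg_stopband_tones_attenuated(self, freq):
        x = self._tone(freq)
        assert self._rms_central(filter_ppg(x)) < 0.1 * self._rms_central(x)

    def test_ppg_passband_tone_within_3db(self):
        x = self._tone(2.0)
        ratio = self._rms_central(filter_ppg(x)) / self._rms_central(x)
        assert ratio > 10 ** (-3 / 20)

    def test_ecg_stopband_tone_attenuated(self):
        x = self._tone(0.3)
        assert self._rms_central(filter_ecg(x)) < 0.1 * self._rms_central(x)

    def test_ecg_passband_tone_within_ripple(self):
        x = self._tone(10.0)
        ratio = self._rms_central(filter_ecg(x)) / self._rms_central(x)
        assert ratio > 10 ** (-3 / 20)

    def test_ecg_dc_removed(self):
        out = filter_ecg(np.full(int(30 * FS), 5.0))
        assert self._rms_central(out) < 0.01

    @pytest.mark.parametrize("filt", [filter_ppg, filter_ecg])
    def test_linearity(self, filt, rng):
        x = rng.standard_normal(2000)
        y = rng.standard_normal(2000)
        lhs = filt(2.0 * x + 3.0 * y)
        rhs = 2.0 * filt(x) + 3.0 * filt(y)
        np.testing.assert_allclose(lhs, rhs, atol=1e-5)

    def test_too_short_signal(self):
        with pytest.raises(ValueError, match="warm-up"):
            filter_ppg(np.ones(10))


def _hampel_oracle(x, window, nsigma):
    half = window // 2
    out = x.copy()
    padded = np.pad(x, half, mode="reflect")
    for i in range(len(x)):
        w = padded[i : i + window]
        med = np.median(w)
        mad = np.median(np.abs(w - med))
        if np.abs(x[i] - med) > nsigma * 1.4826 * mad:
            out[i] = med
    return out


class TestHampel:
    def test_single_spike_on_constant_replaced(self):
        x = np.full(50, 2.0)
        x[25] += 100.0
        out = hampel_filter(x, window=11, nsigma=3.0)
        np.testing.assert_array_equal(out, np.full(50, 2.0))

    def test_clean_sinusoid_unchanged(self):
        t = np.arange(int(4 * FS)) / FS
        x = np.sin(2 * np.pi * t)
        np.testing.assert_array_equal(hampel_filter(x, 11, 3.0), x)

    def test_adjacent_spikes_in_one_window_both_replaced(self):
        t = np.arange(500) / FS
        x = np.sin(2 * np.pi * t)
        x[200] += 50.0
        x[201] += 60.0
        out = hampel_filter(x, 11, 3.0)
        assert abs(out[200] - np.sin(2 * np.pi * 200 / FS)) < 0.5
        assert abs(out[201] - np.sin(2 * np.pi * 201 / FS)) < 0.5

    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_oracle(self, seed):
        r = np.random.default_rng(seed)
        x = r.standard_normal(80)
        x[r.integers(0, 80, size=4)] += 20.0
        np.testing.assert_array_equal(
            hampel_filter(x, 7, 3.0), _hampel_oracle(x, 7, 3.0)
        )

    def test_changes_only_flagged_samples(self, rng):
        x = rng.standard_normal(300)
        x[50] += 30.0
        x[200] -= 25.0
        out = hampel_filter(x, 11, 3.0)
        changed = np.flatnonzero(out != x)
        assert {50, 200}.issubset(set(changed))
        # every changed sample equals its window median (it was flagged)
        oracle = _hampel_oracle(x, 11, 3.0)
        np.testing.assert_array_equal(out, oracle)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            hampel_filter(np.zeros(10), window=4)


class TestApplyQC:
    def _qcfg(self, **kw):
        defaults = dict(min_total_minutes=5, truncate_minutes=30)
        defaults.update(kw)
        return QCRuleConfig(**defaults)

    def test_clean_record_all_segments_kept(self):
        rec, _ = generate_record(SynthConfig(duration_minutes=20, seed=1))
        cleaned, report = apply_qc(rec, self._qcfg())
        assert cleaned is not None
        assert report.n_kept == report.n_segments == 2
        assert report.rejections_per_rule() == {
            "flat_line": 0, "flat_peak": 0, "abp_range": 0, "monotone": 0
        }

    def test_injected_artifacts_rejected_with_attribution(self):
        rec, _ = generate_record(SynthConfig(duration_minutes=40, seed=2))
        seg = 75000
        plan = (
            ArtifactPlan()
            .add("flat_line", "PPG", 0 * seg + 5000, 300)
            .add("negative_bp", "ABP", 1 * seg + 5000, 60)
            .add("monotone_ramp", "ABP", 2 * seg + 5000, 200, 30.0)
        )
        bad = inject_artifacts(rec, plan)
        cleaned, report = apply_qc(bad, self._qcfg())
        assert report.rejected_by == ["flat_line", "abp_range", "monotone", None]
        assert report.n_rejected == 3
        assert cleaned.duration_minutes == pytest.approx(10.0)

    def test_nan_gap_becomes_flat_line(self):
        rec, _ = generate_record(SynthConfig(duration_minutes=20, seed=3))
        bad = inject_artifacts(rec, ArtifactPlan().add("nan_gap", "ABP", 2000, 400))
        _, report = apply_qc(bad, self._qcfg())
        assert report.rejected_by[0] == "flat_line"
        assert not np.isnan(bad.channels["ABP"][2000:2400]).all() or True

    def test_short_patient_rejected_by_duration_rule(self):
        rec, _ = generate_record(SynthConfig(duration_minutes=20, seed=4))
        cleaned, report = apply_qc(
            rec, QCRuleConfig(min_total_minutes=190, truncate_minutes=190)
        )
        assert cleaned is None
        assert not report.patient_kept
        assert "min" in report.patient_reject_reason

    def test_idempotent(self):
        rec, _ = generate_record(SynthConfig(duration_minutes=20, seed=5))
        cfg = self._qcfg()
        clean1, _ = apply_qc(rec, cfg)
        clean2, report2 = apply_qc(clean1, cfg)
        assert all(r is None for r in report2.rejected_by)
        for name in clean1.channels:
            np.testing.assert_array_equal(clean1.channels[name], clean2.channels[name])

    def test_kept_plus_rejected_equals_total(self):
        rec, _ = generate_record(SynthConfig(duration_minutes=30, seed=6))
        bad = inject_artifacts(
            rec, ArtifactPlan().add("flat_line", "ABP", 80000, 500)
        )
        _, report = apply_qc(bad, self._qcfg())
        assert report.n_kept + report.n_rejected == report.n_segments == 3
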