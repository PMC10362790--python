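"""QC pipeline: flat runs, Hampel, band-pass, cycles, gating, labels."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ppgvitals.io import WaveformRecord
from ppgvitals.qc import (
    CycleIndex,
    QCConfig,
    RecordRejected,
    assess_segment,
    butterworth_bandpass,
    detect_cycles,
    detect_flat_runs,
    drop_or_suture,
    extract_labels,
    flat_fraction,
    hampel_filter,
    preprocess_record,
)
from ppgvitals.synth import Artifact, GroundTruthMap, SyntheticPatientSpec, generate_record


def brute_force_flat_runs(x, min_run=3):
    """Independent O(n^2) enumeration of maximal equal-value runs."""
    runs, i, n = [], 0, len(x)
    while i < n:
        j = i
        while j + 1 < n and x[j + 1] == x[i]:
            j += 1
        if j - i + 1 >= min_run:
            runs.append((i, j - i + 1))
        i = j + 1
    return runs


class TestFlatRuns:
    @pytest.mark.parametrize(
        "x, expected",
        [
            ([1, 2, 2, 2, 3], [(1, 3)]),
            ([1, 2, 2, 3], []),
            ([5.0] * 10, [(0, 10)]),
            ([1, 1, 1, 2, 2, 2, 2], [(0, 3), (3, 4)]),
        ],
    )
    def test_exact_repetition_runs(self, x, expected):
        runs = detect_flat_runs(np.asarray(x, dtype=float))
        assert [(r.start, r.length) for r in runs] == expected

    @given(st.lists(st.integers(0, 3), min_size=1, max_size=60))
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_enumeration(self, vals):
        x = np.asarray(vals, dtype=float)
        runs = [(r.start, r.length) for r in detect_flat_runs(x)]
        assert runs == brute_force_flat_runs(x)

    def test_fraction_arithmetic(self):
        x = np.arange(2500.0)
        x[100:225] = 7.0
        runs = detect_flat_runs(x)
        assert flat_fraction(x, runs) == 125 / 2500
        assert flat_fraction(x, []) == 0.0


class TestDropOrSuture:
    def _rec(self, ppg, abp):
        return WaveformRecord("s", "r", 125.0, {"PLETH": ppg, "ABP": abp})

    def test_record_beyond_five_percent_rejected(self):
        abp = np.sin(np.arange(2500.0))
        abp[:150] = 1.0  # 6% flat
        with pytest.raises(RecordRejected, match="flat_fraction"):
            drop_or_suture(self._rec(np.sin(np.arange(2500.0) / 3), abp))

    def test_clean_record_returned_unchanged(self):
        rec = self._rec(np.sin(np.arange(2500.0) / 3), np.sin(np.arange(2500.0)))
        out = drop_or_suture(rec)
        np.testing.assert_array_equal(out.channel("PLETH"), rec.channel("PLETH"))

    def test_suture_removes_flat_samples_from_all_channels(self):
        ppg = np.sin(np.arange(2500.0) / 3)
        ppg[500:600] = ppg[500]  # 4% flat in PPG only
        abp = np.sin(np.arange(2500.0))
        out = drop_or_suture(self._rec(ppg, abp))
        assert out.n_samples == 2400
        expected_abp = np.concatenate([abp[:500], abp[600:]])
        np.testing.assert_array_equal(out.channel("ABP"), expected_abp)


def brute_force_hampel(x, window=100, n_sigmas=3.0):
    """Independent sliding median/MAD oracle (truncated centered windows)."""
    x = np.asarray(x, dtype=float)
    out = x.copy()
    half = window // 2
    for i in range(len(x)):
        win = x[max(0, i - half) : min(len(x), i + half + 1)]
        med = float(np.median(win))
        mad = float(np.median(np.abs(win - med)))
        if abs(x[i] - med) > n_sigmas * 1.4826 * mad:
            out[i] = med
    return out


class TestHampel:
    def test_constant_series_unchanged(self):
        np.testing.assert_array_equal(hampel_filter(np.full(50, 3.0)), np.full(50, 3.0))

    def test_single_outlier_replaced_by_window_median(self):
        x = np.full(200, 100.0)
        x[77] = 300.0
        out = hampel_filter(x)
        assert out[77] == 100.0
        assert np.all(out[np.arange(200) != 77] == 100.0)

    def test_inliers_pass_unchanged(self):
        rng = np.random.default_rng(0)
        x = 100 + rng.normal(0, 1, size=300)
        out = hampel_filter(x, window=50, n_sigmas=10)
        np.testing.assert_array_equal(out, x)

    @given(st.integers(0, 2**31 - 1), st.integers(5, 500))
    @settings(max_examples=30, deadline=None)
    def test_matches_brute_force_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        x[rng.integers(0, n, size=max(1, n // 20))] += rng.normal(0, 20, size=max(1, n // 20))
        np.testing.assert_array_equal(hampel_filter(x), brute_force_hampel(x))


class TestBandpass:
    def test_passband_tone_preserved_within_two_percent(self):
        t = np.arange(5000) / 125.0
        x = np.sin(2 * np.pi * 2.0 * t)
        y = butterworth_bandpass(x, 125.0)
        core = slice(500, -500)  # avoid edge transients
        assert abs(np.max(np.abs(y[core])) - 1.0) < 0.02

    def test_dc_removed(self):
        y = butterworth_bandpass(np.full(5000, 5.0), 125.0)
        assert np.max(np.abs(y)) < 1e-6 * 5.0

    def test_20hz_tone_attenuated_40db(self):
        t = np.arange(5000) / 125.0
        x = np.sin(2 * np.pi * 20.0 * t)
        y = butterworth_bandpass(x, 125.0)
        assert np.max(np.abs(y[500:-500])) < 10 ** (-40 / 20)

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError, match="band"):
            butterworth_bandpass(np.zeros(100), fs=12.0)  # high=8 >= fs/2


class TestCycleDetection:
    def test_60bpm_gives_20_peaks(self, clean_record):
        c = detect_cycles(clean_record.channel("PLETH"), 125.0)
        assert abs(len(c.peaks) - 20) <= 1
        # peaks and valleys interleave
        merged = np.sort(np.concatenate([c.peaks, c.valleys]))
        kinds = np.isin(merged, c.peaks)
        assert np.all(kinds[:-1] != kinds[1:])

    def test_40bpm_gives_13_peaks(self, noiseless_map):
        spec = SyntheticPatientSpec(patient_id="s", heart_rate_bpm=40.0)
        rec = generate_record(spec, 20.0, 125.0, seed=0, gt_map=noiseless_map)
        c = detect_cycles(rec.channel("PLETH"), 125.0)
        assert abs(len(c.peaks) - 13) <= 1

    def test_flat_line_has_no_cycles(self):
        c = detect_cycles(np.zeros(2500), 125.0)
        assert len(c.peaks) == 0 and len(c.valleys) == 0


def _synthetic_cycles(n_beats=20, fs=125.0, bad_amp_beats=()):
    """Hand-built segment: triangular beats with unit amplitude, selected
    beats doubled, returning (signal, CycleIndex)."""
    period = int(fs)
    n = n_beats * period
    x = np.zeros(n)
    valleys = [0]
    peaks = []
    for k in range(n_beats):
        v0, p = k * period, k * period + period // 2
        amp = 2.0 if k in bad_amp_beats else 1.0
        x[v0 : v0 + period // 2] = np.linspace(0, amp, period // 2, endpoint=False)
        x[p : (k + 1) * period] = np.linspace(amp, 0, period - period // 2, endpoint=False)
        peaks.append(p)
        valleys.append((k + 1) * period - 1)
    return x, CycleIndex(peaks=np.array(peaks), valleys=np.array(valleys[:-1] + [n - 1]))


class TestSegmentAssessment:
    def test_clean_segment_has_zero_anomalies(self):
        x, cyc = _synthetic_cycles()
        ok, counts = assess_segment(cyc, cyc, 125.0, ppg=x, abp=x)
        assert ok and counts == {"PLETH": 0, "ABP": 0}

    def test_exactly_three_anomalous_cycles_still_qualifies(self):
        x, cyc = _synthetic_cycles(bad_amp_beats=(2, 7, 11))
        clean_x, clean_cyc = _synthetic_cycles()
        ok, counts = assess_segment(cyc, clean_cyc, 125.0, ppg=x, abp=clean_x)
        assert counts["PLETH"] == 3 and ok

    def test_four_distorted_cycles_rejected(self):
        x, cyc = _synthetic_cycles(bad_amp_beats=(2, 7, 11, 15))
        clean_x, clean_cyc = _synthetic_cycles()
        ok, counts = assess_segment(cyc, clean_cyc, 125.0, ppg=x, abp=clean_x)
        assert counts["PLETH"] == 4 and not ok

    def test_out_of_band_cycle_lengths_flagged(self):
        # valley spacing of 0.2 s is faster than 200 bpm
        cyc = CycleIndex(peaks=np.arange(10, 100, 25), valleys=np.arange(0, 101, 25))
        ok, counts = assess_segment(cyc, cyc, 125.0)
        assert not ok or counts["PLETH"] > 0


class TestLabels:
    def test_labels_are_means_of_extrema(self):
        abp = np.zeros(100)
        peaks = np.array([10, 40, 70])
        valleys = np.array([0, 25, 55, 90])
        abp[peaks] = [120, 122, 118]
        abp[valleys] = [80, 79, 81, 80]
        cyc = CycleIndex(peaks=peaks, valleys=valleys)
        asbp, adbp, spo2 = extract_labels(abp, cyc)
        assert asbp == pytest.approx(120.0)
        assert adbp == pytest.approx(80.0)
        assert spo2 is None

    def test_degenerate_constant_abp_gives_equal_labels(self):
        cyc = CycleIndex(peaks=np.array([10, 30]), valleys=np.array([0, 20, 40]))
        asbp, adbp, _ = extract_labels(np.full(50, 100.0), cyc)
        assert asbp == adbp == 100.0  # violates asbp > adbp; pipeline rejects it

    def test_empty_cycles_raise(self):
        with pytest.raises(ValueError):
            extract_labels(np.zeros(10), CycleIndex(np.array([]), np.array([])))


class TestFullPipeline:
    def test_ten_minute_clean_record_gives_30_slices(self, noiseless_map):
        spec = SyntheticPatientSpec(patient_id="p", heart_rate_bpm=60.0)
        rec = generate_record(spec, 600.0, 125.0, seed=0, gt_map=noiseless_map)
        slices, report = preprocess_record(rec)
        assert len(slices) == 30
        assert report.rejected == {}
        assert all(len(s.ppg) == 2500 and s.asbp > s.adbp for s in slices)

    def test_noiseless_labels_match_generator_within_1mmhg(self, noiseless_map):
        spec = SyntheticPatientSpec(patient_id="p", heart_rate_bpm=72.0)
        rec = generate_record(spec, 200.0, 125.0, seed=0, gt_map=noiseless_map)
        asbp, adbp, spo2 = noiseless_map.expected_targets(spec)
        slices, _ = preprocess_record(rec)
        assert len(slices) > 0
        for s in slices:
            assert abs(s.asbp - asbp) < 1.0
            assert abs(s.adbp - adbp) < 1.0
            assert abs(s.spo2 - spo2) < 0.5

    def test_corrupted_window_rejected_others_kept(self, noiseless_map):
        arts = tuple(Artifact("motion_spike", 45.0 + 2 * k, 0.4) for k in range(4))
        spec = SyntheticPatientSpec(patient_id="p", heart_rate_bpm=60.0, artifact_plan=arts)
        rec = generate_record(spec, 200.0, 125.0, seed=3, gt_map=noiseless_map)
        slices, report = preprocess_record(rec)
        assert report.rejected.get("anomalous_cycles") == 1
        assert report.kept == 9

    def test_flat_record_rejected_with_reason(self, noiseless_map):
        spec = SyntheticPatientSpec(
            patient_id="p",
            heart_rate_bpm=60.0,
            artifact_plan=(Artifact("flat_line", 10.0, 15.0),),
        )
        rec = generate_record(spec, 200.0, 125.0, seed=0, gt_map=noiseless_map)
        slices, report = preprocess_record(rec)
        assert slices == []
        assert "flat_fraction" in report.rejected

    def test_pipeline_is_deterministic(self, noiseless_map):
        spec = SyntheticPatientSpec(patient_id="p", heart_rate_bpm=66.0, noise_sd=0.02)
        rec = generate_record(spec, 100.0, 125.0, seed=5, gt_map=noiseless_map)
        a, _ = preprocess_record(rec)
        b, _ = preprocess_record(rec)
        assert len(a) == len(b)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.ppg, sb.ppg)
            assert sa.asbp == sb.asbp
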