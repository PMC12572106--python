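"""Acceleration processing: normalization, decimation, static/dynamic
decomposition, segmentation, peak detection, the Fisher test and the
spectrogram."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crowtag import motion
from crowtag.formats_io import AccelTable
from crowtag.motion import (ContingencyTable2x2, MotionConfig, Segment,
                            accel_spectrogram, classify_segments,
                            decimate_accel, decompose_static_dynamic,
                            detect_static_peaks, extract_dive_clips,
                            fisher_exact_two_sided, normalize_accel,
                            split_low_amplitude)
from helpers_oracles import fisher_exact_enumeration, prune_peaks_brute_force


def _table(xyz, fs=50.0, t0=0.0):
    n = len(xyz)
    return AccelTable(t0 + np.arange(n) / fs, xyz[:, 0], xyz[:, 1],
                      xyz[:, 2], fs)


def _constant_trace(n=500, vec=(0.0, 0.0, 9.81), fs=50.0):
    return _table(np.tile(vec, (n, 1)), fs)


class TestNormalize:
    def test_gravity_vector_scaled_to_unit(self):
        out = normalize_accel(_constant_trace())
        assert np.allclose(out.az, 1.0, atol=1e-12)
        assert np.allclose(out.ax, 0.0)

    def test_idempotent(self, rng):
        t = _table(rng.normal(0, 1, (300, 3)) + [0, 0, 1])
        once = normalize_accel(t)
        twice = normalize_accel(once)
        assert np.allclose(once.xyz, twice.xyz, atol=1e-12)

    def test_mean_magnitude_is_one(self, rng):
        t = _table(rng.normal(0.5, 2.0, (400, 3)))
        out = normalize_accel(t)
        assert np.mean(out.magnitude()) == pytest.approx(1.0, abs=1e-9)

    def test_zero_trace_rejected(self):
        with pytest.raises(ValueError):
            normalize_accel(_constant_trace(vec=(0.0, 0.0, 0.0)))


class TestDecimate:
    def test_constant_trace_preserved(self):
        out = decimate_accel(_constant_trace(n=2000, fs=200.0), 4)
        assert out.fs == 50.0
        assert len(out) == 500
        assert np.allclose(out.az, 9.81, atol=1e-6)

    def test_passband_sine_amplitude_kept(self):
        fs, n = 200.0, 4000
        t = np.arange(n) / fs
        xyz = np.zeros((n, 3))
        xyz[:, 2] = np.sin(2 * np.pi * 1.0 * t)
        out = decimate_accel(_table(xyz, fs), 4)
        interior = out.az[50:-50]
        assert np.max(np.abs(interior)) == pytest.approx(1.0, rel=0.01)

    def test_stopband_sine_attenuated(self):
        fs, n = 200.0, 4000
        t = np.arange(n) / fs
        xyz = np.zeros((n, 3))
        xyz[:, 2] = np.sin(2 * np.pi * 40.0 * t)  # above target Nyquist
        out = decimate_accel(_table(xyz, fs), 4)
        atten_db = 20 * np.log10(np.max(np.abs(out.az[50:-50])) / 1.0)
        assert atten_db < -20.0

    def test_bad_factor_rejected(self):
        with pytest.raises(ValueError):
            decimate_accel(_constant_trace(), 0)


class TestDecomposition:
    def test_constant_goes_to_static(self):
        static, dyn = decompose_static_dynamic(_constant_trace())
        assert np.allclose(static.az, 9.81, atol=1e-9)
        assert np.allclose(dyn.az, 0.0, atol=1e-9)

    def test_additive_identity_exact(self, rng):
        t = _table(rng.normal(0, 1, (600, 3)))
        static, dyn = decompose_static_dynamic(t)
        assert np.max(np.abs(static.xyz + dyn.xyz - t.xyz)) < 1e-9

    def test_linearity(self, rng):
        x = _table(rng.normal(0, 1, (400, 3)))
        y = _table(rng.normal(0, 1, (400, 3)))
        sx, dx = decompose_static_dynamic(x)
        sy, dy = decompose_static_dynamic(y)
        sxy, dxy = decompose_static_dynamic(_table(x.xyz + y.xyz))
        assert np.allclose(dxy.xyz, dx.xyz + dy.xyz, atol=1e-9)
        assert np.allclose(sxy.xyz, sx.xyz + sy.xyz, atol=1e-9)

    def test_10hz_power_in_dynamic(self):
        fs, n = 50.0, 1000
        t = np.arange(n) / fs
        xyz = np.zeros((n, 3))
        xyz[:, 2] = np.sin(2 * np.pi * 10.0 * t)
        static, dyn = decompose_static_dynamic(_table(xyz, fs))
        total = np.sum(xyz[:, 2] ** 2)
        assert np.sum(dyn.az**2) / total > 0.95
        assert np.sum(static.az**2) / total < 0.05

    def test_slow_drift_power_in_static(self):
        fs, n = 50.0, 1000
        t = np.arange(n) / fs
        xyz = np.zeros((n, 3))
        xyz[:, 2] = np.sin(2 * np.pi * 0.2 * t)
        static, dyn = decompose_static_dynamic(_table(xyz, fs))
        total = np.sum(xyz[:, 2] ** 2)
        assert np.sum(static.az**2) / total > 0.95

    def test_too_short_trace_rejected(self):
        with pytest.raises(ValueError):
            decompose_static_dynamic(_constant_trace(n=50))


class TestDiveClips:
    def _trace(self, dur=600.0, fs=50.0):
        n = int(dur * fs)
        return _table(np.tile([0.0, 0.0, 1.0], (n, 1)), fs)

    def test_single_clip_clamped_window(self):
        clips = extract_dive_clips(self._trace(), [300.0])
        assert clips == [(240.0, 360.0)]

    def test_overlapping_clips_merged(self):
        clips = extract_dive_clips(self._trace(), [300.0, 350.0])
        assert clips == [(240.0, 410.0)]

    def test_distant_clips_stay_separate(self):
        clips = extract_dive_clips(self._trace(), [300.0, 500.0])
        assert len(clips) == 2

    def test_empty_dive_list(self):
        assert extract_dive_clips(self._trace(), []) == []

    def test_clamped_at_trace_edges(self):
        clips = extract_dive_clips(self._trace(dur=100.0), [10.0])
        assert clips[0][0] == 0.0


class TestSegmentation:
    def _clip(self, active_mask, fs=50.0, amp=0.6):
        n = len(active_mask)
        t = np.arange(n) / fs
        xyz = np.tile([0.0, 0.0, 1.0], (n, 1))
        xyz[:, 2] += amp * np.sin(2 * np.pi * 5.0 * t) * active_mask
        return _table(xyz, fs)

    def test_fully_active_single_segment(self):
        clip = self._clip(np.ones(6000))  # 120 s
        segs = split_low_amplitude(clip)
        assert len(segs) == 1
        assert segs[0].stop_s - segs[0].start_s == pytest.approx(120.0, abs=0.1)

    def test_short_tail_dropped(self):
        # active 30 s / quiet 6 s / active 15 s -> only the 30-s span kept
        mask = np.ones(int(51 * 50))
        mask[30 * 50: 36 * 50] = 0.0
        segs = split_low_amplitude(self._clip(mask))
        assert len(segs) == 1
        assert segs[0].stop_s - segs[0].start_s == pytest.approx(30.0, abs=0.3)

    def test_sub_5s_gap_does_not_split(self):
        mask = np.ones(int(60 * 50))
        mask[25 * 50: 28 * 50] = 0.0  # 3-s lull, below the separator span
        segs = split_low_amplitude(self._clip(mask))
        assert len(segs) == 1

    def test_segments_disjoint_ordered_within_clip(self, rng):
        mask = np.ones(int(150 * 50))
        for start in (30, 70, 110):
            mask[start * 50: (start + 7) * 50] = 0.0
        clip = self._clip(mask)
        segs = split_low_amplitude(clip)
        for a, b in zip(segs, segs[1:]):
            assert a.stop_s <= b.start_s
        for s in segs:
            assert clip.t[0] <= s.start_s < s.stop_s <= clip.t[-1] + 0.03


class TestPeakDetection:
    def test_flat_series_no_peaks(self):
        assert detect_static_peaks(np.ones(500), 50.0) == []

    def test_close_bumps_keep_higher(self):
        fs = 50.0
        t = np.arange(500) / fs
        z = np.ones(500)
        z += 1.2 * np.exp(-0.5 * ((t - 4.0) / 0.1) ** 2)   # peak 2.2
        z += 1.0 * np.exp(-0.5 * ((t - 4.5) / 0.1) ** 2)   # peak 2.0, 0.5 s later
        peaks = detect_static_peaks(z, fs)
        assert len(peaks) == 1
        assert abs(peaks[0] - 4.0) < 0.1

    def test_planted_peaks_all_recovered(self):
        fs = 50.0
        t = np.arange(1000) / fs
        z = np.ones(1000)
        planted = [4.0, 8.0, 14.0]
        for c in planted:
            z += 0.9 * np.exp(-0.5 * ((t - c) / 0.15) ** 2)  # reaches 1.9
        peaks = detect_static_peaks(z, fs)
        assert len(peaks) == 3
        for p, c in zip(peaks, planted):
            assert abs(p - c) < 0.1

    @pytest.mark.parametrize("seed", range(20))
    def test_equals_pruning_oracle(self, seed):
        r = np.random.default_rng(seed)
        fs = 50.0
        t = np.arange(1500) / fs
        z = np.ones(1500)
        for _ in range(int(r.integers(1, 8))):
            c = float(r.uniform(2.0, 28.0))
            h = float(r.uniform(0.5, 1.5))
            z += h * np.exp(-0.5 * ((t - c) / float(r.uniform(0.08, 0.3))) ** 2)
        got = detect_static_peaks(z, fs)
        expected = [i / fs for i in prune_peaks_brute_force(z, 1.8, 50)]
        assert got == pytest.approx(expected)


class TestClassifyAndFisher:
    def test_tally(self):
        segs = [
            Segment(0, 30, "dive", [5.0]),
            Segment(40, 70, "dive", [50.0, 60.0]),
            Segment(80, 110, "dive", []),
            Segment(120, 150, "non_dive", []),
        ]
        tbl = classify_segments(segs)
        assert (tbl.a, tbl.b, tbl.c, tbl.d) == (2, 1, 0, 1)

    def test_empty_input_zero_table(self):
        tbl = classify_segments([])
        assert (tbl.a, tbl.b, tbl.c, tbl.d) == (0, 0, 0, 0)

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError):
            classify_segments([Segment(0, 30, "swimming", [])])

    def test_study_contingency_p_value(self):
        p = fisher_exact_two_sided(ContingencyTable2x2(11, 9, 3, 17))
        assert p == pytest.approx(fisher_exact_enumeration(11, 9, 3, 17),
                                  rel=1e-10)
        assert 0.018 <= p < 0.019  # prints as 0.018

    def test_balanced_table_p_one(self):
        assert fisher_exact_two_sided(ContingencyTable2x2(5, 5, 5, 5)) == 1.0

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_two_sided(ContingencyTable2x2(0, 0, 3, 17))

    @given(
        a=st.integers(0, 12), b=st.integers(0, 12),
        c=st.integers(0, 12), d=st.integers(0, 12),
    )
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_matches_enumeration_oracle(self, a, b, c, d):
        if min(a + b, c + d, a + c, b + d) == 0:
            return
        p = fisher_exact_two_sided(ContingencyTable2x2(a, b, c, d))
        assert 0.0 < p <= 1.0
        assert p == pytest.approx(fisher_exact_enumeration(a, b, c, d),
                                  rel=1e-9)

    @given(
        a=st.integers(1, 12), b=st.integers(1, 12),
        c=st.integers(1, 12), d=st.integers(1, 12),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_invariant_under_row_and_column_swap(self, a, b, c, d):
        p1 = fisher_exact_two_sided(ContingencyTable2x2(a, b, c, d))
        p2 = fisher_exact_two_sided(ContingencyTable2x2(d, c, b, a))
        assert p1 == pytest.approx(p2, rel=1e-12)


class TestSpectrogram:
    def test_pure_tone_peak_bin(self):
        fs, n = 50.0, 2000
        t = np.arange(n) / fs
        x = np.sin(2 * np.pi * 10.0 * t)
        freqs, times, mag = accel_spectrogram(x, fs)
        target_bin = np.argmin(np.abs(freqs - 10.0))
        interior = mag[:, 10:-10]
        assert np.all(np.argmax(interior, axis=0) == target_bin)

    def test_zeros_all_zero(self):
        _, _, mag = accel_spectrogram(np.zeros(500), 50.0)
        assert not mag.any()

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            accel_spectrogram(np.zeros(100), 50.0)

    def test_frame_energy_parseval(self, rng):
        fs = 50.0
        x = rng.normal(0, 1, 1000)
        cfg = MotionConfig()
        freqs, times, mag = accel_spectrogram(x, fs, cfg)
        win = __import__("scipy.signal", fromlist=["windows"]).windows.hann(
            cfg.spec_win, sym=False)
        half = cfg.spec_win // 2
        padded = np.concatenate([np.zeros(half), x, np.zeros(half)])
        k = 20  # an interior frame
        frame = padded[k * cfg.spec_hop: k * cfg.spec_hop + cfg.spec_win] * win
        direct = np.sum(frame**2)
        spec = mag[:, k] ** 2
        via_fft = (spec[0] + 2 * np.sum(spec[1:-1]) + spec[-1]) / cfg.spec_nfft
        assert via_fft == pytest.approx(direct, rel=0.01)


class TestEndToEnd:
    def test_dive_vs_flight_discrimination(self):
        from crowtag.synthgen import AccelScenarioSpec, generate_accel_trace
        spec = AccelScenarioSpec(
            duration_s=600.0,
            dive_events=((150.0, 2.2, 1.5),),
            quiet_gaps=((90.0, 96.0), (210.0, 216.0), (300.0, 306.0)),
            seed=21,
        )
        trace, truth = generate_accel_trace(spec)
        segments, tbl, p = motion.dive_discrimination(
            trace, [150.0], [(306.0, 600.0)]
        )
        assert tbl.a >= 1      # the dive segment carries a peak
        assert tbl.c == 0      # ordinary flight does not
        assert 0.0 < p <= 1.0
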