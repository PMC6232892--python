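"""Filter response and time-domain feature oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal as sps

from myotrain.core import CueEntry, CueSchedule, EMGRecording, LabelStream
from myotrain.signal import (
    FeatureConfig,
    FilterSpec,
    apply_filter,
    curve_length,
    design_highpass,
    extract_features,
    mav,
    slope_sign_changes,
    zero_crossings,
)

window = st.lists(
    st.floats(min_value=-10, max_value=10, allow_nan=False), min_size=3, max_size=60
).map(np.array)


def gain_at(b, a, f_hz, fs):
    _, h = sps.freqz(b, a, worN=[f_hz], fs=fs)
    return abs(h[0])


class TestHighpassDesign:
    def test_dc_gain_vanishes(self):
        b, a = design_highpass(FilterSpec())
        assert gain_at(b, a, 0.0, 1000.0) < 1e-6

    def test_minus_3db_at_break_frequency(self):
        b, a = design_highpass(FilterSpec())
        assert gain_at(b, a, 20.0, 1000.0) == pytest.approx(2 ** -0.5, abs=0.005)

    def test_passband_gain_matches_analytic_butterworth(self):
        # |H(f)| = sqrt(1 / (1 + (fc/f)^(2n))) for an analog high-pass
        # prototype; the bilinear design warps frequencies, so compare at a
        # passband point where both are ~1.
        b, a = design_highpass(FilterSpec())
        analytic = (1.0 / (1.0 + (20.0 / 400.0) ** 6)) ** 0.5
        assert analytic == pytest.approx(1.0, abs=1e-6)
        assert 0.99 <= gain_at(b, a, 400.0, 1000.0) <= 1.01

    def test_cutoff_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            FilterSpec(cutoff_hz=600.0, sample_rate=1000.0)


class TestApplyFilter:
    def test_dc_is_rejected(self):
        rec = EMGRecording(np.full((2, 4000), 3.0))
        out = apply_filter(rec)
        assert np.abs(out.samples[:, -500:].mean()) < 1e-3 * 3.0

    def test_zero_in_zero_out(self):
        rec = EMGRecording(np.zeros((3, 100)))
        out = apply_filter(rec)
        assert np.all(out.samples == 0)

    def test_low_frequency_attenuation_matches_analytic_magnitude(self):
        # 5 Hz is f/fc = 0.25; analytic 3rd-order HP magnitude there is
        # (1 + (1/0.25)^6)^(-1/2) ~= 0.0156, far below the 0.2 bound.
        t = np.arange(0, 8.0, 1e-3)
        rec = EMGRecording(np.sin(2 * np.pi * 5 * t)[None, :])
        out = apply_filter(rec)
        steady = out.samples[0, 4000:]
        assert steady.max() < 0.2
        analytic = (1.0 + (20.0 / 5.0) ** 6) ** -0.5
        assert steady.max() == pytest.approx(analytic, rel=0.15)

    def test_zero_phase_mode_has_no_delay(self):
        t = np.arange(0, 4.0, 1e-3)
        x = np.sin(2 * np.pi * 100 * t)[None, :]
        rec = EMGRecording(x)
        causal = apply_filter(rec, mode="causal").samples[0]
        zero_phase = apply_filter(rec, mode="zero-phase").samples[0]
        mid = slice(1000, 3000)
        # 100 Hz is deep in the passband: zero-phase output tracks the input.
        assert np.corrcoef(zero_phase[mid], x[0][mid])[0, 1] > 0.9999
        assert np.corrcoef(causal[mid], x[0][mid])[0, 1] < 0.9999

    def test_too_short_recording_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            apply_filter(EMGRecording(np.zeros((1, 5))))


class TestFeaturePrimitives:
    @pytest.mark.parametrize(
        "x, expected",
        [([1, -2, 3], 2.0), ([0, 0, 0, 0], 0.0), ([-5], 5.0)],
    )
    def test_mav_examples(self, x, expected):
        assert mav(np.array(x, dtype=float)) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "x, expected",
        [([0, 1, 0, 1], 3.0), ([2, 2, 2], 0.0), ([0, 1, 2, 3, 4, 5], 5.0)],
    )
    def test_curve_length_examples(self, x, expected):
        assert curve_length(np.array(x, dtype=float)) == pytest.approx(expected)

    def test_curve_length_of_monotone_ramp_telescopes(self):
        for n in (2, 7, 50):
            ramp = np.linspace(0.0, 5.0, n)
            assert curve_length(ramp) == pytest.approx(5.0)

    @pytest.mark.parametrize(
        "x, thresh, expected",
        [
            ([1, -1, 1, -1], 0.0, 3),
            ([1, -1, 1, -1], 5.0, 0),  # threshold above max step
            ([1, 2, 3], 0.0, 0),
        ],
    )
    def test_zero_crossings_examples(self, x, thresh, expected):
        assert zero_crossings(np.array(x, dtype=float), thresh) == expected

    @pytest.mark.parametrize(
        "x, thresh, expected",
        [
            ([0, 1, 0, 1, 0], 0.0, 3),
            ([0, 1, 2, 3], 0.0, 0),  # monotone ramp
            ([0, 1, 0, 1, 0], 5.0, 0),
        ],
    )
    def test_slope_sign_changes_examples(self, x, thresh, expected):
        assert slope_sign_changes(np.array(x, dtype=float), thresh) == expected

    @pytest.mark.parametrize("fn", [mav, curve_length])
    def test_empty_or_short_windows_rejected(self, fn):
        with pytest.raises(ValueError):
            fn(np.array([]))
        with pytest.raises(ValueError):
            zero_crossings(np.array([1.0]))
        with pytest.raises(ValueError):
            slope_sign_changes(np.array([1.0, 2.0]))

    @given(window, st.floats(min_value=-5, max_value=5, allow_nan=False))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_mav_and_cl_scale_equivariance(self, x, a):
        assert mav(a * x) == pytest.approx(abs(a) * mav(x), abs=1e-9)
        assert curve_length(a * x) == pytest.approx(abs(a) * curve_length(x), abs=1e-9)

    @given(window)
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_zc_and_ssc_sign_flip_invariance(self, x):
        assert zero_crossings(x, 0.0) == zero_crossings(-x, 0.0)
        assert slope_sign_changes(x, 0.0) == slope_sign_changes(-x, 0.0)

    @given(window)
    @settings(deadline=None, max_examples=30, derandomize=True)
    def test_deadband_above_all_steps_silences_counts(self, x):
        thresh = float(np.max(np.abs(np.diff(x)))) + 1.0
        assert zero_crossings(x, thresh) == 0
        assert slope_sign_changes(x, thresh) == 0


class TestExtractFeatures:
    def test_window_count_for_ten_second_recording(self, rng):
        rec = EMGRecording(rng.standard_normal((8, 10_000)))
        feats = extract_features(rec, None, FeatureConfig())
        assert len(feats) == 99
        assert feats.values.shape == (99, 32)

    def test_all_zero_recording_gives_all_zero_features(self):
        rec = EMGRecording(np.zeros((4, 1000)))
        feats = extract_features(rec)
        assert np.all(feats.values == 0)

    def test_matches_per_window_loop_oracle_exactly(self, rng):
        cfg = FeatureConfig(window_ms=50, stride_ms=30, zc_threshold=0.2,
                            ssc_threshold=0.1)
        rec = EMGRecording(rng.standard_normal((3, 700)))
        feats = extract_features(rec, None, cfg)
        win, stride = 50, 30
        for w in range(len(feats)):
            for c in range(3):
                seg = rec.samples[c, w * stride : w * stride + win]
                expected = [
                    mav(seg),
                    curve_length(seg),
                    zero_crossings(seg, 0.2),
                    slope_sign_changes(seg, 0.1),
                ]
                assert feats.values[w, c * 4 : c * 4 + 4] == pytest.approx(expected)

    def test_labels_come_from_cue_at_window_center(self, rng):
        rec = EMGRecording(rng.standard_normal((1, 1000)))
        sched = CueSchedule([CueEntry(7, 0.0, 0.25), CueEntry(2, 0.5, 0.5)])
        feats = extract_features(rec, sched, FeatureConfig())
        # centers at 0.1, 0.2, ... , 0.9 s; the cue interval is half-open
        assert feats.labels.labels.tolist() == [7, 7, -1, -1, 2, 2, 2, 2, 2]

    def test_per_sample_label_stream_read_at_center(self, rng):
        rec = EMGRecording(rng.standard_normal((1, 400)))
        labels = np.full(400, -1)
        labels[:200] = 4
        feats = extract_features(rec, LabelStream(labels), FeatureConfig())
        assert feats.labels.labels.tolist() == [4, -1, -1]

    def test_recording_shorter_than_window_rejected(self, rng):
        rec = EMGRecording(rng.standard_normal((1, 100)))
        with pytest.raises(ValueError, match="shorter than one"):
            extract_features(rec, None, FeatureConfig(window_ms=200, stride_ms=100))

    def test_column_names_are_channel_major(self, rng):
        rec = EMGRecording(rng.standard_normal((2, 1000)))
        feats = extract_features(rec)
        assert feats.column_names[:5] == [
            "ch0_MAV", "ch0_CL", "ch0_ZC", "ch0_SSC", "ch1_MAV",
        ]

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            FeatureConfig(window_ms=50, stride_ms=100)
        with pytest.raises(ValueError):
            FeatureConfig(zc_threshold=-1)
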