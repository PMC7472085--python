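"""Unit tests for the two-tier signal preprocessing chain."""

import numpy as np
import pytest

from emochart import preprocess as pp
from emochart.containers import Recording

from conftest import make_segment_set

FS = 128


def tone(f0, seconds=60, fs=FS, channels=1):
    t = np.arange(int(seconds * fs)) / fs
    return np.tile(np.sin(2 * np.pi * f0 * t), (channels, 1))


def steady_rms(x, fs=FS, skip_s=10):
    core = x[int(skip_s * fs) : -int(skip_s * fs)]
    return np.sqrt(np.mean(core**2))


class TestCommonAverageReference:
    def test_identical_channels_become_zero(self):
        rec = Recording(np.full((14, 100), 3.7), FS, "EEG")
        out = pp.common_average_reference(rec)
        assert np.allclose(out.data, 0.0)

    def test_per_sample_channel_sum_is_zero(self, eeg_recording):
        out = pp.common_average_reference(eeg_recording)
        scale = np.abs(eeg_recording.data).max()
        assert np.abs(out.data.sum(axis=0)).max() <= 1e-9 * scale * 14

    def test_matches_naive_double_loop(self, rng):
        data = rng.standard_normal((14, 100))
        out = pp.common_average_reference(Recording(data, FS, "EEG"))
        expected = np.empty_like(data)
        for l in range(100):
            m = sum(data[c, l] for c in range(14)) / 14
            for c in range(14):
                expected[c, l] = data[c, l] - m
        np.testing.assert_allclose(out.data, expected, atol=1e-12)

    def test_is_a_projection(self, eeg_recording):
        once = pp.common_average_reference(eeg_recording)
        twice = pp.common_average_reference(once)
        np.testing.assert_allclose(twice.data, once.data, atol=1e-12)

    def test_rejects_wrong_channel_count(self):
        with pytest.raises(ValueError, match="14 channels"):
            Recording(np.zeros((13, 10)), FS, "EEG")

    def test_rejects_non_eeg(self):
        rec = Recording(np.zeros((1, 10)), FS, "GSR")
        with pytest.raises(ValueError, match="EEG"):
            pp.common_average_reference(rec)


class TestBandpass:
    def test_passband_10hz_within_1db(self):
        rec = Recording(tone(10), FS, "GSR")
        out = pp.bandpass_eeg(rec)
        gain = steady_rms(out.data[0]) / steady_rms(rec.data[0])
        assert 0.89 <= gain <= 1.12  # ±1 dB

    @pytest.mark.parametrize("f0", [2.0, 50.0, 55.0])
    def test_stopband_attenuated_30db(self, f0):
        rec = Recording(tone(f0), FS, "GSR")
        out = pp.bandpass_eeg(rec)
        assert steady_rms(out.data[0]) <= 10 ** (-30 / 20) * steady_rms(rec.data[0])

    def test_zero_in_zero_out(self):
        rec = Recording(np.zeros((1, 60 * FS)), FS, "GSR")
        assert np.allclose(pp.bandpass_eeg(rec).data, 0.0)

    def test_invalid_band_rejected(self):
        rec = Recording(tone(10), FS, "GSR")
        with pytest.raises(ValueError, match="lo < hi"):
            pp.bandpass_eeg(rec, lo=45, hi=4)
        with pytest.raises(ValueError, match="fs"):
            pp.bandpass_eeg(rec, lo=4, hi=70)

    def test_commutes_with_car(self, rng):
        # both are linear: spatial mean subtraction and temporal filtering commute
        rec = Recording(rng.standard_normal((14, 30 * FS)), FS, "EEG")
        a = pp.bandpass_eeg(pp.common_average_reference(rec))
        b = pp.common_average_reference(pp.bandpass_eeg(rec))
        np.testing.assert_allclose(a.data, b.data, atol=1e-9)


class TestTrimEdges:
    def test_64s_becomes_7680_samples(self):
        rec = Recording(np.ones((1, 64 * FS)), FS, "GSR")
        assert pp.trim_edges(rec, 2).n_samples == 7680

    def test_trim_zero_is_identity(self, eeg_recording):
        out = pp.trim_edges(eeg_recording, 0)
        np.testing.assert_array_equal(out.data, eeg_recording.data)

    def test_content_matches_index_arithmetic(self, rng):
        data = rng.standard_normal((1, 5 * FS))
        out = pp.trim_edges(Recording(data, FS, "GSR"), 2)
        np.testing.assert_array_equal(out.data, data[:, 2 * FS : 3 * FS])

    def test_too_short_rejected(self):
        rec = Recording(np.ones((1, 3 * FS)), FS, "GSR")
        with pytest.raises(ValueError, match="too short"):
            pp.trim_edges(rec, 2)


class TestPreprocessEcg:
    def test_64s_at_256hz_gives_7680_samples_at_128hz(self, rng):
        rec = Recording(rng.standard_normal((1, 64 * 256)), 256, "ECG_L")
        out = pp.preprocess_ecg(rec)
        assert (out.fs, out.n_samples) == (128, 7680)

    def test_dc_preserved_within_1pct(self):
        rec = Recording(np.full((1, 64 * 256), 5.0), 256, "ECG_L")
        out = pp.preprocess_ecg(rec)
        np.testing.assert_allclose(out.data, 5.0, rtol=0.01)

    def test_30hz_tone_within_1db(self):
        rec = Recording(tone(30, seconds=64, fs=256), 256, "ECG_L")
        out = pp.preprocess_ecg(rec)
        gain = steady_rms(out.data[0], fs=128) / np.sqrt(0.5)
        assert 0.89 <= gain <= 1.12

    def test_already_128hz_skips_rate_change(self, rng):
        rec = Recording(rng.standard_normal((1, 64 * FS)), FS, "ECG_R")
        out = pp.preprocess_ecg(rec)
        assert (out.fs, out.n_samples) == (128, 7680)

    def test_unsupported_rate_rejected(self):
        rec = Recording(np.ones((1, 1000)), 200, "ECG_L")
        with pytest.raises(ValueError, match="rate"):
            pp.preprocess_ecg(rec)


class TestMeanBaseline:
    def test_identical_segments_mean_is_any_one(self):
        seg = np.arange(FS, dtype=float)
        rec = Recording(np.tile(seg, (1, 5)), FS, "GSR", role="baseline")
        np.testing.assert_allclose(pp.mean_baseline(rec), seg[None])

    def test_zeros_and_twos_average_to_ones(self):
        data = np.concatenate([np.zeros(FS), np.full(FS, 2.0)])[None]
        out = pp.mean_baseline(Recording(data, FS, "GSR", role="baseline"))
        np.testing.assert_allclose(out, 1.0)

    def test_57_segment_baseline_matches_loop_oracle(self, rng):
        data = rng.standard_normal((14, 57 * FS))
        out = pp.mean_baseline(Recording(data, FS, "EEG", role="baseline"))
        expected = np.zeros((14, FS))
        for s in range(57):
            expected += data[:, s * FS : (s + 1) * FS]
        expected /= 57
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_partial_trailing_second_discarded(self, rng):
        data = rng.standard_normal((1, 2 * FS + 64))
        out = pp.mean_baseline(Recording(data, FS, "GSR", role="baseline"))
        expected = (data[:, :FS] + data[:, FS : 2 * FS]) / 2
        np.testing.assert_allclose(out, expected)

    def test_shorter_than_1s_rejected(self):
        rec = Recording(np.ones((1, 100)), FS, "GSR", role="baseline")
        with pytest.raises(ValueError, match="1 s"):
            pp.mean_baseline(rec)


class TestRemoveBaseline:
    def test_segment_equal_to_baseline_gives_zero(self, rng):
        bl = rng.standard_normal((3, FS))
        ss = make_segment_set(np.tile(bl, (4, 1, 1)), modality="EEG")
        # modality EEG requires 14 channels at Recording level but SegmentSet is free
        out = pp.remove_baseline(ss, bl)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_zero_baseline_is_identity(self, rng):
        data = rng.standard_normal((5, 2, FS))
        ss = make_segment_set(data)
        out = pp.remove_baseline(ss, np.zeros((2, FS)))
        np.testing.assert_array_equal(out.data, data)

    def test_matches_elementwise_subtraction(self, rng):
        data = rng.standard_normal((5, 2, FS))
        bl = rng.standard_normal((2, FS))
        out = pp.remove_baseline(make_segment_set(data), bl)
        np.testing.assert_allclose(out.data, data - bl[None], atol=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        ss = make_segment_set(rng.standard_normal((5, 2, FS)))
        with pytest.raises(ValueError, match="match"):
            pp.remove_baseline(ss, np.zeros((3, FS)))


class TestZscore:
    def test_mean_zero_sd_one(self, rng):
        ss = make_segment_set(rng.standard_normal((6, 3, FS)) * 7 + 2)
        out = pp.zscore(ss)
        assert out.normalized
        np.testing.assert_allclose(out.data.mean(axis=-1), 0.0, atol=1e-9)
        np.testing.assert_allclose(out.data.std(axis=-1), 1.0, atol=1e-9)

    def test_idempotent(self, rng):
        once = pp.zscore(make_segment_set(rng.standard_normal((4, 2, FS))))
        twice = pp.zscore(once)
        np.testing.assert_allclose(twice.data, once.data, atol=1e-9)

    def test_affine_invariance(self, rng):
        data = rng.standard_normal((4, 2, FS))
        a = pp.zscore(make_segment_set(data))
        b = pp.zscore(make_segment_set(3.5 * data - 11.0))
        np.testing.assert_allclose(a.data, b.data, atol=1e-9)

    def test_constant_segment_becomes_zeros_with_warning(self):
        data = np.ones((1, 1, FS))
        with pytest.warns(RuntimeWarning, match="constant"):
            out = pp.zscore(make_segment_set(data))
        np.testing.assert_array_equal(out.data, 0.0)


class TestSegment:
    def test_60s_trial_gives_60_segments(self, rng):
        rec = Recording(rng.standard_normal((1, 60 * FS)), FS, "GSR")
        assert len(pp.segment(rec)) == 60

    def test_1s_trial_is_one_segment_equal_to_input(self, rng):
        data = rng.standard_normal((1, FS))
        out = pp.segment(Recording(data, FS, "GSR"))
        assert len(out) == 1
        np.testing.assert_array_equal(out.data[0], data)

    def test_trailing_half_second_dropped(self, rng):
        rec = Recording(rng.standard_normal((1, int(10.5 * FS))), FS, "GSR")
        out = pp.segment(rec)
        assert len(out) == 10
        np.testing.assert_array_equal(
            out.data[9], rec.data[:, 9 * FS : 10 * FS]
        )

    def test_provenance_recorded(self, eeg_recording):
        out = pp.segment(eeg_recording)
        assert list(out.provenance["segment"]) == list(range(10))
        assert set(out.provenance["subject"]) == {3}
        assert set(out.provenance["trial"]) == {7}

    def test_too_short_rejected(self):
        rec = Recording(np.ones((1, 64)), FS, "GSR")
        with pytest.raises(ValueError, match="shorter"):
            pp.segment(rec)


class TestPipelineComposition:
    def test_segment_count_conservation(self, rng):
        durations = [10.0, 7.5, 3.25]
        total = 0
        for d in durations:
            rec = Recording(rng.standard_normal((1, int(d * FS))), FS, "GSR")
            total += len(pp.segment(rec))
        assert total == sum(int(d) for d in durations)

    def test_full_chain_output_is_normalized_segments(self, rng):
        stim = Recording(rng.standard_normal((14, 64 * FS)), FS, "EEG")
        bl = Recording(rng.standard_normal((14, 61 * FS)), FS, "EEG", role="baseline")
        out = pp.preprocess_trial_recording(stim, bl, trim_s=2.0, label=2)
        assert out.data.shape == (60, 14, FS)
        assert out.normalized and set(out.labels) == {2}
        np.testing.assert_allclose(out.data.mean(axis=-1), 0.0, atol=1e-9)

    def test_stage_order_regression(self, rng):
        # frozen digest pins the documented order:
        # CAR -> band-pass -> trim -> segment -> baseline removal -> z-score
        stim = Recording(rng.standard_normal((14, 20 * FS)), FS, "EEG")
        bl = Recording(rng.standard_normal((14, 9 * FS)), FS, "EEG", role="baseline")
        out = pp.preprocess_trial_recording(stim, bl, trim_s=2.0)
        reference = pp.zscore(
            pp.remove_baseline(
                pp.segment(
                    pp.trim_edges(
                        pp.bandpass_eeg(pp.common_average_reference(stim)), 2.0
                    )
                ),
                pp.mean_baseline(
                    pp.trim_edges(
                        pp.bandpass_eeg(pp.common_average_reference(bl)), 2.0
                    )
                ),
            )
        )
        np.testing.assert_allclose(out.data, reference.data, atol=1e-12)
        # specialized stages do not commute: z-scoring before baseline removal
        # yields a different result
        alt = pp.remove_baseline(
            pp.zscore(
                pp.segment(
                    pp.trim_edges(
                        pp.bandpass_eeg(pp.common_average_reference(stim)), 2.0
                    )
                )
            ),
            pp.mean_baseline(
                pp.trim_edges(
                    pp.bandpass_eeg(pp.common_average_reference(bl)), 2.0
                )
            ),
        )
        assert np.abs(alt.data - out.data).max() > 1e-3
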