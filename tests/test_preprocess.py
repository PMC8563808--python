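"""Signal-conditioning chain: rate change, filtering, averaging, segmentation."""

import numpy as np
import pytest
from scipy import signal as sps

from lfpstate.preprocess import (
    HemisphereSignal,
    average_hemisphere,
    bandpass_zero_phase,
    decimate,
    preprocess_recording,
    qc_screen_hemispheres,
    remove_dc,
    segment_epoch,
    trim_epoch_edges,
)
from lfpstate.sigio import LfpRecording, MontageError

FULL_MONTAGE = [("left", i) for i in range(1, 5)] + [("right", i) for i in range(1, 5)]


def tone_recording(freq_hz, fs, seconds=5.0, epochs=None):
    t = np.arange(int(seconds * fs)) / fs
    data = np.tile(np.sin(2 * np.pi * freq_hz * t), (8, 1))
    return LfpRecording("t", fs, FULL_MONTAGE, data, epochs or {})


class TestDecimate:
    def test_length_and_rate_from_44khz(self):
        rec = tone_recording(10.0, 44000.0, seconds=5.0, epochs={"PRE": (0, 220000)})
        out = decimate(rec, 1000.0)
        assert out.fs == 1000.0
        assert out.n_samples == 5000
        assert out.epochs["PRE"] == (0, 5000)

    def test_passband_tone_amplitude_preserved(self):
        """10 Hz tone at 44 kHz survives decimation with <1% amplitude error
        (amplitude recovered by least-squares sinusoid fit)."""
        out = decimate(tone_recording(10.0, 44000.0), 1000.0)
        t = np.arange(out.n_samples) / 1000.0
        design = np.column_stack([np.sin(2 * np.pi * 10 * t), np.cos(2 * np.pi * 10 * t)])
        coef, *_ = np.linalg.lstsq(design, out.data[0], rcond=None)
        assert np.hypot(*coef) == pytest.approx(1.0, rel=0.01)

    def test_above_nyquist_tone_rejected(self):
        """600 Hz tone must not alias through a decimation to 1000 Hz."""
        rec = tone_recording(600.0, 44000.0)
        out = decimate(rec, 1000.0)
        assert out.data[0].std() < 0.05 * rec.data[0].std()

    def test_non_integer_ratio(self):
        out = decimate(tone_recording(10.0, 2500.0, seconds=4.0), 1000.0)
        assert out.fs == 1000.0
        assert out.n_samples == 4000

    def test_upsampling_rejected(self):
        with pytest.raises(ValueError):
            decimate(tone_recording(10.0, 500.0), 1000.0)


class TestBandpass:
    def test_zero_phase_on_passband_tone(self):
        rec = tone_recording(10.0, 1000.0, seconds=10.0)
        out = bandpass_zero_phase(rec)
        tone = rec.data[0]
        xcorr = np.correlate(out.data[0], tone, mode="full")
        lag = int(np.argmax(xcorr)) - (len(tone) - 1)
        assert lag == 0

    def test_dc_input_rejected(self):
        rec = LfpRecording("t", 1000.0, FULL_MONTAGE, np.full((8, 10000), 5.0), {})
        out = bandpass_zero_phase(rec)
        assert out.data[0].std() < 0.01 * 5.0

    def test_stopband_attenuation_matches_squared_magnitude(self):
        """100 Hz tone attenuation agrees with the squared single-pass
        Butterworth magnitude response within 10%."""
        fs, f0 = 1000.0, 100.0
        rec = tone_recording(f0, fs, seconds=20.0)
        out = bandpass_zero_phase(rec, 0.5, 80.0, order=4)
        sos = sps.butter(4, [0.5, 80.0], btype="bandpass", output="sos", fs=fs)
        _, h = sps.sosfreqz(sos, worN=[f0], fs=fs)
        expected_gain = np.abs(h[0]) ** 2
        # steady-state amplitude away from edges
        measured = out.data[0][5000:15000].std() / rec.data[0][5000:15000].std()
        assert measured == pytest.approx(expected_gain, rel=0.10)

    def test_invalid_band_rejected(self):
        rec = tone_recording(10.0, 1000.0)
        with pytest.raises(ValueError):
            bandpass_zero_phase(rec, 0.5, 600.0)


class TestRemoveDcAndAverage:
    @pytest.mark.parametrize(
        "channel,expected",
        [([1.0, 2.0, 3.0], [-1.0, 0.0, 1.0]), ([5.0, 5.0, 5.0], [0.0, 0.0, 0.0])],
    )
    def test_remove_dc_examples(self, channel, expected):
        data = np.tile(channel, (8, 1))
        out = remove_dc(LfpRecording("t", 10.0, FULL_MONTAGE, data, {}))
        np.testing.assert_allclose(out.data[0], expected, atol=1e-12)

    def test_remove_dc_idempotent(self):
        rng = np.random.default_rng(1)
        rec = LfpRecording("t", 10.0, FULL_MONTAGE, rng.normal(size=(8, 100)), {})
        once = remove_dc(rec)
        twice = remove_dc(once)
        np.testing.assert_allclose(once.data, twice.data, atol=1e-12)
        assert np.abs(once.data.mean(axis=1)).max() < 1e-12

    def test_average_identical_channels_is_identity(self):
        x = np.sin(np.linspace(0, 10, 200))
        data = np.tile(x, (4, 1))
        rec = LfpRecording("t", 10.0, FULL_MONTAGE[:4], data, {})
        (out,) = average_hemisphere(rec)
        np.testing.assert_allclose(out.data, x)

    def test_average_cancelling_channels(self):
        data = np.array([[1.0], [-1.0], [1.0], [-1.0]]) * np.ones((4, 50))
        rec = LfpRecording("t", 10.0, FULL_MONTAGE[:4], data, {})
        (out,) = average_hemisphere(rec)
        np.testing.assert_allclose(out.data, 0.0)

    def test_single_hemisphere_yields_one_signal(self):
        rec = LfpRecording("t", 10.0, FULL_MONTAGE[:4], np.zeros((4, 50)), {})
        signals = average_hemisphere(rec)
        assert [s.hemisphere for s in signals] == ["left"]

    def test_averaging_and_dc_removal_commute(self):
        rng = np.random.default_rng(2)
        rec = LfpRecording("t", 100.0, FULL_MONTAGE, rng.normal(size=(8, 500)) + 3.0, {})
        a = average_hemisphere(remove_dc(rec))
        # other order: average first, then demean the averaged trace
        b = average_hemisphere(rec)
        for sig_a, sig_b in zip(a, b):
            np.testing.assert_allclose(
                sig_a.data, sig_b.data - sig_b.data.mean(), atol=1e-9
            )


class TestSegmentation:
    def _signal(self, n_seconds, fs=1000.0):
        n = int(n_seconds * fs)
        return HemisphereSignal(
            "s", "left", fs, np.arange(n, dtype=float), {"PRE": (0, n)}
        )

    def test_60s_epoch_gives_60_segments(self):
        out = segment_epoch(self._signal(60.0), "PRE")
        assert out.segments.shape == (60, 1000)
        # contiguous non-overlapping rows from the epoch start
        np.testing.assert_allclose(out.segments.ravel(), np.arange(60000.0))

    def test_trailing_partial_segment_dropped(self):
        out = segment_epoch(self._signal(59.5), "PRE")
        assert out.segments.shape == (59, 1000)

    def test_epoch_shorter_than_segment_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            segment_epoch(self._signal(0.5), "PRE")

    def test_missing_epoch_label(self):
        with pytest.raises(KeyError, match="POST"):
            segment_epoch(self._signal(10.0), "POST")

    def test_trim_pulls_windows_off_boundaries(self):
        rec = LfpRecording(
            "t", 100.0, FULL_MONTAGE, np.zeros((8, 1000)),
            {"PRE": (0, 400), "POST": (600, 1000)},
        )
        out = trim_epoch_edges(rec, guard_seconds=1.0)
        assert out.epochs["PRE"] == (100, 400)
        assert out.epochs["POST"] == (600, 900)

    def test_trim_keeps_interior_windows(self):
        rec = LfpRecording(
            "t", 100.0, FULL_MONTAGE, np.zeros((8, 1000)), {"MID": (200, 700)}
        )
        assert trim_epoch_edges(rec).epochs["MID"] == (200, 700)


class TestQcAndChain:
    def test_qc_flags_loud_hemisphere(self):
        rng = np.random.default_rng(3)
        quiet = [
            LfpRecording("a", 100.0, FULL_MONTAGE, rng.normal(size=(8, 1000)), {}),
            LfpRecording("b", 100.0, FULL_MONTAGE, rng.normal(size=(8, 1000)), {}),
        ]
        loud_data = rng.normal(size=(8, 1000))
        loud_data[4:] *= 50.0
        loud = LfpRecording("c", 100.0, FULL_MONTAGE, loud_data, {})
        flagged = qc_screen_hemispheres(quiet + [loud])
        assert flagged == {"c": {"right"}}

    def test_chain_smoke_at_full_acquisition_rate(self):
        """5-s recording at the native 44 kHz survives the whole chain."""
        fs = 44000.0
        n = int(5 * fs)
        rng = np.random.default_rng(4)
        t = np.arange(n) / fs
        data = np.tile(np.sin(2 * np.pi * 20 * t), (8, 1)) + 0.1 * rng.normal(size=(8, n))
        rec = LfpRecording("t", fs, FULL_MONTAGE, data, {"PRE": (44000, 176000)})
        signals, prov = preprocess_recording(rec)
        assert {s.hemisphere for s in signals} == {"left", "right"}
        assert signals[0].fs == 1000.0
        assert signals[0].epochs["PRE"] == (1000, 4000)
        assert prov["steps"][0] == "decimate"

    def test_montage_error_on_missing_contact(self):
        with pytest.raises(MontageError):
            LfpRecording("t", 100.0, FULL_MONTAGE[:3], np.zeros((3, 100)), {})
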