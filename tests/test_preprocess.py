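"""Preprocessing contracts: montage, masking, resampling, filters, windows."""

import numpy as np
import pytest

from seegtc.preprocess import (
    average_reference,
    band_filter,
    drop_tc_channels_post,
    extract_windows,
    notch_power_line,
    preprocess_recording,
    reject_artifacts,
    resample_to_500,
)
from seegtc.signal import CANONICAL_BANDS, BandSpec, Recording


def _rec(data, fs=500.0, period="pre", names=None):
    data = np.asarray(data, dtype=float)
    names = names or [f"C{i}" for i in range(data.shape[0])]
    return Recording(data=data, fs=fs, channel_names=names, period=period,
                     patient_id="P01")


def _sine(freq, fs, dur):
    t = np.arange(int(dur * fs)) / fs
    return np.sin(2 * np.pi * freq * t)


class TestAverageReference:
    def test_mean_removal(self):
        rec = _rec([[1, 1, 1], [3, 3, 3]])
        out = average_reference(rec)
        np.testing.assert_allclose(out.data, [[-1, -1, -1], [1, 1, 1]])

    def test_column_sums_zero(self, tiny_recording):
        out = average_reference(tiny_recording)
        np.testing.assert_allclose(out.data.sum(axis=0), 0.0, atol=1e-9)

    def test_identical_channels_zero_out(self):
        rec = _rec([[2.0, -1.0, 4.0]] * 3)
        assert np.allclose(average_reference(rec).data, 0.0)

    def test_single_channel_errors(self):
        with pytest.raises(ValueError, match="2 channels"):
            average_reference(_rec([[1.0, 2.0]]))


class TestArtifactRejection:
    def test_empty_span_list_is_identity(self, tiny_recording):
        out = reject_artifacts(tiny_recording, [])
        np.testing.assert_array_equal(out.data, tiny_recording.data)
        assert out.artifact_spans == {}

    def test_aligned_span_removes_exactly_that_window(self, tiny_recording):
        rec = reject_artifacts(tiny_recording, [("A1", 10.0, 20.0)])
        ws = extract_windows(rec, CANONICAL_BANDS["low"], window_s=10.0,
                             total_s=30.0)
        assert ws.window_indices["A1"].tolist() == [0, 2]
        assert ws.window_indices["A2"].tolist() == [0, 1, 2]

    def test_fully_masked_channel_drops_out(self, tiny_recording):
        rec = reject_artifacts(tiny_recording, [("A1", 0.0, 1e6)])
        ws = extract_windows(rec, CANONICAL_BANDS["low"], window_s=10.0,
                             total_s=30.0)
        assert "A1" not in ws.windows and "A2" in ws.windows

    def test_overlapping_spans_merged(self, tiny_recording):
        rec = reject_artifacts(tiny_recording,
                               [("A1", 0.0, 5.0), ("A1", 4.0, 12.0)])
        assert rec.artifact_spans["A1"] == [(0.0, 12.0)]

    def test_unknown_channel_errors(self, tiny_recording):
        with pytest.raises(KeyError):
            reject_artifacts(tiny_recording, [("ZZ", 0.0, 1.0)])


class TestResampling:
    def test_1000hz_sine_preserved_at_500(self):
        fs = 1000.0
        rec = _rec(np.vstack([_sine(10, fs, 10.0)] * 2), fs=fs)
        out = resample_to_500(rec)
        assert out.fs == 500.0
        assert out.n_samples == 5000
        spec = np.abs(np.fft.rfft(out.data[0]))
        freqs = np.fft.rfftfreq(out.n_samples, 1 / 500.0)
        peak = freqs[spec.argmax()]
        assert peak == pytest.approx(10.0, abs=0.1)
        # amplitude of the dominant component within 1%
        amp = 2 * spec.max() / out.n_samples
        assert amp == pytest.approx(1.0, rel=0.01)

    def test_512hz_passthrough(self):
        rec = _rec(np.random.default_rng(0).standard_normal((2, 5120)),
                   fs=512.0)
        out = resample_to_500(rec)
        assert out.fs == 512.0
        np.testing.assert_array_equal(out.data, rec.data)

    def test_2000hz_constant_stays_constant(self):
        rec = _rec(np.ones((2, 20000)), fs=2000.0)
        out = resample_to_500(rec)
        inner = out.data[:, 100:-100]
        np.testing.assert_allclose(inner, 1.0, atol=1e-6)


class TestNotch:
    def test_power_line_attenuated_30db(self):
        rec = _rec(np.vstack([_sine(50, 500.0, 10.0)] * 2))
        out = notch_power_line(rec)
        # edge transients of the zero-phase filter excluded
        ratio = np.std(out.data[0][1000:-1000]) / np.std(rec.data[0][1000:-1000])
        assert ratio < 0.032

    def test_passband_preserved(self):
        rec = _rec(np.vstack([_sine(40, 500.0, 10.0)] * 2))
        out = notch_power_line(rec)
        ratio = np.std(out.data[0]) / np.std(rec.data[0])
        assert 0.9 < ratio < 1.1

    def test_white_noise_psd_dips_at_harmonics(self):
        from scipy.signal import welch

        rng = np.random.default_rng(1)
        rec = _rec(rng.standard_normal((2, 50000)))
        out = notch_power_line(rec)
        f, p = welch(out.data[0], fs=500.0, nperseg=4096)
        def level(freq):
            return p[np.abs(f - freq).argmin()]
        for notch_f in (50.0, 150.0):
            nearby = p[(np.abs(f - notch_f) > 5) & (np.abs(f - notch_f) < 15)]
            assert level(notch_f) < 0.2 * nearby.mean()


class TestBandFilter:
    @pytest.mark.parametrize("freq,band,passes", [
        (10, "low", True),
        (10, "ripple", False),
        (65, "high_gamma", True),
    ])
    def test_pass_and_stop_bands(self, freq, band, passes):
        rec = _rec(np.vstack([_sine(freq, 500.0, 10.0)] * 2))
        out = band_filter(rec, CANONICAL_BANDS[band])
        ratio = np.std(out.data[0][500:-500]) / np.std(rec.data[0][500:-500])
        if passes:
            assert ratio > 10 ** (-1 / 20)  # within 1 dB
        else:
            assert ratio < 10 ** (-20 / 20)  # >= 20 dB down

    def test_zero_phase(self):
        rec = _rec(np.vstack([_sine(10, 500.0, 10.0)] * 2))
        out = band_filter(rec, CANONICAL_BANDS["low"])
        xc = np.correlate(out.data[0][500:-500], rec.data[0][500:-500], "full")
        lag = xc.argmax() - (len(xc) // 2)
        assert lag == 0

    def test_band_above_nyquist_errors(self):
        rec = _rec(np.zeros((2, 1000)), fs=100.0)
        with pytest.raises(ValueError, match="ripple"):
            band_filter(rec, CANONICAL_BANDS["ripple"])

    def test_edge_at_nyquist_degrades_to_highpass(self):
        # ripple band at fs 500: upper edge 250 = Nyquist
        rec = _rec(np.vstack([_sine(100, 500.0, 10.0)] * 2))
        out = band_filter(rec, CANONICAL_BANDS["ripple"])
        ratio = np.std(out.data[0][500:-500]) / np.std(rec.data[0][500:-500])
        assert ratio > 10 ** (-1 / 20)


class TestWindows:
    def test_200s_gives_20_windows_of_5000(self):
        rec = _rec(np.zeros((2, int(200 * 500))), fs=500.0)
        ws = extract_windows(rec, CANONICAL_BANDS["low"])
        assert ws.windows["C0"].shape == (20, 5000)

    def test_trailing_seconds_ignored(self):
        rec = _rec(np.zeros((2, int(205 * 500))), fs=500.0)
        ws = extract_windows(rec, CANONICAL_BANDS["low"])
        assert ws.windows["C0"].shape == (20, 5000)
        assert ws.window_indices["C0"].tolist() == list(range(20))

    def test_insufficient_duration_yields_short_channel(self, caplog):
        rec = _rec(np.zeros((2, int(150 * 500))), fs=500.0)
        with caplog.at_level("WARNING"):
            ws = extract_windows(rec, CANONICAL_BANDS["low"])
        assert ws.windows["C0"].shape[0] == 15
        assert any("15/20" in m for m in caplog.messages)


class TestDropTC:
    def _contacts(self):
        import pandas as pd

        return pd.DataFrame({
            "patient_id": ["P01"] * 4,
            "channel_name": ["A1", "A2", "B1", "B2"],
            "electrode": ["A", "A", "B", "B"],
            "contact_index": [1, 2, 1, 2],
            "is_tc": [True, False, True, False],
        })

    def test_post_removes_tc_channels(self, tiny_recording):
        rec = tiny_recording.copy_with(period="post")
        out = drop_tc_channels_post(rec, self._contacts())
        assert out.channel_names == ["A2", "B2"]

    def test_pre_unchanged(self, tiny_recording):
        out = drop_tc_channels_post(tiny_recording, self._contacts())
        assert out.channel_names == tiny_recording.channel_names

    def test_missing_flagged_channel_errors(self, tiny_recording):
        contacts = self._contacts()
        contacts.loc[0, "channel_name"] = "ZZ"
        rec = tiny_recording.copy_with(period="post")
        with pytest.raises(ValueError, match="ZZ"):
            drop_tc_channels_post(rec, contacts)


class TestPipelineDeterminism:
    def test_rerun_bit_identical(self, tiny_recording):
        import pandas as pd

        contacts = pd.DataFrame({
            "patient_id": ["P01"] * 4,
            "channel_name": ["A1", "A2", "B1", "B2"],
            "electrode": ["A"] * 4, "contact_index": [1, 2, 3, 4],
            "is_tc": [False] * 4,
        })
        a = preprocess_recording(tiny_recording, contacts, window_s=2.0,
                                 total_s=10.0)
        b = preprocess_recording(tiny_recording, contacts, window_s=2.0,
                                 total_s=10.0)
        for band in a:
            for ch in a[band].windows:
                np.testing.assert_array_equal(a[band].windows[ch],
                                              b[band].windows[ch])
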